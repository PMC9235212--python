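"""End-to-end experiment orchestration: scenario grids, replicates, CV,
deregression and model-comparison statistics.

The four model specifications compared throughout are

* ``GCTA``      — single GRM, uniform SNP weights;
* ``LDAK``      — single GRM, LD weights;
* ``GCTA-LDS``  — one uniform GRM per LD level (five-level stratification);
* ``LDAK-LDS``  — one LD-weighted GRM per LD level.

Per replicate a trait is simulated on the shared genotype panel, individuals
are split 90/10 into training and validation, variance components are
re-estimated on the training set for every model, and GBLUP accuracy is the
Pearson correlation between predicted and true genetic values of the
validation individuals. Replicate seeds derive deterministically from
(master seed, scenario index, replicate index), so the full grid is
reproducible and replicates are paired across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .grm import GRMatrix, standardize
from .ld_metrics import LDProfile, ld_profile
from .mixed_model import aic, gblup_predict, reml_fit
from .panel import GenotypePanel
from .synthetic_data import (
    SimScenario,
    build_medium_panel,
    classify_tagging,
    select_causal,
    simulate_genotypes,
    simulate_phenotypes,
)

MODELS = ("GCTA", "LDAK", "GCTA-LDS", "LDAK-LDS")


# ---------------------------------------------------------------------------
# GRM factory with rank-k downdates for causal-SNP removal
# ---------------------------------------------------------------------------

class ModelGRMs:
    """Precomputes cross-products for the four model specs on one panel.

    Removing a replicate's causal SNPs from the panel only subtracts a
    rank-``k`` term from each cross-product, so per-replicate GRMs under
    ``remove_causal`` cost O(n²k) instead of O(n²m).
    """

    def __init__(self, panel: GenotypePanel, profile: LDProfile | None = None,
                 n_groups: int = 5):
        self.panel = panel
        self.profile = profile if profile is not None else ld_profile(panel, n_groups=n_groups)
        self.x = standardize(panel)
        self.w_raw = self.profile.ldak_weight
        self.levels = self.profile.ld_level
        ids = panel.individual_ids
        self._ids = ids

        self._s_uniform = {None: self.x @ self.x.T}
        self._s_ldak = {None: (self.x * self.w_raw) @ self.x.T}
        self._level_idx = {}
        for lev in np.unique(self.levels):
            idx = np.where(self.levels == lev)[0]
            self._level_idx[int(lev)] = idx
            x_t = self.x[:, idx]
            self._s_uniform[int(lev)] = x_t @ x_t.T
            self._s_ldak[int(lev)] = (x_t * self.w_raw[idx]) @ x_t.T

    def _one(self, kind: str, level: int | None, drop: np.ndarray | None) -> GRMatrix:
        if level is None:
            idx = np.arange(self.panel.n_snps)
        else:
            idx = self._level_idx[level]
        drop_here = (
            np.intersect1d(drop, idx) if drop is not None else np.empty(0, dtype=int)
        )
        label = "all" if level is None else f"ld_level {level}"
        if kind == "uniform":
            s = self._s_uniform[level]
            n_snps = len(idx) - len(drop_here)
            if n_snps <= 0:
                raise ValueError(f"no SNPs left in component {label}")
            if len(drop_here):
                xc = self.x[:, drop_here]
                s = s - xc @ xc.T
            g = s / n_snps
        else:
            s = self._s_ldak[level]
            keep_mask = np.ones(self.panel.n_snps, dtype=bool)
            if drop is not None:
                keep_mask[drop] = False
            w_sum = self.w_raw[idx[keep_mask[idx]]].sum()
            n_snps = int(keep_mask[idx].sum())
            if n_snps <= 0 or w_sum <= 0:
                raise ValueError(f"no weighted SNPs left in component {label}")
            if len(drop_here):
                xc = self.x[:, drop_here]
                s = s - (xc * self.w_raw[drop_here]) @ xc.T
            # G = X W* X' / N with w* rescaled so sum(w*) = N  =>  S_raw / sum(w_raw)
            g = s / w_sum
        g = (g + g.T) / 2.0
        return GRMatrix(g, n_snps, self._ids,
                        weighting=kind if kind == "uniform" else "ldak", label=label)

    def for_model(self, model: str, drop_causal: np.ndarray | None = None) -> list[GRMatrix]:
        """GRM list for one model spec, optionally excluding causal SNPs."""
        if model == "GCTA":
            return [self._one("uniform", None, drop_causal)]
        if model == "LDAK":
            return [self._one("ldak", None, drop_causal)]
        if model == "GCTA-LDS":
            return [self._one("uniform", lev, drop_causal) for lev in sorted(self._level_idx)]
        if model == "LDAK-LDS":
            return [self._one("ldak", lev, drop_causal) for lev in sorted(self._level_idx)]
        raise ValueError(f"unknown model {model!r}")


def subset_grms(grms: list[GRMatrix], idx: np.ndarray) -> list[GRMatrix]:
    return [
        GRMatrix(g.values[np.ix_(idx, idx)], g.n_snps, g.individual_ids[idx],
                 g.weighting, g.label)
        for g in grms
    ]


# ---------------------------------------------------------------------------
# Simulation grid
# ---------------------------------------------------------------------------

def _fit_and_predict(grms, y, tbv, train_idx, val_idx):
    fit = reml_fit(y[train_idx], subset_grms(grms, train_idx))
    pred = gblup_predict(fit, grms, y[train_idx], train_idx, val_idx,
                         reference=tbv[val_idx])
    return fit, pred


def run_simulation_grid(
    scenarios: list[SimScenario],
    n_replicates: int = 30,
    panel: GenotypePanel | None = None,
    panel_kwargs: dict | None = None,
    master_seed: int = 0,
    models: tuple[str, ...] = MODELS,
    n_groups: int = 5,
    train_fraction: float = 0.9,
    fresh_genotypes: bool = False,
) -> pd.DataFrame:
    """Run every scenario × model × replicate and tabulate the outcomes.

    Genotypes are simulated once (or supplied) and reused across scenarios
    and replicates — fresh traits and train/validation splits per replicate —
    unless ``fresh_genotypes`` asks for a new panel per replicate. Returns a
    long-format table with one row per (scenario, model, replicate) carrying
    accuracy, total and per-component ĥ², AIC, and the seed trail.
    """
    rows = []
    shared: tuple[GenotypePanel, ModelGRMs, dict] | None = None
    if panel is None and not fresh_genotypes:
        panel = simulate_genotypes(seed=master_seed, **(panel_kwargs or {}))
    for s_i, scen in enumerate(scenarios):
        for rep in range(n_replicates):
            rng = np.random.default_rng([master_seed, s_i, rep])
            try:
                if fresh_genotypes:
                    shared = None
                    rep_panel = simulate_genotypes(seed=int(rng.integers(2**31)),
                                                   **(panel_kwargs or {}))
                else:
                    rep_panel = panel
                if shared is None or shared[0] is not rep_panel:
                    builder = ModelGRMs(rep_panel, n_groups=n_groups)
                    tagging = classify_tagging(rep_panel, builder.profile.ld_score)
                    shared = (rep_panel, builder, tagging)
                rep_panel, builder, tagging = shared

                causal = select_causal(rep_panel, tagging, scen.tagging_class,
                                       scen.n_causal, rng)
                trait = simulate_phenotypes(rep_panel, causal, scen.h2,
                                            scen.var_p, rng)
                n = rep_panel.n_individuals
                perm = rng.permutation(n)
                n_train = int(round(train_fraction * n))
                train_idx, val_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
                drop = causal if scen.remove_causal_from_panel else None

                for model in models:
                    grms = builder.for_model(model, drop_causal=drop)
                    fit, pred = _fit_and_predict(grms, trait.phenotype, trait.tbv,
                                                 train_idx, val_idx)
                    rows.append({
                        "scenario": scen.tagging_class,
                        "h2_true": scen.h2,
                        "model": model,
                        "replicate": rep,
                        "accuracy": pred.accuracy,
                        "h2_total": fit.h2_total,
                        "h2_components": tuple(fit.h2_components),
                        "aic": aic(fit),
                        "converged": fit.converged,
                        "error": "",
                    })
            except Exception as exc:  # record and continue the grid
                rows.append({
                    "scenario": scen.tagging_class, "h2_true": scen.h2,
                    "model": "", "replicate": rep, "accuracy": np.nan,
                    "h2_total": np.nan, "h2_components": (), "aic": np.nan,
                    "converged": False, "error": f"{type(exc).__name__}: {exc}",
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validation (real-trait mode)
# ---------------------------------------------------------------------------

def cross_validate(
    grms: list[GRMatrix],
    phenotypes: np.ndarray,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated k-fold cross-validated GBLUP accuracy.

    Fold assignment is random (no stratification), repeated ``n_repeats``
    times. Variance components are re-estimated within each training fold.
    Accuracy per fold is the Pearson correlation between GEBV and the
    held-out phenotypes (for deregressed EBV this is the realised predictive
    correlation, not corrected for reliability).
    """
    y = np.asarray(phenotypes, dtype=float)
    n = len(y)
    if grms[0].n != n:
        raise ValueError("phenotype length does not match GRM order")
    if n < n_folds:
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(seed)
    rows = []
    for repeat in range(n_repeats):
        assignment = rng.permutation(np.arange(n) % n_folds)
        for fold in range(n_folds):
            val_idx = np.where(assignment == fold)[0]
            if len(val_idx) < 3:
                raise ValueError(f"fold {fold} has fewer than 3 individuals")
            train_idx = np.where(assignment != fold)[0]
            fit = reml_fit(y[train_idx], subset_grms(grms, train_idx))
            pred = gblup_predict(fit, grms, y[train_idx], train_idx, val_idx,
                                 reference=y[val_idx], reference_kind="phenotype")
            rows.append({"repeat": repeat, "fold": fold, "accuracy": pred.accuracy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deregression of EBV
# ---------------------------------------------------------------------------

def deregress(ebv: pd.DataFrame) -> pd.DataFrame:
    """Deregress EBV: standardize to mean 0 / variance 1, then divide by r².

    Expects columns ``individual_id``, ``value`` (EBV) and ``reliability``
    (r² ∈ (0, 1]). Deregression removes the shrinkage of the EBV so it can
    serve as a pseudo-phenotype; heterogeneous reliabilities inflate the
    variance above 1.
    """
    if "reliability" not in ebv.columns:
        raise ValueError("deregression requires a reliability column")
    r2 = ebv["reliability"].to_numpy(dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    g = ebv["value"].to_numpy(dtype=float)
    g_std = (g - g.mean()) / g.std()
    out = ebv.copy()
    out["value"] = g_std / r2
    return out


# ---------------------------------------------------------------------------
# Model comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """ANOVA + Bonferroni-adjusted paired t-tests across models for one metric."""

    metric: str
    means: pd.Series
    sds: pd.Series
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def _sig_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_models(table: pd.DataFrame, metric: str = "accuracy",
                   anova_alpha: float = 0.05) -> ComparisonReport:
    """One-way ANOVA across models; if significant, Bonferroni paired t-tests.

    Replicates must be paired across models (same replicate indices, i.e.
    same seeds). The Bonferroni factor is the number of model pairs; adjusted
    p-values are clipped at 1.
    """
    models = sorted(table["model"].unique())
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    wide = table.pivot(index="replicate", columns="model", values=metric)
    if wide.isna().any().any():
        raise ValueError("replicates are not paired across models")
    if len(wide) < 3:
        raise ValueError("need at least 3 replicates")

    groups = [wide[m].to_numpy() for m in models]
    if np.allclose(np.var([g.mean() for g in groups]), 0) and all(
        np.allclose(g, groups[0]) for g in groups
    ):
        anova_f, anova_p = 0.0, 1.0
    else:
        anova_f, anova_p = stats.f_oneway(*groups)
        if np.isnan(anova_p):
            anova_f, anova_p = 0.0, 1.0

    pairwise_rows = []
    if anova_p < anova_alpha:
        n_pairs = len(models) * (len(models) - 1) // 2
        for a, b in combinations(models, 2):
            diff = wide[a].to_numpy() - wide[b].to_numpy()
            degenerate = np.allclose(diff.std(ddof=1), 0.0)
            if degenerate:
                # zero within-pair variance: t undefined; a nonzero constant
                # shift is detected with certainty
                p_raw = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
                t_stat = np.inf * np.sign(diff.mean()) if p_raw == 0.0 else 0.0
            else:
                t_stat, p_raw = stats.ttest_rel(wide[a], wide[b])
            p_adj = min(1.0, p_raw * n_pairs)
            pairwise_rows.append({
                "model_a": a, "model_b": b, "t": float(t_stat),
                "p_raw": float(p_raw), "p_adj": float(p_adj),
                "significance": _sig_code(p_adj), "degenerate": degenerate,
            })
    return ComparisonReport(
        metric=metric,
        means=wide.mean(),
        sds=wide.std(ddof=1),
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        pairwise=pd.DataFrame(pairwise_rows),
    )


# ---------------------------------------------------------------------------
# Panel-density comparison
# ---------------------------------------------------------------------------

def density_comparison(
    panel_high: GenotypePanel,
    medium_target: int,
    tagging_class: str = "weak",
    n_causal: int = 100,
    h2: float = 0.8,
    var_p: float = 1.0,
    n_replicates: int = 30,
    master_seed: int = 0,
    models: tuple[str, ...] = ("GCTA",),
    n_groups: int = 5,
    train_fraction: float = 0.9,
) -> pd.DataFrame:
    """Paired high- vs medium-density evaluation of the same simulated traits.

    The medium panel takes evenly distributed SNPs from the high panel.
    Causal variants are selected on the high panel (so the trait is identical
    under both densities) and removed from both panels before GRMs are
    built. Returns a long table with a ``density`` column, replicate-paired.
    """
    if medium_target > panel_high.n_snps:
        raise ValueError("medium panel larger than high panel")
    panel_medium = build_medium_panel(panel_high, medium_target)

    builders = {"high": ModelGRMs(panel_high, n_groups=n_groups),
                "medium": ModelGRMs(panel_medium, n_groups=n_groups)}
    tagging = classify_tagging(panel_high, builders["high"].profile.ld_score)
    medium_ids = set(panel_medium.snp_ids.tolist())
    med_pos = {sid: i for i, sid in enumerate(panel_medium.snp_ids)}

    rows = []
    n = panel_high.n_individuals
    for rep in range(n_replicates):
        rng = np.random.default_rng([master_seed, 777, rep])
        causal = select_causal(panel_high, tagging, tagging_class, n_causal, rng)
        trait = simulate_phenotypes(panel_high, causal, h2, var_p, rng)
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        train_idx, val_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        causal_ids = panel_high.snp_ids[causal]
        drops = {
            "high": causal,
            "medium": np.array(
                [med_pos[sid] for sid in causal_ids if sid in medium_ids], dtype=int
            ),
        }
        for density in ("high", "medium"):
            for model in models:
                grms = builders[density].for_model(model, drop_causal=drops[density])
                fit, pred = _fit_and_predict(grms, trait.phenotype, trait.tbv,
                                             train_idx, val_idx)
                rows.append({
                    "density": density, "model": model, "replicate": rep,
                    "scenario": tagging_class, "accuracy": pred.accuracy,
                    "h2_total": fit.h2_total, "aic": aic(fit),
                    "converged": fit.converged,
                })
    return pd.DataFrame(rows)
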