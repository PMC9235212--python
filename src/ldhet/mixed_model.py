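"""GREML variance-component estimation and GBLUP prediction.

Fits the linear mixed model

    y = 1·μ + Σ_t g_t + e,   g_t ~ N(0, G_t σ²_t),   e ~ N(0, I σ²_e),

by restricted maximum likelihood: four expectation–maximisation (EM) burn-in
updates followed by average-information (AI) Newton steps until the change
in restricted log-likelihood falls below tolerance. An AI step that would
decrease the restricted likelihood is replaced by an EM step, so the
likelihood is non-decreasing after burn-in; variance components whose
updates go negative are pinned to a small positive boundary. With a single
relationship matrix this is the classical single-component GREML; with one
matrix per LD level it is the LD-stratified multi-component model (no
covariances between component effects).

Genomic prediction for individuals without phenotypes uses the conditional
mean of their genetic values given the training phenotypes:
GEBV_val = C_vt · V_tt⁻¹ · (y_train − μ̂), where V_tt is the phenotypic
covariance among training individuals and C_vt the genetic covariance
between validation and training individuals under the fitted components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .grm import GRMatrix


@dataclass
class VarianceFit:
    """Converged (or best-effort) REML solution."""

    variances: np.ndarray          # genetic variances, one per component
    residual: float
    mu: float
    loglik: float                  # restricted log-likelihood at the optimum
    h2_components: np.ndarray
    h2_total: float
    n_iter: int
    converged: bool
    component_labels: list[str] = field(default_factory=list)
    se_variances: np.ndarray | None = None
    se_h2_total: float | None = None

    @property
    def n_components(self) -> int:
        return len(self.variances)


def _check_aligned(grms: list[GRMatrix]) -> np.ndarray:
    ids = grms[0].individual_ids
    for g in grms[1:]:
        if len(g.individual_ids) != len(ids) or np.any(g.individual_ids != ids):
            raise ValueError("all GRMs must cover the same individuals in the same order")
    return ids


def _reml_quantities(y, x_fix, mats, theta):
    """P-matrix machinery shared by the REML iterations.

    Returns (logL, P, Py, trPG list, ytPGPy list, GPy columns).
    """
    n = len(y)
    v = np.zeros((n, n))
    for g_i, th in zip(mats, theta):
        v += th * g_i
    try:
        cf = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular phenotypic covariance: {exc}") from exc
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    vix = vinv @ x_fix                       # n × 1
    xtvix = float((x_fix * vix).sum())
    p = vinv - np.outer(vix[:, 0], vix[:, 0]) / xtvix
    py = p @ y
    loglik = -0.5 * (logdet_v + np.log(xtvix) + float(y @ py))
    tr_pg = [float(np.sum(p * g_i)) for g_i in mats]
    gpy = np.column_stack([g_i @ py for g_i in mats])
    yt_pgpy = [float(py @ gpy[:, i]) for i in range(len(mats))]
    return loglik, p, py, tr_pg, yt_pgpy, gpy, vinv, xtvix


def reml_fit(
    y: np.ndarray,
    grms: list[GRMatrix] | GRMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_em_burnin: int = 4,
    verbose: bool = False,
) -> VarianceFit:
    """AI-REML fit of variance components for one or more GRMs.

    ``y`` must be aligned with the GRMs' individual order (one record per
    individual; the only fixed effect is an intercept). Returns a
    :class:`VarianceFit`; non-convergence is flagged, not raised.
    """
    if isinstance(grms, GRMatrix):
        grms = [grms]
    _check_aligned(grms)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_comp = len(grms)
    if grms[0].n != n:
        raise ValueError("phenotype length does not match GRM order")
    if n < n_comp + 2:
        raise ValueError("too few individuals for the number of components")

    mats = [g.values for g in grms] + [np.eye(n)]
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * var_y
    # start: half the variance in the residual, the rest split evenly
    theta = np.full(n_comp + 1, 0.5 * var_y / n_comp)
    theta[-1] = 0.5 * var_y
    x_fix = np.ones((n, 1))

    converged = False
    ai_inv = None
    it = 0
    quant = _reml_quantities(y, x_fix, mats, theta)
    loglik = quant[0]
    for it in range(1, max_iter + 1):
        _, p, py, tr_pg, yt_pgpy, gpy, _vinv, _ = quant
        score = -0.5 * (np.array(tr_pg) - np.array(yt_pgpy))
        em_theta = np.maximum(
            theta + theta**2 * (np.array(yt_pgpy) - np.array(tr_pg)) / n, floor
        )
        use_em = it <= n_em_burnin
        new_theta = new_quant = None
        if not use_em:
            pgpy = p @ gpy
            ai = 0.5 * (gpy.T @ pgpy)
            # components stuck at the boundary with an inward-pointing score
            # are held there and dropped from the Newton system
            free = ~((theta <= floor * 1.01) & (score < 0.0))
            if not free.any():
                free[:] = True
            try:
                step = np.zeros_like(theta)
                step[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
                for _half in range(4):  # step halving on likelihood decrease
                    cand = np.maximum(theta + step, floor)
                    cand_quant = _reml_quantities(y, x_fix, mats, cand)
                    if cand_quant[0] >= loglik - 1e-10:
                        new_theta, new_quant = cand, cand_quant
                        ai_inv = np.linalg.pinv(ai)
                        break
                    step *= 0.5
                else:
                    use_em = True  # AI direction failed even after halving
            except np.linalg.LinAlgError:
                use_em = True
        if use_em:
            new_theta = em_theta
            new_quant = _reml_quantities(y, x_fix, mats, new_theta)
        if verbose:
            print(f"iter {it}: logL={new_quant[0]:.6f} theta={new_theta}")
        delta = new_quant[0] - loglik
        theta, quant, loglik = new_theta, new_quant, new_quant[0]
        if abs(delta) < tol:
            converged = True
            break

    # final quantities at the optimum
    _, _p, _py, _tr, _yq, _gpy, vinv, xtvix = quant
    mu = float((vinv @ y).sum() / xtvix)
    var_g = theta[:-1]
    var_e = float(theta[-1])
    # per-component phenotypic-variance contribution is σ²_t · tr(G_t)/n,
    # which makes h² invariant to the overall scaling of any GRM; for
    # standard GRMs tr(G)/n ≈ 1 and this reduces to σ²_t directly
    diag_scale = np.array([np.trace(g.values) / n for g in grms])
    contrib = var_g * diag_scale
    total = contrib.sum() + var_e
    h2_comp = contrib / total
    h2_total = float(contrib.sum() / total)

    se_var = se_h2 = None
    if ai_inv is not None:
        se_var = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
        # delta method for h2_total = sum(d_t·var_g_t) / total
        grad = np.empty(n_comp + 1)
        grad[:n_comp] = diag_scale * var_e / total**2
        grad[-1] = -contrib.sum() / total**2
        se_h2 = float(np.sqrt(max(grad @ ai_inv @ grad, 0.0)))

    return VarianceFit(
        variances=var_g.copy(),
        residual=var_e,
        mu=mu,
        loglik=float(loglik),
        h2_components=h2_comp,
        h2_total=h2_total,
        n_iter=it,
        converged=converged,
        component_labels=[g.label for g in grms],
        se_variances=se_var[:n_comp] if se_var is not None else None,
        se_h2_total=se_h2,
    )


def restricted_loglik(y: np.ndarray, grms: list[GRMatrix], variances: np.ndarray,
                      residual: float) -> float:
    """Restricted log-likelihood at given variance components (intercept only)."""
    y = np.asarray(y, dtype=float)
    mats = [g.values for g in grms] + [np.eye(len(y))]
    theta = np.append(np.asarray(variances, dtype=float), residual)
    return _reml_quantities(y, np.ones((len(y), 1)), mats, theta)[0]


def aic(fit: VarianceFit) -> float:
    """Akaike information criterion, −2·logL_restricted + 2·k.

    k counts the variance parameters (T genetic + 1 residual); the intercept
    is conditioned out by REML. Only AIC differences between models fitted to
    the same data are meaningful.
    """
    return -2.0 * fit.loglik + 2.0 * (fit.n_components + 1)


def heritability_enrichment(fit: VarianceFit, snps_per_group: np.ndarray) -> np.ndarray:
    """Per-group genetic-variance share divided by SNP share.

    enrichment_t = (σ²_t / Σ_u σ²_u) / (m_t / m_total); 1 everywhere means the
    genetic variance is spread in proportion to SNP counts.
    """
    if fit.n_components < 2:
        raise ValueError("enrichment needs at least 2 components")
    m = np.asarray(snps_per_group, dtype=float)
    if len(m) != fit.n_components:
        raise ValueError("snps_per_group length mismatch")
    total = fit.variances.sum()
    if total <= 0:
        raise ValueError("all genetic variances are zero")
    share = fit.variances / total
    return share / (m / m.sum())


@dataclass
class PredictionResult:
    """GEBV for validation individuals plus the realised accuracy."""

    gebv: np.ndarray
    validation_ids: np.ndarray
    accuracy: float
    reference_kind: str = "true_genetic_value"


def gblup_predict(
    fit: VarianceFit,
    grms: list[GRMatrix] | GRMatrix,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    reference: np.ndarray | None = None,
    reference_kind: str = "true_genetic_value",
) -> PredictionResult:
    """Predict genetic values of validation individuals by GBLUP.

    ``grms`` must cover train ∪ validation individuals; ``train_idx`` /
    ``val_idx`` index rows of the GRMs. ``reference`` (e.g. true genetic
    values or deregressed EBV of the validation individuals) is optional;
    when given, accuracy is its Pearson correlation with the GEBV.
    """
    if isinstance(grms, GRMatrix):
        grms = [grms]
    ids = _check_aligned(grms)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    y_train = np.asarray(y_train, dtype=float)
    if len(y_train) != len(train_idx):
        raise ValueError("y_train length must match train_idx")
    if val_idx.max(initial=-1) >= len(ids) or train_idx.max(initial=-1) >= len(ids):
        raise ValueError("index outside GRM")

    n_t = len(train_idx)
    v_tt = fit.residual * np.eye(n_t)
    c_vt = np.zeros((len(val_idx), n_t))
    for g, s2 in zip(grms, fit.variances):
        sub = g.values[np.ix_(train_idx, train_idx)]
        v_tt += s2 * sub
        c_vt += s2 * g.values[np.ix_(val_idx, train_idx)]
    cf = linalg.cho_factor(v_tt, lower=True, check_finite=False)
    vi_y = linalg.cho_solve(cf, y_train, check_finite=False)
    vi_1 = linalg.cho_solve(cf, np.ones(n_t), check_finite=False)
    mu = float(np.sum(vi_y) / np.sum(vi_1))  # GLS intercept on the training data
    gebv = c_vt @ linalg.cho_solve(cf, y_train - mu, check_finite=False)

    accuracy = np.nan
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if len(reference) != len(val_idx):
            raise ValueError("reference length must match val_idx")
        accuracy = float(np.corrcoef(gebv, reference)[0, 1])
    return PredictionResult(
        gebv=gebv,
        validation_ids=ids[val_idx],
        accuracy=accuracy,
        reference_kind=reference_kind,
    )
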