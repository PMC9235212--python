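"""Genotype simulator LD structure, tagging classes, and trait calibration."""

import numpy as np
import pytest

import ldhet
from ldhet.synthetic_data import (
    build_medium_panel,
    classify_tagging,
    drop_causal,
    select_causal,
    simulate_genotypes,
    simulate_phenotypes,
)
from .conftest import make_panel


def _adjacent_dosage_r2(panel):
    x = panel.dosages - panel.dosages.mean(axis=0)
    x /= x.std(axis=0)
    r = (x[:, :-1] * x[:, 1:]).mean(axis=0)
    same_chrom = panel.chromosomes[:-1] == panel.chromosomes[1:]
    return (r * r)[same_chrom]


class TestSimulateGenotypes:
    def test_determinism(self):
        a = simulate_genotypes(n_individuals=50, n_snps=200, n_chromosomes=2,
                               chrom_length=2_000_000, seed=9)
        b = simulate_genotypes(n_individuals=50, n_snps=200, n_chromosomes=2,
                               chrom_length=2_000_000, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_zero_correlation_gives_null_adjacent_r2(self):
        n = 4000
        panel = simulate_genotypes(n_individuals=n, n_snps=150, n_chromosomes=1,
                                   chrom_length=10_000_000,
                                   within_block_corr_range=(0.0, 0.0),
                                   maf_range=(0.2, 0.5), seed=11)
        r2 = _adjacent_dosage_r2(panel)
        # under independence E[r²] ≈ 1/(n−1)
        assert r2.mean() == pytest.approx(1.0 / (n - 1), rel=0.5)

    def test_high_block_correlation_gives_r2_near_rho_squared(self):
        """One long high-ρ block: adjacent dosage r² concentrates near ρ²,
        cross-checked against a Monte-Carlo evaluation of the haplotype-chain
        correlation → dosage-r² relation."""
        rho, n = 0.95, 20_000
        # Monte Carlo oracle: simulate the two-state chain directly
        rng = np.random.default_rng(123)
        p = 0.3
        h1 = rng.random(n) < p
        nxt = np.where(h1, p + rho * (1 - p), p * (1 - rho))
        h2 = rng.random(n) < nxt
        g1 = h1[: n // 2].astype(float) + h1[n // 2:]
        g2 = h2[: n // 2].astype(float) + h2[n // 2:]
        oracle_r2 = np.corrcoef(g1, g2)[0, 1] ** 2
        assert oracle_r2 == pytest.approx(rho**2, abs=0.02)

        panel = simulate_genotypes(n_individuals=n, n_snps=40, n_chromosomes=1,
                                   chrom_length=1_000_000,
                                   block_length_range=(1_000_000, 1_000_000),
                                   within_block_corr_range=(rho, rho),
                                   rho_jitter=0.0,
                                   maf_range=(0.2, 0.5), seed=21)
        r2 = _adjacent_dosage_r2(panel)
        assert r2.mean() == pytest.approx(rho**2, abs=0.03)

    def test_regional_ld_heterogeneity_severalfold(self):
        # needs enough 1–5 Mb LD regions and enough individuals that the
        # null-r² noise floor (~window count / n) does not compress the ratio
        panel = simulate_genotypes(n_individuals=800, n_snps=4000, n_chromosomes=3,
                                   chrom_length=25_000_000, seed=55)
        scores = ldhet.snp_ld_score(panel)
        regional = ldhet.regional_mean_ld_score(panel, scores)
        q90, q10 = np.percentile(regional, [90, 10])
        assert q90 / q10 >= 3.0

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ValueError):
            simulate_genotypes(n_snps=10, chrom_length=0)
        with pytest.raises(ValueError):
            simulate_genotypes(within_block_corr_range=(0.5, 1.0))


class TestClassifyTagging:
    def test_quantile_counts_10_snps(self):
        panel = make_panel(np.random.default_rng(0).integers(0, 3, (8, 10)).astype(float))
        classes = classify_tagging(panel, np.arange(10, dtype=float))
        assert len(classes["very_weak"]) == 2
        assert len(classes["weak"]) == 4
        assert len(classes["strong"]) == 4
        assert len(classes["very_strong"]) == 2
        assert len(classes["average"]) == 10

    def test_scores_1_to_100_against_direct_sort(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(np.arange(1.0, 101.0))
        panel = make_panel(rng.integers(0, 3, (5, 100)).astype(float))
        classes = classify_tagging(panel, scores)
        assert set(scores[classes["weak"]]) == set(range(1, 41))
        assert set(scores[classes["very_strong"]]) == set(range(81, 101))
        assert set(scores[classes["very_weak"]]) <= set(scores[classes["weak"]])

    def test_ties_broken_by_position_order(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.integers(0, 3, (5, 10)).astype(float))
        classes = classify_tagging(panel, np.ones(10))
        assert len(classes["very_weak"]) == 2
        np.testing.assert_array_equal(classes["very_weak"], [0, 1])
        np.testing.assert_array_equal(classes["very_strong"], [8, 9])

    def test_too_few_snps_raise(self):
        panel = make_panel(np.zeros((3, 4)) + np.arange(4) % 3)
        with pytest.raises(ValueError):
            classify_tagging(panel, np.arange(4.0))


class TestSelectCausal:
    def test_sampled_within_class(self, small_panel):
        scores = ldhet.snp_ld_score(small_panel)
        classes = classify_tagging(small_panel, scores)
        causal = select_causal(small_panel, classes, "weak", 100, seed=3)
        assert len(causal) == 100
        assert len(np.unique(causal)) == 100
        assert np.isin(causal, classes["weak"]).all()

    def test_whole_class_when_m_equals_size(self, small_panel):
        scores = ldhet.snp_ld_score(small_panel)
        classes = classify_tagging(small_panel, scores)
        k = len(classes["very_weak"])
        causal = select_causal(small_panel, classes, "very_weak", k, seed=99)
        np.testing.assert_array_equal(causal, classes["very_weak"])

    def test_seed_overlap_near_hypergeometric_expectation(self, small_panel):
        """Two independent draws of m from a class of size K overlap by ≈ m²/K."""
        scores = ldhet.snp_ld_score(small_panel)
        classes = classify_tagging(small_panel, scores)
        pool = len(classes["weak"])  # 240
        m = 100
        overlaps = [
            len(np.intersect1d(
                select_causal(small_panel, classes, "weak", m, seed=2 * s),
                select_causal(small_panel, classes, "weak", m, seed=2 * s + 1),
            ))
            for s in range(40)
        ]
        assert np.mean(overlaps) == pytest.approx(m * m / pool, rel=0.1)

    def test_m_exceeding_class_raises(self, small_panel):
        scores = ldhet.snp_ld_score(small_panel)
        classes = classify_tagging(small_panel, scores)
        with pytest.raises(ValueError):
            select_causal(small_panel, classes, "very_weak",
                          len(classes["very_weak"]) + 1, seed=0)


class TestSimulatePhenotypes:
    def test_zero_noise_limit(self, small_panel):
        trait = simulate_phenotypes(small_panel, np.arange(10), h2=1.0, seed=0)
        np.testing.assert_allclose(trait.phenotype, trait.tbv, atol=1e-12)

    def test_single_causal_effect_closed_form(self):
        """p=0.5, h²=0.8, δ_p²=1 → |a| = sqrt(1.6) ≈ 1.2649."""
        dos = np.tile([0.0, 1.0, 2.0, 1.0], 25)[:, None]
        panel = make_panel(dos)
        assert panel.allele_freq[0] == 0.5
        trait = simulate_phenotypes(panel, [0], h2=0.8, var_p=1.0, seed=1,
                                    random_signs=False)
        assert trait.effects[0] == pytest.approx((2 * 0.5 * 0.5) ** -0.5 * np.sqrt(0.8))
        assert trait.effects[0] == pytest.approx(np.sqrt(1.6), abs=1e-9)

    def test_equal_per_causal_contributions(self, small_panel):
        trait = simulate_phenotypes(small_panel, np.arange(0, 200, 2), h2=0.8, seed=5)
        p = small_panel.allele_freq[trait.causal_indices]
        contrib = 2 * p * (1 - p) * trait.effects**2
        np.testing.assert_allclose(contrib, 0.8 / 100, rtol=1e-10)

    def test_monomorphic_causal_raises(self):
        panel = make_panel(np.column_stack([np.full(10, 2.0), np.tile([0.0, 1.0], 5)]))
        with pytest.raises(ValueError, match="monomorphic"):
            simulate_phenotypes(panel, [0], h2=0.5, seed=0)

    def test_phenotypic_variance_calibrated(self):
        """var(y) ≈ δ_p² at n=5000 with causal variants in low-LD regions."""
        panel = simulate_genotypes(n_individuals=5000, n_snps=600, n_chromosomes=2,
                                   chrom_length=30_000_000,
                                   within_block_corr_range=(0.0, 0.3),
                                   maf_range=(0.1, 0.5), seed=77)
        rng = np.random.default_rng(8)
        vars_y = []
        for _ in range(5):
            causal = np.sort(rng.choice(panel.n_snps, 100, replace=False))
            trait = simulate_phenotypes(panel, causal, h2=0.8, var_p=1.0, seed=rng)
            vars_y.append(trait.phenotype.var())
        assert np.mean(vars_y) == pytest.approx(1.0, abs=0.05)


class TestPanelManipulation:
    def test_medium_panel_identity_when_target_is_full(self, small_panel):
        medium = build_medium_panel(small_panel, small_panel.n_snps)
        np.testing.assert_array_equal(medium.snp_ids, small_panel.snp_ids)

    def test_medium_panel_stride_on_single_chromosome(self):
        rng = np.random.default_rng(3)
        panel = make_panel(rng.integers(0, 3, (4, 100)).astype(float))
        medium = build_medium_panel(panel, 10)
        np.testing.assert_array_equal(
            [int(s[1:]) for s in medium.snp_ids], np.arange(0, 100, 10)
        )

    def test_medium_panel_proportional_allocation(self, small_panel):
        medium = build_medium_panel(small_panel, 120)
        assert medium.n_snps == 120
        _, counts_full = np.unique(small_panel.chromosomes, return_counts=True)
        _, counts_med = np.unique(medium.chromosomes, return_counts=True)
        expected = counts_full * 120 / small_panel.n_snps
        assert np.abs(counts_med - expected).max() <= 1

    def test_drop_causal_counts_and_identity(self, small_panel):
        dropped = drop_causal(small_panel, np.arange(100))
        assert dropped.n_snps == small_panel.n_snps - 100
        same = drop_causal(small_panel, np.array([], dtype=int))
        np.testing.assert_array_equal(same.snp_ids, small_panel.snp_ids)
        with pytest.raises(IndexError):
            drop_causal(small_panel, np.array([small_panel.n_snps]))

    def test_drop_causal_changes_grm(self, small_panel):
        from ldhet import grm_gcta, standardize
        g_full = grm_gcta(standardize(small_panel))
        dropped = drop_causal(small_panel, np.arange(50))
        g_drop = grm_gcta(standardize(dropped))
        assert not np.allclose(g_full.values, g_drop.values)
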