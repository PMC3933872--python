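"""Genotype/pathway simulators and the scenario truth machinery."""

import numpy as np
import pytest
from scipy import stats

from pathbayes.synthetic_data import (
    GenotypeSimParams,
    PathwaySimParams,
    ScenarioParams,
    make_scenario,
    simulate_genotypes,
    simulate_pathways,
    simulate_phenotypes,
    simulate_study,
)


class TestSimulateGenotypes:
    def test_independent_snps_respect_hardy_weinberg(self):
        p = GenotypeSimParams(n_individuals=10_000, n_snps=20, seed=1)
        g = simulate_genotypes(p)
        mafs = g.values.mean(axis=0) / 2
        for j in range(20):
            f = mafs[j]
            obs = np.array([(g.values[:, j] == k).sum() for k in (0, 1, 2)])
            exp = 10_000 * np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            assert stats.chi2.sf(chi2, 1) > 0.01 / 20  # Bonferroni-ish slack

    def test_symmetric_maf_centres_allele_count_at_one(self):
        g = simulate_genotypes(GenotypeSimParams(n_individuals=5000, n_snps=10, maf_range=(0.5, 0.5), seed=2))
        assert g.values.mean() == pytest.approx(1.0, abs=0.03)

    def test_deterministic_given_seed(self):
        a = simulate_genotypes(GenotypeSimParams(n_individuals=50, n_snps=30, seed=9))
        b = simulate_genotypes(GenotypeSimParams(n_individuals=50, n_snps=30, seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_ld_blocks_induce_correlation(self):
        p = GenotypeSimParams(n_individuals=4000, n_snps=10, ld_block_size=5, ld_rho=0.8, seed=3)
        g = simulate_genotypes(p)
        within = np.corrcoef(g.values[:, 0], g.values[:, 1])[0, 1]
        across = np.corrcoef(g.values[:, 0], g.values[:, 7])[0, 1]
        assert within > 0.4
        assert abs(across) < 0.1


class TestSimulatePathways:
    def test_zero_overlap_gives_disjoint_pathways(self):
        p = PathwaySimParams(n_pathways=5, size_log_mean=np.log(20), size_log_sd=0.3,
                             size_bounds=(5, 40), overlap_fraction=0.0, seed=4)
        pw = simulate_pathways(p, [f"s{i}" for i in range(300)])
        assert (pw.membership.sum(axis=1) <= 1).all()

    def test_sizes_within_bounds(self):
        p = PathwaySimParams(n_pathways=20, size_bounds=(30, 1500), seed=5)
        pw = simulate_pathways(p, [f"s{i}" for i in range(5000)])
        sizes = pw.sizes()
        assert sizes.min() >= 30 and sizes.max() <= 1500

    def test_truncated_lognormal_mean(self):
        """Empirical mean size matches the truncated log-normal expectation."""
        p = PathwaySimParams(n_pathways=2000, size_log_mean=np.log(50), size_log_sd=0.5,
                             size_bounds=(20, 150), overlap_fraction=1.0, seed=6)
        pw = simulate_pathways(p, [f"s{i}" for i in range(200)])
        lo, hi = 20, 150
        mu, sd = np.log(50), 0.5
        # E[S | lo <= S <= hi] for S lognormal
        a = (np.log(lo) - mu) / sd
        b = (np.log(hi) - mu) / sd
        expect = np.exp(mu + sd ** 2 / 2) * (
            (stats.norm.cdf(b - sd) - stats.norm.cdf(a - sd))
            / (stats.norm.cdf(b) - stats.norm.cdf(a))
        )
        assert pw.sizes().mean() == pytest.approx(expect, rel=0.05)

    def test_infeasible_request_raises(self):
        p = PathwaySimParams(n_pathways=5, size_log_mean=np.log(80), size_log_sd=0.1,
                             size_bounds=(60, 100), overlap_fraction=0.0, seed=7)
        with pytest.raises(ValueError):
            simulate_pathways(p, [f"s{i}" for i in range(100)])


@pytest.fixture(scope="module")
def tiny_study():
    g = simulate_genotypes(GenotypeSimParams(n_individuals=150, n_snps=600, seed=21))
    pw = simulate_pathways(
        PathwaySimParams(n_pathways=12, size_log_mean=np.log(60), size_log_sd=0.6,
                         size_bounds=(10, 200), overlap_fraction=0.5, seed=22),
        g.snp_ids,
    )
    return g, pw


class TestMakeScenario:
    def test_truth_labels_are_consistent(self, tiny_study):
        g, pw = tiny_study
        sp = ScenarioParams(n_true_pathways=3, n_causal_snps=20, seed=1)
        s = make_scenario(g, pw, "random", sp)
        truth = s.truth_labels(pw.n_pathways)
        assert truth.sum() == 3
        assert set(np.flatnonzero(truth)) == set(s.pathway_idx)

    def test_size_scenarios_respect_the_cut(self, tiny_study):
        g, pw = tiny_study
        sizes = pw.sizes()
        sp = ScenarioParams(n_true_pathways=3, n_causal_snps=20, seed=2,
                            small_cut=60, large_cut=60)
        small = make_scenario(g, pw, "size-small", sp)
        assert (sizes[small.pathway_idx] < 60).all()
        large = make_scenario(g, pw, "size-large", sp)
        assert (sizes[large.pathway_idx] > 60).all()

    def test_method_selected_truth_has_target_count(self, tiny_study):
        g, pw = tiny_study
        sp = ScenarioParams(n_true_pathways=3, n_causal_snps=20, seed=3, target_count=4)
        for sid in ("nbf-selected", "snal-selected", "fm-selected"):
            s = make_scenario(g, pw, sid, sp)
            assert s.pathway_idx.size == 4

    def test_causal_snp_default_count(self, tiny_study):
        g, pw = tiny_study
        sp = ScenarioParams(seed=4)  # default K = 100
        s = make_scenario(g, pw, "random", sp)
        assert s.snp_idx.size == 100

    def test_null_scenario_has_zero_effects(self, tiny_study):
        g, pw = tiny_study
        s = make_scenario(g, pw, "null", ScenarioParams(n_causal_snps=20, seed=5))
        np.testing.assert_array_equal(s.beta, 0.0)
        np.testing.assert_array_equal(s.u, 0.0)


class TestSimulatePhenotypes:
    def test_null_phenotypes_are_pure_noise_with_unit_sd(self, tiny_study):
        g, pw = tiny_study
        s = make_scenario(g, pw, "null", ScenarioParams(n_causal_snps=20, n_replicates=40, seed=6))
        Y = simulate_phenotypes(s, g, pw)
        assert Y.shape == (40, 150)
        assert Y.std() == pytest.approx(s.sigma_eps, rel=0.05)

    def test_variance_decomposition(self):
        """var(y) ~ var(pathway term) + var(SNP term) + residual variance."""
        g = simulate_genotypes(GenotypeSimParams(n_individuals=5000, n_snps=400, seed=31))
        pw = simulate_pathways(
            PathwaySimParams(n_pathways=8, size_log_mean=np.log(40), size_log_sd=0.4,
                             size_bounds=(10, 120), overlap_fraction=0.3, seed=32),
            g.snp_ids,
        )
        sp = ScenarioParams(n_true_pathways=3, n_causal_snps=30, ve_pathway=0.15,
                            ve_snp=0.10, n_replicates=5, seed=33)
        s = make_scenario(g, pw, "random", sp)
        Y = simulate_phenotypes(s, g, pw)
        # effects were rescaled empirically, so total variance should be ~1
        assert Y.var(axis=1).mean() == pytest.approx(1.0, rel=0.05)

    def test_deterministic_given_seed(self, tiny_study):
        g, pw = tiny_study
        sp = ScenarioParams(n_true_pathways=3, n_causal_snps=20, n_replicates=3, seed=8)
        s1 = make_scenario(g, pw, "random", sp)
        s2 = make_scenario(g, pw, "random", sp)
        np.testing.assert_array_equal(simulate_phenotypes(s1, g, pw), simulate_phenotypes(s2, g, pw))

    def test_pilot_fit_effects_are_weak_for_random_small_truth(self, tiny_study):
        """Size presets take their effects from a least-squares fit of a
        pilot phenotype, so pathway terms carry only overfit-level
        variance."""
        g, pw = tiny_study
        sp = ScenarioParams(n_true_pathways=3, n_causal_snps=20, seed=9,
                            small_cut=60, large_cut=60)
        s = make_scenario(g, pw, "size-small", sp)
        X = g.values @ pw.membership.astype(float)
        path_var = (X[:, s.pathway_idx] @ s.beta).var()
        assert path_var < 0.25  # far below the pilot's total variance of ~1


def test_simulate_study_pipeline_runs():
    study = simulate_study(
        "random",
        GenotypeSimParams(n_individuals=80, n_snps=300, seed=41),
        PathwaySimParams(n_pathways=6, size_log_mean=np.log(40), size_log_sd=0.4,
                         size_bounds=(10, 100), overlap_fraction=0.4, seed=42),
        ScenarioParams(n_true_pathways=2, n_causal_snps=15, n_replicates=4, seed=43),
    )
    assert study.phenotypes.shape == (4, 80)
    assert study.truth.sum() == 2
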