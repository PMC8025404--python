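"""Imputer stand-ins, accuracy metrics, and the scenario runner."""

import numpy as np
import pandas as pd
import pytest

import crossmosaic as cm
from crossmosaic.imputation import (
    ScenarioSpec,
    allelic_correlation,
    best_guess_genotypes,
    concordance_rate,
    fill_sporadic_missing,
    frequency_impute,
    grm_offdiagonal_correlation,
    impute,
    maf_stratified_accuracy,
    run_scenarios,
)

from conftest import toy_matrix


class TestFillSporadicMissing:
    def test_identity_without_missing(self, f1_cohort):
        out = fill_sporadic_missing(f1_cohort.genotypes)
        assert np.array_equal(out.genotypes, f1_cohort.genotypes.genotypes)

    def test_mode_fill_and_het_tiebreak(self):
        g = toy_matrix([[0, 0], [0, 2], [2, -1], [-1, 2]])
        out = fill_sporadic_missing(g)
        # site 0: {0,0,2,missing} -> mode 0; site 1: {0,2,2} -> mode 2
        assert out.genotypes[3, 0] == 0
        assert out.genotypes[2, 1] == 2

    def test_tie_between_homozygotes_fills_heterozygote(self):
        g = toy_matrix([[0], [2], [-1]])
        out = fill_sporadic_missing(g)
        assert out.genotypes[2, 0] == 1

    def test_fully_missing_site_rejected(self):
        g = toy_matrix([[-1], [-1]])
        with pytest.raises(ValueError):
            fill_sporadic_missing(g)


class TestImputer:
    def test_perfect_copy_in_the_no_error_limit(self, two_pools):
        pools, gmap = two_pools
        ref = pools[0].haplotypes
        h = ref[7]
        target = np.stack([np.stack([h, h])])
        typed = cm.define_panels(2000, (0.05, 0.2, 1.0), seed=40)[0].mask()
        res = impute(
            target, typed, ref, gmap, mismatch_rate=1e-9, recomb_scale=1e-9
        )
        assert np.abs(res.dosages[0] - 2.0 * h).max() <= 1e-6

    def test_no_typed_sites_returns_reference_frequency(self, two_pools):
        pools, gmap = two_pools
        ref = pools[0].haplotypes
        target = np.zeros((3, 2, 2000), dtype=np.uint8)
        res = impute(target, np.zeros(2000, bool), ref, gmap)
        expected = 2.0 * ref.mean(axis=0)
        assert np.allclose(res.dosages, expected[None, :])

    def test_dosages_within_range_and_typed_sites_observed(self, two_pools, bc1_cohort):
        pools, gmap = two_pools
        typed = cm.define_panels(2000, (0.05, 0.2, 1.0), seed=41)[0].mask()
        res = impute(bc1_cohort.haplotypes[:5], typed, pools[1].haplotypes, gmap)
        assert (res.dosages >= 0).all() and (res.dosages <= 2).all()
        obs = bc1_cohort.genotypes.genotypes[:5][:, typed]
        assert np.array_equal(res.dosages[:, typed], obs.astype(float))

    def test_within_pool_reference_beats_cross_pool(self, two_pools):
        pools, gmap = two_pools
        target = cm.make_cross(cm.CrossSpec.pure("EU", 20, seed=42), pools, gmap)
        typed = cm.define_panels(2000, (0.05, 0.2, 1.0), seed=42)[0].mask()
        res_within = impute(target.haplotypes, typed, pools[0].haplotypes, gmap)
        res_cross = impute(target.haplotypes, typed, pools[1].haplotypes, gmap)
        r_within = allelic_correlation(res_within, target.genotypes).mean_r
        r_cross = allelic_correlation(res_cross, target.genotypes).mean_r
        assert r_within >= 0.9
        assert r_within > r_cross

    def test_empty_reference_rejected(self, two_pools):
        pools, gmap = two_pools
        with pytest.raises(ValueError, match="empty"):
            impute(
                np.zeros((1, 2, 2000), dtype=np.uint8),
                np.ones(2000, bool),
                np.empty((0, 2000), dtype=np.uint8),
                gmap,
            )

    def test_site_list_mismatch_rejected(self, two_pools):
        pools, gmap = two_pools
        with pytest.raises(ValueError):
            impute(
                np.zeros((1, 2, 2000), dtype=np.uint8),
                np.ones(2000, bool),
                pools[0].haplotypes[:, :1999],
                gmap,
            )

    def test_more_reference_haplotypes_never_hurt(self):
        # mean r with a doubled reference stays within MC noise of, or
        # above, the smaller reference (3 seeds)
        for seed in (50, 51, 52):
            pools, gmap = cm.make_ancestral_pools(
                2, 160, 1000, divergence=0.3, seed=seed, names=["A", "B"]
            )
            target = cm.make_cross(cm.CrossSpec.pure("A", 15, seed=seed), pools, gmap)
            typed = cm.define_panels(1000, (0.05, 0.2, 1.0), seed=seed)[0].mask()
            r_small = allelic_correlation(
                impute(target.haplotypes, typed, pools[0].haplotypes[:40], gmap),
                target.genotypes,
            ).mean_r
            r_big = allelic_correlation(
                impute(target.haplotypes, typed, pools[0].haplotypes[:80], gmap),
                target.genotypes,
            ).mean_r
            assert r_big >= r_small - 0.03


class TestBestGuess:
    def test_half_integer_ties_round_to_heterozygote(self):
        d = np.array([[0.49, 0.5, 1.5, 1.51, 2.0]])
        assert list(best_guess_genotypes(d)[0]) == [0, 1, 1, 2, 2]


class TestMetrics:
    def _result(self, dosages, typed_len):
        dosages = np.asarray(dosages, dtype=float)
        n, m = dosages.shape
        sites = pd.DataFrame(
            {"chrom": ["1"] * m, "pos": range(1, m + 1), "cm": range(m)}
        )
        return cm.ImputationResult(
            dosages,
            best_guess_genotypes(dosages),
            np.zeros(m, dtype=bool),
            [f"i{k}" for k in range(n)],
            sites,
        )

    def test_pearson_matches_brute_force(self):
        truth = toy_matrix(np.array([[0], [0], [1], [1], [2], [2]], dtype=np.int8))
        dos = np.array([[0.1], [0.2], [1.0], [1.1], [1.8], [1.9]])
        res = self._result(dos, 1)
        r = allelic_correlation(res, truth).per_site[0]
        x, y = dos[:, 0], truth.genotypes[:, 0].astype(float)
        num = sum((xi - x.mean()) * (yi - y.mean()) for xi, yi in zip(x, y))
        den = (
            sum((xi - x.mean()) ** 2 for xi in x)
            * sum((yi - y.mean()) ** 2 for yi in y)
        ) ** 0.5
        assert r == pytest.approx(num / den, abs=1e-9)

    def test_identical_dosage_gives_r_one(self):
        truth = toy_matrix([[0, 2], [1, 1], [2, 0]])
        res = self._result(truth.genotypes.astype(float), 2)
        summary = allelic_correlation(res, truth)
        assert np.allclose(summary.per_site, 1.0)
        assert summary.mean_r == pytest.approx(1.0)

    def test_constant_dosage_scores_zero_monomorphic_excluded(self):
        truth = toy_matrix([[0, 0], [1, 0], [2, 0]])
        res = self._result(np.full((3, 2), 1.0), 2)
        summary = allelic_correlation(res, truth)
        assert summary.per_site[0] == 0.0  # zero-variance imputation
        assert np.isnan(summary.per_site[1])  # monomorphic truth excluded
        assert summary.n_excluded_monomorphic == 1

    def test_single_individual_rejected(self):
        truth = toy_matrix([[0, 1]])
        res = self._result([[0.0, 1.0]], 2)
        with pytest.raises(ValueError):
            allelic_correlation(res, truth)

    def test_concordance_direct_counts(self):
        truth = toy_matrix([[0], [1], [2]])
        res = self._result([[0.0], [2.0], [2.0]], 1)
        summary = concordance_rate(res, truth)
        assert summary.allele_rate == pytest.approx(5 / 6)
        truth2 = toy_matrix([[0, 0], [0, 0]])
        res2 = self._result([[2.0, 2.0], [2.0, 2.0]], 2)
        assert concordance_rate(res2, truth2).allele_rate == 0.0
        res3 = self._result(truth.genotypes.astype(float), 1)
        assert concordance_rate(res3, truth).allele_rate == 1.0

    def test_maf_stratification_single_bin_matches_global(self, two_pools):
        pools, gmap = two_pools
        target = cm.make_cross(cm.CrossSpec.pure("EU", 20, seed=43), pools, gmap)
        typed = cm.define_panels(2000, (0.1, 0.5, 1.0), seed=43)[0].mask()
        res = impute(target.haplotypes, typed, pools[0].haplotypes, gmap)
        tab = maf_stratified_accuracy(res, target.genotypes, bin_edges=(0.0, 0.5))
        conc = concordance_rate(res, target.genotypes)
        assert len(tab) == 1
        assert tab["concordance"].iloc[0] == pytest.approx(
            conc.per_site.mean(), abs=1e-12
        )

    def test_frequency_imputer_inflates_low_maf_concordance(self, two_pools):
        pools, gmap = two_pools
        target = cm.make_cross(cm.CrossSpec.pure("EU", 40, seed=44), pools, gmap)
        typed = np.zeros(2000, dtype=bool)
        res = frequency_impute(target.genotypes, typed, pools[0].allele_freqs)
        truth_maf = target.genotypes.minor_allele_freqs()
        low = truth_maf < 0.05
        conc = concordance_rate(res, target.genotypes)
        corr = allelic_correlation(res, target.genotypes)
        assert conc.per_site[low].mean() >= 0.90
        assert abs(np.nanmean(corr.per_site)) <= 0.1


class TestGrmOffdiagonal:
    def test_identical_matrices_correlate_perfectly(self, mixed_cohort):
        g = mixed_cohort.genotypes
        assert grm_offdiagonal_correlation(g, g) == pytest.approx(1.0)

    def test_permuting_individuals_destroys_relatedness(self, mixed_cohort):
        g = mixed_cohort.genotypes
        rng = np.random.default_rng(4)
        g_perm = cm.GenotypeMatrix(
            g.genotypes[rng.permutation(g.n_individuals)], g.samples, g.sites
        )
        assert abs(grm_offdiagonal_correlation(g, g_perm)) < 0.2

    def test_too_few_individuals_rejected(self):
        g = toy_matrix([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            grm_offdiagonal_correlation(g, g)


@pytest.fixture(scope="module")
def setup():
    pools, gmap = cm.make_ancestral_pools(
        2, 120, 1000, divergence=0.3, seed=60, names=["A", "B"]
    )
    cohorts = {
        "targetA": cm.make_cross(cm.CrossSpec.pure("A", 25, seed=60), pools, gmap),
        "refA": cm.make_cross(cm.CrossSpec.pure("A", 40, seed=61), pools, gmap),
        "refB": cm.make_cross(cm.CrossSpec.pure("B", 40, seed=62), pools, gmap),
    }
    panels = {p.name: p for p in cm.define_panels(1000, (0.05, 0.2, 1.0), seed=60)}
    return cohorts, panels


class TestScenarios:
    def test_direct_and_cv_reports(self, setup):
        cohorts, panels = setup
        specs = [
            ScenarioSpec("direct", ["refA"], "targetA", "low", "high", 1),
            ScenarioSpec("cv", [], "targetA", "low", "high", cv_folds=5),
        ]
        reports = run_scenarios(specs, cohorts, panels, seed=1)
        for rep in reports:
            assert 0 <= rep.concordance <= 1
            assert rep.n_sites_imputed == 950
            assert np.isfinite(rep.mean_r)
        assert reports[0].n_reference_haplotypes == 80
        assert reports[1].n_reference_haplotypes == 40  # 20 of 25 inds per fold

    def test_deterministic_given_seed(self, setup):
        cohorts, panels = setup
        spec = [ScenarioSpec("cv", [], "targetA", "low", "high", cv_folds=5)]
        r1 = run_scenarios(spec, cohorts, panels, seed=2)[0]
        r2 = run_scenarios(spec, cohorts, panels, seed=2)[0]
        assert r1.mean_r == r2.mean_r
        assert r1.per_site.equals(r2.per_site)

    def test_metrics_invariant_to_individual_order(self, setup):
        cohorts, panels = setup
        spec = [ScenarioSpec("direct", ["refA"], "targetA", "low", "high", 1)]
        base = run_scenarios(spec, cohorts, panels, seed=3)[0]
        perm = np.random.default_rng(0).permutation(25)
        cohorts2 = dict(cohorts)
        cohorts2["targetA"] = cohorts["targetA"].take_individuals(perm)
        shuffled = run_scenarios(spec, cohorts2, panels, seed=3)[0]
        assert shuffled.mean_r == pytest.approx(base.mean_r, abs=1e-12)
        assert shuffled.concordance == pytest.approx(base.concordance, abs=1e-12)

    def test_unknown_cohort_or_panel_rejected(self, setup):
        cohorts, panels = setup
        with pytest.raises(KeyError, match="ghost"):
            run_scenarios(
                [ScenarioSpec("x", ["ghost"], "targetA")], cohorts, panels
            )
        with pytest.raises(KeyError, match="ultra"):
            run_scenarios(
                [ScenarioSpec("x", ["refA"], "targetA", "low", "ultra")],
                cohorts,
                panels,
            )

    def test_fold_too_small_rejected(self, setup):
        cohorts, panels = setup
        small = dict(cohorts)
        small["tiny"] = cohorts["targetA"].take_individuals(np.arange(6))
        with pytest.raises(ValueError, match="fewer than 2"):
            run_scenarios(
                [ScenarioSpec("x", [], "tiny", "low", "high", cv_folds=5)],
                small,
                panels,
            )
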