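import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from radtme.perfstats import (
    DegenerateDistributionError,
    UnpairedSamplesError,
    abc_from_samples,
    area_between_curves,
    auc_superiority,
    cliffs_delta_from_auc,
    cohens_d,
    compare,
    ensemble_summary,
    exceedance_curve,
    exceedance_pair,
    high_intensity_fraction,
    hodges_lehmann_paired,
)
from radtme.synthetic import gen_intensity_pair


class TestCohensD:
    def test_identical_distributions_give_zero(self):
        a = np.array([0.1, 0.4, 0.9])
        assert cohens_d(a, a) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d([0, 1, 2], [2, 3, 4]) == pytest.approx(-2.0, rel=1e-12)

    def test_constant_shift_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.1, 500)
        c = 0.23
        d = cohens_d(a + c, a)
        assert d == pytest.approx(c / a.std(ddof=1), rel=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            cohens_d([1.0, 1.0, 1.0], [2.0, 2.0])


class TestAUCandCliff:
    def test_symmetry_and_total_separation(self):
        a = np.array([0.1, 0.5, 0.9])
        assert auc_superiority(a, a) == pytest.approx(0.5)
        assert auc_superiority([5, 6, 7], [1, 2]) == 1.0

    def test_small_brute_force_case(self):
        assert auc_superiority([1.0, 3.0], [2.0]) == pytest.approx(0.5)

    @given(
        seed=st.integers(0, 500),
        na=st.integers(1, 12),
        nb=st.integers(1, 12),
    )
    def test_rank_formulation_matches_brute_force(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        # coarse grid forces ties
        a = rng.integers(0, 5, na) / 4.0
        b = rng.integers(0, 5, nb) / 4.0
        brute = np.mean([
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        ])
        auc = auc_superiority(a, b)
        assert auc == pytest.approx(brute, abs=1e-12)
        # Cliff's delta equals the direct signed brute force
        cliff_brute = np.mean([np.sign(x - y) for x, y in itertools.product(a, b)])
        assert cliffs_delta_from_auc(auc) == pytest.approx(cliff_brute, abs=1e-12)

    def test_reference_delta_from_auc(self):
        assert cliffs_delta_from_auc(0.902) == pytest.approx(0.804, rel=1e-12)
        assert cliffs_delta_from_auc(0.5) == 0.0
        assert cliffs_delta_from_auc(1.0) == 1.0
        with pytest.raises(ValueError):
            cliffs_delta_from_auc(1.2)


class TestHodgesLehmann:
    def test_constant_shift(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.2, 0.9, 100)
        assert hodges_lehmann_paired(a, a - 0.107) == pytest.approx(0.107, rel=1e-12)
        assert hodges_lehmann_paired(a, a) == 0.0

    def test_median_of_differences(self):
        assert hodges_lehmann_paired([1, 2, 3], [0, 0, 0]) == 2.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(UnpairedSamplesError):
            hodges_lehmann_paired([1, 2, 3], [1, 2])

    def test_cross_method_matches_brute_force(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 1, 15), rng.uniform(0, 1, 11)
        brute = np.median([x - y for x in a for y in b])
        assert hodges_lehmann_paired(a, b, method="cross") == pytest.approx(brute)


class TestExceedance:
    def test_all_ones_and_direct_count(self):
        e = exceedance_curve(np.ones(10), [0.0, 0.5, 0.99])
        assert np.all(e.values == 1.0)
        e2 = exceedance_curve([0.2, 0.8], [0.5])
        assert e2.values[0] == 0.5

    def test_strict_inequality_at_sample_value(self):
        e = exceedance_curve([0.5, 0.7], [0.5])
        assert e.values[0] == 0.5  # 0.5 itself does not exceed 0.5

    @given(seed=st.integers(0, 300), n=st.integers(1, 50))
    def test_non_increasing(self, seed, n):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0, 1, n)
        e = exceedance_curve(s, np.linspace(0, 1, 31))
        assert np.all(np.diff(e.values) <= 0)

    def test_high_intensity_fraction(self):
        assert high_intensity_fraction([0.1, 0.2], 0.7) == 0.0
        assert high_intensity_fraction([0.75, 0.65], 0.7) == 50.0
        assert high_intensity_fraction([0.3, 0.4], 0.0) == 100.0


class TestABC:
    def test_exact_mean_difference_identity(self):
        a, b, _ = gen_intensity_pair(0.650, 0.525, 0.06, 5000, seed=0)
        assert abc_from_samples(a, b) == pytest.approx(0.125, abs=1e-12)

    def test_identical_samples_zero(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 1, 100)
        assert abc_from_samples(s, s) == 0.0

    @given(seed=st.integers(0, 300), n=st.integers(2, 60), m=st.integers(2, 60))
    def test_survival_integral_equals_mean_difference(self, seed, n, m):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, n)
        b = rng.uniform(0, 1, m)
        assert abc_from_samples(a, b) == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_common_grid_required(self):
        e1 = exceedance_curve([0.2, 0.8], np.linspace(0, 1, 5))
        e2 = exceedance_curve([0.3], np.linspace(0, 1, 7))
        with pytest.raises(ValueError):
            area_between_curves(e1, e2)

    def test_pair_grid_is_exact_step_representation(self):
        a = np.array([0.1, 0.4, 0.4, 0.9])
        b = np.array([0.2, 0.5])
        e1, e2 = exceedance_pair(a, b)
        assert area_between_curves(e1, e2) == pytest.approx(a.mean() - b.mean(), abs=1e-15)


class TestCompare:
    def test_report_consistency(self):
        a, b, _ = gen_intensity_pair(0.650, 0.525, 0.06, 2000, seed=1)
        rep = compare(a, b, taus=(0.7,))
        assert rep.cliffs_delta == pytest.approx(2 * rep.auc - 1)
        assert rep.abc == pytest.approx(rep.mean_a - rep.mean_b, abs=1e-12)
        assert rep.cohen_d > 0
        fa, fb = rep.threshold_fractions[0.7]
        assert fa >= fb


class TestEnsembleSummary:
    @staticmethod
    def _exact_mean_pairs(n, mean_ehd, mean_non, jitter_sd, seed):
        rng = np.random.default_rng(seed)
        j1 = rng.normal(0, jitter_sd, n)
        j2 = rng.normal(0, jitter_sd, n)
        return mean_ehd + j1 - j1.mean(), mean_non + j2 - j2.mean()

    def test_reference_grand_means_delta_and_gain(self):
        ehd, non = self._exact_mean_pairs(15, 0.722, 0.576, 0.015, 0)
        summ = ensemble_summary(ehd, non, n_boot=2000, seed=0)
        assert summ.delta == pytest.approx(0.146, abs=1e-12)
        assert summ.relative_gain_percent == pytest.approx(25.35, abs=0.02)

    def test_uniformly_positive_differences_exact_wilcoxon_p(self):
        ehd, non = self._exact_mean_pairs(15, 0.722, 0.576, 0.015, 0)
        assert np.all(ehd - non > 0)
        summ = ensemble_summary(ehd, non, n_boot=500, seed=0)
        assert summ.wilcoxon_p == pytest.approx(2.0 / 2**15, rel=1e-9)

    def test_identical_pairs_flagged_degenerate(self):
        x = np.linspace(0.3, 0.7, 10)
        summ = ensemble_summary(x, x, n_boot=100, seed=0)
        assert summ.degenerate and summ.delta == 0.0 and summ.wilcoxon_p == 1.0
        assert summ.relative_gain_percent == 0.0

    def test_bootstrap_reproducible_and_covers_delta(self):
        ehd, non = self._exact_mean_pairs(15, 0.722, 0.576, 0.02, 3)
        s1 = ensemble_summary(ehd, non, n_boot=4000, seed=7)
        s2 = ensemble_summary(ehd, non, n_boot=4000, seed=7)
        assert (s1.ci_low, s1.ci_high) == (s2.ci_low, s2.ci_high)
        assert s1.ci_low <= s1.delta <= s1.ci_high

    @given(seed=st.integers(0, 200), n=st.integers(3, 12))
    def test_exact_wilcoxon_matches_enumeration(self, seed, n):
        """Exact two-sided signed-rank p equals full 2^n sign enumeration."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0.1, 1.0, n)
        d = d[d != 0]
        n = len(d)
        if n < 2:
            return
        ranks = stats.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        # null distribution of W+ by enumeration
        ws = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ])
        mu = ranks.sum() / 2.0
        p_enum = np.mean(np.abs(ws - mu) >= abs(w - mu) - 1e-12)
        p_lib = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert p_lib == pytest.approx(p_enum, abs=1e-10)
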