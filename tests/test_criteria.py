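"""Step/plateau detection and the three quality criteria."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import loglogstep as ls
from conftest import curve_of


def make_curve(log_eps, log_C, m=3):
    return ls.CorrelationCurve(
        log_eps=np.asarray(log_eps, float), log_C=np.asarray(log_C, float), m=m, n_points=0
    )


def make_deriv(slopes, step=0.05):
    mids = step * np.arange(len(slopes))
    return ls.DerivativeCurve(log_eps_mid=mids, slope=np.asarray(slopes, float))


class TestDerivative:
    def test_constant_curve_has_zero_slope(self):
        cv = make_curve([0, 0.1, 0.2, 0.3], [-1, -1, -1, -1])
        np.testing.assert_array_equal(ls.derivative(cv).slope, 0.0)

    def test_single_jump(self):
        cv = make_curve([0, 0.1, 0.2, 0.3], [-1, -1, -0.5, -0.5])
        np.testing.assert_allclose(ls.derivative(cv).slope, [0, 5.0, 0])

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=20))
    def test_slopes_nonnegative_for_monotone_curves(self, increments):
        log_C = -np.cumsum([0.0] + sorted(increments, reverse=False))[::-1]
        log_C = np.sort(log_C)
        log_eps = 0.05 * np.arange(log_C.size)
        cv = make_curve(log_eps, log_C)
        assert np.all(ls.derivative(cv).slope >= 0)

    def test_degenerate_grid_rejected(self):
        cv = make_curve([0.0, 0.0, 0.1], [-1, -0.5, 0])
        with pytest.raises(ValueError):
            ls.derivative(cv)


class TestCountPeaks:
    @pytest.mark.parametrize(
        "slopes,level,expected",
        [
            ([0, 0, 0], 0.5, 0),
            ([0, 2, 2, 0], 0.5, 1),
            ([0, 2, 0, 3, 0], 0.5, 2),
            ([1, 0, 1], 0.5, 2),  # runs touching both ends count separately
            ([0, 0.5, 0], 0.5, 0),  # strictly above
        ],
    )
    def test_run_counting(self, slopes, level, expected):
        assert ls.count_peaks(make_deriv(slopes), level) == expected

    def test_level_must_be_positive(self):
        with pytest.raises(ValueError):
            ls.count_peaks(make_deriv([0, 1]), 0.0)


class TestPlateauCount:
    def test_all_below_lowest_level_counts_every_sample(self):
        d = make_deriv([0.01] * 7)
        assert ls.plateau_count(d) == 7.0

    def test_all_above_highest_level_counts_nothing(self):
        d = make_deriv([5.0] * 7)
        assert ls.plateau_count(d) == 0.0

    def test_weighted_average_of_per_level_counts(self):
        lw = ls.LevelWeights(levels=(0.05, 0.1, 0.2), weights=(3, 2, 1))
        d = make_deriv([0.01, 0.07, 0.15, 3.0])
        # below 0.05: 1 sample; below 0.1: 2; below 0.2: 3
        assert ls.plateau_count(d, lw) == pytest.approx((3 * 1 + 2 * 2 + 1 * 3) / 6)


class TestCriterionA:
    def test_noiseless_pattern_scores_full_weight(self, noiseless_series, all_refs_config):
        """One sharp step at m = p at every level: no surrogate term triggers."""
        cv = curve_of(noiseless_series, 3, all_refs_config)
        surr = ls.make_surrogate(noiseless_series, seed=1)
        surr_cv = curve_of(surr, 3, all_refs_config)
        lw = ls.DEFAULT_PEAK_LEVELS
        assert ls.criterion_a(cv, [surr_cv], lw) == pytest.approx(sum(lw.weights))

    def test_surrogate_required_when_repeated_steps_emerge(self):
        # two clean steps -> 2 peaks at every level -> surrogate branch triggers
        log_eps = 0.05 * np.arange(9)
        log_C = np.array([-2, -2, -2, -1, -1, -1, 0, 0, 0], float)
        cv = make_curve(log_eps, log_C)
        with pytest.raises(ValueError):
            ls.criterion_a(cv, [])

    def test_repeated_steps_discounted_against_steppier_surrogate(self):
        log_eps = 0.05 * np.arange(9)
        two_steps = make_curve(log_eps, [-2, -2, -2, -1, -1, -1, 0, 0, 0])
        three_steps = make_curve(
            0.05 * np.arange(12), [-3, -3, -3, -2, -2, -2, -1, -1, -1, 0, 0, 0]
        )
        lw = ls.DEFAULT_PEAK_LEVELS
        # data has 2 peaks everywhere, the surrogate 3: positive distance term
        score = ls.criterion_a(two_steps, [three_steps], lw)
        assert score == pytest.approx(sum(lw.weights) * (2 - 1) / 2)
        # data as steppy as the surrogate: zero distance term
        assert ls.criterion_a(three_steps, [three_steps], lw) == 0.0

    def test_patterned_beats_surrogate_median(self, pattern134):
        """Moderate contamination: criterion (a) suppresses permuted series."""
        cfg = ls.CorrelationConfig(n_ref=150, seed=0)
        data_scores, surr_scores = [], []
        for r in range(12):
            sd = ls.cell_seed(5, 0, 0, r)
            s = ls.generate_series(
                pattern134, ls.JitterSpec(0.05), ls.NoiseSpec(0.2), 3002, seed=sd
            )
            surr = ls.make_surrogate(s, sd + 1)
            ens = [
                curve_of(ls.make_surrogate(s, sd + 2 + k), 3, cfg, n_points=3000)
                for k in range(3)
            ]
            data_scores.append(ls.criterion_a(curve_of(s, 3, cfg, n_points=3000), ens))
            surr_scores.append(ls.criterion_a(curve_of(surr, 3, cfg, n_points=3000), ens))
        assert np.median(data_scores) > np.median(surr_scores)


class TestCriterionB:
    def test_noiseless_pattern_full_score_at_m1(self, noiseless_series, all_refs_config):
        """Three distinct scalar cluster distances {1, 2, 3} -> three sharp steps."""
        cv = curve_of(noiseless_series, 1, all_refs_config)
        assert ls.criterion_b(cv, 3) == pytest.approx(sum(ls.DEFAULT_PEAK_LEVELS.weights))

    def test_flat_curve_scores_zero(self):
        cv = make_curve(0.05 * np.arange(5), np.zeros(5), m=1)
        assert ls.criterion_b(cv, 3) == 0.0

    def test_permutation_invariance_at_m1(self, pattern134):
        """The m = 1 correlation integral depends only on the interval multiset,
        so criterion (b) is identical for a series and its surrogate under the
        full pairwise computation."""
        s = ls.generate_series(pattern134, ls.JitterSpec(0.05), ls.NoiseSpec(0.3), 1000, seed=3)
        surr = ls.make_surrogate(s, seed=4)
        cfg = ls.CorrelationConfig(n_ref=10**9, seed=0)
        cv = curve_of(s, 1, cfg)
        cv_s = curve_of(surr, 1, cfg)
        np.testing.assert_array_equal(cv.log_C, cv_s.log_C)
        assert ls.criterion_b(cv, 3) == ls.criterion_b(cv_s, 3)


class TestCriterionC:
    def test_identical_curves_give_zero(self, noiseless_series, all_refs_config):
        cv = curve_of(noiseless_series, 3, all_refs_config)
        assert ls.criterion_c(cv, cv) == 0.0

    def test_flat_vs_steep_difference(self):
        log_eps = 0.05 * np.arange(10)
        flat = make_curve(log_eps, np.full(10, -0.5))
        steep = make_curve(log_eps, np.linspace(-3, 0, 10))
        assert ls.criterion_c(flat, steep) == pytest.approx(9.0)

    def test_noiseless_pattern_positive_difference(self, noiseless_series, all_refs_config):
        """m = 3 has one long plateau, m = 2 has two shorter ones split by a step."""
        hi = curve_of(noiseless_series, 3, all_refs_config)
        lo = curve_of(noiseless_series, 2, all_refs_config)
        assert ls.criterion_c(hi, lo) > 0

    def test_non_overlapping_spans_rejected(self):
        a = make_curve([0.0, 0.1, 0.2], [-1, -0.5, 0])
        b = make_curve([5.0, 5.1, 5.2], [-1, -0.5, 0])
        with pytest.raises(ValueError):
            ls.criterion_c(a, b)

    def test_patterned_beats_surrogate_median(self, pattern134):
        cfg = ls.CorrelationConfig(n_ref=150, seed=0)
        data_scores, surr_scores = [], []
        for r in range(12):
            sd = ls.cell_seed(6, 0, 0, r)
            s = ls.generate_series(
                pattern134, ls.JitterSpec(0.1), ls.NoiseSpec(0.3), 3002, seed=sd
            )
            surr = ls.make_surrogate(s, sd + 1)
            data_scores.append(
                ls.criterion_c(curve_of(s, 3, cfg, 3000), curve_of(s, 2, cfg, 3000))
            )
            surr_scores.append(
                ls.criterion_c(curve_of(surr, 3, cfg, 3000), curve_of(surr, 2, cfg, 3000))
            )
        assert np.median(data_scores) > np.median(surr_scores)


class TestNormalize:
    def test_divides_by_maximum(self):
        np.testing.assert_allclose(ls.normalize_over_grid(np.array([2.0, 4.0])), [0.5, 1.0])

    def test_idempotent_when_max_is_one(self):
        grid = np.array([[0.2, 1.0], [0.5, 0.1]])
        np.testing.assert_array_equal(ls.normalize_over_grid(grid), grid)

    def test_commutes_with_positive_rescaling(self):
        grid = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(
            ls.normalize_over_grid(3.7 * grid), ls.normalize_over_grid(grid)
        )

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError):
            ls.normalize_over_grid(np.array([0.0, -1.0]))


class TestTranslationInvariance:
    def test_peak_counts_invariant_under_horizontal_shift(self, noiseless_series, all_refs_config):
        cv = curve_of(noiseless_series, 1, all_refs_config)
        shifted = ls.CorrelationCurve(
            log_eps=cv.log_eps + 2.0, log_C=cv.log_C, m=cv.m, n_points=cv.n_points
        )
        for level in ls.DEFAULT_PEAK_LEVELS.levels:
            assert ls.count_peaks(ls.derivative(cv), level) == ls.count_peaks(
                ls.derivative(shifted), level
            )
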