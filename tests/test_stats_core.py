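import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from saxsqc.io_formats import ScatteringProfile, SeriesError
from saxsqc.simulate import sphere_profile
from saxsqc.stats_core import (
    average_profiles,
    chi2_compare,
    filter_frames,
    linreg_ttest,
    modified_z_outliers,
    sequential_rejection,
    t_to_pvalue,
)


def _ols_oracle(x, y):
    """Closed-form normal-equations OLS with slope t-test, kept independent
    of the implementation under test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s_a = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    t = slope / s_a
    p = 2 * sps.t.sf(abs(t), n - 2)
    return slope, intercept, s_a, t, p


class TestLinregTTest:
    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 12)
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n) + rng.normal() * x
            fit = linreg_ttest(x, y)
            slope, intercept, s_a, t, p = _ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.stderr == pytest.approx(s_a, abs=1e-10)
            assert fit.t == pytest.approx(t, abs=1e-8)
            assert fit.p == pytest.approx(p, abs=1e-10)

    def test_hand_computed_example(self):
        fit = linreg_ttest([1, 2, 3, 4], [1, 2, 3, 5])
        assert fit.slope == pytest.approx(1.3)
        assert fit.intercept == pytest.approx(-0.5)
        assert fit.df == 2

    def test_flat_response_gives_p_one(self):
        fit = linreg_ttest(np.arange(1, 9), np.full(8, 3.7))
        assert fit.t == 0.0
        assert fit.p == 1.0

    def test_exact_trend_gives_p_zero(self):
        x = np.arange(5.0)
        fit = linreg_ttest(x, 3 * x + 1)
        assert fit.stderr == 0.0
        assert fit.p == 0.0

    def test_degenerate_regressor_rejected(self):
        with pytest.raises(ValueError):
            linreg_ttest(np.ones(5), np.arange(5.0))

    def test_type_one_error_calibrated(self):
        # under the null the p < 0.05 rate must be 5%: the basis of every
        # damage/concentration call in the pipeline
        rng = np.random.default_rng(123)
        x = np.arange(1.0, 9.0)
        hits = sum(
            linreg_ttest(x, rng.normal(0, 1, 8)).p < 0.05 for _ in range(2000)
        )
        assert hits / 2000 == pytest.approx(0.05, abs=0.02)


class TestTToPvalue:
    @pytest.mark.parametrize(
        "t, df, expected",
        [
            (0.0, 5, 1.0),
            (12.706, 1, 0.05),   # classical table, alpha=0.05, df=1
            (2.447, 6, 0.05),    # df = 8 exposures - 2
        ],
    )
    def test_classical_table_values(self, t, df, expected):
        assert t_to_pvalue(t, df) == pytest.approx(expected, abs=5e-4)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            t_to_pvalue(1.0, 0)

    @given(st.floats(-30, 30), st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, t, df):
        p = t_to_pvalue(t, df)
        assert 0.0 <= p <= 1.0
        assert t_to_pvalue(abs(t) + 1.0, df) <= p + 1e-12


class TestChi2Compare:
    def test_identical_profiles_give_zero(self, sphere30):
        assert chi2_compare(sphere30, sphere30).value == 0.0

    def test_symmetry(self, noisy_sphere):
        a, b = noisy_sphere(1), noisy_sphere(2)
        assert chi2_compare(a, b).value == chi2_compare(b, a).value

    def test_ten_sigma_offset_gives_fifty(self, sphere30):
        shifted = ScatteringProfile(
            sphere30.q, sphere30.intensity + 10 * sphere30.sigma, sphere30.sigma
        )
        assert chi2_compare(sphere30, shifted).value == pytest.approx(50.0)

    def test_similar_profiles_average_to_one(self, noisy_sphere):
        vals = [
            chi2_compare(noisy_sphere(2 * i), noisy_sphere(2 * i + 1)).value
            for i in range(50)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_grid_mismatch_rejected(self, sphere30):
        other = sphere_profile(30.0, q_grid=np.linspace(0.02, 0.36, 500))
        with pytest.raises(SeriesError):
            chi2_compare(sphere30, other)


class TestModifiedZOutliers:
    def test_single_gross_outlier_flagged(self):
        flags = modified_z_outliers(np.array([10.0, 10.1, 9.9, 10.05, 20.0]))
        assert list(flags) == [False, False, False, False, True]

    def test_all_equal_no_outliers(self):
        assert not modified_z_outliers(np.full(6, 2.0)).any()

    def test_zero_mad_flags_any_deviation(self):
        flags = modified_z_outliers(np.array([1.0, 1.0, 1.0, 1.0, 2.0]))
        assert list(flags) == [False, False, False, False, True]


class TestAverageProfiles:
    def test_single_profile_identity(self, sphere30):
        avg = average_profiles([sphere30])
        np.testing.assert_allclose(avg.intensity, sphere30.intensity)
        np.testing.assert_allclose(avg.sigma, sphere30.sigma)

    def test_k_identical_profiles_reduce_sigma_by_sqrt_k(self, sphere30):
        avg = average_profiles([sphere30] * 4)
        np.testing.assert_allclose(avg.intensity, sphere30.intensity)
        np.testing.assert_allclose(avg.sigma, sphere30.sigma / 2.0)

    def test_inverse_variance_weighting(self):
        q = np.linspace(0.01, 0.3, 20)
        a = ScatteringProfile(q, np.full(20, 1.0), np.full(20, 0.1))
        b = ScatteringProfile(q, np.full(20, 2.0), np.full(20, 0.2))
        avg = average_profiles([a, b])
        # sigma ratio 1:2 -> weights 4:1
        np.testing.assert_allclose(avg.intensity, (4 * 1.0 + 1 * 2.0) / 5.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([])


class TestFrameRejection:
    def test_flat_series_keeps_all(self):
        kept, fit = sequential_rejection(
            np.arange(1, 9), np.array([5, 5.01, 4.99, 5.0, 5.02, 4.98, 5.01, 5.0])
        )
        assert len(kept) == 8

    def test_perfect_linear_trend_rejects_whole_series(self):
        x = np.arange(1.0, 9.0)
        kept, fit = sequential_rejection(x, 2 * x + 1)
        assert len(kept) == 0 and fit is None

    def test_noiseless_driftfree_series_never_loses_frames(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = np.full(8, rng.uniform(1, 10))
            kept, _ = sequential_rejection(np.arange(1, 9), y)
            assert len(kept) == 8

    def test_changepoint_caught_by_screen_plus_rejection(self):
        # 20-sigma step ramp in the last three of eight frames: the outlier
        # screen plus sequential rejection must drop frames 6-8
        rng = np.random.default_rng(3)
        x = np.arange(1, 9)
        hits = 0
        for _ in range(200):
            y = rng.normal(0, 1.0, 8)
            y[5:] += 20.0 * np.array([1.0, 2.0, 3.0])
            kept, _ = filter_frames(x, y)
            hits += not ({5, 6, 7} & set(kept.tolist()))
        assert hits / 200 >= 0.90
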