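import numpy as np
import pytest

from saxsqc.concentration import (
    CONC_PARAMETERS,
    concentration_dependence,
    estimate_concentration,
    profile_parameters,
    scale_series,
)
from saxsqc.io_formats import ConcentrationSeries, ScatteringProfile
from saxsqc.simulate import (
    NoiseModel,
    ParticleModel,
    make_concentration_series,
)


@pytest.fixture(scope="module")
def ideal_series():
    return make_concentration_series(
        ParticleModel(radius=30.0), [0.001, 0.002, 0.005],
        NoiseModel(seed=0), structure_factor=False, noiseless=True,
    )


class TestScaleSeries:
    def test_exact_ratios_recovered_noiseless(self, ideal_series):
        abscissae = scale_series(ideal_series).abscissae
        np.testing.assert_allclose(abscissae, [1.0, 2.0, 5.0], rtol=1e-10)

    def test_first_member_always_unity(self, ideal_series):
        assert scale_series(ideal_series).abscissae[0] == 1.0

    def test_median_robust_to_corrupted_point(self, ideal_series):
        profiles = [p for p in ideal_series.profiles]
        q = profiles[1].q
        bad_i = profiles[1].intensity.copy()
        region_start = int(np.searchsorted(q, 0.07))
        bad_i[region_start + 7] *= 100.0  # one corrupted point of the 50
        profiles[1] = ScatteringProfile(q, bad_i, profiles[1].sigma)
        abscissae = scale_series(ConcentrationSeries(profiles)).abscissae
        assert abscissae[1] == pytest.approx(2.0, rel=1e-10)

    def test_noisy_scaling_within_half_percent(self):
        for seed in range(10):
            cs = make_concentration_series(
                ParticleModel(radius=30.0), [0.001, 0.002, 0.005],
                NoiseModel(seed=seed), structure_factor=False,
            )
            abscissae = scale_series(cs).abscissae
            assert abscissae[1] == pytest.approx(2.0, rel=0.005)
            assert abscissae[2] == pytest.approx(5.0, rel=0.005)

    def test_short_grid_uses_remaining_points(self):
        q = np.linspace(0.01, 0.08, 100)  # only ~13 points past 0.07
        profiles = [
            ScatteringProfile(q, c * np.ones(100), 0.01 * np.ones(100))
            for c in (1.0, 2.0, 3.0)
        ]
        res = scale_series(ConcentrationSeries(profiles))
        assert res.scaling_region[1] < 50
        np.testing.assert_allclose(res.abscissae, [1.0, 2.0, 3.0])


class TestEstimateConcentration:
    def test_calibration_identity(self):
        # calib chosen so a known 1 mg/ml sample returns 1.0
        i0, mw = 3.3e-2, 20000.0
        calib = i0 / (1.0 * mw)
        assert estimate_concentration(i0, mw, calib) == pytest.approx(1.0)

    def test_linearity_in_i0(self):
        assert estimate_concentration(2.0, 1e4, 1e-5) == pytest.approx(
            2 * estimate_concentration(1.0, 1e4, 1e-5)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_concentration(1.0, 1e4, 0.0)
        with pytest.raises(ValueError):
            estimate_concentration(1.0, 0.0, 1e-5)


class TestConcentrationDependence:
    def test_report_always_has_ten_parameter_slots(self):
        cs = make_concentration_series(
            ParticleModel(radius=30.0), [0.001, 0.002, 0.005], NoiseModel(seed=1),
            structure_factor=False,
        )
        rep = concentration_dependence(cs)
        assert set(rep.trends) == set(CONC_PARAMETERS)
        assert len(rep.trends) == 10

    def test_p_values_invariant_under_common_rescaling(self):
        cs = make_concentration_series(
            ParticleModel(radius=30.0), [0.001, 0.002, 0.005], NoiseModel(seed=2),
            structure_factor=False,
        )
        scaled = ConcentrationSeries([p.scaled(41.7) for p in cs.profiles])
        rep1 = concentration_dependence(cs)
        rep2 = concentration_dependence(scaled)
        for name in CONC_PARAMETERS:
            t1, t2 = rep1.trends[name].test, rep2.trends[name].test
            if t1 is None:
                assert t2 is None
                continue
            assert t2.p == pytest.approx(t1.p, abs=1e-6)

    def test_hard_sphere_series_strongly_flagged(self):
        cs = make_concentration_series(
            ParticleModel(radius=30.0), [0.02, 0.04, 0.08], NoiseModel(seed=3),
            structure_factor=True,
        )
        rep = concentration_dependence(cs)
        n_red = sum(
            1 for n in CONC_PARAMETERS
            if rep.trends[n].test is not None and rep.trends[n].test.p <= 0.05
        )
        assert n_red >= 3

    def test_estimated_concentrations_within_ten_percent(self):
        model = ParticleModel(radius=30.0, forward_intensity_per_conc=0.05)
        phis = [c / 1370.0 for c in (1.0, 2.0, 5.0)]  # 1, 2, 5 mg/ml
        cs = make_concentration_series(
            model, phis, NoiseModel(seed=4), structure_factor=False,
        )
        # calibrate against the simulated sphere: I(0)/(c*MW_true)
        mw_true = 4.0 / 3.0 * np.pi * 30.0**3 * 0.825033
        calib = model.forward_intensity_per_conc / mw_true
        rep = concentration_dependence(cs, calib=calib)
        assert rep.estimated_concentrations is not None
        np.testing.assert_allclose(
            rep.estimated_concentrations, [1.0, 2.0, 5.0], rtol=0.10
        )
        assert rep.impact_units == "percent_per_mg_ml"


class TestProfileParameters:
    def test_clean_sphere_fills_pr_slots(self, sphere30):
        pp = profile_parameters(sphere30)
        assert np.isfinite(pp.values["rg_pr"])
        assert np.isfinite(pp.values["i0_pr"])
        assert np.isfinite(pp.values["dmax"])
        assert np.isfinite(pp.values["mw_porod"])
        assert np.isfinite(pp.values["rg_g1"])
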