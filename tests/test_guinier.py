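import numpy as np
import pytest

from saxsqc.guinier import (
    guinier_fit,
    guinier_regions,
    iterate_guinier,
    nonlinearity_test,
    rg_seed,
)
from saxsqc.io_formats import ScatteringProfile
from saxsqc.simulate import (
    DamageModel,
    NoiseModel,
    ParticleModel,
    make_exposure_series,
)
from saxsqc.stats_core import average_profiles

from conftest import SPHERE_RG


def exact_guinier_profile(rg=23.238, i0=2.0, q=None):
    q = np.linspace(0.005, 0.1, 200) if q is None else q
    intensity = i0 * np.exp(-(rg**2) / 3.0 * q**2)
    return ScatteringProfile(q, intensity, 0.01 * intensity + 1e-9)


class TestGuinierFit:
    def test_exact_slope_recovers_rg(self):
        # ln I linear in q^2 with slope -100 -> rg = sqrt(300)
        prof = exact_guinier_profile(rg=np.sqrt(300.0))
        fit = guinier_fit(prof, prof.q[0], prof.q[-1])
        assert fit.rg == pytest.approx(np.sqrt(300.0), rel=1e-8)
        assert fit.i0 == pytest.approx(2.0, rel=1e-8)

    def test_noiseless_sphere_rg_within_systematic_bias(self, sphere30):
        # fitting a sphere all the way to q*Rg = 1.3 carries a known ~+2%
        # systematic from the q^4 term of the form factor
        fit = guinier_fit(sphere30, sphere30.q[0], 1.3 / SPHERE_RG)
        assert fit.rg == pytest.approx(SPHERE_RG, rel=0.021)

    def test_scale_invariance_of_rg(self, noisy_sphere):
        prof = noisy_sphere(3)
        big = prof.scaled(137.0)
        f1 = guinier_fit(prof, 0.01, 1.3 / SPHERE_RG)
        f2 = guinier_fit(big, 0.01, 1.3 / SPHERE_RG)
        assert f2.rg == pytest.approx(f1.rg, rel=1e-12)
        assert f2.i0 == pytest.approx(137.0 * f1.i0, rel=1e-9)

    def test_flat_profile_flagged_not_raised(self):
        q = np.linspace(0.01, 0.1, 50)
        prof = ScatteringProfile(q, np.full(50, 2.0), np.full(50, 0.02))
        fit = guinier_fit(prof, 0.01, 0.1)
        assert not fit.ok and np.isnan(fit.rg)

    def test_too_few_points_raises(self, sphere30):
        with pytest.raises(ValueError):
            guinier_fit(sphere30, 0.010, 0.0105)


class TestGuinierRegions:
    def test_region_bounds_arithmetic(self):
        q = np.linspace(0.01, 0.35, 500)
        regions = guinier_regions(23.24, 60.0, q)
        r1, r2, r3 = regions
        assert r1.q_min_G == pytest.approx(0.01)
        assert r2.q_min_G == pytest.approx(np.pi / 60.0)      # 0.05236
        assert r2.q_max_G == pytest.approx(1.3 / 23.24)       # 0.05594
        assert r3.q_min_G == pytest.approx(0.65 / 23.24)

    def test_region3_lower_bound_is_half_its_upper(self):
        regions = guinier_regions(23.24, 60.0, np.linspace(0.01, 0.35, 500))
        r3 = regions[2]
        assert r3.q_min_G == pytest.approx(r3.q_max_G / 2.0)

    def test_clipping_to_measured_grid(self):
        q = np.linspace(0.06, 0.35, 300)
        regions = guinier_regions(15.0, 60.0, q)
        assert regions[1].q_min_G == pytest.approx(0.06)

    def test_sparse_region_marked_unusable(self):
        q = np.linspace(0.01, 0.35, 30)  # coarse grid
        regions = guinier_regions(23.24, 60.0, q)
        assert not regions[1].usable

    def test_region3_inside_region1(self):
        regions = guinier_regions(20.0, 70.0, np.linspace(0.01, 0.35, 500))
        r1, _, r3 = regions
        assert r1.q_min_G <= r3.q_min_G and r3.q_max_G <= r1.q_max_G


class TestIterateGuinier:
    def test_converges_from_bad_seed(self, sphere30):
        res = iterate_guinier(sphere30, rg_seed=1.5 * SPHERE_RG)
        assert res.converged
        assert res.rg == pytest.approx(SPHERE_RG, rel=0.021)

    def test_correct_seed_is_fixed_point(self, sphere30):
        res1 = iterate_guinier(sphere30, rg_seed=SPHERE_RG)
        res2 = iterate_guinier(sphere30, rg_seed=res1.rg)
        assert res2.rg == pytest.approx(res1.rg, rel=0.01)

    def test_flat_profile_propagates_flag(self):
        q = np.linspace(0.01, 0.1, 50)
        prof = ScatteringProfile(q, np.full(50, 2.0), np.full(50, 0.02))
        res = iterate_guinier(prof, rg_seed=20.0)
        assert not res.ok


class TestNonlinearity:
    def test_exact_guinier_law_gives_p_one(self):
        prof = exact_guinier_profile()
        res = nonlinearity_test(prof, prof.q[0], 1.3 / 23.238)
        assert res.p == 1.0
        assert res.sign == "none"

    def test_n_windows_bookkeeping(self):
        prof = exact_guinier_profile()
        n_in = int(np.sum((prof.q >= prof.q[0]) & (prof.q < 1.3 / 23.238)))
        res = nonlinearity_test(prof, prof.q[0], 1.3 / 23.238)
        assert res.n_windows == n_in - 2

    def test_q4_curvature_detected_as_repulsive_shape(self):
        q = np.linspace(0.005, 0.06, 200)
        intensity = np.exp(-(23.238**2) / 3.0 * q**2 - 5e4 * q**4)
        prof = ScatteringProfile(q, intensity, 0.01 * intensity + 1e-9)
        res = nonlinearity_test(prof, q[0], 1.3 / 23.238)
        assert res.p <= 0.05
        assert res.sign == "repulsive"

    def test_too_few_points_gives_nan(self, sphere30):
        res = nonlinearity_test(sphere30, 0.01, 0.012)
        assert np.isnan(res.p) and res.sign == "none"

    def test_trace_aggregate_flagged_attractive(self):
        # 3% (by mass) of a 3x-larger sphere dominates the lowest q; on the
        # 8-frame averaged profile the upturn must read as attraction
        hits = 0
        n = 25
        for seed in range(n):
            es = make_exposure_series(
                ParticleModel(radius=30.0), DamageModel(), NoiseModel(seed=seed),
                n_frames=8, trace_aggregate_fraction=0.03,
            )
            avg = average_profiles(es.profiles)
            res = nonlinearity_test(avg, avg.q[0], 1.3 / rg_seed(avg))
            hits += res.sign == "attractive"
        assert hits / n >= 0.80
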