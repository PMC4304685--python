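"""Synthetic SAXS exposure and dilution series with known ground truth.

The generator produces everything the quality-assessment pipeline consumes:
single noiseless form-factor curves (sphere, prolate ellipsoid), a
Percus–Yevick hard-sphere structure factor of tunable strength for
interparticle-interference effects, per-frame monotone growth of particle
size and forward scattering (the phenomenology of radiation damage), and
serial-dilution concentration series with optionally imperfect dilution
factors.  Noise is Gaussian with σ(q) = sigma_fraction·I(q) + floor and the
σ column always reports the true σ used, so reduced-χ² comparisons of two
realizations of the same curve are calibrated to 1 by construction.

Ground truth for a homogeneous sphere of radius R: R_g = R·(3/5)^½,
D_max = 2R, volume = 4πR³/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ConcentrationSeries, ExposureSeries, ScatteringProfile

#: protein mass density used to map hard-sphere volume fraction to mg/ml
PROTEIN_DENSITY_MG_ML = 1370.0  # 1.37 g/cm³

DEFAULT_Q_GRID = np.linspace(0.01, 0.35, 500)


@dataclass
class ParticleModel:
    """Scattering particle: a sphere or a prolate ellipsoid of revolution.

    ``radius`` is the sphere radius in Å; for an ellipsoid, ``semi_axis_a``
    is the polar (long) semi-axis and ``radius`` the equatorial one.
    ``forward_intensity_per_conc`` sets I(0) per mg ml⁻¹ in arbitrary units.
    """

    shape: str = "sphere"  # "sphere" | "ellipsoid"
    radius: float = 30.0
    semi_axis_a: float | None = None
    forward_intensity_per_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "ellipsoid":
            if self.semi_axis_a is None or self.semi_axis_a <= 0:
                raise ValueError("ellipsoid needs a positive polar semi-axis")

    def form_factor_intensity(self, q: np.ndarray) -> np.ndarray:
        """Normalized single-particle intensity F²(q) with F²(0) = 1."""
        if self.shape == "sphere":
            return _sphere_ff(q, self.radius)
        return _ellipsoid_ff(q, self.semi_axis_a, self.radius)


@dataclass
class DamageModel:
    """Geometric per-frame drift emulating cumulative radiation damage.

    Frame k (1-based) uses radius·(1+rg_drift_per_frame)^(k−1) and forward
    intensity·(1+i0_drift_per_frame)^(k−1).
    """

    rg_drift_per_frame: float = 0.0
    i0_drift_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.rg_drift_per_frame < 0 or self.i0_drift_per_frame < 0:
            raise ValueError("drift rates must be non-negative")


@dataclass
class NoiseModel:
    """Gaussian noise with σ(q) = sigma_fraction·I(q) + floor."""

    sigma_fraction: float = 0.01
    floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_fraction < 0:
            raise ValueError("sigma_fraction must be non-negative")
        if self.floor <= 0:
            raise ValueError("floor must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sigma(self, intensity: np.ndarray) -> np.ndarray:
        return self.sigma_fraction * np.abs(intensity) + self.floor


def _sphere_ff(q: np.ndarray, radius: float) -> np.ndarray:
    x = np.asarray(q, dtype=float) * radius
    amp = np.ones_like(x)
    nz = x != 0
    xn = x[nz]
    amp[nz] = 3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn**3
    return amp**2


def _ellipsoid_ff(
    q: np.ndarray, a: float, b: float, n_quad: int = 128
) -> np.ndarray:
    # orientational average over cos(theta) by Gauss-Legendre quadrature
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    mu = 0.5 * (nodes + 1.0)  # cos(theta) on [0, 1]
    w = 0.5 * weights
    r_eff = np.sqrt(a**2 * mu**2 + b**2 * (1.0 - mu**2))  # (n_quad,)
    x = np.outer(np.asarray(q, dtype=float), r_eff)  # (nq, n_quad)
    amp = np.where(
        x == 0, 1.0, 3.0 * (np.sin(x) - x * np.cos(x)) / np.where(x == 0, 1.0, x) ** 3
    )
    return (amp**2) @ w


def sphere_profile(
    radius: float,
    q_grid: np.ndarray | None = None,
    scale: float = 1.0,
    label: str = "sphere",
) -> ScatteringProfile:
    """Noiseless sphere scattering curve; σ is set to a nominal 1% of I.

    I(q) = scale·[3(sin qR − qR·cos qR)/(qR)³]², so I → scale as q → 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = DEFAULT_Q_GRID.copy() if q_grid is None else np.asarray(q_grid, dtype=float)
    intensity = scale * _sphere_ff(q, radius)
    sigma = 0.01 * np.abs(intensity) + 1e-6 * scale
    return ScatteringProfile(q, intensity, sigma, label=label)


def hard_sphere_sf(
    q_grid: np.ndarray, radius: float, volume_fraction: float
) -> np.ndarray:
    """Percus–Yevick structure factor of a hard-sphere fluid.

    At ``volume_fraction`` 0 this is exactly 1 at every q (dilute limit);
    as the packing grows, low-q intensity is suppressed (repulsion) and a
    correlation peak appears near q ≈ 2π/(2R).
    """
    if not 0.0 <= volume_fraction < 0.3:
        raise ValueError("volume_fraction must be in [0, 0.3)")
    q = np.asarray(q_grid, dtype=float)
    if volume_fraction == 0.0:
        return np.ones_like(q)
    phi = volume_fraction
    alpha = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    beta = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    gamma = phi * alpha / 2.0
    A = 2.0 * q * radius
    # series-safe evaluation: use the analytic A->0 limit below a threshold
    small = A < 1e-3
    As = np.where(small, 1.0, A)
    sinA, cosA = np.sin(As), np.cos(As)
    G = (
        alpha * (sinA - As * cosA) / As**2
        + beta * (2.0 * As * sinA + (2.0 - As**2) * cosA - 2.0) / As**3
        + gamma
        * (-(As**4) * cosA + 4.0 * ((3.0 * As**2 - 6.0) * cosA + (As**3 - 6.0 * As) * sinA + 6.0))
        / As**5
    )
    S = 1.0 / (1.0 + 24.0 * phi * G / As)
    # c(0) limit: S(0) = (1-phi)^4 / (1+2 phi)^2
    S0 = (1.0 - phi) ** 4 / (1.0 + 2.0 * phi) ** 2
    return np.where(small, S0, S)


def _noisy(
    q: np.ndarray,
    intensity: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    label: str,
) -> ScatteringProfile:
    sigma = noise.sigma(intensity)
    noisy_i = intensity + rng.normal(0.0, sigma)
    return ScatteringProfile(q, noisy_i, sigma, label=label)


def make_exposure_series(
    model: ParticleModel,
    damage: DamageModel,
    noise: NoiseModel,
    n_frames: int = 8,
    q_grid: np.ndarray | None = None,
    concentration_mg_ml: float = 1.0,
    trace_aggregate_fraction: float = 0.0,
    aggregate_radius_factor: float = 3.0,
    noiseless: bool = False,
) -> ExposureSeries:
    """Simulate consecutive exposures of one sample.

    Frame k scales the particle radius by (1+rg_drift)^(k−1) and the forward
    intensity by (1+i0_drift)^(k−1); each frame gets independent Gaussian
    noise drawn from one generator seeded by ``noise.seed``.
    ``trace_aggregate_fraction`` is the mass fraction of material present as
    an aggregate sphere ``aggregate_radius_factor`` times larger.  Forward
    scattering per unit mass scales with particle volume, so even a small
    mass fraction of a large aggregate dominates the lowest-q intensity —
    the classic low-q upturn read as apparent attraction.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    q = DEFAULT_Q_GRID.copy() if q_grid is None else np.asarray(q_grid, dtype=float)
    rng = noise.rng()
    i0 = model.forward_intensity_per_conc * concentration_mg_ml
    profiles = []
    for k in range(1, n_frames + 1):
        r_k = model.radius * (1.0 + damage.rg_drift_per_frame) ** (k - 1)
        i0_k = i0 * (1.0 + damage.i0_drift_per_frame) ** (k - 1)
        frame_model = ParticleModel(
            shape=model.shape,
            radius=r_k,
            semi_axis_a=None
            if model.semi_axis_a is None
            else model.semi_axis_a * (1.0 + damage.rg_drift_per_frame) ** (k - 1),
            forward_intensity_per_conc=model.forward_intensity_per_conc,
        )
        intensity = i0_k * frame_model.form_factor_intensity(q)
        if trace_aggregate_fraction > 0.0:
            f = trace_aggregate_fraction
            v_ratio = aggregate_radius_factor**3
            w_agg = f * v_ratio / ((1.0 - f) + f * v_ratio)
            r_agg = r_k * aggregate_radius_factor
            intensity = (1.0 - w_agg) * intensity + (
                w_agg * i0_k * _sphere_ff(q, r_agg)
            )
        label = f"expo{k}"
        if noiseless:
            profiles.append(
                ScatteringProfile(q, intensity, noise.sigma(intensity), label=label)
            )
        else:
            profiles.append(_noisy(q, intensity, noise, rng, label))
    return ExposureSeries(profiles)


def make_concentration_series(
    model: ParticleModel,
    volume_fractions: list[float] | np.ndarray,
    noise: NoiseModel,
    q_grid: np.ndarray | None = None,
    structure_factor: bool = True,
    dilution_error: float = 0.0,
    noiseless: bool = False,
) -> ConcentrationSeries:
    """Simulate a dilution series, lowest concentration first.

    Member i is scale_i·F²(q)·S(q; φ_i) + noise with scale_i ∝ φ_i.  The
    hard-sphere structure factor can be switched off (``structure_factor
    False``) to produce an ideal, interaction-free series.
    ``dilution_error`` perturbs each member's true concentration by a
    relative Gaussian factor, emulating imperfect serial dilution.
    """
    phis = np.asarray(volume_fractions, dtype=float)
    if len(phis) < 3:
        raise ValueError("need at least 3 concentrations")
    q = DEFAULT_Q_GRID.copy() if q_grid is None else np.asarray(q_grid, dtype=float)
    rng = noise.rng()
    ff = model.form_factor_intensity(q)
    profiles, concs = [], []
    for i, phi in enumerate(phis):
        phi_true = phi
        if dilution_error > 0.0:
            phi_true = phi * max(0.1, 1.0 + dilution_error * rng.normal())
        conc = phi_true * PROTEIN_DENSITY_MG_ML
        sf = hard_sphere_sf(q, model.radius, phi_true) if structure_factor else 1.0
        intensity = model.forward_intensity_per_conc * conc * ff * sf
        label = f"conc{i + 1}"
        if noiseless:
            profiles.append(
                ScatteringProfile(q, intensity, noise.sigma(intensity), label=label)
            )
        else:
            profiles.append(_noisy(q, intensity, noise, rng, label))
        concs.append(conc)
    return ConcentrationSeries(profiles, nominal_concentration=concs)


@dataclass
class SimulatedSample:
    """A full simulated sample: exposure series per concentration."""

    exposure_series: list[ExposureSeries]
    concentrations_mg_ml: list[float]
    model: ParticleModel
    seed: int


def make_sample(
    model: ParticleModel,
    volume_fractions: list[float],
    noise: NoiseModel,
    damage: DamageModel | None = None,
    n_frames: int = 8,
    q_grid: np.ndarray | None = None,
    structure_factor: bool = True,
) -> SimulatedSample:
    """Simulate the full acquisition of one sample: ``n_frames`` exposures at
    each of several concentrations, with optional damage drift and
    interparticle interference."""
    damage = damage or DamageModel()
    q = DEFAULT_Q_GRID.copy() if q_grid is None else np.asarray(q_grid, dtype=float)
    series, concs = [], []
    for i, phi in enumerate(volume_fractions):
        conc = phi * PROTEIN_DENSITY_MG_ML
        sf = hard_sphere_sf(q, model.radius, phi) if structure_factor else np.ones_like(q)
        sub_noise = NoiseModel(
            sigma_fraction=noise.sigma_fraction,
            floor=noise.floor,
            seed=noise.seed + 1000 * (i + 1),
        )
        rng = sub_noise.rng()
        i0 = model.forward_intensity_per_conc * conc
        profiles = []
        for k in range(1, n_frames + 1):
            r_k = model.radius * (1.0 + damage.rg_drift_per_frame) ** (k - 1)
            i0_k = i0 * (1.0 + damage.i0_drift_per_frame) ** (k - 1)
            intensity = i0_k * _sphere_ff(q, r_k) * sf
            profiles.append(_noisy(q, intensity, sub_noise, rng, f"c{i + 1}_e{k}"))
        series.append(ExposureSeries(profiles))
        concs.append(conc)
    return SimulatedSample(series, concs, model, noise.seed)
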