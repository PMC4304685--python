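"""Reading and writing 1-D SAXS profiles and series manifests.

Profiles are plain whitespace-delimited text with three columns — momentum
transfer q (Å⁻¹), intensity I(q) (arbitrary units) and the 1σ uncertainty of
the intensity.  Lines starting with ``#`` and non-numeric header lines are
skipped; columns beyond the third are ignored (several beamline dialects
append per-point flags).  A manifest (YAML or JSON) groups profile files into
per-concentration exposure series for one or more samples.

All downstream analysis consumes only the in-memory containers defined here:
:class:`ScatteringProfile`, :class:`ExposureSeries` and
:class:`ConcentrationSeries`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: relative tolerance for deciding that two profiles share one q grid
GRID_RTOL = 1e-8

#: minimum number of valid points for a usable profile
MIN_POINTS = 10


class ProfileFormatError(ValueError):
    """A profile file could not be parsed into a valid scattering profile."""


class SeriesError(ValueError):
    """Profiles grouped into a series violate the series contract."""


@dataclass
class ScatteringProfile:
    """One buffer-subtracted 1-D scattering curve.

    Parameters
    ----------
    q
        Momentum transfer values in Å⁻¹, strictly increasing and positive.
    intensity
        I(q) at each q, arbitrary units.
    sigma
        1σ uncertainty of the intensity, same units, strictly positive.
    label
        Free-text identifier, typically the file stem.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ProfileFormatError("q, intensity and sigma must have equal length")
        if len(self.q) < MIN_POINTS:
            raise ProfileFormatError(
                f"profile {self.label!r} has {len(self.q)} points; "
                f"at least {MIN_POINTS} required"
            )
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ProfileFormatError("q must be positive and strictly increasing")
        if np.any(self.sigma <= 0):
            raise ProfileFormatError("sigma must be positive everywhere")

    def __len__(self) -> int:
        return len(self.q)

    def same_grid(self, other: "ScatteringProfile") -> bool:
        return len(self) == len(other) and np.allclose(
            self.q, other.q, rtol=GRID_RTOL, atol=0.0
        )

    def scaled(self, factor: float, label: str | None = None) -> "ScatteringProfile":
        """Return a copy with intensity and sigma multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ScatteringProfile(
            self.q.copy(),
            self.intensity * factor,
            self.sigma * factor,
            label if label is not None else self.label,
        )


@dataclass
class ExposureSeries:
    """Ordered consecutive exposures of one sample at one concentration.

    All profiles must share an identical q grid; at least three exposures are
    required so a trend test has at least one degree of freedom.
    """

    profiles: list[ScatteringProfile]
    exposure_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.profiles) < 3:
            raise SeriesError("an exposure series needs at least 3 frames")
        first = self.profiles[0]
        for p in self.profiles[1:]:
            if not first.same_grid(p):
                raise SeriesError(
                    f"profile {p.label!r} is not on the q grid of {first.label!r}"
                )
        if not self.exposure_index:
            self.exposure_index = list(range(1, len(self.profiles) + 1))
        if len(self.exposure_index) != len(self.profiles):
            raise SeriesError("exposure_index length must match number of profiles")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0].q


@dataclass
class ConcentrationSeries:
    """Per-concentration averaged profiles of one sample, lowest first.

    ``nominal_concentration`` (mg ml⁻¹) is optional and only used for
    reporting; the regression abscissae are the relative scale factors
    computed from the data themselves.
    """

    profiles: list[ScatteringProfile]
    nominal_concentration: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.profiles) < 3:
            raise SeriesError(
                "concentration-dependence analysis requires at least 3 concentrations"
            )
        first = self.profiles[0]
        for p in self.profiles[1:]:
            if not first.same_grid(p):
                raise SeriesError("concentration series members must share one q grid")
        if self.nominal_concentration is not None and len(
            self.nominal_concentration
        ) != len(self.profiles):
            raise SeriesError("nominal_concentration length mismatch")

    def __len__(self) -> int:
        return len(self.profiles)


def read_profile(path: str | Path, q_units: str = "A^-1") -> ScatteringProfile:
    """Read a 3-column (q, I, σ) text profile.

    Comment lines (``#``) and non-numeric header lines are skipped.  Rows with
    non-positive q or σ are dropped with a logged count.  ``q_units`` may be
    ``"A^-1"`` (default) or ``"nm^-1"``; nm⁻¹ values are divided by 10 so the
    in-memory grid is always Å⁻¹.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            try:
                q, i, s = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                continue  # header / footer text
            if q <= 0 or s <= 0:
                n_dropped += 1
                continue
            rows.append((q, i, s))
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-positive q or sigma", path, n_dropped)
    if len(rows) < MIN_POINTS:
        raise ProfileFormatError(
            f"{path}: only {len(rows)} valid data rows (need ≥ {MIN_POINTS})"
        )
    arr = np.array(rows, dtype=float)
    q = arr[:, 0]
    if q_units == "nm^-1":
        q = q / 10.0
    elif q_units != "A^-1":
        raise ValueError(f"unknown q_units {q_units!r}")
    return ScatteringProfile(q, arr[:, 1], arr[:, 2], label=path.stem)


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a profile as 3-column text at full precision (9+ digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {profile.label}\n")
        fh.write("# q(A^-1)  I(q)  sigma\n")
        for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
            fh.write(f"{q:.12e} {i:.12e} {s:.12e}\n")


def read_manifest(path: str | Path) -> dict:
    """Read a YAML/JSON manifest describing samples and their series.

    Expected layout::

        samples:
          - name: sample_1
            concentrations:
              - nominal_mg_ml: 1.0     # optional
                exposures: [s1_c1_e1.dat, s1_c1_e2.dat, ...]
              - ...
        q_units: A^-1                  # optional
        calibration_constant: 1.0e-6   # optional, units per (mg/ml · Da)

    Relative exposure paths are resolved against the manifest directory.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "samples" not in manifest:
        raise ProfileFormatError(f"{path}: manifest must contain a 'samples' list")
    manifest.setdefault("q_units", "A^-1")
    manifest["_base_dir"] = str(path.parent)
    return manifest


def load_sample(manifest: dict, sample_entry: dict) -> list[ExposureSeries]:
    """Load every concentration's exposure series for one manifest sample."""
    base = Path(manifest.get("_base_dir", "."))
    q_units = manifest.get("q_units", "A^-1")
    series = []
    for conc in sample_entry["concentrations"]:
        profiles = [
            read_profile(base / f, q_units=q_units) for f in conc["exposures"]
        ]
        series.append(ExposureSeries(profiles))
    return series


def write_manifest(manifest: dict, path: str | Path) -> None:
    clean = {k: v for k, v in manifest.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=False)
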