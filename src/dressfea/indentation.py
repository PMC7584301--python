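"""Flat-punch indentation analysis: effective dressing moduli from
load-displacement curves.

A rigid flat-ended cylindrical punch (radius a) on an elastic layer of
thickness t bonded to a rigid base has initial stiffness

    dF/dδ = 2 a E / (1 − ν²) · κ(a/t),

where κ ≥ 1 is a bonded-layer confinement correction (κ = 1 recovers the
elastic half-space).  The effective modulus is identified from the fitted
slope over an early-compression window (default 5–25 % of the layer
thickness, avoiding toe-in seating artifacts and large-strain
stiffening), and the conservative rule picks the minimum modulus across
all probed locations and samples.

Units: displacement mm, force N, modulus kPa.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataQualityError",
    "SamplingError",
    "ProbeSpec",
    "IndentationCurve",
    "EffectiveModulusResult",
    "layer_correction",
    "flat_punch_force",
    "effective_modulus_from_curve",
    "analyze_replicates",
    "conservative_modulus",
    "write_curves",
    "read_curves",
]


class DataQualityError(ValueError):
    """Curve unusable: zero/negative or non-monotone force in the window."""


class SamplingError(ValueError):
    """Too few samples inside the fit window."""


@dataclass(frozen=True)
class ProbeSpec:
    """Flat-punch probe: 6 mm cylinder, 1 mm/s, to 50 % compression."""

    diameter: float = 6.0  # mm
    compression_rate: float = 1.0  # mm/s
    peak_displacement_fraction: float = 0.5

    def __post_init__(self):
        if self.diameter <= 0 or self.compression_rate <= 0:
            raise ValueError("probe dimensions/rate must be positive")
        if not (0 < self.peak_displacement_fraction <= 1):
            raise ValueError("peak displacement fraction must lie in (0, 1]")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class IndentationCurve:
    """One load-displacement record for a dressing sample."""

    displacement: np.ndarray  # mm, monotone non-decreasing, starts at 0
    force: np.ndarray  # N
    sample_thickness: float  # mm
    dressing_name: str = ""
    location_id: int = 0
    replicate_id: int = 0

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        self.force = np.asarray(self.force, float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D arrays")
        if self.sample_thickness <= 0:
            raise ValueError("sample thickness must be positive")
        if self.displacement.size and abs(self.displacement[0]) > 1e-12:
            raise ValueError("displacement must start at 0")
        if (np.diff(self.displacement) < -1e-12).any():
            raise ValueError("displacement must be monotone non-decreasing")


@dataclass
class EffectiveModulusResult:
    modulus: float  # kPa
    fit_window: tuple  # (mm, mm)
    fit_quality: float  # R²
    replicate_moduli: list = field(default_factory=list)


def layer_correction(a_over_t: float) -> float:
    """Bonded-layer confinement factor κ(a/t) ≥ 1.

    Shull-type polynomial correction for a flat cylindrical punch on a
    layer bonded to a rigid substrate: κ = 1 + 1.33 (a/t) + 1.33 (a/t)³.
    """
    x = float(a_over_t)
    if x < 0:
        raise ValueError("a/t must be >= 0")
    return 1.0 + 1.33 * x + 1.33 * x**3


def flat_punch_force(
    displacement: np.ndarray,
    modulus_kpa: float,
    thickness: float,
    probe: ProbeSpec = ProbeSpec(),
    poisson: float = 0.1,
    bonded_layer: bool = True,
    stiffening: float = 0.0,
) -> np.ndarray:
    """Forward flat-punch model: force (N) at given displacement (mm).

    ``stiffening`` adds an optional large-strain term
    (1 + stiffening·(δ/t)²) emulating the upturn seen deep into
    compression; zero (default) keeps the ideal linear relation.
    """
    d = np.asarray(displacement, float)
    a = probe.radius
    kappa = layer_correction(a / thickness) if bonded_layer else 1.0
    E_MPa = modulus_kpa / 1000.0  # N/mm²
    k = 2.0 * a * E_MPa / (1.0 - poisson**2) * kappa  # N/mm
    return k * d * (1.0 + stiffening * (d / thickness) ** 2)


def effective_modulus_from_curve(
    curve: IndentationCurve,
    probe: ProbeSpec = ProbeSpec(),
    poisson: float = 0.1,
    bonded_layer: bool = True,
    window: tuple = (0.05, 0.25),
) -> EffectiveModulusResult:
    """Identify the effective modulus from the initial-slope fit.

    The slope dF/dδ is fitted by least squares (with intercept) over the
    compression window ``window`` (fractions of the sample thickness) and
    inverted through the flat-punch relation.
    """
    t = curve.sample_thickness
    lo, hi = window[0] * t, window[1] * t
    m = (curve.displacement >= lo) & (curve.displacement <= hi)
    if m.sum() < 5:
        raise SamplingError(
            f"only {int(m.sum())} samples in fit window [{lo:.3g}, {hi:.3g}] mm; need >= 5"
        )
    d, f = curve.displacement[m], curve.force[m]
    # reject broken records: flat/zero or grossly non-monotone force
    span = float(f.max() - f.min())
    if f.max() <= 0 or span <= 0:
        raise DataQualityError("force does not rise in the fit window")
    drops = np.diff(f)
    if (drops < -0.25 * span).any():
        raise DataQualityError("non-monotone force in the fit window")
    A = np.column_stack([d, np.ones_like(d)])
    coef, *_ = np.linalg.lstsq(A, f, rcond=None)
    slope = float(coef[0])
    if slope <= 0:
        raise DataQualityError("non-positive fitted slope")
    resid = f - A @ coef
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    a = probe.radius
    kappa = layer_correction(a / t) if bonded_layer else 1.0
    E_MPa = slope * (1.0 - poisson**2) / (2.0 * a * kappa)
    return EffectiveModulusResult(
        modulus=E_MPa * 1000.0,
        fit_window=(lo, hi),
        fit_quality=max(0.0, min(1.0, r2)),
        replicate_moduli=[E_MPa * 1000.0],
    )


def analyze_replicates(
    curves,
    probe: ProbeSpec = ProbeSpec(),
    **kwargs,
) -> list:
    """Fit every replicate curve; returns a list of results."""
    return [effective_modulus_from_curve(c, probe, **kwargs) for c in curves]


def conservative_modulus(results) -> float:
    """Minimum modulus across all replicates/locations (conservative rule)."""
    moduli = []
    for r in results:
        if isinstance(r, EffectiveModulusResult):
            moduli.extend(r.replicate_moduli or [r.modulus])
        else:
            moduli.append(float(r))
    if not moduli:
        raise ValueError("empty result list")
    return float(min(moduli))


# ---------------------------------------------------------------------------
# delimited-text curve I/O
# ---------------------------------------------------------------------------


def write_curves(curves, path) -> None:
    """Write curves as delimited text: per-curve header + CSV samples."""
    with open(path, "w") as fh:
        for c in curves:
            fh.write(
                f"# dressing={c.dressing_name or 'unknown'} "
                f"location={c.location_id} replicate={c.replicate_id} "
                f"thickness_mm={c.sample_thickness}\n"
            )
            fh.write("displacement_mm,force_N\n")
            for d, f in zip(c.displacement, c.force):
                fh.write(f"{d:.9g},{f:.9g}\n")
            fh.write("\n")


def read_curves(path) -> list:
    """Read curves written by :func:`write_curves` (one or many per file)."""
    curves = []
    header = None
    rows: list = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        arr = np.array(rows, float) if rows else np.zeros((0, 2))
        curves.append(
            IndentationCurve(
                displacement=arr[:, 0],
                force=arr[:, 1],
                sample_thickness=float(header.get("thickness_mm", 0) or 0),
                dressing_name=header.get("dressing", ""),
                location_id=int(header.get("location", 0)),
                replicate_id=int(header.get("replicate", 0)),
            )
        )
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                flush()
                header = dict(
                    kv.split("=", 1) for kv in line.lstrip("# ").split() if "=" in kv
                )
            elif not line or line.startswith("displacement"):
                continue
            else:
                rows.append([float(v) for v in line.split(",")])
    flush()
    return curves
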