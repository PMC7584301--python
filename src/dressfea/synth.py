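"""Synthetic inputs with known ground truth.

Provides the packaged nine-dressing parameter table (commercial silicone
foam dressings: effective foam stiffness and thickness, plus the
published %SED-reduction columns), noisy flat-punch indentation curves
generated from the same forward model the analysis inverts, and the
ready-to-solve ten-case scenario suite (nine dressings + the no-dressing
control) sharing one geometry, physiology materials, 0.4 friction and
the 40 N / 45° load case.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constitutive import BONE, MATTRESS, TISSUE, Material, dressing_material
from .geometry import DomainSpec
from .indentation import IndentationCurve, ProbeSpec, flat_punch_force
from .solver import ContactSpec, LoadCase

__all__ = [
    "DRESSING_NAMES",
    "packaged_dressing_table",
    "generate_indentation_curves",
    "ScenarioCase",
    "ScenarioSuite",
    "generate_scenario_suite",
]

# name: (foam stiffness kPa, foam thickness mm,
#        published % SED reduction: total, <0.5 kPa, >=0.5 kPa)
_TABLE = {
    "AGB": (30.8, 4.10, 25.2, 25.1, 37.8),
    "ALD": (14.2, 7.00, 23.8, 23.8, 31.1),
    "AFA": (7.4, 3.60, 20.9, 20.9, 30.9),
    "AFP": (23.5, 3.75, 23.0, 23.0, 30.3),
    "BSD": (11.3, 5.50, 21.6, 21.6, 29.0),
    "MBF": (13.9, 4.50, 22.0, 22.0, 30.7),
    "MBS": (17.5, 4.50, 23.7, 23.7, 34.8),
    "OGF": (17.5, 3.30, 24.1, 24.1, 35.5),
    "TSF": (19.0, 5.50, 24.6, 24.6, 35.3),
}

DRESSING_NAMES = tuple(_TABLE)


def packaged_dressing_table() -> pd.DataFrame:
    """The nine packaged dressing rows, verbatim published values."""
    rows = [
        {
            "Dressing": name,
            "Foam stiffness (kPa)": v[0],
            "Foam thickness (mm)": v[1],
            "% SED reduction in total": v[2],
            "% SED reduction of <0.5 kPa": v[3],
            "% SED reduction of ≥0.5 kPa": v[4],
        }
        for name, v in _TABLE.items()
    ]
    return pd.DataFrame(rows)


def generate_indentation_curves(
    true_modulus: float,
    thickness: float,
    probe: ProbeSpec = ProbeSpec(),
    noise_cv: float = 0.03,
    n_locations: int = 3,
    n_samples: int = 5,
    n_points: int = 120,
    seed=None,
    poisson: float = 0.1,
    bonded_layer: bool = True,
    stiffening: float = 0.0,
    dressing_name: str = "",
) -> list:
    """Noisy flat-punch curves with known ground-truth modulus.

    One curve per (location, sample) pair — the bench protocol probes
    3 locations on each of 5 samples per dressing type.  Noise is
    multiplicative Gaussian on force with coefficient of variation
    ``noise_cv`` (default 3 %), reproducible under a fixed ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_locations < 1 or n_samples < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    peak = probe.peak_displacement_fraction * thickness
    d = np.linspace(0.0, peak, n_points)
    curves = []
    for rep in range(n_samples):
        for loc in range(n_locations):
            f = flat_punch_force(
                d, true_modulus, thickness, probe, poisson, bonded_layer, stiffening
            )
            if noise_cv > 0:
                f = f * (1.0 + noise_cv * rng.standard_normal(f.shape))
            curves.append(
                IndentationCurve(
                    displacement=d.copy(),
                    force=f,
                    sample_thickness=thickness,
                    dressing_name=dressing_name,
                    location_id=loc,
                    replicate_id=rep,
                )
            )
    return curves


@dataclass(frozen=True)
class ScenarioCase:
    """One solvable case: a dressing (or the control) on shared geometry."""

    name: str
    spec: DomainSpec
    dressing: Material | None = None  # None = no-dressing control


@dataclass(frozen=True)
class ScenarioSuite:
    """Control + nine dressings; cases differ only in dressing layer."""

    spec: DomainSpec
    materials: dict
    load: LoadCase
    contact: ContactSpec  # dressing-mattress interface
    skin_contact: ContactSpec  # tissue-mattress interface (control case)
    cases: tuple

    def case(self, name: str) -> ScenarioCase:
        for c in self.cases:
            if c.name == name:
                return c
        raise KeyError(name)


def generate_scenario_suite(
    spec: DomainSpec | None = None,
    table: pd.DataFrame | None = None,
    load: LoadCase | None = None,
    friction: float = 0.4,
    skin_friction: float = 0.7,
    foam_poisson: float = 0.1,
    solid_fraction: float = 0.02,
) -> ScenarioSuite:
    """Build the ten ready-to-solve cases of the comparison study.

    All cases share geometry, tissue/bone/mattress materials and the
    40 N load at 45°; dressing cases differ only in layer thickness and
    foam material.  The dressing-mattress interface carries the
    "somewhat sticky" 0.4 friction; in the bare control the skin itself
    rests on the mattress, with the higher skin-support coefficient
    (default 0.7, typical of skin on textiles/foams).  Construction is
    pure: identical inputs give identical suites.
    """
    spec = spec if spec is not None else DomainSpec()
    table = table if table is not None else packaged_dressing_table()
    load = load if load is not None else LoadCase()
    materials = {"tissue": TISSUE, "bone": BONE, "mattress": MATTRESS}
    contact = ContactSpec(friction_coefficient=friction)
    skin_contact = ContactSpec(friction_coefficient=skin_friction)
    cases = [ScenarioCase("no_dressing", replace(spec, dressing_thickness=0.0), None)]
    for _, row in table.iterrows():
        name = str(row["Dressing"])
        E = float(row["Foam stiffness (kPa)"])
        t = float(row["Foam thickness (mm)"])
        mat = dressing_material(
            E, t, solid_fraction=solid_fraction, poisson_ratio=foam_poisson, name=name
        )
        cases.append(ScenarioCase(name, replace(spec, dressing_thickness=t), mat))
    return ScenarioSuite(
        spec=spec,
        materials=materials,
        load=load,
        contact=contact,
        skin_contact=skin_contact,
        cases=tuple(cases),
    )
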