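"""End-to-end scenario runs: mesh a case, solve to the target reaction,
quantify, and compare the dressing suite against the control.

The packaged reference scenario is a 2-D plane-strain sagittal section:
a 200 mm × 75 mm tissue block (250 mm out-of-plane) over a rounded bony
prominence driven at 45° until the mattress reaction reaches 40 N, on a
75 mm foam mattress, with the dressing bonded to the skin and a 0.4
friction contact against the mattress.  The default production
resolution is 0.15 elements/mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import build_layered_domain, Mesh
from .quantify import compare_dressings, default_edges
from .solver import (
    ContactPair,
    ContactSpec,
    Dirichlet,
    LoadCase,
    Problem,
    SolutionField,
    SolverSettings,
    force_targeted_solve,
)
from .synth import ScenarioCase, ScenarioSuite, generate_scenario_suite

__all__ = [
    "DEFAULT_RESOLUTION",
    "build_case_problem",
    "run_case",
    "run_suite",
    "SuiteResult",
]

DEFAULT_RESOLUTION = 0.15  # elements per mm


def default_penalty(suite: ScenarioSuite, case: ScenarioCase, mesh: Mesh) -> float:
    """Contact penalty: 50× the softer neighbor modulus per element length."""
    E_soft = suite.materials["mattress"].constants.E
    if case.dressing is not None:
        E_soft = min(E_soft, case.dressing.constants.E)
    else:
        E_soft = min(E_soft, suite.materials["tissue"].constants.E)
    h = case.spec.tissue_width / mesh.meta.get("nx", 30)
    return 50.0 * E_soft / h


def build_case_problem(
    suite: ScenarioSuite,
    case: ScenarioCase,
    resolution: float = DEFAULT_RESOLUTION,
) -> Problem:
    """Mesh one case and assemble its boundary conditions and contact."""
    mesh = build_layered_domain(case.spec, resolution)
    materials = dict(suite.materials)
    if case.dressing is not None:
        materials["dressing"] = case.dressing
    spec = suite.contact if case.dressing is not None else suite.skin_contact
    kn = spec.normal_penalty or default_penalty(suite, case, mesh)
    kt = spec.tangential_penalty or kn
    pair = ContactPair(mesh, spec, kn=kn, kt=kt)
    base = Dirichlet(nodes=mesh.boundary["mattress_base"], value=np.zeros(2))
    return Problem(mesh=mesh, materials=materials, dirichlet=[base], contacts=[pair])


def run_case(
    suite: ScenarioSuite,
    case: ScenarioCase,
    resolution: float = DEFAULT_RESOLUTION,
    settings: SolverSettings | None = None,
) -> SolutionField:
    """Solve one case to the target mattress reaction."""
    problem = build_case_problem(suite, case, resolution)
    sol = force_targeted_solve(problem, suite.load, settings)
    sol.meta["case"] = case.name
    return sol


@dataclass
class SuiteResult:
    solutions: dict
    report: pd.DataFrame
    resolution: float
    meta: dict = field(default_factory=dict)


def run_suite(
    suite: ScenarioSuite | None = None,
    resolution: float = DEFAULT_RESOLUTION,
    settings: SolverSettings | None = None,
    case_names=None,
    table: pd.DataFrame | None = None,
    edges: np.ndarray | None = None,
    progress=None,
) -> SuiteResult:
    """Run the control and the requested dressing cases; build the report."""
    suite = suite or generate_scenario_suite()
    if table is None:
        from .synth import packaged_dressing_table

        table = packaged_dressing_table()
    names = [c.name for c in suite.cases] if case_names is None else list(case_names)
    if "no_dressing" not in names:
        names = ["no_dressing"] + names
    solutions = {}
    for name in names:
        case = suite.case(name)
        if progress:
            progress(name)
        solutions[name] = run_case(suite, case, resolution, settings)
    control = solutions["no_dressing"]
    dressings = {k: v for k, v in solutions.items() if k != "no_dressing"}
    report = compare_dressings(
        control, dressings, table, edges if edges is not None else default_edges()
    )
    return SuiteResult(
        solutions=solutions,
        report=report,
        resolution=resolution,
        meta={
            "control_peak_tissue_sed_kpa": float(
                control.element_sed[control.mesh.region_elements("tissue")].max()
            )
        },
    )
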