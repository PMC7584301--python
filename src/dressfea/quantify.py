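"""Biomechanical quantification of converged solutions.

Strain energy density (SED) is the injury-risk surrogate: elastic energy
stored per unit volume of tissue.  The analysis bins soft-tissue SED into
a volume-weighted histogram over the analyzed range (default 0.05–1.0 kPa),
pools it at the 0.5 kPa potential-damage threshold, and compares the
pooled areas under the volume-vs-SED curve (AUC) between each dressing
and the shared no-dressing control:

    %SED reduction = (AUC_no_dressing − AUC_dressing) / AUC_no_dressing × 100.

The default histogram uses 19 uniform bins of width 0.05 kPa so the
0.5 kPa damage threshold falls exactly on a bin edge; volume below and
above the analyzed range is tracked separately, and the "≥ 0.5 kPa" pool
includes the above-range volume (at one bin width) by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import element_volumes
from .solver import SolutionField

__all__ = [
    "AlignmentError",
    "SEDHistogram",
    "PooledAUC",
    "default_edges",
    "sed_field",
    "distortional_stress_field",
    "volume_weighted_histogram",
    "pool_auc",
    "percent_sed_reduction",
    "compare_from_fields",
    "compare_dressings",
    "export_contour",
    "read_contour",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "Dressing",
    "Foam stiffness (kPa)",
    "Foam thickness (mm)",
    "% SED reduction in total",
    "% SED reduction of <0.5 kPa",
    "% SED reduction of ≥0.5 kPa",
]

DAMAGE_THRESHOLD_KPA = 0.5


class AlignmentError(ValueError):
    """Pooling threshold does not coincide with a histogram bin edge."""


def default_edges(lo: float = 0.05, hi: float = 1.0, n_bins: int = 19) -> np.ndarray:
    """Uniform bin edges over the analyzed SED range (kPa)."""
    return np.linspace(lo, hi, n_bins + 1)


@dataclass
class SEDHistogram:
    """Volume-weighted SED distribution over a tissue region."""

    bin_edges: np.ndarray  # (B+1,) kPa, strictly increasing
    bin_volumes: np.ndarray  # (B,) mm³
    under_volume: float  # volume with SED below the first edge
    over_volume: float  # volume with SED above the last edge
    total_volume: float
    normalization: str = "absolute"  # or "fraction"

    def as_fraction(self) -> "SEDHistogram":
        t = self.total_volume
        if t <= 0:
            raise ValueError("empty histogram")
        return SEDHistogram(
            bin_edges=self.bin_edges.copy(),
            bin_volumes=self.bin_volumes / t,
            under_volume=self.under_volume / t,
            over_volume=self.over_volume / t,
            total_volume=1.0,
            normalization="fraction",
        )

    def to_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame(
            {"bin_midpoint_kPa": mid, "tissue_volume": self.bin_volumes}
        )


@dataclass
class PooledAUC:
    """Rectangular AUC of the volume-vs-SED histogram per damage pool."""

    auc_low: float  # SED in [0, threshold)
    auc_high: float  # SED >= threshold
    threshold: float = DAMAGE_THRESHOLD_KPA

    @property
    def auc_total(self) -> float:
        return self.auc_low + self.auc_high


def sed_field(solution: SolutionField, region: str = "tissue") -> np.ndarray:
    """Per-element SED (kPa) restricted to one region label."""
    ids = solution.mesh.region_elements(region)
    if ids.size == 0:
        raise LookupError(f"region {region!r} absent from mesh")
    return solution.element_sed[ids]


def distortional_stress_field(
    solution: SolutionField, measure: str = "von_mises"
) -> np.ndarray:
    """Scalar distortional (shear) stress per element, kPa.

    ``von_mises`` (default) is the standard deviatoric equivalent stress;
    ``tresca`` gives twice the maximum shear stress.
    """
    sig = solution.element_stress
    if measure == "von_mises":
        tr = np.trace(sig, axis1=1, axis2=2) / 3.0
        dev = sig - tr[:, None, None] * np.eye(3)
        return np.sqrt(1.5 * np.einsum("eab,eab->e", dev, dev))
    if measure == "tresca":
        lam = np.linalg.eigvalsh(sig)
        return lam[:, -1] - lam[:, 0]
    raise ValueError(f"unknown measure {measure!r}")


def volume_weighted_histogram(
    field: np.ndarray,
    volumes: np.ndarray,
    edges: np.ndarray | None = None,
) -> SEDHistogram:
    """Accrue each element's volume to the bin containing its SED.

    Bins are half-open [lo, hi) with the last bin closed; volume falling
    below/above the edge range is tracked separately.
    """
    field = np.asarray(field, float)
    volumes = np.asarray(volumes, float)
    if field.shape != volumes.shape:
        raise ValueError("field and volumes must align")
    if (volumes < 0).any():
        raise ValueError("negative element volume")
    edges = default_edges() if edges is None else np.asarray(edges, float)
    if edges.ndim != 1 or edges.size < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("edges must be strictly increasing")
    under = field < edges[0]
    over = field > edges[-1]
    inside = ~(under | over)
    bins, _ = np.histogram(field[inside], bins=edges, weights=volumes[inside])
    return SEDHistogram(
        bin_edges=edges,
        bin_volumes=bins,
        under_volume=float(volumes[under].sum()),
        over_volume=float(volumes[over].sum()),
        total_volume=float(volumes.sum()),
    )


def pool_auc(
    hist: SEDHistogram,
    threshold: float = DAMAGE_THRESHOLD_KPA,
    include_overflow: bool = True,
) -> PooledAUC:
    """Pool the histogram at the damage threshold and compute per-pool AUC.

    AUC is the rectangular area Σ bin_volume × bin_width restricted to
    each pool.  With ``include_overflow`` the above-range volume joins
    the high pool at one mean bin width (it is tissue at SED "≥ 0.5 kPa
    and greater"); below-range volume lies outside the analyzed range
    and never contributes.
    """
    edges = hist.bin_edges
    j = np.argmin(np.abs(edges - threshold))
    if abs(edges[j] - threshold) > 1e-9 * max(1.0, abs(threshold)):
        raise AlignmentError(
            f"threshold {threshold} kPa is not a bin edge; re-bin the histogram"
        )
    widths = np.diff(edges)
    auc = hist.bin_volumes * widths
    low = float(auc[:j].sum())
    high = float(auc[j:].sum())
    if include_overflow:
        high += hist.over_volume * float(widths.mean())
    return PooledAUC(auc_low=low, auc_high=high, threshold=threshold)


def percent_sed_reduction(auc_no_dressing: float, auc_dressing: float) -> float:
    """((AUC_nd − AUC_d) / AUC_nd) · 100; positive = dressing reduces AUC."""
    if auc_no_dressing <= 0.0:
        raise ZeroDivisionError("no-dressing AUC must be positive")
    return (auc_no_dressing - auc_dressing) / auc_no_dressing * 100.0


def compare_from_fields(
    control: tuple[np.ndarray, np.ndarray],
    cases: dict,
    table: pd.DataFrame,
    edges: np.ndarray | None = None,
    threshold: float = DAMAGE_THRESHOLD_KPA,
    include_overflow: bool = True,
) -> pd.DataFrame:
    """Reduction report from raw (SED, volume) field pairs.

    ``control`` and each ``cases[name]`` are (sed, volumes) arrays for the
    soft-tissue region; ``table`` supplies the per-dressing stiffness and
    thickness columns (indexed by dressing name).
    """
    edges = default_edges() if edges is None else edges
    sed0, vol0 = control
    auc0 = pool_auc(volume_weighted_histogram(sed0, vol0, edges), threshold, include_overflow)
    rows = []
    tab = table.set_index("Dressing") if "Dressing" in table.columns else table
    for name, (sedd, vold) in cases.items():
        aucd = pool_auc(
            volume_weighted_histogram(sedd, vold, edges), threshold, include_overflow
        )
        stiff = thick = np.nan
        if name in tab.index:
            if "Foam stiffness (kPa)" in tab.columns:
                stiff = float(tab.loc[name, "Foam stiffness (kPa)"])
            if "Foam thickness (mm)" in tab.columns:
                thick = float(tab.loc[name, "Foam thickness (mm)"])
        rows.append(
            {
                REPORT_COLUMNS[0]: name,
                REPORT_COLUMNS[1]: stiff,
                REPORT_COLUMNS[2]: thick,
                REPORT_COLUMNS[3]: percent_sed_reduction(auc0.auc_total, aucd.auc_total),
                REPORT_COLUMNS[4]: percent_sed_reduction(auc0.auc_low, aucd.auc_low),
                REPORT_COLUMNS[5]: percent_sed_reduction(auc0.auc_high, aucd.auc_high),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _tissue_fields(solution: SolutionField, deformed: bool = False):
    ids = solution.mesh.region_elements("tissue")
    vols = element_volumes(solution.mesh, solution.u if deformed else None)
    return solution.element_sed[ids], vols[ids]


def compare_dressings(
    control: SolutionField,
    dressings: dict,
    table: pd.DataFrame,
    edges: np.ndarray | None = None,
    deformed_volumes: bool = False,
) -> pd.DataFrame:
    """Per-dressing %SED-reduction report versus the shared control.

    All solutions must share the soft-tissue mesh topology (identical
    element count and connectivity of the tissue region).  Reference
    element volumes are used by default.
    """
    ids0 = control.mesh.region_elements("tissue")
    ref = control.mesh.elements[ids0]
    for name, sol in dressings.items():
        ids = sol.mesh.region_elements("tissue")
        if ids.size != ids0.size or sol.mesh.elements[ids].shape != ref.shape:
            raise ValueError(f"case {name!r}: tissue mesh topology differs from control")
    cases = {
        name: _tissue_fields(sol, deformed_volumes) for name, sol in dressings.items()
    }
    return compare_from_fields(_tissue_fields(control, deformed_volumes), cases, table, edges)


def export_contour(
    solution: SolutionField,
    path,
    plane: str = "sagittal",
    field: str = "SED",
    fmt: str = "csv",
):
    """Write a cell field for external visualization, in MPa.

    In 2-D only the sagittal plane exists (``plane="axial"`` raises).
    ``fmt="csv"`` writes centroid x, y and the value; ``fmt="vtk"``
    writes a legacy VTK unstructured grid with the field as cell data.
    SED/stress are stored in kPa and converted to MPa on export only.
    """
    mesh = solution.mesh
    if mesh.dim == 2 and plane != "sagittal":
        raise ValueError("2-D models expose only the sagittal plane")
    if field == "SED":
        values = solution.element_sed / 1000.0
    elif field == "distortional":
        values = distortional_stress_field(solution) / 1000.0
    else:
        raise ValueError(f"unknown field {field!r}")
    if fmt == "vtk":
        from .vtkio import write_vtk

        write_vtk(
            mesh,
            path,
            point_data={"displacement": solution.u},
            cell_data={f"{field}_MPa": values},
        )
        return
    cent = mesh.nodes[mesh.elements].mean(axis=1)
    df = pd.DataFrame({"x_mm": cent[:, 0], "y_mm": cent[:, 1], f"{field}_MPa": values})
    df.to_csv(path, index=False)


def read_contour(path) -> pd.DataFrame:
    """Read back a CSV contour export."""
    return pd.read_csv(path)
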