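"""Constitutive models and elastic-constant algebra.

Materials in the layered sacral model:

* soft tissue — nearly incompressible neo-Hookean (G = 19.254 kPa,
  K = 1919.022 kPa, i.e. ν = 0.495);
* sacral bone — linear elastic, E = 3.4 GPa, ν = 0.36 (usually driven
  rigidly by the solver);
* foam mattress — E = 50 kPa, ν = 0.3;
* foam dressings — compressible neo-Hookean built from the effective
  indentation modulus, with a low foam Poisson ratio (default 0.1) and a
  solid volume fraction carried as metadata (default 2%).

Units throughout: lengths mm, stresses/moduli/energy densities kPa.

The compressible neo-Hookean energy is the classical form

    W(F) = G/2 (I1 - 3) - G ln J + λ/2 (ln J)²,

with I1 = tr(FᵀF), J = det F, and (G, λ) the shear modulus and Lamé
constant of the small-strain limit.  "Incompressible" tissue is realized
as nearly incompressible through its large bulk modulus; no mixed
formulation is claimed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidConstantsError",
    "InvertedStateError",
    "ElasticConstants",
    "Material",
    "DeformationState",
    "elastic_constants",
    "strain_energy_density",
    "first_piola_stress",
    "cauchy_stress",
    "material_tangent",
    "dressing_material",
    "TISSUE",
    "BONE",
    "MATTRESS",
]


class InvalidConstantsError(ValueError):
    """Elastic constants outside the admissible isotropic range."""


class InvertedStateError(ValueError):
    """Deformation gradient with non-positive Jacobian."""


@dataclass(frozen=True)
class ElasticConstants:
    """Consistent set of isotropic elastic constants (kPa where dimensional)."""

    E: float
    nu: float
    G: float
    K: float
    lam: float


_PAIR_NAMES = ("E", "nu", "G", "K", "lam")


def elastic_constants(**kwargs: float) -> ElasticConstants:
    """Build a full consistent set from exactly two independent constants.

    Accepted names: ``E`` (Young), ``nu`` (Poisson), ``G`` (shear),
    ``K`` (bulk), ``lam`` (Lamé λ).

    Raises
    ------
    InvalidConstantsError
        If not exactly two constants are given, the pair is unsupported,
        or the implied set violates G > 0, K > 0, −1 < ν < 0.5.
    """
    unknown = set(kwargs) - set(_PAIR_NAMES)
    if unknown:
        raise InvalidConstantsError(f"unknown constant name(s): {sorted(unknown)}")
    if len(kwargs) != 2:
        raise InvalidConstantsError(
            f"exactly two constants required, got {sorted(kwargs)}"
        )
    pair = frozenset(kwargs)
    v = dict(kwargs)
    try:
        if pair == {"G", "K"}:
            G, K = v["G"], v["K"]
        elif pair == {"E", "nu"}:
            E, nu = v["E"], v["nu"]
            _check_nu(nu)
            G = E / (2.0 * (1.0 + nu))
            K = E / (3.0 * (1.0 - 2.0 * nu))
        elif pair == {"G", "nu"}:
            G, nu = v["G"], v["nu"]
            _check_nu(nu)
            K = 2.0 * G * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
        elif pair == {"K", "nu"}:
            K, nu = v["K"], v["nu"]
            _check_nu(nu)
            G = 3.0 * K * (1.0 - 2.0 * nu) / (2.0 * (1.0 + nu))
        elif pair == {"E", "G"}:
            E, G = v["E"], v["G"]
            nu = E / (2.0 * G) - 1.0
            _check_nu(nu)
            K = E / (3.0 * (1.0 - 2.0 * nu))
        elif pair == {"E", "K"}:
            E, K = v["E"], v["K"]
            if 9.0 * K - E <= 0.0:
                raise InvalidConstantsError("E/K pair implies non-positive G")
            G = 3.0 * K * E / (9.0 * K - E)
        elif pair == {"G", "lam"}:
            G, lam = v["G"], v["lam"]
            K = lam + 2.0 * G / 3.0
        else:
            raise InvalidConstantsError(f"unsupported constant pair {sorted(pair)}")
    except ZeroDivisionError as exc:  # e.g. nu == 0.5 slipped through
        raise InvalidConstantsError(str(exc)) from exc

    if not (G > 0.0 and K > 0.0):
        raise InvalidConstantsError(f"implied G={G!r}, K={K!r} not both positive")
    nu = (3.0 * K - 2.0 * G) / (6.0 * K + 2.0 * G)
    if not (-1.0 < nu < 0.5):
        raise InvalidConstantsError(f"implied Poisson ratio {nu!r} outside (-1, 0.5)")
    E = 9.0 * K * G / (3.0 * K + G)
    lam = K - 2.0 * G / 3.0
    return ElasticConstants(E=E, nu=nu, G=G, K=K, lam=lam)


def _check_nu(nu: float) -> None:
    if not (-1.0 < nu < 0.5):
        raise InvalidConstantsError(f"Poisson ratio {nu!r} outside (-1, 0.5)")


@dataclass(frozen=True)
class Material:
    """Constitutive description of one mesh region.

    ``solid_fraction`` is the foam solid volume fraction φ; it is 1 for
    non-porous materials and recorded metadata for dressings (their
    mechanics are those of the homogenized compressible neo-Hookean
    solid built from the effective modulus).
    """

    family: str  # "neo_hookean" | "linear_elastic"
    constants: ElasticConstants
    solid_fraction: float = 1.0
    name: str = ""
    foam_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("neo_hookean", "linear_elastic"):
            raise ValueError(f"unknown material family {self.family!r}")
        if not (0.0 < self.solid_fraction <= 1.0):
            raise ValueError("solid_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class DeformationState:
    """Pointwise deformation gradient (3×3; 2-D states promoted with F33 = 1)."""

    F: np.ndarray

    @classmethod
    def from_F(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        if F.shape == (2, 2):
            F3 = np.eye(3)
            F3[:2, :2] = F
            F = F3
        if F.shape != (3, 3):
            raise ValueError("F must be 2x2 or 3x3")
        if np.linalg.det(F) <= 0.0:
            raise InvertedStateError(f"det F = {np.linalg.det(F)} <= 0")
        return cls(F=F)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1(self) -> float:
        return float(np.trace(self.F.T @ self.F))


def _require_valid(state: DeformationState) -> np.ndarray:
    F = np.asarray(state.F, dtype=float)
    if np.linalg.det(F) <= 0.0:
        raise InvertedStateError("deformation state has det F <= 0")
    return F


def strain_energy_density(state: DeformationState, mat: Material) -> float:
    """Energy per unit reference volume, kPa. Zero at the identity."""
    F = _require_valid(state)
    G, lam = mat.constants.G, mat.constants.lam
    if mat.family == "neo_hookean":
        J = np.linalg.det(F)
        I1 = np.trace(F.T @ F)
        lnJ = np.log(J)
        return float(0.5 * G * (I1 - 3.0) - G * lnJ + 0.5 * lam * lnJ**2)
    # geometrically linear branch: engineering strain from F
    eps = 0.5 * (F + F.T) - np.eye(3)
    tr = np.trace(eps)
    return float(0.5 * lam * tr**2 + G * np.tensordot(eps, eps))


def first_piola_stress(state: DeformationState, mat: Material) -> np.ndarray:
    """First Piola–Kirchhoff stress P = ∂W/∂F, kPa."""
    F = _require_valid(state)
    G, lam = mat.constants.G, mat.constants.lam
    if mat.family == "neo_hookean":
        J = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        return G * (F - Finv.T) + lam * np.log(J) * Finv.T
    eps = 0.5 * (F + F.T) - np.eye(3)
    return lam * np.trace(eps) * np.eye(3) + 2.0 * G * eps


def cauchy_stress(state: DeformationState, mat: Material) -> np.ndarray:
    """Cauchy stress tensor, kPa (symmetric; zero at the identity)."""
    F = _require_valid(state)
    if mat.family == "neo_hookean":
        J = np.linalg.det(F)
        P = first_piola_stress(state, mat)
        sig = P @ F.T / J
        return 0.5 * (sig + sig.T)  # symmetrize away round-off
    return first_piola_stress(state, mat)  # small strain: σ ≡ P


def material_tangent(state: DeformationState, mat: Material) -> np.ndarray:
    """First elasticity tensor A_iJkL = ∂P_iJ/∂F_kL (3×3×3×3), kPa.

    Possesses major symmetry A_iJkL = A_kLiJ for both families.
    """
    F = _require_valid(state)
    G, lam = mat.constants.G, mat.constants.lam
    I3 = np.eye(3)
    if mat.family == "neo_hookean":
        J = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        lnJ = np.log(J)
        A = G * np.einsum("ik,JL->iJkL", I3, I3)
        A += (G - lam * lnJ) * np.einsum("Jk,Li->iJkL", Finv, Finv)
        A += lam * np.einsum("Ji,Lk->iJkL", Finv, Finv)
        return A
    A = lam * np.einsum("iJ,kL->iJkL", I3, I3)
    A += G * (
        np.einsum("ik,JL->iJkL", I3, I3) + np.einsum("iL,Jk->iJkL", I3, I3)
    )
    return A


def dressing_material(
    effective_modulus: float,
    thickness: float,
    solid_fraction: float = 0.02,
    poisson_ratio: float = 0.1,
    name: str = "",
) -> Material:
    """Homogenized foam-dressing material from its effective modulus.

    The small-strain Young's modulus of the returned neo-Hookean solid
    equals ``effective_modulus`` (kPa); ``thickness`` (mm) is recorded for
    scenario construction; ``solid_fraction`` is metadata (see module
    docstring).
    """
    if effective_modulus <= 0.0:
        raise InvalidConstantsError("effective modulus must be positive")
    if thickness <= 0.0:
        raise InvalidConstantsError("dressing thickness must be positive")
    if not (0.0 < solid_fraction <= 1.0):
        raise InvalidConstantsError("solid fraction must lie in (0, 1]")
    consts = elastic_constants(E=effective_modulus, nu=poisson_ratio)
    return Material(
        family="neo_hookean",
        constants=consts,
        solid_fraction=solid_fraction,
        name=name,
        foam_thickness_mm=thickness,
    )


# Packaged physiology/support materials (printed constants).
TISSUE = Material(
    family="neo_hookean",
    constants=elastic_constants(G=19.254, K=1919.022),
    name="soft_tissue",
)
BONE = Material(
    family="linear_elastic",
    constants=elastic_constants(E=3.4e6, nu=0.36),  # 3.4 GPa in kPa
    name="sacral_bone",
)
MATTRESS = Material(
    family="neo_hookean",
    constants=elastic_constants(E=50.0, nu=0.3),
    name="foam_mattress",
)
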