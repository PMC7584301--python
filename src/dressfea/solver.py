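"""Quasi-static nonlinear finite-element solver (2-D plane strain).

Implements the mechanics of the layered sacral model: total-Lagrangian
bilinear quadrilaterals with analytic consistent tangents, selective
reduced integration of the volumetric energy for nearly incompressible
neo-Hookean regions (mean-point quadrature of the λ-term, preventing
volumetric locking at ν = 0.495), node-to-segment penalty contact with
Coulomb friction at the body-mattress interface, Newton iteration with
load stepping / automatic substepping / backtracking line search, and an
outer safeguarded secant that scales the prescribed oblique bone
displacement until the mattress-base reaction reaches the target force.

Unit system: mm, kPa.  Residual entries are kPa·mm² ( = mN per mm of
out-of-plane thickness); :func:`reaction_force` converts to newtons using
the mesh's out-of-plane thickness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import Material
from .geometry import Mesh, _quad_gradN, quad_gauss_points

__all__ = [
    "LoadCase",
    "ContactSpec",
    "ContactPair",
    "SolverSettings",
    "Dirichlet",
    "Problem",
    "SolutionField",
    "NonconvergenceError",
    "TargetUnreachableError",
    "StateInvalidError",
    "assemble",
    "newton_solve",
    "force_targeted_solve",
    "reaction_force",
]

FORCE_TO_N = 1e-3  # kPa·mm² per mm thickness → N per mm thickness


class NonconvergenceError(RuntimeError):
    def __init__(self, message: str, log: list | None = None):
        super().__init__(message)
        self.log = log or []


class TargetUnreachableError(RuntimeError):
    def __init__(self, message: str, attained_force: float):
        super().__init__(message)
        self.attained_force = attained_force


class StateInvalidError(RuntimeError):
    """Element inversion during assembly; carries the element id."""

    def __init__(self, element_id: int):
        super().__init__(f"inverted element {element_id} during assembly")
        self.element_id = element_id


@dataclass
class LoadCase:
    """Oblique displacement-controlled loading of the bone.

    ``direction_angle``: degrees from the mattress normal, tilting
    caudally (+x); 45° models Fowler's position.  The bone is displaced
    along this direction until the mattress reaction reaches
    ``target_reaction_force`` (N).
    """

    direction_angle: float = 45.0
    target_reaction_force: float = 40.0
    max_displacement_guess: float = 30.0

    def __post_init__(self):
        if not (0.0 <= self.direction_angle < 90.0):
            raise ValueError("direction_angle must be in [0, 90)")
        if self.target_reaction_force <= 0.0:
            raise ValueError("target force must be positive")

    @property
    def direction(self) -> np.ndarray:
        a = math.radians(self.direction_angle)
        return np.array([math.sin(a), -math.cos(a)])


@dataclass
class SolverSettings:
    load_steps: int = 10
    newton_tolerance: float = 1e-6
    max_newton_iterations: int = 60
    force_target_tolerance: float = 0.1
    line_search_enabled: bool = True

    def __post_init__(self):
        if self.newton_tolerance <= 0 or self.force_target_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.load_steps < 1 or self.max_newton_iterations < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class Dirichlet:
    """Prescribed displacement on a node set (value at load factor 1)."""

    nodes: np.ndarray
    value: np.ndarray  # (2,) displacement at full load
    mask: tuple = (True, True)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, int)
        self.value = np.asarray(self.value, float)


# ---------------------------------------------------------------------------
# batched 2x2 material point evaluation
# ---------------------------------------------------------------------------


def _det2(F):
    return F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]


def _inv2(F, det):
    inv = np.empty_like(F)
    inv[..., 0, 0] = F[..., 1, 1]
    inv[..., 1, 1] = F[..., 0, 0]
    inv[..., 0, 1] = -F[..., 0, 1]
    inv[..., 1, 0] = -F[..., 1, 0]
    return inv / det[..., None, None]


_I2 = np.eye(2)


def _eval_part(F: np.ndarray, mat: Material, part: str, want_tangent: bool):
    """Batched P, A, W, s33 for one energy part on 2x2 gradients.

    Parts: "iso"/"vol" split the neo-Hookean energy (G-terms / λ-term);
    "lin" is the geometrically linear branch.  s33 is the out-of-plane
    Cauchy stress contribution for plane strain.
    """
    G, lam = mat.constants.G, mat.constants.lam
    E = F.shape[0]
    if part == "lin":
        eps = 0.5 * (F + np.swapaxes(F, -1, -2)) - _I2
        tr = eps[..., 0, 0] + eps[..., 1, 1]
        P = lam * tr[..., None, None] * _I2 + 2.0 * G * eps
        W = 0.5 * lam * tr**2 + G * np.einsum("...ab,...ab->...", eps, eps)
        s33 = lam * tr
        A = None
        if want_tangent:
            A = np.broadcast_to(
                lam * np.einsum("ab,cd->abcd", _I2, _I2)
                + G
                * (
                    np.einsum("ac,bd->abcd", _I2, _I2)
                    + np.einsum("ad,bc->abcd", _I2, _I2)
                ),
                (E, 2, 2, 2, 2),
            )
        return P, A, W, s33

    det = _det2(F)
    if (det <= 0.0).any():
        raise StateInvalidError(int(np.argmax(det <= 0.0)))
    Finv = _inv2(F, det)
    FinvT = np.swapaxes(Finv, -1, -2)
    lnJ = np.log(det)
    if part == "iso":
        P = G * (F - FinvT)
        I1 = np.einsum("...ab,...ab->...", F, F) + 1.0
        W = 0.5 * G * (I1 - 3.0) - G * lnJ
        s33 = np.zeros(E)
        A = None
        if want_tangent:
            A = G * np.einsum("ac,bd->abcd", _I2, _I2)[None] + G * np.einsum(
                "...bc,...da->...abcd", Finv, Finv
            )
        return P, A, W, s33
    if part == "vol":
        P = lam * lnJ[..., None, None] * FinvT
        W = 0.5 * lam * lnJ**2
        s33 = lam * lnJ / det
        A = None
        if want_tangent:
            A = lam * np.einsum("...ab,...cd->...abcd", FinvT, FinvT)
            A -= lam * lnJ[..., None, None, None, None] * np.einsum(
                "...bc,...da->...abcd", Finv, Finv
            )
        return P, A, W, s33
    raise ValueError(part)


class _Group:
    """Assembly cache for one (region, energy part, quadrature) group."""

    def __init__(self, mesh: Mesh, elem_ids: np.ndarray, mat: Material, part: str, order: int):
        self.mat = mat
        self.part = part
        self.elem_ids = elem_ids
        conn = mesh.elements[elem_ids]
        self.conn = conn
        dofs = np.empty((conn.shape[0], 8), dtype=int)
        dofs[:, 0::2] = 2 * conn
        dofs[:, 1::2] = 2 * conn + 1
        self.dofs = dofs
        X = mesh.nodes[conn]  # (E, 4, 2)
        gps = quad_gauss_points(order)
        self.gradN = []
        self.wdet = []
        for xi, eta, w in gps:
            dN = _quad_gradN(xi, eta)  # (4,2)
            Jm = np.einsum("ena,nb->eab", X, dN)
            det = _det2(Jm)
            if (det <= 0.0).any():
                raise StateInvalidError(int(elem_ids[np.argmax(det <= 0.0)]))
            Jinv = _inv2(Jm, det)
            self.gradN.append(np.einsum("nb,eba->ena", dN, Jinv))
            self.wdet.append(w * det)

    def deformation(self, u: np.ndarray, gp: int) -> np.ndarray:
        ue = u[self.conn]  # (E,4,2)
        F = np.einsum("ena,enb->eab", ue, self.gradN[gp])
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        return F


def _build_groups(mesh: Mesh, materials: dict) -> list:
    groups = []
    for label in np.unique(mesh.region):
        if label not in materials:
            raise LookupError(f"no material assigned to region {label!r}")
        mat = materials[label]
        ids = mesh.region_elements(label)
        if mat.family == "neo_hookean":
            groups.append(_Group(mesh, ids, mat, "iso", 2))
            groups.append(_Group(mesh, ids, mat, "vol", 1))
        else:
            groups.append(_Group(mesh, ids, mat, "lin", 2))
    return groups


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------


@dataclass
class ContactSpec:
    """Declarative contact pair between named mesh surfaces.

    ``master_surface=None`` denotes a rigid plane y = ``plane_y`` (used in
    verification problems).  Penalties in kPa/mm; ``None`` lets the
    pipeline derive them from the neighboring materials (50× the softer
    modulus per unit element length).
    """

    slave_surface: str = "dressing_bottom"
    master_surface: str | None = "mattress_top"
    friction_coefficient: float = 0.4
    normal_penalty: float | None = None
    tangential_penalty: float | None = None
    plane_y: float = 0.0
    regularization_depth: float = 1e-3  # mm; C1 smoothing of first engagement

    def __post_init__(self):
        if self.friction_coefficient < 0.0:
            raise ValueError("friction coefficient must be >= 0")
        for p in (self.normal_penalty, self.tangential_penalty):
            if p is not None and p <= 0.0:
                raise ValueError("penalties must be positive")


_ANCHOR_ARG = 3.0  # tanh argument at which the stick anchor is dragged along


def _node_normal(px, py, ax, ay, bx, by):
    """Averaged (angle-bisecting) outward normal at a master node (scalars)."""
    n0 = n1 = 0.0
    dx, dy = ax - px, ay - py
    L = math.hypot(dx, dy)
    if L > 0.0:
        n0 -= dy / L
        n1 += dx / L
    dx, dy = bx - ax, by - ay
    L = math.hypot(dx, dy)
    if L > 0.0:
        n0 -= dy / L
        n1 += dx / L
    L = math.hypot(n0, n1)
    if L <= 0.0:
        return 0.0, 1.0
    return n0 / L, n1 / L


class ContactPair:
    """Runtime node-to-segment penalty contact with Coulomb friction.

    Slave nodes carry a stick anchor (a material point on the master);
    the tangential traction is a penalty on the slip relative to that
    anchor, return-mapped onto the Coulomb cone |t| <= μ·p at the end of
    each converged load step.
    """

    def __init__(self, mesh: Mesh, spec: ContactSpec, kn: float, kt: float):
        self.spec = spec
        self.mu = spec.friction_coefficient
        slave = np.asarray(mesh.boundary[spec.slave_surface], int)
        order = np.argsort(mesh.nodes[slave, 0], kind="stable")
        self.slave = slave[order]
        xs = mesh.nodes[self.slave, 0]
        trib = np.empty_like(xs)
        if xs.size > 1:
            trib[1:-1] = 0.5 * (xs[2:] - xs[:-2])
            trib[0] = 0.5 * (xs[1] - xs[0])
            trib[-1] = 0.5 * (xs[-1] - xs[-2])
        else:
            trib[:] = 1.0
        self.kn_s = kn * trib  # kPa·mm/mm of slip → integrated per node
        self.kt_s = kt * trib
        if spec.master_surface is None:
            self.master = None
        else:
            m = np.asarray(mesh.boundary[spec.master_surface], int)
            order = np.argsort(mesh.nodes[m, 0], kind="stable")
            self.master = m[order]
        self.g0 = max(spec.regularization_depth, 0.0)
        # anchor: (segment index, xi) material coords on master, or x for plane
        self.anchor = [None] * self.slave.size

    def _pressure(self, i: int, g: float) -> float:
        """Regularized penalty pressure: quadratic ramp over the first
        ``g0`` of penetration (C1 at engagement), linear beyond."""
        depth = -g
        if depth <= 0.0:
            return 0.0
        g0 = self.g0
        if g0 > 0.0 and depth < g0:
            return 0.5 * self.kn_s[i] * depth * depth / g0
        return self.kn_s[i] * (depth - 0.5 * g0)

    def _friction(self, i: int, slip: float, p: float) -> float:
        """Regularized Coulomb traction: −μp·tanh(k_t·slip / μp).

        Smooth stick-to-slip transition with stick stiffness k_t at zero
        slip, saturating at the Coulomb cone |t| = μ·p.
        """
        cap = self.mu * p
        if cap <= 1e-30:
            return 0.0
        return -cap * math.tanh(self.kt_s[i] * slip / cap)

    # -- local force --------------------------------------------------

    def _local(self, i: int, sx: float, sy: float, xm: tuple | None, xa: tuple | None):
        """Scalar contact force at slave i.

        Returns (fsx, fsy, f1x, f1y, f2x, f2y, p, slip) or None for an
        open gap.  ``xm`` packs segment ends + neighbor nodes
        (x1, y1, x2, y2, x0, y0, x3, y3) of the current master segment;
        ``xa`` packs the anchor-segment nodes; both None for the rigid
        plane master.
        """
        mu = self.mu
        if self.master is None:
            g = sy - self.spec.plane_y
            if g >= 0.0:
                return None
            p = self._pressure(i, g)
            ft = 0.0
            slip = 0.0
            if mu > 0.0 and self.anchor[i] is not None:
                slip = sx - self.anchor[i]
                ft = self._friction(i, slip, p)
            return (ft, p, 0.0, 0.0, 0.0, 0.0, p, slip)

        x1x, x1y, x2x, x2y, x0x, x0y, x3x, x3y = xm
        tx, ty = x2x - x1x, x2y - x1y
        L = math.hypot(tx, ty)
        tx /= L
        ty /= L
        xi = ((sx - x1x) * tx + (sy - x1y) * ty) / L
        xi = 0.0 if xi < 0.0 else (1.0 if xi > 1.0 else xi)
        # continuous normal field: averaged nodal normals interpolated
        # along the segment (kills the Newton limit cycle a sliding node
        # otherwise hits when crossing master nodes)
        a0, a1 = _node_normal(x0x, x0y, x1x, x1y, x2x, x2y)
        b0, b1 = _node_normal(x1x, x1y, x2x, x2y, x3x, x3y)
        nx = (1.0 - xi) * a0 + xi * b0
        ny = (1.0 - xi) * a1 + xi * b1
        Ln = math.hypot(nx, ny)
        nx /= Ln
        ny /= Ln
        if ny < 0.0:
            nx, ny = -nx, -ny
        px_, py_ = x1x + xi * L * tx, x1y + xi * L * ty
        g = (sx - px_) * nx + (sy - py_) * ny
        if g >= 0.0:
            return None
        p = self._pressure(i, g)
        ftx = fty = 0.0
        slip = 0.0
        if mu > 0.0 and self.anchor[i] is not None and xa is not None:
            tdx, tdy = ny, -nx  # tangent consistent with n
            seg_xi = self.anchor[i][1]
            pax = (1.0 - seg_xi) * xa[0] + seg_xi * xa[2]
            pay = (1.0 - seg_xi) * xa[1] + seg_xi * xa[3]
            slip = (sx - pax) * tdx + (sy - pay) * tdy
            ft = self._friction(i, slip, p)
            ftx, fty = ft * tdx, ft * tdy
        fsx = p * nx + ftx
        fsy = p * ny + fty
        return (
            fsx,
            fsy,
            -(1.0 - xi) * fsx,
            -(1.0 - xi) * fsy,
            -xi * fsx,
            -xi * fsy,
            p,
            slip,
        )

    def _segment_of(self, x: np.ndarray, xpt: float) -> int:
        mx = x[self.master, 0]
        seg = int(np.searchsorted(mx, xpt)) - 1
        return min(max(seg, 0), self.master.size - 2)

    def forces(self, mesh: Mesh, u: np.ndarray, want_tangent: bool):
        """Contact residual contribution (2N,) and COO tangent triplets."""
        N = mesh.n_nodes
        r = np.zeros(2 * N)
        rows, cols, vals = [], [], []
        x = mesh.nodes + u
        for i, s in enumerate(self.slave):
            if self.master is None:
                seg_nodes = []
                m0 = m1 = m2 = m3 = a1 = a2 = None
            else:
                seg = self._segment_of(x, x[s, 0])
                m1, m2 = self.master[seg], self.master[seg + 1]
                m0 = self.master[max(seg - 1, 0)]
                m3 = self.master[min(seg + 2, self.master.size - 1)]
                seg_nodes = []
                for nd in (m1, m2, m0, m3):
                    if nd not in seg_nodes:
                        seg_nodes.append(nd)
                a1 = a2 = None
                if self.anchor[i] is not None:
                    aseg = self.anchor[i][0]
                    a1, a2 = self.master[aseg], self.master[aseg + 1]
                    for nd in (a1, a2):
                        if nd not in seg_nodes:
                            seg_nodes.append(nd)
            dofmap = [2 * s, 2 * s + 1]
            off = {}
            for q, nd in enumerate(seg_nodes):
                dofmap += [2 * nd, 2 * nd + 1]
                off[nd] = 2 + 2 * q
            nloc = len(dofmap)
            if seg_nodes:
                o1, o2 = off[m1], off[m2]

            def local_r(xflat):
                if self.master is None:
                    out = self._local(i, xflat[0], xflat[1], None, None)
                else:
                    om0, om3 = off[m0], off[m3]
                    xm = (
                        xflat[o1], xflat[o1 + 1], xflat[o2], xflat[o2 + 1],
                        xflat[om0], xflat[om0 + 1], xflat[om3], xflat[om3 + 1],
                    )
                    xa = None
                    if a1 is not None:
                        oa1, oa2 = off[a1], off[a2]
                        xa = (xflat[oa1], xflat[oa1 + 1], xflat[oa2], xflat[oa2 + 1])
                    out = self._local(i, xflat[0], xflat[1], xm, xa)
                fl = np.zeros(nloc)
                if out is None:
                    return fl
                fl[0] = out[0]
                fl[1] = out[1]
                if self.master is not None:
                    fl[o1] += out[2]
                    fl[o1 + 1] += out[3]
                    fl[o2] += out[4]
                    fl[o2 + 1] += out[5]
                return fl

            xflat = np.concatenate([x[s]] + [x[nd] for nd in seg_nodes]) if seg_nodes else x[s].copy()
            fl = local_r(xflat)
            if not fl.any():
                continue
            # contact force on nodes enters the residual with negative sign
            r[dofmap] -= fl
            if want_tangent:
                # forward differences of the local force (cheap, accurate to
                # O(h) on the smooth branches; h sits inside the C1 zone)
                Kl = np.empty((nloc, nloc))
                h = 1e-6
                for c in range(nloc):
                    xp = xflat.copy()
                    xp[c] += h
                    Kl[:, c] = -(local_r(xp) - fl) / h
                for a in range(nloc):
                    rows.extend([dofmap[a]] * nloc)
                    cols.extend(dofmap)
                    vals.extend(Kl[a])
        return r, (rows, cols, vals)

    def update_state(self, mesh: Mesh, u: np.ndarray) -> float:
        """Return-map friction anchors after a converged step.

        Returns the incremental dissipation-like quantity
        Σ |f_t · Δslip| over slipping nodes (>= 0 by construction).
        """
        x = mesh.nodes + u
        dissipation = 0.0
        for i, s in enumerate(self.slave):
            if self.master is None:
                g = x[s, 1] - self.spec.plane_y
                if g >= 0.0:
                    self.anchor[i] = None
                    continue
                if self.anchor[i] is None:
                    self.anchor[i] = float(x[s, 0])
                    continue
                p = self._pressure(i, g)
                slip = x[s, 0] - self.anchor[i]
                cap = self.mu * p
                smax = _ANCHOR_ARG * cap / self.kt_s[i]
                if self.mu > 0.0 and abs(slip) > smax:
                    excess = abs(slip) - smax
                    self.anchor[i] += math.copysign(excess, slip)
                    dissipation += cap * excess
                elif self.mu == 0.0:
                    self.anchor[i] = float(x[s, 0])
                continue
            seg = self._segment_of(x, x[s, 0])
            m1, m2 = self.master[seg], self.master[seg + 1]
            x1, x2 = x[m1], x[m2]
            tvec = x2 - x1
            L = np.hypot(tvec[0], tvec[1])
            that = tvec / L
            n = np.array([-that[1], that[0]])
            if n[1] < 0:
                n = -n
            xi = np.clip(np.dot(x[s] - x1, that) / L, 0.0, 1.0)
            g = np.dot(x[s] - (x1 + xi * L * that), n)
            if g >= 0.0:
                self.anchor[i] = None
                continue
            if self.anchor[i] is None or self.mu == 0.0:
                self.anchor[i] = (seg, float(xi))
                continue
            p = self._pressure(i, g)
            aseg, axi = self.anchor[i]
            pa = (1.0 - axi) * x[self.master[aseg]] + axi * x[self.master[aseg + 1]]
            slip = np.dot(x[s] - pa, that)
            cap = self.mu * p
            smax = _ANCHOR_ARG * cap / self.kt_s[i]
            if abs(slip) > smax:
                # slide the anchor along the master so the residual stretch
                # keeps the regularized traction essentially at the cone
                excess = abs(slip) - smax
                target = x[s] - math.copysign(smax, slip) * that
                nseg = self._segment_of(x, target[0])
                y1, y2 = x[self.master[nseg]], x[self.master[nseg + 1]]
                sv = y2 - y1
                sL2 = float(sv @ sv)
                nxi = np.clip(float((target - y1) @ sv) / sL2, 0.0, 1.0)
                self.anchor[i] = (nseg, nxi)
                dissipation += cap * excess
        return dissipation

    def snapshot(self):
        return list(self.anchor)

    def restore(self, snap):
        self.anchor = list(snap)


# ---------------------------------------------------------------------------
# problem and assembly
# ---------------------------------------------------------------------------


@dataclass
class Problem:
    mesh: Mesh
    materials: dict
    dirichlet: list
    contacts: list = field(default_factory=list)
    external_forces: np.ndarray | None = None

    def __post_init__(self):
        if self.mesh.dim != 2:
            raise NotImplementedError(
                "the nonlinear solver operates on 2-D plane-strain meshes; "
                "coarse 3-D meshes are supported for geometry/quantification only"
            )
        self._groups = _build_groups(self.mesh, self.materials)
        N = self.mesh.n_nodes
        fixed = np.zeros(2 * N, dtype=bool)
        for bc in self.dirichlet:
            for a in range(2):
                if bc.mask[a]:
                    fixed[2 * bc.nodes + a] = True
        self.fixed = fixed
        self.free = ~fixed

    def apply_dirichlet(self, u: np.ndarray, factor: float) -> None:
        for bc in self.dirichlet:
            for a in range(2):
                if bc.mask[a]:
                    u[bc.nodes, a] = factor * bc.value[a]

    def internal(self, u: np.ndarray, want_tangent: bool = True):
        """Internal + contact force vector (2N,) and sparse tangent."""
        mesh = self.mesh
        N = mesh.n_nodes
        f = np.zeros(2 * N)
        rows, cols, vals = [], [], []
        uu = u.reshape(N, 2)
        for g in self._groups:
            E = g.conn.shape[0]
            if E == 0:
                continue
            fe = np.zeros((E, 4, 2))
            Ke = np.zeros((E, 8, 8)) if want_tangent else None
            for gp in range(len(g.gradN)):
                F = g.deformation(uu, gp)
                try:
                    P, A, _W, _s = _eval_part(F, g.mat, g.part, want_tangent)
                except StateInvalidError as exc:
                    raise StateInvalidError(int(g.elem_ids[exc.element_id])) from None
                wd = g.wdet[gp]
                fe += np.einsum("eab,eib,e->eia", P, g.gradN[gp], wd, optimize=True)
                if want_tangent:
                    Kg = np.einsum(
                        "eib,eabcd,ejd,e->eiajc",
                        g.gradN[gp],
                        A,
                        g.gradN[gp],
                        wd,
                        optimize=True,
                    )
                    Ke += Kg.reshape(E, 8, 8)
            np.add.at(f, g.dofs.ravel(), fe.reshape(E, 8).ravel())
            if want_tangent:
                rows.append(np.repeat(g.dofs, 8, axis=1).ravel())
                cols.append(np.tile(g.dofs, (1, 8)).ravel())
                vals.append(Ke.ravel())
        for pair in self.contacts:
            rc, (cr, cc, cv) = pair.forces(mesh, uu, want_tangent)
            f += rc
            if want_tangent and cr:
                rows.append(np.asarray(cr))
                cols.append(np.asarray(cc))
                vals.append(np.asarray(cv))
        K = None
        if want_tangent:
            K = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(2 * N, 2 * N),
            ).tocsr()
        return f, K


def assemble(mesh: Mesh, materials: dict, state: np.ndarray, contacts=()):
    """Residual (out-of-balance internal force) and consistent tangent.

    ``state`` is the nodal displacement field (N, 2) or flat (2N,).
    External loads are not included (the caller subtracts them).
    """
    prob = Problem(mesh=mesh, materials=materials, dirichlet=[], contacts=list(contacts))
    u = np.asarray(state, float).reshape(-1)
    return prob.internal(u)


# ---------------------------------------------------------------------------
# element post-processing
# ---------------------------------------------------------------------------


def element_fields(problem: Problem, u: np.ndarray):
    """Volume-averaged per-element SED (kPa) and Cauchy stress (E,3,3)."""
    mesh = problem.mesh
    E = mesh.n_elements
    sed = np.zeros(E)
    vol = np.zeros(E)
    stress = np.zeros((E, 3, 3))
    uu = u.reshape(-1, 2)
    for g in problem._groups:
        ids = g.elem_ids
        if ids.size == 0:
            continue
        for gp in range(len(g.gradN)):
            F = g.deformation(uu, gp)
            P, _A, W, s33 = _eval_part(F, g.mat, g.part, want_tangent=False)
            wd = g.wdet[gp]
            sed[ids] += W * wd
            if g.part == "lin":
                sig2 = P
                det = np.ones(F.shape[0])
            else:
                det = _det2(F)
                sig2 = np.einsum("eab,ecb->eac", P, F) / det[:, None, None]
            stress[ids, :2, :2] += sig2 * wd[:, None, None]
            stress[ids, 2, 2] += s33 * wd
            if g.part != "vol" or g.mat.family != "neo_hookean":
                vol[ids] += wd
    vol[vol == 0.0] = 1.0
    sed /= vol
    stress /= vol[:, None, None]
    stress = 0.5 * (stress + stress.transpose(0, 2, 1))
    return sed, stress


@dataclass
class SolutionField:
    """Converged state: displacements, element SED/stress, residual, log."""

    mesh: Mesh
    u: np.ndarray  # (N, 2)
    element_sed: np.ndarray  # (E,) kPa
    element_stress: np.ndarray  # (E, 3, 3) kPa
    residual: np.ndarray  # (2N,) internal - external at convergence
    log: list
    materials: dict
    load_factor: float = 1.0
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Newton solution
# ---------------------------------------------------------------------------


def _newton_step(problem: Problem, u: np.ndarray, factor: float, fext: np.ndarray,
                 settings: SolverSettings, log: list, step_label) -> np.ndarray:
    uu = u.reshape(-1, 2)
    problem.apply_dirichlet(uu, factor)
    u = uu.reshape(-1)
    free = problem.free
    prev_u = None
    prev_du = None
    prev_rnorm = np.inf
    for it in range(settings.max_newton_iterations + 1):
        try:
            f, K = problem.internal(u)
            r = f - factor * fext
            rnorm = float(np.linalg.norm(r[free]))
        except StateInvalidError:
            rnorm = np.inf
        # optimistic full steps with retrospective backtracking: only when
        # the previous step made the residual worse do we pay for extra
        # (tangent-free) evaluations along that step
        if (
            settings.line_search_enabled
            and prev_u is not None
            and rnorm > max(1.01 * prev_rnorm, 1e-14)
        ):
            alpha = 0.5
            accepted = False
            while alpha > 1.0 / 64.0:
                utry = prev_u.copy()
                utry[free] += alpha * prev_du
                try:
                    ftry, _ = problem.internal(utry, want_tangent=False)
                except StateInvalidError:
                    alpha *= 0.5
                    continue
                rtry = float(np.linalg.norm((ftry - factor * fext)[free]))
                if rtry < prev_rnorm:
                    u = utry
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                prev_u = None
                continue  # recompute tangent at the accepted point
            if not np.isfinite(rnorm):
                raise NonconvergenceError("element inversion during Newton step", log)
        elif not np.isfinite(rnorm):
            raise NonconvergenceError("element inversion during Newton step", log)
        ref = max(
            1.0,
            float(np.linalg.norm(r[problem.fixed])),
            float(np.linalg.norm(factor * fext)),
        )
        log.append({"step": step_label, "iteration": it, "residual": rnorm, "reference": ref})
        if rnorm <= settings.newton_tolerance * ref:
            return u
        if it == settings.max_newton_iterations:
            raise NonconvergenceError(
                f"Newton did not converge in {it} iterations (residual {rnorm:.3e})", log
            )
        Kff = K[free][:, free]
        du = spla.spsolve(Kff.tocsc(), -r[free])
        if not np.all(np.isfinite(du)):
            raise NonconvergenceError("singular tangent", log)
        prev_u = u.copy()
        prev_du = du
        prev_rnorm = rnorm
        u[free] += du
    raise NonconvergenceError("unreachable", log)


def newton_solve(
    problem: Problem,
    settings: SolverSettings | None = None,
    u0: np.ndarray | None = None,
    load_factors: np.ndarray | None = None,
    base_factor: float = 0.0,
) -> SolutionField:
    """Ramp the prescribed displacements/loads and converge each step.

    Load steps that fail to converge are automatically bisected (up to 5
    levels) before a :class:`NonconvergenceError` is raised.  For warm
    starts, ``base_factor`` is the load factor the initial state already
    equilibrates (bisection never steps below it).
    """
    settings = settings or SolverSettings()
    N = problem.mesh.n_nodes
    u = np.zeros(2 * N) if u0 is None else np.asarray(u0, float).reshape(-1).copy()
    fext = np.zeros(2 * N)
    if problem.external_forces is not None:
        fext = np.asarray(problem.external_forces, float).reshape(-1)
    if load_factors is None:
        load_factors = np.linspace(1.0 / settings.load_steps, 1.0, settings.load_steps)
    log: list = []
    prev = base_factor
    pending = list(np.atleast_1d(load_factors))
    depth = 0
    while pending:
        lam = pending[0]
        snaps = [c.snapshot() for c in problem.contacts]
        try:
            u = _newton_step(problem, u.copy(), lam, fext, settings, log, round(lam, 6))
        except (NonconvergenceError, StateInvalidError):
            for c, s in zip(problem.contacts, snaps):
                c.restore(s)
            if depth >= 5:
                raise NonconvergenceError(
                    f"step to load factor {lam} failed after 5 bisections", log
                )
            pending.insert(0, 0.5 * (prev + lam))
            depth += 1
            continue
        depth = 0
        dissipation = 0.0
        for c in problem.contacts:
            dissipation += c.update_state(problem.mesh, u.reshape(-1, 2))
        log.append({"step": round(lam, 6), "contact_dissipation": dissipation})
        prev = lam
        pending.pop(0)

    f, _ = problem.internal(u, want_tangent=False)
    residual = f - prev * fext
    sed, stress = element_fields(problem, u)
    return SolutionField(
        mesh=problem.mesh,
        u=u.reshape(-1, 2),
        element_sed=sed,
        element_stress=stress,
        residual=residual,
        log=log,
        materials=problem.materials,
        load_factor=prev,
    )


def reaction_force(solution: SolutionField, surface: str) -> np.ndarray:
    """Constraint force (N) transmitted through the named surface.

    Sum of nodal residuals over the surface's nodes, converted to newtons
    through the mesh's out-of-plane thickness.
    """
    if surface not in solution.mesh.boundary:
        raise LookupError(f"unknown surface {surface!r}")
    nodes = np.asarray(solution.mesh.boundary[surface], int)
    r = solution.residual.reshape(-1, 2)[nodes].sum(axis=0)
    return r * solution.mesh.out_of_plane_thickness * FORCE_TO_N


def force_targeted_solve(
    problem: Problem,
    load: LoadCase,
    settings: SolverSettings | None = None,
    driver_nodes: np.ndarray | None = None,
    base_surface: str = "mattress_base",
) -> SolutionField:
    """Displace the bone obliquely until the mattress reaction hits target.

    Outer safeguarded secant (with bisection fallback once a bracket
    exists) on the displacement scale s; inner continuation re-uses the
    converged state between evaluations.  The returned solution stores
    the final displacement scale in ``meta["displacement_scale"]``.
    """
    settings = settings or SolverSettings()
    mesh = problem.mesh
    if driver_nodes is None:
        driver_nodes = mesh.boundary["bone_nodes"]
    driver_nodes = np.asarray(driver_nodes, int)
    if driver_nodes.size == 0:
        raise ValueError("empty driver node set")
    direction = load.direction

    driver_bc = Dirichlet(nodes=driver_nodes, value=direction.copy())
    prob = Problem(
        mesh=mesh,
        materials=problem.materials,
        dirichlet=list(problem.dirichlet) + [driver_bc],
        contacts=problem.contacts,
        external_forces=problem.external_forces,
    )

    target = load.target_reaction_force
    tol = settings.force_target_tolerance
    smax = load.max_displacement_guess

    state = {"s": 0.0, "u": np.zeros(2 * mesh.n_nodes)}
    ds_ref = smax / (4.0 * settings.load_steps)

    def evaluate(s: float) -> tuple[float, SolutionField]:
        s = min(max(s, 1e-9), smax)
        delta = s - state["s"]
        nsub = max(1, int(math.ceil(abs(delta) / ds_ref)))
        nsub = min(nsub, 4 * settings.load_steps)
        if state["s"] == 0.0:
            nsub = max(nsub, min(settings.load_steps, 10))
        driver_bc.value = direction * s
        factors = (state["s"] + (np.arange(1, nsub + 1) / nsub) * delta) / s
        snaps = [c.snapshot() for c in prob.contacts]
        try:
            sol = newton_solve(
                prob,
                settings,
                u0=state["u"],
                load_factors=factors,
                base_factor=state["s"] / s,
            )
        except (NonconvergenceError, StateInvalidError) as exc:
            for c, sn in zip(prob.contacts, snaps):
                c.restore(sn)
            log = getattr(exc, "log", [])
            raise NonconvergenceError(
                f"continuation from {state['s']:.4g} to {s:.4g} mm failed: {exc}",
                log,
            ) from exc
        state["s"] = s
        state["u"] = sol.u.reshape(-1).copy()
        Rv = reaction_force(sol, base_surface)
        sol.meta["displacement_scale"] = s
        sol.meta["base_reaction_N"] = Rv
        return float(np.linalg.norm(Rv)), sol

    fail_bound: list = [None]  # smallest displacement at which continuation failed

    def guarded(s: float):
        """Evaluate, backing off toward the current state on nonconvergence."""
        while True:
            s = min(max(s, 1e-6), smax)
            if fail_bound[0] is not None:
                s = min(s, 0.95 * fail_bound[0])
            try:
                R, sol = evaluate(s)
                return s, R, sol
            except NonconvergenceError:
                fail_bound[0] = s
                s = 0.5 * (state["s"] + s)
                if abs(s - state["s"]) < 1e-4 * smax:
                    raise

    # small probe, then safeguarded secant with geometric growth caps
    s0 = 0.02 * smax
    s0, R0, sol = guarded(s0)
    if abs(R0 - target) <= tol:
        return sol
    history = [(s0, R0)]
    lo, hi = None, None  # bracket (s, R) with R below/above target
    if R0 < target:
        lo = (s0, R0)
    else:
        hi = (s0, R0)
    s = s0 * target / max(R0, 1e-12)
    for _ in range(40):
        if hi is None:
            s = min(s, 4.0 * max(history[-1][0], s0))  # cap growth pre-bracket
        s, R, sol = guarded(s)
        if abs(R - target) <= tol:
            return sol
        if R < target:
            if lo is None or s > lo[0]:
                lo = (s, R)
        else:
            if hi is None or s < hi[0]:
                hi = (s, R)
        history.append((s, R))
        if lo is not None and hi is not None:
            # secant within the bracket, bisection fallback
            s_sec = lo[0] + (target - lo[1]) * (hi[0] - lo[0]) / (hi[1] - lo[1])
            if not (lo[0] < s_sec < hi[0]):
                s_sec = 0.5 * (lo[0] + hi[0])
            s = s_sec
        else:
            (s1, R1), (s2, R2) = history[-2], history[-1]
            if abs(R2 - R1) > 1e-12:
                s = s2 + (target - R2) * (s2 - s1) / (R2 - R1)
            else:
                s = s2 * 1.5
            if R2 < target and s <= s2:
                s = min(1.5 * s2, smax)
            limit = smax if fail_bound[0] is None else 0.95 * fail_bound[0]
            if s >= limit and R2 < target and s2 >= 0.999 * limit:
                raise TargetUnreachableError(
                    f"reaction {R2:.2f} N at displacement {s2:.2f} mm below "
                    f"target {target} N (limit {limit:.2f} mm)",
                    attained_force=R2,
                )
    raise TargetUnreachableError(
        f"force targeting did not converge to {target} N within iteration budget "
        f"(last reaction {history[-1][1]:.3f} N)",
        attained_force=history[-1][1],
    )
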