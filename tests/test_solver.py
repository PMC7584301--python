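"""Finite-element solver verification: patch tests, closed-form oracles,
tangent consistency, objectivity, equilibrium."""
import numpy as np
import pytest

from dressfea.constitutive import Material, TISSUE, elastic_constants
from dressfea.geometry import Mesh, structured_grid
from dressfea.solver import (
    Dirichlet,
    LoadCase,
    NonconvergenceError,
    Problem,
    SolverSettings,
    TargetUnreachableError,
    assemble,
    element_fields,
    force_targeted_solve,
    newton_solve,
    reaction_force,
)

LINEAR = Material(family="linear_elastic", constants=elastic_constants(E=100.0, nu=0.3))
NEO = Material(family="neo_hookean", constants=elastic_constants(G=19.254, K=1919.022))


def strip_mesh(nx=2, ny=8, w=10.0, h=20.0, region="tissue"):
    nodes, elems = structured_grid(np.linspace(0, w, nx + 1), np.linspace(0, h, ny + 1))
    return Mesh(
        nodes=nodes,
        elements=elems,
        region=np.full(elems.shape[0], region),
        boundary={
            "bottom": np.flatnonzero(np.abs(nodes[:, 1]) < 1e-12),
            "top": np.flatnonzero(np.abs(nodes[:, 1] - h) < 1e-12),
            "left": np.flatnonzero(np.abs(nodes[:, 0]) < 1e-12),
        },
    )


def distorted_patch_mesh(seed=3):
    """3x3 patch with interior nodes displaced off the regular grid."""
    nodes, elems = structured_grid(np.linspace(0, 3, 4), np.linspace(0, 3, 4))
    rng = np.random.default_rng(seed)
    interior = [
        i
        for i, (x, y) in enumerate(nodes)
        if 0 < x < 3 and 0 < y < 3
    ]
    nodes = nodes.copy()
    nodes[interior] += 0.25 * rng.uniform(-1, 1, (len(interior), 2))
    return Mesh(
        nodes=nodes,
        elements=elems,
        region=np.full(elems.shape[0], "tissue"),
        boundary={},
    )


class TestAssembly:
    def test_zero_state_zero_residual(self):
        mesh = strip_mesh()
        r, K = assemble(mesh, {"tissue": NEO}, np.zeros(mesh.nodes.shape))
        assert np.allclose(r, 0.0, atol=1e-12)

    def test_single_linear_element_matches_hand_assembled_stiffness(self):
        # independent hand assembly of the plane-strain Q4 stiffness
        nodes = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        mesh = Mesh(
            nodes=nodes, elements=np.array([[0, 1, 2, 3]]), region=np.array(["tissue"])
        )
        lam, G = LINEAR.constants.lam, LINEAR.constants.G
        C = np.array(
            [
                [lam + 2 * G, lam, 0],
                [lam, lam + 2 * G, 0],
                [0, 0, G],
            ]
        )
        gp = 1 / np.sqrt(3)
        K_hand = np.zeros((8, 8))
        for xi in (-gp, gp):
            for eta in (-gp, gp):
                dN = 0.25 * np.array(
                    [
                        [-(1 - eta), -(1 - xi)],
                        [(1 - eta), -(1 + xi)],
                        [(1 + eta), (1 + xi)],
                        [-(1 + eta), (1 - xi)],
                    ]
                )
                J = nodes.T @ dN
                grad = dN @ np.linalg.inv(J)
                B = np.zeros((3, 8))
                for a in range(4):
                    B[0, 2 * a] = grad[a, 0]
                    B[1, 2 * a + 1] = grad[a, 1]
                    B[2, 2 * a] = grad[a, 1]
                    B[2, 2 * a + 1] = grad[a, 0]
                K_hand += B.T @ C @ B * np.linalg.det(J)
        rng = np.random.default_rng(0)
        u = 1e-3 * rng.standard_normal((4, 2))
        r, _ = assemble(mesh, {"tissue": LINEAR}, u)
        assert np.allclose(r, K_hand @ u.reshape(-1), rtol=1e-9, atol=1e-12)

    def test_tangent_matches_finite_differences(self):
        mesh = strip_mesh(nx=2, ny=3)
        rng = np.random.default_rng(1)
        u = 0.02 * rng.standard_normal(mesh.nodes.shape)
        for mat in (NEO, LINEAR):
            f, K = assemble(mesh, {"tissue": mat}, u)
            h = 1e-6
            for d in rng.choice(2 * mesh.n_nodes, 10, replace=False):
                up = u.reshape(-1).copy()
                um = u.reshape(-1).copy()
                up[d] += h
                um[d] -= h
                fp, _ = assemble(mesh, {"tissue": mat}, up.reshape(-1, 2))
                fm, _ = assemble(mesh, {"tissue": mat}, um.reshape(-1, 2))
                fd = (fp - fm) / (2 * h)
                col = K[:, d].toarray().ravel()
                scale = max(1.0, np.abs(fd).max())
                assert np.allclose(col, fd, atol=1e-5 * scale)


class TestPatchTest:
    @pytest.mark.parametrize(
        "grad_u",
        [
            np.array([[0.01, 0.0], [0.0, -0.004]]),
            np.array([[0.003, 0.005], [0.005, 0.002]]),
        ],
    )
    def test_linear_material_exact_uniform_stress(self, grad_u):
        mesh = distorted_patch_mesh()
        u_exact = mesh.nodes @ grad_u.T
        # prescribe the linear field on every boundary node only
        boundary = [
            i
            for i, (x, y) in enumerate(mesh.nodes)
            if x < 1e-12 or y < 1e-12 or x > 3 - 1e-12 or y > 3 - 1e-12
        ]
        prob = Problem(
            mesh=mesh,
            materials={"tissue": LINEAR},
            dirichlet=[],
        )
        # manual solve: constrain boundary dofs to the exact field
        fixed = np.zeros(2 * mesh.n_nodes, bool)
        for n in boundary:
            fixed[2 * n : 2 * n + 2] = True
        u = np.zeros(2 * mesh.n_nodes)
        u[fixed] = u_exact.reshape(-1)[fixed]
        f, K = prob.internal(u)
        import scipy.sparse.linalg as spla

        free = ~fixed
        du = spla.spsolve(K[free][:, free].tocsc(), -f[free])
        u[free] += du
        assert np.allclose(u, u_exact.reshape(-1), atol=1e-10)
        _, stress = element_fields(prob, u)
        eps = 0.5 * (grad_u + grad_u.T)
        lam, G = LINEAR.constants.lam, LINEAR.constants.G
        sig_exact = lam * np.trace(eps) * np.eye(2) + 2 * G * eps
        for e in range(mesh.n_elements):
            assert np.allclose(stress[e, :2, :2], sig_exact, atol=1e-10)

    def test_neo_hookean_small_strain_patch(self):
        mesh = distorted_patch_mesh(seed=5)
        grad_u = np.array([[1e-4, 2e-5], [2e-5, -5e-5]])
        u_exact = (mesh.nodes @ grad_u.T).reshape(-1)
        prob = Problem(mesh=mesh, materials={"tissue": NEO}, dirichlet=[])
        fixed = np.zeros(2 * mesh.n_nodes, bool)
        for i, (x, y) in enumerate(mesh.nodes):
            if x < 1e-12 or y < 1e-12 or x > 3 - 1e-12 or y > 3 - 1e-12:
                fixed[2 * i : 2 * i + 2] = True
        u = np.zeros(2 * mesh.n_nodes)
        u[fixed] = u_exact[fixed]
        import scipy.sparse.linalg as spla

        free = ~fixed
        for _ in range(3):
            f, K = prob.internal(u)
            u[free] += spla.spsolve(K[free][:, free].tocsc(), -f[free])
        assert np.allclose(u, u_exact, atol=1e-8)


class TestNewton:
    def test_linear_problem_converges_in_one_iteration(self):
        mesh = strip_mesh()
        prob = Problem(
            mesh=mesh,
            materials={"tissue": LINEAR},
            dirichlet=[
                Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2)),
                Dirichlet(nodes=mesh.boundary["top"], value=np.array([0.0, -0.5])),
            ],
        )
        sol = newton_solve(prob, SolverSettings(load_steps=1))
        iters = [e for e in sol.log if "iteration" in e]
        # one residual check, one solve, one converged check
        assert iters[-1]["iteration"] == 1
        assert iters[-1]["residual"] <= 1e-6 * iters[-1]["reference"]

    def test_confined_neo_hookean_bar_matches_closed_form(self):
        # plane-strain confined compression: F = diag(1, stretch, 1),
        # P22 = G (s - 1/s) + lam ln s / s
        mesh = strip_mesh(nx=2, ny=8)
        stretch = 0.9
        all_nodes = np.arange(mesh.n_nodes)
        prob = Problem(
            mesh=mesh,
            materials={"tissue": NEO},
            dirichlet=[
                Dirichlet(nodes=all_nodes, value=np.zeros(2), mask=(True, False)),
                Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2), mask=(False, True)),
                Dirichlet(
                    nodes=mesh.boundary["top"],
                    value=np.array([0.0, -20.0 * (1 - stretch)]),
                    mask=(False, True),
                ),
            ],
        )
        sol = newton_solve(prob, SolverSettings(load_steps=4))
        R = reaction_force(sol, "top")
        G, lam = NEO.constants.G, NEO.constants.lam
        P22 = G * (stretch - 1 / stretch) + lam * np.log(stretch) / stretch
        expected = P22 * 10.0 * 1e-3  # width 10 mm, unit out-of-plane mm
        assert R[1] == pytest.approx(expected, rel=1e-6)

    def test_symmetric_stack_solution_is_symmetric(self):
        mesh = strip_mesh(nx=6, ny=6, w=12.0, h=12.0)
        prob = Problem(
            mesh=mesh,
            materials={"tissue": NEO},
            dirichlet=[
                Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2)),
                Dirichlet(
                    nodes=mesh.boundary["top"], value=np.array([0.0, -1.0])
                ),
            ],
        )
        sol = newton_solve(prob, SolverSettings(load_steps=4))
        # mirror about x = 6: ux antisymmetric, uy symmetric
        for i, (x, y) in enumerate(mesh.nodes):
            xm = 12.0 - x
            j = np.argmin(np.hypot(mesh.nodes[:, 0] - xm, mesh.nodes[:, 1] - y))
            assert sol.u[i, 0] == pytest.approx(-sol.u[j, 0], abs=1e-8)
            assert sol.u[i, 1] == pytest.approx(sol.u[j, 1], abs=1e-8)

    def test_equilibrium_base_equals_minus_top(self):
        mesh = strip_mesh()
        prob = Problem(
            mesh=mesh,
            materials={"tissue": NEO},
            dirichlet=[
                Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2)),
                Dirichlet(nodes=mesh.boundary["top"], value=np.array([0.3, -1.5])),
            ],
        )
        sol = newton_solve(prob)
        Rb = reaction_force(sol, "bottom")
        Rt = reaction_force(sol, "top")
        assert np.allclose(Rb, -Rt, atol=1e-8)

    def test_unloaded_body_zero_reaction(self):
        mesh = strip_mesh()
        prob = Problem(
            mesh=mesh,
            materials={"tissue": NEO},
            dirichlet=[Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2))],
        )
        sol = newton_solve(prob, SolverSettings(load_steps=1))
        assert np.allclose(reaction_force(sol, "bottom"), 0.0, atol=1e-12)

    def test_uniform_traction_patch_reaction(self):
        # one element, traction t on the top edge: reaction = t * A
        nodes = np.array([[0.0, 0], [2, 0], [2, 1], [0, 1]])
        mesh = Mesh(
            nodes=nodes,
            elements=np.array([[0, 1, 2, 3]]),
            region=np.array(["tissue"]),
            boundary={"bottom": np.array([0, 1]), "top": np.array([2, 3])},
        )
        t = 5.0  # kPa over edge length 2 mm
        fext = np.zeros((4, 2))
        fext[[2, 3], 1] = -t * 2.0 / 2  # consistent nodal loads
        prob = Problem(
            mesh=mesh,
            materials={"tissue": LINEAR},
            dirichlet=[Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2))],
            external_forces=fext,
        )
        sol = newton_solve(prob, SolverSettings(load_steps=1))
        # support force on the body balances the downward traction t*A
        Rb = reaction_force(sol, "bottom")
        assert Rb[1] == pytest.approx(t * 2.0 * 1e-3, rel=1e-9)


class TestObjectivity:
    def test_rigid_rotation_leaves_element_sed_unchanged(self):
        mesh = strip_mesh(nx=3, ny=5)
        prob = Problem(
            mesh=mesh,
            materials={"tissue": NEO},
            dirichlet=[
                Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2)),
                Dirichlet(nodes=mesh.boundary["top"], value=np.array([0.5, -2.0])),
            ],
        )
        sol = newton_solve(prob)
        theta = 0.4
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        x_rot = (mesh.nodes + sol.u) @ R.T
        u_rot = x_rot - mesh.nodes
        sed_rot, _ = element_fields(prob, u_rot.reshape(-1))
        assert np.allclose(sed_rot, sol.element_sed, rtol=1e-9, atol=1e-12)


class TestForceTargeting:
    def test_linear_column_hits_target(self):
        mesh = strip_mesh(nx=2, ny=4, w=10.0, h=10.0, region="mattress")
        mesh.boundary["mattress_base"] = mesh.boundary["bottom"]
        mesh.boundary["bone_nodes"] = mesh.boundary["top"]
        prob = Problem(
            mesh=mesh,
            materials={"mattress": LINEAR},
            dirichlet=[Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2))],
        )
        load = LoadCase(direction_angle=0.0, target_reaction_force=0.5, max_displacement_guess=8.0)
        sol = force_targeted_solve(prob, load, SolverSettings(load_steps=4))
        R = reaction_force(sol, "mattress_base")
        assert np.linalg.norm(R) == pytest.approx(0.5, abs=0.1)

    def test_confined_bar_inverse_recovers_stretch(self):
        # choose the target from the closed form at stretch 0.9 and check
        # the solver recovers that stretch
        mesh = strip_mesh(nx=2, ny=8)
        mesh.boundary["mattress_base"] = mesh.boundary["bottom"]
        mesh.boundary["bone_nodes"] = mesh.boundary["top"]
        all_nodes = np.arange(mesh.n_nodes)
        prob = Problem(
            mesh=mesh,
            materials={"tissue": NEO},
            dirichlet=[
                Dirichlet(nodes=all_nodes, value=np.zeros(2), mask=(True, False)),
                Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2), mask=(False, True)),
            ],
        )
        stretch = 0.9
        G, lam = NEO.constants.G, NEO.constants.lam
        P22 = G * (stretch - 1 / stretch) + lam * np.log(stretch) / stretch
        target = abs(P22) * 10.0 * 1e-3
        load = LoadCase(
            direction_angle=0.0,
            target_reaction_force=target,
            max_displacement_guess=6.0,
        )
        settings = SolverSettings(load_steps=5, force_target_tolerance=1e-4 * target)
        sol = force_targeted_solve(prob, load, settings)
        disp = sol.meta["displacement_scale"]
        assert 20.0 * (1 - stretch) == pytest.approx(disp, rel=5e-3)

    def test_unreachable_target_raises(self):
        mesh = strip_mesh(nx=2, ny=4)
        mesh.boundary["mattress_base"] = mesh.boundary["bottom"]
        mesh.boundary["bone_nodes"] = mesh.boundary["top"]
        prob = Problem(
            mesh=mesh,
            materials={"tissue": LINEAR},
            dirichlet=[Dirichlet(nodes=mesh.boundary["bottom"], value=np.zeros(2))],
        )
        load = LoadCase(
            direction_angle=0.0, target_reaction_force=1e4, max_displacement_guess=0.5
        )
        with pytest.raises(TargetUnreachableError):
            force_targeted_solve(prob, load, SolverSettings(load_steps=2))
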