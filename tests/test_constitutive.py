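"""Constitutive model unit and property tests."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dressfea.constitutive import (
    BONE,
    MATTRESS,
    TISSUE,
    DeformationState,
    InvalidConstantsError,
    InvertedStateError,
    Material,
    cauchy_stress,
    dressing_material,
    elastic_constants,
    first_piola_stress,
    material_tangent,
    strain_energy_density,
)


def rotation(theta, axis=2):
    c, s = math.cos(theta), math.sin(theta)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


class TestElasticConstants:
    def test_printed_tissue_constants_imply_nu_0495(self):
        # shear 19.254 kPa with bulk 1919.022 kPa is the published
        # nearly incompressible soft-tissue pairing
        ec = elastic_constants(G=19.254, K=1919.022)
        assert round(ec.nu, 3) == 0.495

    def test_mattress_pair_gives_shear_modulus(self):
        ec = elastic_constants(E=50.0, nu=0.3)
        assert ec.G == pytest.approx(50.0 / 2.6, rel=1e-12)
        assert ec.G == pytest.approx(19.2308, abs=1e-4)

    def test_zero_poisson_limit_has_zero_lame_lambda(self):
        G = 1.0
        K = 2.0 / 3.0 * G  # nu = 0
        ec = elastic_constants(G=G, K=K)
        assert ec.nu == pytest.approx(0.0, abs=1e-15)
        assert ec.lam == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"E": 10.0, "nu": 0.6},
            {"E": 10.0, "nu": 0.5},
            {"G": -1.0, "K": 1.0},
            {"E": 10.0},
            {"E": 1.0, "nu": 0.2, "G": 1.0},
            {"bogus": 1.0, "E": 2.0},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(InvalidConstantsError):
            elastic_constants(**kwargs)

    @given(
        G=st.floats(0.1, 1e4),
        ratio=st.floats(0.7, 1000.0),  # K/G; conversions through nu lose
        # precision as nu -> 0.5, so bound the amplification factor
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_through_any_pair(self, G, ratio):
        K = G * ratio
        ec = elastic_constants(G=G, K=K)
        back = elastic_constants(E=ec.E, nu=ec.nu)
        assert back.G == pytest.approx(G, rel=1e-12)
        assert back.K == pytest.approx(K, rel=1e-12)

    @pytest.mark.parametrize(
        "pair",
        [
            lambda ec: {"G": ec.G, "nu": ec.nu},
            lambda ec: {"K": ec.K, "nu": ec.nu},
            lambda ec: {"E": ec.E, "G": ec.G},
            lambda ec: {"E": ec.E, "K": ec.K},
            lambda ec: {"G": ec.G, "lam": ec.lam},
        ],
    )
    def test_all_pairs_consistent(self, pair):
        ref = elastic_constants(E=57.0, nu=0.43)
        ec = elastic_constants(**pair(ref))
        for name in ("E", "nu", "G", "K", "lam"):
            assert getattr(ec, name) == pytest.approx(getattr(ref, name), rel=1e-9, abs=1e-12)


class TestPackagedMaterials:
    def test_tissue_is_nearly_incompressible_neo_hookean(self):
        assert TISSUE.family == "neo_hookean"
        assert TISSUE.constants.nu == pytest.approx(0.495, abs=5e-4)

    def test_bone_constants(self):
        assert BONE.family == "linear_elastic"
        assert BONE.constants.E == pytest.approx(3.4e6)
        assert BONE.constants.nu == pytest.approx(0.36)

    def test_mattress_modulus(self):
        assert MATTRESS.constants.E == pytest.approx(50.0)


class TestStrainEnergy:
    def test_zero_at_identity_and_under_rotation(self):
        st_ = DeformationState.from_F(np.eye(3))
        assert strain_energy_density(st_, TISSUE) == pytest.approx(0.0, abs=1e-15)
        R = rotation(0.7) @ rotation(0.3, axis=0)
        stR = DeformationState.from_F(R)
        assert strain_energy_density(stR, TISSUE) == pytest.approx(0.0, abs=1e-12)

    def test_isochoric_stretch_matches_independent_expression(self):
        # independent evaluation with plain floats of the compressible
        # neo-Hookean form W = G/2 (I1-3) - G lnJ + lam/2 (lnJ)^2
        F = np.diag([1.1, 1 / 1.1, 1.0])
        G, lam = TISSUE.constants.G, TISSUE.constants.lam
        I1 = 1.1**2 + (1 / 1.1) ** 2 + 1.0
        expected = 0.5 * G * (I1 - 3.0)  # J = 1 exactly
        got = strain_energy_density(DeformationState.from_F(F), TISSUE)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_energy_blows_up_towards_collapse(self):
        Ws = [
            strain_energy_density(
                DeformationState.from_F(np.diag([a, a, 1.0])), TISSUE
            )
            for a in (0.5, 0.2, 0.05, 0.01)
        ]
        assert all(np.diff(Ws) > 0)
        assert Ws[-1] > 1e3

    def test_frame_invariance_of_energy(self):
        rng = np.random.default_rng(7)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        R = rotation(1.1) @ rotation(-0.4, axis=1)
        for mat in (TISSUE, dressing_material(19.0, 5.5)):
            w1 = strain_energy_density(DeformationState.from_F(F), mat)
            w2 = strain_energy_density(DeformationState.from_F(R @ F), mat)
            assert w2 == pytest.approx(w1, rel=1e-12)


class TestStressAndTangent:
    def test_stress_zero_at_identity(self):
        s = cauchy_stress(DeformationState.from_F(np.eye(3)), TISSUE)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_volumetric_state_is_hydrostatic(self):
        s = cauchy_stress(DeformationState.from_F(1.05 * np.eye(3)), TISSUE)
        off = s - np.diag(np.diag(s))
        assert np.allclose(off, 0.0, atol=1e-12)
        assert np.allclose(np.diag(s), s[0, 0], atol=1e-12)

    def test_inverted_state_rejected(self):
        with pytest.raises(InvertedStateError):
            DeformationState.from_F(np.diag([-1.0, 1.0, 1.0]))

    @pytest.mark.parametrize("mat", [TISSUE, BONE, dressing_material(30.8, 4.1)])
    def test_piola_is_derivative_of_energy(self, mat):
        rng = np.random.default_rng(11)
        for _ in range(20):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            st_ = DeformationState.from_F(F)
            P = first_piola_stress(st_, mat)
            h = 1e-6
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    dW = (
                        strain_energy_density(DeformationState.from_F(Fp), mat)
                        - strain_energy_density(DeformationState.from_F(Fm), mat)
                    ) / (2 * h)
                    assert dW == pytest.approx(P[i, j], rel=2e-5, abs=1e-5 * mat.constants.G)

    def test_tangent_consistency_on_random_states(self):
        # 100 random states across the packaged materials
        rng = np.random.default_rng(3)
        mats = [TISSUE, MATTRESS, BONE, dressing_material(7.4, 3.6)]
        checked = 0
        while checked < 100:
            mat = mats[checked % len(mats)]
            F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.3:
                continue
            A = material_tangent(DeformationState.from_F(F), mat)
            # major symmetry
            assert np.allclose(A, A.transpose(2, 3, 0, 1), rtol=1e-9, atol=1e-9 * mat.constants.G)
            h = 1e-6 if mat.constants.G < 1e4 else 1e-4
            scale = mat.constants.G + abs(mat.constants.lam)
            for i, j in [(0, 0), (0, 1), (2, 2), (1, 0)]:
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                dP = (
                    first_piola_stress(DeformationState.from_F(Fp), mat)
                    - first_piola_stress(DeformationState.from_F(Fm), mat)
                ) / (2 * h)
                assert np.allclose(dP, A[:, :, i, j], rtol=1e-5, atol=1e-5 * scale)
            checked += 1

    def test_neo_hookean_tangent_at_identity_equals_linear(self):
        nh = material_tangent(DeformationState.from_F(np.eye(3)), TISSUE)
        lin = material_tangent(
            DeformationState.from_F(np.eye(3)),
            Material(family="linear_elastic", constants=TISSUE.constants),
        )
        assert np.allclose(nh, lin, rtol=1e-12, atol=1e-9)


class TestDressingMaterial:
    def test_packaged_examples(self):
        tsf = dressing_material(19.0, 5.50, 0.02, name="TSF")
        assert tsf.constants.E == pytest.approx(19.0)
        assert tsf.solid_fraction == pytest.approx(0.02)
        agb = dressing_material(30.8, 4.10, 0.02)
        assert agb.constants.E == pytest.approx(30.8)
        assert agb.family == "neo_hookean"

    def test_full_solid_fraction_reduces_to_plain_neo_hookean(self):
        solid = dressing_material(19.0, 5.5, solid_fraction=1.0)
        rng = np.random.default_rng(5)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        ref = Material(family="neo_hookean", constants=solid.constants)
        st_ = DeformationState.from_F(F)
        assert strain_energy_density(st_, solid) == pytest.approx(
            strain_energy_density(st_, ref), rel=1e-15
        )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConstantsError):
            dressing_material(-1.0, 5.5)
        with pytest.raises(InvalidConstantsError):
            dressing_material(19.0, 0.0)
        with pytest.raises(InvalidConstantsError):
            dressing_material(19.0, 5.5, solid_fraction=0.0)
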