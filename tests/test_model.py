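"""Core motion model: antisymmetric-matrix convention, both ADP routes,
composition of TLS matrices, and the algebraic invariants tying them."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tlsvalid import (
    AtomGroup,
    ElementalMotions,
    InvalidInputError,
    TLSMatrices,
    adp_from_matrices,
    adp_from_motions,
    antisym_matrix,
    matrices_from_motions,
)
from tlsvalid.synthetic import random_valid_motions, toy_chain

ORIGIN = np.zeros(3)


class TestAntisymMatrix:
    def test_zero_at_origin(self):
        assert np.array_equal(antisym_matrix(ORIGIN, ORIGIN), np.zeros((3, 3)))

    def test_unit_x_pattern(self):
        a = antisym_matrix([1.0, 0.0, 0.0], ORIGIN)
        expected = np.zeros((3, 3))
        expected[1, 2] = 1.0
        expected[2, 1] = -1.0
        assert np.array_equal(a, expected)

    def test_cross_product_oracle(self, rng):
        # A(p) q must equal q x p for random pairs (sign fixed by the
        # ensemble-consistency requirement on screw motions)
        for _ in range(100):
            p, q = rng.normal(size=3), rng.normal(size=3)
            assert np.allclose(antisym_matrix(p, ORIGIN) @ q, np.cross(q, p),
                               atol=1e-12)

    def test_exactly_antisymmetric(self, rng):
        a = antisym_matrix(rng.normal(size=3), rng.normal(size=3))
        assert np.array_equal(a, -a.T)

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            antisym_matrix([np.nan, 0, 0], ORIGIN)


class TestAdpFromMatrices:
    def test_pure_translation_copies_t(self):
        tls = TLSMatrices(np.diag([0.04, 0.0, 0.0]), np.zeros((3, 3)),
                          np.zeros((3, 3)), ORIGIN)
        group = toy_chain(5, seed=0)
        for u in adp_from_matrices(tls, group).as_array():
            assert np.allclose(u, np.diag([0.04, 0.0, 0.0]), atol=1e-14)

    def test_libration_about_z_moves_atom_along_y(self):
        lam = 0.01
        tls = TLSMatrices(np.zeros((3, 3)), np.diag([0.0, 0.0, lam]),
                          np.zeros((3, 3)), ORIGIN)
        group = AtomGroup.from_coords([[1.0, 0.0, 0.0]])
        u = adp_from_matrices(tls, group).as_array()[0]
        expected = np.zeros((3, 3))
        expected[1, 1] = lam
        assert np.allclose(u, expected, atol=1e-14)

    @pytest.mark.parametrize("c", [-1.0, 0.37])
    def test_sigma_gauge_invariance(self, c, toy_group):
        m = random_valid_motions(7)
        tls = matrices_from_motions(m)
        u0 = adp_from_matrices(tls, toy_group).as_array()
        u1 = adp_from_matrices(tls.shifted_sigma(c), toy_group).as_array()
        assert np.abs(u0 - u1).max() < 1e-12

    @given(c=st.floats(-10.0, 10.0))
    def test_sigma_gauge_invariance_property(self, c):
        tls = matrices_from_motions(random_valid_motions(11))
        group = toy_chain(6, seed=2)
        u0 = adp_from_matrices(tls, group).as_array()
        u1 = adp_from_matrices(tls.shifted_sigma(c), group).as_array()
        assert np.abs(u0 - u1).max() < 1e-11 * (1.0 + abs(c))


class TestMatricesFromMotions:
    def test_pure_vibration(self):
        m = ElementalMotions(d=np.zeros(3), l_axes=np.eye(3),
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=[0.1, 0.0, 0.0], v_axes=np.eye(3), origin=ORIGIN)
        tls = matrices_from_motions(m)
        assert np.allclose(tls.T, np.diag([0.01, 0, 0]), atol=1e-15)
        assert np.allclose(tls.L, 0.0) and np.allclose(tls.S, 0.0)

    def test_pure_libration_about_z(self):
        m = ElementalMotions(d=[0.0, 0.0, 0.1], l_axes=np.eye(3),
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=np.zeros(3), v_axes=np.eye(3), origin=ORIGIN)
        tls = matrices_from_motions(m)
        assert np.allclose(tls.L, np.diag([0, 0, 0.01]), atol=1e-15)
        assert np.allclose(tls.T, 0.0) and np.allclose(tls.S, 0.0)

    def test_screw_libration_row_pattern(self):
        # axis z through w=(1,0,0) with pitch s: unit-rotation translation
        # a_z = (0, -1, s); S row z = lam*a_z, T gains lam*outer(a_z, a_z)
        d, s = 0.05, 2.0
        lam = d * d
        m = ElementalMotions(d=[0.0, 0.0, d], l_axes=np.eye(3),
                             w_points=[[0, 0, 0], [0, 0, 0], [1.0, 0, 0]],
                             s=[0.0, 0.0, s], t=np.zeros(3), v_axes=np.eye(3),
                             origin=ORIGIN)
        tls = matrices_from_motions(m)
        a_z = np.array([0.0, -1.0, s])
        assert np.allclose(tls.S[2], lam * a_z, atol=1e-15)
        assert np.allclose(tls.S[:2], 0.0)
        assert np.allclose(tls.T, lam * np.outer(a_z, a_z), atol=1e-15)

    def test_matrix_route_matches_direct_route_per_atom(self, rng):
        d, s = 0.05, 2.0
        m = ElementalMotions(d=[0.0, 0.0, d], l_axes=np.eye(3),
                             w_points=[[0, 0, 0], [0, 0, 0], [1.0, 0, 0]],
                             s=[0.0, 0.0, s], t=np.zeros(3), v_axes=np.eye(3),
                             origin=ORIGIN)
        group = AtomGroup.from_coords(rng.normal(scale=5.0, size=(20, 3)))
        u_mat = adp_from_matrices(matrices_from_motions(m), group).as_array()
        u_dir = adp_from_motions(m, group).as_array()
        assert np.abs(u_mat - u_dir).max() < 1e-12

    def test_rejects_non_orthonormal_axes(self):
        with pytest.raises(InvalidInputError):
            ElementalMotions(d=np.zeros(3), l_axes=np.eye(3) * 1.1,
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=np.zeros(3), v_axes=np.eye(3), origin=ORIGIN)


class TestAdpFromMotions:
    def test_all_zero_amplitudes(self, toy_group):
        m = ElementalMotions(d=np.zeros(3), l_axes=np.eye(3),
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=np.zeros(3), v_axes=np.eye(3), origin=ORIGIN)
        assert np.allclose(adp_from_motions(m, toy_group).as_array(), 0.0)

    def test_single_vibration(self, toy_group):
        m = ElementalMotions(d=np.zeros(3), l_axes=np.eye(3),
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=[0.2, 0.0, 0.0], v_axes=np.eye(3), origin=ORIGIN)
        for u in adp_from_motions(m, toy_group).as_array():
            assert np.allclose(u, np.diag([0.04, 0, 0]), atol=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_route_equivalence_random(self, seed, rng):
        m = random_valid_motions(seed)
        group = AtomGroup.from_coords(rng.normal(scale=8.0, size=(50, 3)))
        u_dir = adp_from_motions(m, group).as_array()
        u_mat = adp_from_matrices(matrices_from_motions(m), group).as_array()
        assert np.abs(u_dir - u_mat).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_produced_adps_are_psd(self, seed, toy_group):
        u = adp_from_motions(random_valid_motions(seed), toy_group).as_array()
        assert np.linalg.eigvalsh(u).min() >= -1e-10

    def test_translation_covariance(self, toy_group):
        m = random_valid_motions(9)
        shift = np.array([3.0, -7.0, 11.0])
        u0 = adp_from_motions(m, toy_group).as_array()
        m2 = m.copy()
        m2.origin = m.origin + shift
        m2.w_points = m.w_points + shift
        g2 = toy_group.with_coords(toy_group.coords + shift)
        u1 = adp_from_motions(m2, g2).as_array()
        assert np.abs(u0 - u1).max() < 1e-12


class TestElementalMotionsValidation:
    def test_screw_on_zero_libration_zeroed_and_flagged(self):
        m = ElementalMotions(d=[0.0, 0.1, 0.1], l_axes=np.eye(3),
                             w_points=np.zeros((3, 3)), s=[5.0, 1.0, 1.0],
                             t=np.zeros(3), v_axes=np.eye(3), origin=ORIGIN)
        assert m.s[0] == 0.0
        assert any("undefined" in f for f in m.flags)
        assert list(m.screw_defined) == [False, True, True]

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(InvalidInputError):
            ElementalMotions(d=[-0.1, 0, 0], l_axes=np.eye(3),
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=np.zeros(3), v_axes=np.eye(3), origin=ORIGIN)

    def test_w_l_basis_round_trip(self):
        m = random_valid_motions(21)
        w_l = m.w_in_l_basis()
        back = ElementalMotions.w_from_l_basis(w_l, m.l_axes, m.origin)
        assert np.abs(back - m.w_points).max() < 1e-10


class TestTLSMatricesValidation:
    def test_asymmetric_t_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = 1e-3
        with pytest.raises(InvalidInputError):
            TLSMatrices(t, np.zeros((3, 3)), np.zeros((3, 3)), ORIGIN)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            TLSMatrices(np.full((3, 3), np.inf), np.zeros((3, 3)),
                        np.zeros((3, 3)), ORIGIN)
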