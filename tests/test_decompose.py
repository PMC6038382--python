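"""Decomposition of TLS matrices: sigma strategies, feasibility constraints
and the failure-status taxonomy."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from tlsvalid import (
    DecompositionStatus,
    ElementalMotions,
    InvalidInputError,
    SigmaStrategy,
    TLSMatrices,
    adp_from_motions,
    decompose,
    feasible_sigma_interval,
    matrices_from_motions,
    sigma_smin,
    sigma_trace,
)
from tlsvalid.decompose import _residual_vibration
from tlsvalid.reference_sets import reference_motions
from tlsvalid.synthetic import random_valid_motions, toy_chain

I3 = np.eye(3)
Z3 = np.zeros((3, 3))
ORIGIN = np.zeros(3)


def tls_of(T, L, S):
    return TLSMatrices(T, L, S, ORIGIN)


class TestStatusTaxonomy:
    def test_isotropic_case(self):
        d, t = 0.05, 0.3
        res = decompose(tls_of(t**2 * I3, d**2 * I3, Z3))
        assert res.status is DecompositionStatus.OK
        assert np.allclose(res.motions.d, d, atol=1e-12)
        assert np.allclose(res.motions.t, t, atol=1e-12)
        assert np.allclose(res.motions.s, 0.0, atol=1e-12)
        assert np.allclose(res.motions.w_points, 0.0, atol=1e-9)
        assert abs(res.sigma) < 1e-12

    def test_all_zero(self):
        assert decompose(tls_of(Z3, Z3, Z3)).status is \
            DecompositionStatus.MATRICES_ALL_ZERO

    def test_wrong_content_on_nan(self):
        bad = tls_of(I3 * 0.01, Z3, Z3)
        bad.T = bad.T.copy()
        bad.T[0, 0] = np.nan  # corrupt after validation, as a survey would see
        assert decompose(bad).status is DecompositionStatus.WRONG_CONTENT

    def test_l_not_psd(self):
        res = decompose(tls_of(0.01 * I3, np.diag([-1e-4, 1e-4, 2e-4]), Z3))
        assert res.status is DecompositionStatus.L_NOT_PSD

    def test_t_residual_not_psd(self):
        # a screw diagonal too large for T at every feasible sigma
        L = np.diag([1e-4, 1e-4, 1e-4])
        S = np.diag([0.1, -0.1, 0.0])  # cannot be annihilated by one sigma
        res = decompose(tls_of(1e-6 * I3, L, S))
        assert res.status is DecompositionStatus.T_RESIDUAL_NOT_PSD

    def test_libration_undefined_pure_vibration(self):
        res = decompose(tls_of(np.diag([0.01, 0.04, 0.09]), Z3, Z3))
        assert res.status is DecompositionStatus.LIBRATION_UNDEFINED
        assert np.allclose(np.sort(res.motions.t), [0.1, 0.2, 0.3], atol=1e-12)
        assert np.all(res.motions.d == 0.0)

    def test_statuses_are_exclusive_and_total(self):
        cases = [
            tls_of(0.01 * I3, 1e-4 * I3, Z3),
            tls_of(Z3, Z3, Z3),
            tls_of(np.diag([0.01, 0.04, 0.09]), Z3, Z3),
            tls_of(0.01 * I3, np.diag([-1e-4, 1e-4, 2e-4]), Z3),
        ]
        for tls in cases:
            res = decompose(tls)
            assert isinstance(res.status, DecompositionStatus)
            has_motions = res.motions is not None
            expect = res.status in (DecompositionStatus.OK,
                                    DecompositionStatus.LIBRATION_UNDEFINED)
            assert has_motions == expect


class TestSigmaTrace:
    @pytest.mark.parametrize("diag,expected", [
        ((1e-3, 1e-3, 1e-3), 1e-3),
        ((3e-3, 0.0, 0.0), 1e-3),
    ])
    def test_examples(self, diag, expected):
        assert sigma_trace(diag) == pytest.approx(expected, abs=1e-15)

    def test_shifted_diagonal_is_trace_free(self, rng):
        for _ in range(20):
            diag = rng.normal(size=3)
            assert abs(np.sum(diag - sigma_trace(diag))) < 1e-12


class TestSigmaSmin:
    def test_exact_annihilation(self):
        lam = np.array([2e-4, 2e-4, 2e-4])
        c = 0.7
        sigma = sigma_smin(c * lam, lam)
        assert sigma == pytest.approx(c * lam[0], rel=1e-12)
        s = (c * lam - sigma) / lam
        assert np.abs(s).max() < 1e-12

    def test_matches_scan_refined_minimum(self, rng):
        # independent oracle: dense grid bracketing + golden-section refine
        # of the objective sum((S'_kk - sigma)^2 / lam_k^2)
        for _ in range(25):
            lam = rng.uniform(1e-6, 1e-3, size=3)
            diag = rng.normal(scale=1e-3, size=3)

            def objective(sigma):
                return float(np.sum(((diag - sigma) / lam) ** 2))

            grid = np.linspace(diag.min() - 1e-2, diag.max() + 1e-2, 2001)
            i = int(np.argmin([objective(g) for g in grid]))
            res = minimize_scalar(objective,
                                  bracket=(grid[max(i - 1, 0)],
                                           grid[min(i + 1, len(grid) - 1)]),
                                  method="golden",
                                  options={"xtol": 1e-14})
            assert sigma_smin(diag, lam) == pytest.approx(res.x, abs=1e-10)

    def test_reconstructed_pathological_group_scan(self):
        # the deposited-group reconstruction: lam from d = (0.001,0.008,0.014)
        lam = np.array([1e-6, 6.4e-5, 1.96e-4])
        s_printed = np.array([303.63, 2.90, -3.11])
        diag = s_printed * lam

        def objective(sigma):
            return float(np.sum(((diag - sigma) / lam) ** 2))

        res = minimize_scalar(objective, bounds=(diag.min(), diag.max()),
                              method="bounded",
                              options={"xatol": 1e-14})
        assert sigma_smin(diag, lam) == pytest.approx(res.x, abs=1e-10)

    def test_all_zero_lambda_raises(self):
        with pytest.raises(InvalidInputError):
            sigma_smin([1e-3, 0, 0], [0.0, 0.0, 0.0])


class TestFeasibleInterval:
    def test_contains_zero_for_zero_s(self):
        iv = feasible_sigma_interval(0.01 * I3, Z3, [1e-4, 2e-4, 3e-4])
        assert iv is not None and 0.0 in iv

    def test_contains_composing_gauge(self):
        for seed in range(10):
            m = random_valid_motions(seed)
            tls = matrices_from_motions(m)
            evals, evecs = np.linalg.eigh(tls.L)
            iv = feasible_sigma_interval(evecs.T @ tls.T @ evecs,
                                         evecs.T @ tls.S @ evecs, evals)
            assert iv is not None and 0.0 in iv

    def test_endpoints_sit_on_psd_boundary(self):
        m = random_valid_motions(4)
        tls = matrices_from_motions(m)
        evals, evecs = np.linalg.eigh(tls.L)
        T_p = evecs.T @ tls.T @ evecs
        S_p = evecs.T @ tls.S @ evecs
        iv = feasible_sigma_interval(T_p, S_p, evals)
        for endpoint in (iv.lo, iv.hi):
            low = np.linalg.eigvalsh(
                _residual_vibration(T_p, S_p, evals, endpoint))[0]
            # root-finding leaves the endpoint within ~1e-9 of the
            # -tol_T boundary value
            assert -1e-8 - 1e-9 <= low <= 1e-8 + 1e-10

    def test_empty_when_t_too_small(self):
        iv = feasible_sigma_interval(
            1e-6 * I3, np.diag([0.1, -0.1, 0.0]), [1e-4] * 3)
        assert iv is None


class TestDecomposeProperties:
    @pytest.mark.parametrize("strategy", ["trace", "t_min", "s_min"])
    def test_gauge_consistency(self, strategy):
        m = random_valid_motions(6)
        tls = matrices_from_motions(m)
        c = 2.5e-4
        r0 = decompose(tls, strategy)
        r1 = decompose(tls.shifted_sigma(c), strategy)
        assert r0.ok and r1.ok
        assert r1.sigma - r0.sigma == pytest.approx(c, abs=1e-10)
        assert np.abs(r0.motions.d - r1.motions.d).max() < 1e-12
        assert np.abs(r0.motions.s - r1.motions.s).max() < 1e-7
        assert np.abs(r0.motions.t - r1.motions.t).max() < 1e-7

    def test_s_diag_relation_holds(self):
        # S'_kk = s_k lam_k + sigma for every positive-amplitude axis
        m = random_valid_motions(8)
        tls = matrices_from_motions(m)
        res = decompose(tls, "s_min")
        mm = res.motions
        S_p = mm.l_axes @ tls.S @ mm.l_axes.T
        for k in range(3):
            assert S_p[k, k] == pytest.approx(
                mm.s[k] * mm.d[k] ** 2 + res.sigma, abs=1e-12)

    def test_ascending_amplitude_order(self):
        m = random_valid_motions(12)
        res = decompose(matrices_from_motions(m))
        assert np.all(np.diff(res.motions.d) >= 0)
        assert np.all(np.diff(res.motions.t) >= 0)

    def test_deterministic(self):
        tls = matrices_from_motions(random_valid_motions(17))
        r1, r2 = decompose(tls), decompose(tls)
        assert np.array_equal(r1.motions.d, r2.motions.d)
        assert np.array_equal(r1.motions.l_axes, r2.motions.l_axes)
        assert r1.sigma == r2.sigma

    def test_round_trip_at_composing_gauge_recovers_everything(self):
        for seed in range(20):
            m = random_valid_motions(seed)
            res = decompose(matrices_from_motions(m), sigma_override=0.0)
            assert res.ok
            assert np.abs(np.sort(res.motions.d) - np.sort(m.d)).max() < 1e-8
            assert np.abs(np.sort(res.motions.t) - np.sort(m.t)).max() < 1e-8

    def test_s_min_idempotent(self):
        m = random_valid_motions(5)
        m1 = decompose(matrices_from_motions(m), "s_min").motions
        m2 = decompose(matrices_from_motions(m1), "s_min").motions
        assert np.abs(m1.d - m2.d).max() < 1e-10
        assert np.abs(m1.t - m2.t).max() < 1e-10
        assert np.abs(m1.s - m2.s).max() < 1e-8

    def test_harmonic_limit_warning(self):
        m = ElementalMotions(d=[0.0, 0.0, 0.3], l_axes=I3,
                             w_points=np.zeros((3, 3)), s=np.zeros(3),
                             t=[0.1, 0.1, 0.1], v_axes=I3, origin=ORIGIN)
        res = decompose(matrices_from_motions(m))
        assert res.ok
        assert any("harmonic limit" in w for w in res.warnings)

    def test_screw_cap_warning(self):
        m = ElementalMotions(d=[0.001, 0.05, 0.08], l_axes=I3,
                             w_points=np.zeros((3, 3)), s=[300.0, 0, 0],
                             t=[0.3, 0.4, 0.5], v_axes=I3, origin=ORIGIN)
        res = decompose(matrices_from_motions(m), sigma_override=0.0)
        assert any("cap" in w for w in res.warnings)


@pytest.fixture(scope="module")
def tls4():
    return matrices_from_motions(reference_motions("4muy_group6", "t_min"))


class TestPathologicalDepositedGroup:
    """Reconstruction of the published screw pathology (PDB entry 4muy,
    group 6): a 0.001 rad libration carrying a 303.63 A/rad pitch."""

    def test_near_zero_gauge_keeps_printed_pitch(self, tls4):
        res = decompose(tls4, sigma_override=0.0)
        assert res.ok
        assert res.motions.s[0] == pytest.approx(303.63, abs=1e-6)

    def test_smin_collapses_the_pitch(self, tls4):
        res = decompose(tls4, "s_min")
        assert res.ok
        assert abs(res.motions.s[0]) < 0.5
        assert 303.63 / abs(res.motions.s[0]) > 1000
        # sigma moves by a few tens of 1e-5 A.rad to absorb the pitch
        assert 1e-4 < res.sigma < 1e-3

    def test_smin_never_worse_than_trace(self, tls4):
        r_s = decompose(tls4, "s_min")
        r_t = decompose(tls4, "trace")
        assert np.linalg.norm(r_s.motions.s) <= np.linalg.norm(
            r_t.motions.s) + 1e-9


def test_validated_groups_adps_are_gauge_independent(toy_group):
    """Whatever sigma strategy, the recomposed motions reproduce the
    original per-atom ADPs: sigma is a pure gauge."""
    m = random_valid_motions(30)
    tls = matrices_from_motions(m)
    u_ref = adp_from_motions(m, toy_group).as_array()
    for strategy in SigmaStrategy:
        res = decompose(tls, strategy)
        u = adp_from_motions(res.motions, toy_group).as_array()
        assert np.abs(u - u_ref).max() < 1e-8
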