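"""Extraction of elemental motions from TLS matrices.

The libration amplitudes and axes follow from the eigendecomposition of L
and are unambiguous.  The screw pitches do not: a scalar sigma may be added
to the diagonal of S (in any basis) without changing a single ADP, yet it
changes the pitches ``s_k = (S'_kk - sigma) / lam_k`` read off the diagonal
of S in the [L] basis, and through them the residual vibration matrix.  The
decomposition is therefore parameterized by a sigma *strategy*:

``trace``
    the traditional choice, sigma = tr(S')/3, which makes the shifted
    diagonal trace-free;
``t_min``
    the feasibility-constrained variant: the trace sigma projected onto the
    interval of sigma values for which the residual vibration matrix stays
    positive semi-definite.  (The exact vibration-minimizing criterion is
    defined in terms of constraints not reproduced here; this projection is
    a documented approximation and, because every strategy is projected onto
    the same interval, coincides with ``trace`` in this implementation.)
``s_min``
    the pitch-minimizing choice: sigma minimizing ``|s|^2``, in closed form
    the 1/lam_k^2-weighted mean of the S' diagonal, again projected onto the
    feasible interval.  Large screw pitches are the dominant cause of
    disagreement between analytic and ensemble ADPs, which is what makes
    this choice attractive.

Inputs that cannot be decomposed are classified rather than raised: the
status taxonomy (wrong content / non-PSD L / non-PSD residual T / all-zero
matrices / libration undefined) is total over all finite and non-finite
inputs, which the survey machinery relies on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import (
    HARMONIC_LIMIT,
    ElementalMotions,
    InvalidInputError,
    TLSMatrices,
)

__all__ = [
    "SigmaStrategy",
    "DecompositionStatus",
    "DecompositionResult",
    "decompose",
    "sigma_trace",
    "sigma_smin",
    "feasible_sigma_interval",
    "Interval",
]

#: eigenvalues of L below this (rad^2) count as zero; slightly negative
#: values above -TOL_L are clamped (deposition rounding noise)
TOL_L = 1e-9
#: PSD tolerance for the residual vibration matrix (A^2)
TOL_T = 1e-8
#: default warning threshold for screw pitches (A/rad)
DEFAULT_S_CAP = 100.0


class SigmaStrategy(enum.Enum):
    TRACE = "trace"
    T_MIN = "t_min"
    S_MIN = "s_min"

    @classmethod
    def coerce(cls, value) -> "SigmaStrategy":
        if isinstance(value, cls):
            return value
        key = str(value).lower().replace("-", "_")
        aliases = {"trace": cls.TRACE, "t_min": cls.T_MIN, "tmin": cls.T_MIN,
                   "s_min": cls.S_MIN, "smin": cls.S_MIN}
        try:
            return aliases[key]
        except KeyError:
            raise InvalidInputError(f"unknown sigma strategy: {value!r}") from None


class DecompositionStatus(enum.Enum):
    OK = "ok"
    MATRICES_ALL_ZERO = "matrices_all_zero"
    WRONG_CONTENT = "wrong_content"
    L_NOT_PSD = "L_not_psd"
    T_RESIDUAL_NOT_PSD = "T_residual_not_psd"
    LIBRATION_UNDEFINED = "libration_undefined"


@dataclass
class Interval:
    """A closed sigma interval; ``disconnected`` warns that the PSD region
    of the residual vibration matrix had more than one component and only
    the one containing the preferred sigma is reported."""

    lo: float
    hi: float
    disconnected: bool = False

    def clip(self, x: float) -> float:
        return float(min(max(x, self.lo), self.hi))

    def __contains__(self, x: float) -> bool:
        return self.lo - 1e-12 <= x <= self.hi + 1e-12


@dataclass
class DecompositionResult:
    status: DecompositionStatus
    motions: Optional[ElementalMotions] = None
    sigma: float = 0.0
    feasible_interval: Optional[Interval] = None
    strategy: Optional[SigmaStrategy] = None
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status is DecompositionStatus.OK


def sigma_trace(s_diag) -> float:
    """Trace gauge: sigma such that the shifted S diagonal is trace-free."""
    s_diag = np.asarray(s_diag, dtype=float).reshape(3)
    return float(s_diag.sum() / 3.0)


def sigma_smin(s_diag, lambdas, interval: Optional[Interval] = None) -> float:
    """Sigma minimizing the squared screw-vector norm.

    ``|s|^2 = sum_{k: lam_k>0} ((S'_kk - sigma)/lam_k)^2`` is quadratic in
    sigma; the unconstrained minimizer is the 1/lam_k^2-weighted mean of the
    S' diagonal.  Because the weights favour the smallest libration, the
    minimizer essentially annihilates the pitch of the weakest axis.  When
    ``interval`` is given the minimizer is projected onto it, which remains
    optimal over the interval by convexity.
    """
    s_diag = np.asarray(s_diag, dtype=float).reshape(3)
    lam = np.asarray(lambdas, dtype=float).reshape(3)
    pos = lam > 0
    if not np.any(pos):
        raise InvalidInputError("all libration eigenvalues are zero: screw "
                                "pitches (and sigma) are undefined")
    w = 1.0 / lam[pos] ** 2
    sigma = float(np.sum(w * s_diag[pos]) / np.sum(w))
    if interval is not None:
        sigma = interval.clip(sigma)
    return sigma


def _screw_vectors_lbasis(S_prime: np.ndarray, lam: np.ndarray,
                          sigma: float) -> np.ndarray:
    """Unit-rotation translation vectors a_k (rows, [L]-basis) at gauge sigma.

    Row k of S' equals ``lam_k a_k`` with the diagonal element shifted by
    sigma, so ``a_k = (S'[k] - sigma e_k) / lam_k``; zero-amplitude axes get
    a zero row (their rotation carries no weight).
    """
    a = np.zeros((3, 3))
    for k in range(3):
        if lam[k] > 0:
            row = S_prime[k].copy()
            row[k] -= sigma
            a[k] = row / lam[k]
    return a


def _residual_poly(T_prime: np.ndarray, S_prime: np.ndarray, lam: np.ndarray):
    """Coefficients of C(sigma) = C0 + sigma C1 - sigma^2 C2 ([L] basis).

    The screw term is quadratic in sigma, so the residual vibration matrix
    is a quadratic matrix polynomial; evaluating it on a sigma grid is then
    a single batched operation.
    """
    c0 = T_prime.copy()
    c1 = np.zeros((3, 3))
    c2 = np.zeros((3, 3))
    for k in range(3):
        if lam[k] > 0:
            base = S_prime[k] / lam[k]
            c0 -= lam[k] * np.outer(base, base)
            e_k = np.eye(3)[k]
            c1 += np.outer(base, e_k) + np.outer(e_k, base)
            c2[k, k] = 1.0 / lam[k]
    return c0, c1, c2


def _residual_vibration(T_prime: np.ndarray, S_prime: np.ndarray,
                        lam: np.ndarray, sigma: float) -> np.ndarray:
    """C(sigma) = T' - sum_k lam_k a_k(sigma) a_k(sigma)^t  ([L] basis)."""
    c0, c1, c2 = _residual_poly(T_prime, S_prime, lam)
    return c0 + sigma * c1 - sigma**2 * c2


def feasible_sigma_interval(
    T_prime, S_prime, lambdas, tol: float = TOL_T, prefer: Optional[float] = None
) -> Optional[Interval]:
    """Closed interval of sigma values keeping the residual vibration PSD.

    The smallest eigenvalue of ``C(sigma)`` is continuous in sigma and tends
    to -inf as |sigma| grows (the pitch of each positive-amplitude axis
    diverges), so the PSD region is bounded.  It is located by a coarse scan
    over an analytic outer bracket (each diagonal element of C must be
    non-negative, giving ``|sigma - S'_kk| <= sqrt(lam_k (T'_kk + tol))``)
    and its endpoints are refined by root bisection.  If the scan sees more
    than one feasible run, the component containing ``prefer`` (or the
    unconstrained |s|-minimizer) is returned with ``disconnected=True``.

    Returns ``None`` when no feasible sigma exists.
    """
    T_prime = np.asarray(T_prime, dtype=float)
    S_prime = np.asarray(S_prime, dtype=float)
    lam = np.asarray(lambdas, dtype=float).reshape(3)
    pos = lam > 0
    if not np.any(pos):
        raise InvalidInputError("feasible sigma interval undefined when all "
                                "libration eigenvalues are zero")

    c0, c1, c2 = _residual_poly(T_prime, S_prime, lam)

    def min_eig(sigma: float) -> float:
        return float(np.linalg.eigvalsh(c0 + sigma * c1 - sigma**2 * c2)[0])

    # outer bracket from the diagonal-element necessary condition
    lo_b, hi_b = -np.inf, np.inf
    for k in range(3):
        if pos[k]:
            half = float(np.sqrt(max(lam[k] * (T_prime[k, k] + tol), 0.0)))
            lo_b = max(lo_b, S_prime[k, k] - half)
            hi_b = min(hi_b, S_prime[k, k] + half)
    if lo_b > hi_b:
        return None

    if prefer is None:
        prefer = sigma_smin(np.diag(S_prime), lam)

    grid = np.unique(np.concatenate([
        np.linspace(lo_b, hi_b, 513),
        np.clip([prefer, sigma_trace(np.diag(S_prime))], lo_b, hi_b),
    ]))
    c_grid = (c0[None] + grid[:, None, None] * c1
              - (grid**2)[:, None, None] * c2)
    vals = np.linalg.eigvalsh(c_grid)[:, 0]
    feas = vals >= -tol
    if not np.any(feas):
        return None

    # contiguous feasible runs
    runs: List[Tuple[int, int]] = []
    start = None
    for i, f in enumerate(feas):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(grid) - 1))

    def run_dist(run: Tuple[int, int]) -> float:
        a, b = grid[run[0]], grid[run[1]]
        return 0.0 if a <= prefer <= b else min(abs(prefer - a), abs(prefer - b))

    run = min(runs, key=run_dist)
    i0, i1 = run
    f = lambda s: min_eig(s) + tol  # noqa: E731  (root at the PSD boundary)
    lo = grid[i0]
    if i0 > 0 and f(grid[i0 - 1]) < 0 < f(lo):
        lo = brentq(f, grid[i0 - 1], lo, xtol=1e-12, rtol=1e-14)
    hi = grid[i1]
    if i1 < len(grid) - 1 and f(grid[i1 + 1]) < 0 < f(hi):
        hi = brentq(f, hi, grid[i1 + 1], xtol=1e-12, rtol=1e-14)
    return Interval(float(lo), float(hi), disconnected=len(runs) > 1)


def _fix_axis_signs(axes_cols: np.ndarray, right_handed: bool) -> np.ndarray:
    """Deterministic eigenvector orientation.

    Each column gets its largest-|component| entry made positive; if a
    right-handed triplet is required and the determinant is negative, the
    last column is flipped back.
    """
    out = axes_cols.copy()
    for k in range(3):
        j = int(np.argmax(np.abs(out[:, k])))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    if right_handed and np.linalg.det(out) < 0:
        out[:, 2] = -out[:, 2]
    return out


def _vibration_from_matrix(C: np.ndarray, tol: float):
    """Eigen-split a PSD vibration matrix into amplitudes and directions.

    Returns ``(t, v_cols)`` with eigenvalues ascending, or ``None`` if C has
    an eigenvalue below ``-tol``.
    """
    evals, evecs = np.linalg.eigh(0.5 * (C + C.T))
    if evals[0] < -tol:
        return None
    evals = np.clip(evals, 0.0, None)
    return np.sqrt(evals), _fix_axis_signs(evecs, right_handed=False)


def decompose(
    tls: TLSMatrices,
    strategy=SigmaStrategy.S_MIN,
    *,
    sigma_override: Optional[float] = None,
    s_cap: float = DEFAULT_S_CAP,
    tol_l: float = TOL_L,
    tol_t: float = TOL_T,
) -> DecompositionResult:
    """Decompose TLS matrices into elemental motions under a sigma gauge.

    Parameters
    ----------
    tls
        TLS matrices in internal units (A^2, rad^2, A.rad).
    strategy
        Sigma strategy name or :class:`SigmaStrategy`.
    sigma_override
        Fix sigma to this value instead of applying a strategy (not
        projected onto the feasible interval).  Useful for gauge scans and
        for recovering a decomposition at a known composing gauge.
    s_cap
        Screw pitches beyond this magnitude (A/rad) add a warning; they are
        never a failure, only physically implausible.

    Returns
    -------
    DecompositionResult
        With ``status`` ok, motions and sigma set; or a failure status from
        the taxonomy.  Libration amplitudes above the harmonic limit
        (0.15 rad) warn but do not fail.
    """
    strategy = SigmaStrategy.coerce(strategy)
    arrays = (tls.T, tls.L, tls.S, tls.origin)
    if not all(np.all(np.isfinite(a)) for a in arrays):
        return DecompositionResult(DecompositionStatus.WRONG_CONTENT,
                                   strategy=strategy)
    if tls.is_zero():
        return DecompositionResult(DecompositionStatus.MATRICES_ALL_ZERO,
                                   strategy=strategy)

    warnings: List[str] = []
    evals, evecs = np.linalg.eigh(tls.L)  # ascending
    if evals[0] < -tol_l:
        return DecompositionResult(DecompositionStatus.L_NOT_PSD,
                                   strategy=strategy)
    lam = np.where(evals > tol_l, np.clip(evals, 0.0, None), 0.0)
    R = _fix_axis_signs(evecs, right_handed=True)  # columns l_x, l_y, l_z

    if np.all(lam == 0.0):
        # pure-vibration motions straight from T
        vib = _vibration_from_matrix(tls.T, tol_t)
        if vib is None:
            return DecompositionResult(DecompositionStatus.T_RESIDUAL_NOT_PSD,
                                       strategy=strategy)
        t, v_cols = vib
        motions = ElementalMotions(
            d=np.zeros(3), l_axes=R.T,
            w_points=np.tile(tls.origin, (3, 1)),
            s=np.zeros(3), t=t, v_axes=v_cols.T, origin=tls.origin,
            flags=["all libration eigenvalues zero"],
        )
        return DecompositionResult(
            DecompositionStatus.LIBRATION_UNDEFINED, motions=motions,
            sigma=0.0, strategy=strategy, warnings=warnings)

    T_prime = R.T @ tls.T @ R
    S_prime = R.T @ tls.S @ R
    s_diag = np.diag(S_prime)

    interval = feasible_sigma_interval(T_prime, S_prime, lam, tol=tol_t)
    if interval is None:
        return DecompositionResult(DecompositionStatus.T_RESIDUAL_NOT_PSD,
                                   strategy=strategy)
    if interval.disconnected:
        warnings.append("feasible sigma region disconnected; using the "
                        "component nearest the unconstrained optimum")

    if sigma_override is not None:
        sigma = float(sigma_override)
        if sigma not in interval:
            warnings.append(f"sigma_override {sigma:g} lies outside the "
                            f"feasible interval [{interval.lo:g}, {interval.hi:g}]")
    elif strategy is SigmaStrategy.S_MIN:
        sigma = sigma_smin(s_diag, lam, interval=interval)
    else:  # TRACE, and the T_MIN stand-in (projected trace)
        sigma = interval.clip(sigma_trace(s_diag))

    a = _screw_vectors_lbasis(S_prime, lam, sigma)
    s = np.array([a[k, k] if lam[k] > 0 else 0.0 for k in range(3)])
    # axis point in the [L] basis is e_k x a_k (own component drops out)
    w_l = np.stack([np.cross(np.eye(3)[k], a[k]) for k in range(3)])
    w_points = tls.origin + w_l @ R.T  # rows back to the lab frame

    C = _residual_vibration(T_prime, S_prime, lam, sigma)
    # a projected sigma can sit exactly on the bisected PSD boundary, where
    # the smallest eigenvalue equals -tol_t up to root-finding error; pad
    # the final check accordingly (genuine failures overshoot by orders)
    vib = _vibration_from_matrix(C, 2.0 * tol_t)
    if vib is None:
        return DecompositionResult(DecompositionStatus.T_RESIDUAL_NOT_PSD,
                                   strategy=strategy, sigma=sigma,
                                   feasible_interval=interval)
    t, v_cols = vib

    d = np.sqrt(lam)
    flags = [f"screw pitch on axis {k} undefined (zero libration); set to 0"
             for k in range(3) if lam[k] == 0.0]
    for k in range(3):
        if d[k] > HARMONIC_LIMIT:
            warnings.append(f"libration amplitude d[{k}]={d[k]:.3f} rad exceeds "
                            f"the harmonic limit {HARMONIC_LIMIT} rad")
        if abs(s[k]) > s_cap:
            warnings.append(f"screw pitch |s[{k}]|={abs(s[k]):.2f} A/rad exceeds "
                            f"the cap {s_cap:g}")

    motions = ElementalMotions(
        d=d, l_axes=R.T, w_points=w_points, s=s,
        t=t, v_axes=(R @ v_cols).T, origin=tls.origin, flags=flags,
    )
    return DecompositionResult(
        DecompositionStatus.OK, motions=motions, sigma=float(sigma),
        feasible_interval=interval, strategy=strategy, warnings=warnings)
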