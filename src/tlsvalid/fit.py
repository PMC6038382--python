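"""Least-squares fit of TLS matrices to observed per-atom anisotropic ADPs.

The analytic ADP is linear in the 21 TLS matrix elements, and the sigma
gauge removes one degree of freedom, so the fit solves an ordinary linear
least-squares problem in 20 unknowns (gauge fixed by trace(S) = 0; any
other gauge fits identically well, and sigma strategies are applied later
at decomposition time).  The fit is deliberately unconstrained: non-PSD T
or L in the solution is not an error here but a *finding*, classified by
the downstream decomposition exactly as it would be for deposited
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import ADPSet, AtomGroup, InvalidInputError, TLSMatrices, adp_from_matrices

__all__ = ["fit_tls", "FitResult", "DegenerateGeometryError"]

# unique-element order used for the design matrix rows
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


class DegenerateGeometryError(InvalidInputError):
    """The atom geometry leaves some TLS parameters unobservable."""


@dataclass
class FitResult:
    tls: TLSMatrices
    residual: float  # RMS of (U_obs - U_fit) over unique elements, A^2
    rank: int

    def __iter__(self):  # allows  tls, residual = fit_tls(...)
        yield self.tls
        yield self.residual


def _basis_matrices():
    """The 20 unit TLS parameter directions (trace-free S gauge)."""
    basis = []
    eye = np.eye(3)
    zeros = np.zeros((3, 3))
    for i, j in _IJ:  # T, symmetric
        m = np.zeros((3, 3))
        m[i, j] = m[j, i] = 1.0
        basis.append((m, zeros, zeros))
    for i, j in _IJ:  # L, symmetric
        m = np.zeros((3, 3))
        m[i, j] = m[j, i] = 1.0
        basis.append((zeros, m, zeros))
    # S: 8 free elements; S33 = -S11 - S22 keeps the trace zero
    for i, j in [(0, 0), (1, 1), (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]:
        m = np.zeros((3, 3))
        m[i, j] = 1.0
        if i == j:
            m[2, 2] = -1.0
        basis.append((zeros, zeros, m))
    _ = eye
    return basis


def fit_tls(
    group: AtomGroup,
    origin: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit T, L, S to the group's observed ADPs by linear least squares.

    Parameters
    ----------
    group
        Must carry ``u_obs``; needs >= 5 atoms in non-degenerate geometry
        (collinear atoms make libration about the line unobservable).
    origin
        TLS origin; defaults to the group centroid.
    weights
        Optional per-atom weights (plain unweighted LSQ by default).

    Returns
    -------
    FitResult
        Fitted matrices (trace-free S), RMS residual and design rank.
        The residual is zero (to rounding) iff the observed ADPs are
        exactly TLS-generated.
    """
    if group.u_obs is None:
        raise InvalidInputError("group carries no observed ADPs (u_obs)")
    n = len(group)
    if n < 5:
        raise InvalidInputError(f"need at least 5 atoms to fit 20 parameters, got {n}")
    origin = group.centroid if origin is None else np.asarray(origin, dtype=float)

    basis = _basis_matrices()
    design = np.empty((6 * n, len(basis)))
    for col, (t_m, l_m, s_m) in enumerate(basis):
        u = adp_from_matrices(
            TLSMatrices(t_m, l_m, s_m, origin), group).as_array()
        design[:, col] = u[:, [ij[0] for ij in _IJ], [ij[1] for ij in _IJ]].ravel()

    target = group.u_obs.as_array()
    rhs = target[:, [ij[0] for ij in _IJ], [ij[1] for ij in _IJ]].ravel()

    if weights is not None:
        w = np.repeat(np.sqrt(np.asarray(weights, dtype=float)), 6)
        design = design * w[:, None]
        rhs = rhs * w

    rank = np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max()))
    if rank < len(basis):
        raise DegenerateGeometryError(
            f"design rank {rank} < 20: degenerate atom geometry (collinear or "
            "near-collinear atoms leave librations unobservable)")

    coef, _, _, _ = np.linalg.lstsq(design, rhs, rcond=None)
    T = sum(c * b[0] for c, b in zip(coef, basis))
    L = sum(c * b[1] for c, b in zip(coef, basis))
    S = sum(c * b[2] for c, b in zip(coef, basis))
    tls = TLSMatrices(T, L, S, origin)
    misfit = adp_from_matrices(tls, group).as_array() - target
    residual = float(np.sqrt(np.mean(
        misfit[:, [ij[0] for ij in _IJ], [ij[1] for ij in _IJ]] ** 2)))
    return FitResult(tls=tls, residual=residual, rank=int(rank))
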