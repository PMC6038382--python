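"""Rigid-group (TLS) motion model: containers and analytic per-atom ADPs.

Harmonic motion of a rigid atomic group is conventionally collected into
three matrices: ``T`` (A^2, net vibration), ``L`` (rad^2, libration) and
``S`` (A.rad, screw/vibration-libration correlation), defined with respect
to a group origin.  The same motion can be written directly in terms of
*elemental motions*: three independent screw librations about mutually
orthogonal axes plus three independent vibrations along an orthonormal
triplet of directions.

Two equivalent routes from a motion description to per-atom anisotropic
displacement parameters (ADPs, symmetric 3x3 matrices U in A^2) are
implemented:

* the matrix route, ``U_n = T + A_n L A_n^t + A_n S + S^t A_n^t`` with
  ``A_n`` the antisymmetric matrix built from the atom position relative to
  the group origin (:func:`adp_from_matrices`);
* the direct route, summing rank-one contributions of each elemental
  motion (:func:`adp_from_motions`).

The two agree to rounding error; tests rely on that identity.  A scalar
sigma added to the diagonal of ``S`` never changes any ADP (the sigma
gauge); choosing it is the business of :mod:`tlsvalid.decompose`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "AtomGroup",
    "ADPSet",
    "TLSMatrices",
    "ElementalMotions",
    "antisym_matrix",
    "adp_from_matrices",
    "matrices_from_motions",
    "adp_from_motions",
    "InvalidInputError",
]

#: libration RMS amplitude (rad) beyond which finite rotations are visibly
#: anharmonic and the linearized TLS picture degrades
HARMONIC_LIMIT = 0.15

_SYM_TOL = 1e-10
_AXIS_TOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when a value passed to the motion model is malformed."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise InvalidInputError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return v


def _as_mat3(x, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.shape != (3, 3):
        raise InvalidInputError(f"{name} must be 3x3, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return m


def _check_symmetric(m: np.ndarray, name: str) -> None:
    scale = 1.0 + np.abs(m).max()
    if np.abs(m - m.T).max() > _SYM_TOL * scale:
        raise InvalidInputError(f"{name} is not symmetric within tolerance")


@dataclass
class TLSMatrices:
    """TLS matrices ``T`` (A^2), ``L`` (rad^2), ``S`` (A.rad) plus origin (A).

    ``T`` and ``L`` must be symmetric; ``S`` is general.  Internal units are
    always A^2 / rad^2 / A.rad — conversion from the deposition units used in
    PDB headers (deg^2, A.deg) happens at the I/O boundary
    (:func:`tlsvalid.pdb_io.to_internal_units`).
    """

    T: np.ndarray
    L: np.ndarray
    S: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.T = _as_mat3(self.T, "T")
        self.L = _as_mat3(self.L, "L")
        self.S = _as_mat3(self.S, "S")
        self.origin = _as_vec3(self.origin, "origin")
        _check_symmetric(self.T, "T")
        _check_symmetric(self.L, "L")
        # exact symmetry internally; kills accumulated rounding
        self.T = 0.5 * (self.T + self.T.T)
        self.L = 0.5 * (self.L + self.L.T)

    def shifted_sigma(self, sigma: float) -> "TLSMatrices":
        """Return a copy with ``sigma`` added to the diagonal of ``S``.

        This is the gauge transformation: it changes no ADP.
        """
        return TLSMatrices(self.T, self.L, self.S + sigma * np.eye(3), self.origin)

    def is_zero(self, tol: float = 0.0) -> bool:
        return (
            np.abs(self.T).max() <= tol
            and np.abs(self.L).max() <= tol
            and np.abs(self.S).max() <= tol
        )


@dataclass
class Atom:
    """One atom record: identity plus Cartesian coordinates in A."""

    serial: int
    element: str
    chain: str
    resseq: int
    name: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = _as_vec3(self.xyz, "xyz")


@dataclass
class ADPSet:
    """Ordered per-atom symmetric 3x3 displacement matrices U (A^2)."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[1:] != (3, 3):
            raise InvalidInputError(f"u must have shape (N, 3, 3), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise InvalidInputError("ADPs contain non-finite values")
        scale = 1.0 + np.abs(self.u).max()
        if np.abs(self.u - self.u.transpose(0, 2, 1)).max() > _SYM_TOL * scale:
            raise InvalidInputError("ADP matrices must be symmetric")

    def __len__(self) -> int:
        return self.u.shape[0]

    def as_array(self) -> np.ndarray:
        return self.u


@dataclass
class AtomGroup:
    """An ordered atomic group, optionally carrying observed ADPs."""

    atoms: List[Atom]
    u_obs: Optional[ADPSet] = None

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise InvalidInputError("AtomGroup needs at least one atom")
        if self.u_obs is not None and len(self.u_obs) != len(self.atoms):
            raise InvalidInputError(
                "u_obs must hold one U matrix per atom in the same order"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Coordinates as an (N, 3) array (A)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @classmethod
    def from_coords(
        cls,
        coords: Sequence,
        element: str = "C",
        chain: str = "A",
        name: str = "CA",
        u_obs: Optional[ADPSet] = None,
    ) -> "AtomGroup":
        """Build a bare group from an (N, 3) coordinate array."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        atoms = [
            Atom(i + 1, element, chain, i + 1, name, c) for i, c in enumerate(coords)
        ]
        return cls(atoms, u_obs=u_obs)

    def with_coords(self, coords: np.ndarray) -> "AtomGroup":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            Atom(a.serial, a.element, a.chain, a.resseq, a.name, c)
            for a, c in zip(self.atoms, coords)
        ]
        return AtomGroup(atoms)


def _check_orthonormal(axes: np.ndarray, name: str) -> None:
    g = axes @ axes.T
    if np.abs(g - np.eye(3)).max() > _AXIS_TOL:
        raise InvalidInputError(f"{name} rows must be orthonormal within {_AXIS_TOL}")


@dataclass
class ElementalMotions:
    """Direct parameterization of rigid-group motion.

    Three screw librations (RMS amplitude ``d[k]`` in rad about unit axis
    ``l_axes[k]`` passing through the lab-frame point ``w_points[k]``, with
    screw pitch ``s[k]`` in A per rad) plus three vibrations (RMS amplitude
    ``t[j]`` in A along unit direction ``v_axes[j]``).  ``origin`` is the
    reference point the equivalent TLS matrices are expressed about.

    Axis rows of ``l_axes`` must be mutually orthogonal unit vectors;
    ``v_axes`` rows must be orthonormal.  Amplitudes are non-negative.  A
    screw pitch is only meaningful where the corresponding libration
    amplitude is positive; pitches on zero-amplitude axes are stored as 0 and
    noted in :attr:`flags`.
    """

    d: np.ndarray
    l_axes: np.ndarray
    w_points: np.ndarray
    s: np.ndarray
    t: np.ndarray
    v_axes: np.ndarray
    origin: np.ndarray
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float).reshape(3)
        self.s = np.asarray(self.s, dtype=float).reshape(3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        self.l_axes = _as_mat3(self.l_axes, "l_axes")
        self.v_axes = _as_mat3(self.v_axes, "v_axes")
        self.w_points = _as_mat3(self.w_points, "w_points")
        self.origin = _as_vec3(self.origin, "origin")
        for v, nm in ((self.d, "d"), (self.s, "s"), (self.t, "t")):
            if not np.all(np.isfinite(v)):
                raise InvalidInputError(f"{nm} contains non-finite values")
        if np.any(self.d < 0) or np.any(self.t < 0):
            raise InvalidInputError("amplitudes d and t must be non-negative")
        _check_orthonormal(self.l_axes, "l_axes")
        _check_orthonormal(self.v_axes, "v_axes")
        undefined = (self.d == 0) & (self.s != 0)
        if np.any(undefined):
            self.s = np.where(self.d == 0, 0.0, self.s)
            for k in np.nonzero(undefined)[0]:
                self.flags.append(
                    f"screw pitch on axis {k} undefined (zero libration); set to 0"
                )

    @property
    def lam(self) -> np.ndarray:
        """Libration variances d_k^2 (rad^2) — eigenvalues of the L matrix."""
        return self.d**2

    @property
    def screw_defined(self) -> np.ndarray:
        return self.d > 0

    def copy(self) -> "ElementalMotions":
        return ElementalMotions(
            self.d.copy(),
            self.l_axes.copy(),
            self.w_points.copy(),
            self.s.copy(),
            self.t.copy(),
            self.v_axes.copy(),
            self.origin.copy(),
            list(self.flags),
        )

    # -- [L]-basis representation of the axis points ----------------------
    def w_in_l_basis(self) -> np.ndarray:
        """Axis points expressed in the [L] basis relative to the origin.

        Row k holds the coordinates of ``w_points[k] - origin`` along
        ``l_axes``; the component along the axis itself is irrelevant to the
        motion (the screw pitch carries it) but is preserved here.
        """
        return (self.w_points - self.origin) @ self.l_axes.T

    @staticmethod
    def w_from_l_basis(
        w_l: np.ndarray, l_axes: np.ndarray, origin: np.ndarray
    ) -> np.ndarray:
        """Inverse of :meth:`w_in_l_basis` (rows of ``w_l`` in [L] coords)."""
        return np.asarray(origin, float) + np.asarray(w_l, float) @ np.asarray(
            l_axes, float
        )


def antisym_matrix(r, origin) -> np.ndarray:
    """Antisymmetric matrix A built from ``p = r - origin``.

    Convention: ``A = [[0, pz, -py], [-pz, 0, px], [py, -px, 0]]``, so that
    ``A q = q x p`` for any vector q.  This is the matrix appearing in the
    matrix route to ADPs; its sign is pinned by requiring that analytic and
    ensemble-sampled ADPs of a screw libration agree.
    """
    p = _as_vec3(r, "r") - _as_vec3(origin, "origin")
    return np.array(
        [
            [0.0, p[2], -p[1]],
            [-p[2], 0.0, p[0]],
            [p[1], -p[0], 0.0],
        ]
    )


def adp_from_matrices(tls: TLSMatrices, group: AtomGroup) -> ADPSet:
    """Per-atom ADPs from TLS matrices (the matrix route).

    ``U_n = T + A_n L A_n^t + A_n S + S^t A_n^t`` with ``A_n`` from
    :func:`antisym_matrix`.  Invariant under ``S -> S + c I`` because ``A``
    is antisymmetric (``A c I + c I A^t = c(A + A^t) = 0``).
    """
    p = group.coords - tls.origin  # (N, 3)
    n = p.shape[0]
    A = np.zeros((n, 3, 3))
    A[:, 0, 1] = p[:, 2]
    A[:, 0, 2] = -p[:, 1]
    A[:, 1, 0] = -p[:, 2]
    A[:, 1, 2] = p[:, 0]
    A[:, 2, 0] = p[:, 1]
    A[:, 2, 1] = -p[:, 0]
    ALAt = np.einsum("nij,jk,nlk->nil", A, tls.L, A)
    AS = np.einsum("nij,jk->nik", A, tls.S)
    u = tls.T[None, :, :] + ALAt + AS + AS.transpose(0, 2, 1)
    u = 0.5 * (u + u.transpose(0, 2, 1))
    return ADPSet(u)


def _screw_translation_vectors(m: ElementalMotions) -> np.ndarray:
    """Lab-frame translation of a unit rotation about each libration axis.

    Row k is ``a_k = s_k l_k + (w_k - origin) x l_k``: rotating the group by
    one radian about axis k displaces it by ``a_k`` (to first order) relative
    to rotation about a parallel axis through the origin, plus the screw
    advance.  These vectors are what the rows of S and the libration part of
    T are made of.
    """
    rel = m.w_points - m.origin
    return m.s[:, None] * m.l_axes + np.cross(rel, m.l_axes)


def matrices_from_motions(m: ElementalMotions) -> TLSMatrices:
    """Compose TLS matrices from elemental motions (inverse of decomposition).

    With ``lam_k = d_k^2`` and ``a_k`` the unit-rotation translation vector
    of screw axis k:

    * ``L = sum_k lam_k l_k l_k^t``
    * ``S = sum_k lam_k l_k a_k^t``  (diagonal of S in the [L] basis is
      ``lam_k s_k``, i.e. the sigma gauge of the composition is 0)
    * ``T = sum_k lam_k a_k a_k^t + sum_j t_j^2 v_j v_j^t``

    Cross-libration correlations are zero by construction: the three
    librations are independent oscillators about the eigenaxes of L.
    """
    lam = m.lam
    a = _screw_translation_vectors(m)
    L = np.einsum("k,ki,kj->ij", lam, m.l_axes, m.l_axes)
    S = np.einsum("k,ki,kj->ij", lam, m.l_axes, a)
    T = np.einsum("k,ki,kj->ij", lam, a, a) + np.einsum(
        "j,ji,jk->ik", m.t**2, m.v_axes, m.v_axes
    )
    return TLSMatrices(T, L, S, m.origin)


def adp_from_motions(m: ElementalMotions, group: AtomGroup) -> ADPSet:
    """Per-atom ADPs straight from elemental motions (the direct route).

    ``U_n = sum_k d_k^2 b_k b_k^t + sum_j t_j^2 v_j v_j^t`` where
    ``b_k(r) = l_k x (r - w_k) + s_k l_k`` is the first-order displacement of
    an atom at ``r`` per radian of screw rotation about axis k.  Algebraically
    identical to ``adp_from_matrices(matrices_from_motions(m), group)``.
    """
    r = group.coords  # (N, 3)
    rel = r[:, None, :] - m.w_points[None, :, :]  # (N, 3axes, 3)
    b = np.cross(m.l_axes[None, :, :], rel) + (m.s[:, None] * m.l_axes)[None, :, :]
    u = np.einsum("k,nki,nkj->nij", m.lam, b, b)
    u = u + np.einsum("j,ji,jk->ik", m.t**2, m.v_axes, m.v_axes)[None, :, :]
    u = 0.5 * (u + u.transpose(0, 2, 1))
    return ADPSet(u)
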