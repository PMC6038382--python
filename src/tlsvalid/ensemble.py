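"""Explicit sampling of elemental motions into atomic ensembles.

An ensemble makes the statistical content of a TLS description concrete:
each model draws Gaussian amplitudes for the elemental motions, applies
the three *finite* rotations about their (possibly distant) axis points —
exact rotation matrices, not linearizations — advances along each axis by
the screw shift, and adds the vibrations.  Converting the ensemble back to
per-atom ADPs via positional second moments closes the loop, and the
residual disagreement with the analytic ADPs is the validation signal this
package measures.

Sampling convention — the heart of the method.  By default every elemental
component draws its *own* independent amplitude: three rotation angles
``theta_k ~ N(0, d_k^2)``, three axial screw shifts ``eta_k s_k l_k`` with
``eta_k ~ N(0, d_k^2)`` independent of ``theta_k``, and three vibration
shifts ``xi_j ~ N(0, t_j^2)``.  The ensemble covariance then reproduces
every term of the analytic ADP *except* the rotation-shift cross terms
that the off-gauge part of the S diagonal encodes.  That omission is
deliberate and is what gives the validation its teeth: a group whose
screw pitches are large (relative to the libration arms) shows a large,
ensemble-size-independent R_U, while minimizing |s| over the sigma gauge
minimizes exactly the unreproduced content.  With the textbook coupled
screw transform (``couple_screw=True``, shift ``theta_k s_k l_k``) the
ensemble converges to the analytic ADPs for *any* pitch at harmonic
amplitudes — useful for checking sign conventions and the harmonic limit,
useless for detecting pathological screws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .model import ADPSet, AtomGroup, ElementalMotions, InvalidInputError

__all__ = ["Ensemble", "generate_ensemble", "adp_from_ensemble", "DEFAULT_MODELS"]

#: default ensemble size; second moments stabilize at 5000-10000 models
DEFAULT_MODELS = 5000

SeedLike = Union[int, np.random.SeedSequence]


@dataclass
class Ensemble:
    """M coordinate replicas of a template group.

    ``coords`` has shape (M, N, 3); atom order matches the template.
    """

    coords: np.ndarray
    template: AtomGroup
    source_motions: ElementalMotions
    seed: SeedLike

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError(
                f"coords must have shape (M, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise InvalidInputError("an ensemble needs at least one model")
        if self.coords.shape[1] != len(self.template):
            raise InvalidInputError("model atom count differs from template")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_models


def _rng(seed: SeedLike) -> np.random.Generator:
    # counter-based generator: draws for model m occupy a fixed slice of the
    # stream, so growing M extends the ensemble without reshuffling it
    if isinstance(seed, np.random.SeedSequence):
        return np.random.Generator(np.random.Philox(seed))
    return np.random.Generator(np.random.Philox(key=int(seed)))


def generate_ensemble(
    m: ElementalMotions,
    group: AtomGroup,
    n_models: int = DEFAULT_MODELS,
    seed: SeedLike = 0,
    couple_screw: bool = False,
) -> Ensemble:
    """Sample ``n_models`` replicas of ``group`` under the given motions.

    The three screw rotations are applied in axis order x, y, z as finite
    rotations about their axis points (Rodrigues form), each advanced along
    its axis by the screw shift; vibrations are added afterwards.  Finite
    rotations do not commute, but within the harmonic regime the ordering
    effect is second order in the amplitudes, far below the sampling-noise
    floor.

    Parameters
    ----------
    couple_screw
        ``False`` (default): the axial shift of screw axis k is
        ``eta_k s_k l_k`` with an independent ``eta_k ~ N(0, d_k^2)`` — the
        validation convention (see module docstring).  ``True``: the exact
        rigid screw ``theta_k s_k l_k``, deterministically coupled to the
        rotation angle.

    Deterministic for a given seed; the first models of a longer run are
    bit-identical to a shorter run with the same seed.
    """
    if n_models < 1:
        raise InvalidInputError("n_models must be >= 1")
    draws = _rng(seed).standard_normal((n_models, 9))
    theta = draws[:, 0:3] * m.d            # rotation angles
    eta = theta if couple_screw else draws[:, 3:6] * m.d  # screw amplitudes
    xi = draws[:, 6:9] * m.t               # vibration shifts

    r = np.broadcast_to(group.coords, (n_models, len(group), 3)).copy()
    for k in range(3):
        if m.d[k] == 0.0:
            continue
        axis = m.l_axes[k]
        th = theta[:, k][:, None, None]
        p = r - m.w_points[k]
        cos_t, sin_t = np.cos(th), np.sin(th)
        along = np.einsum("mni,i->mn", p, axis)[:, :, None] * axis
        r = (m.w_points[k]
             + cos_t * p
             + sin_t * np.cross(axis, p)
             + (1.0 - cos_t) * along
             + (eta[:, k] * m.s[k])[:, None, None] * axis)
    r = r + (xi @ m.v_axes)[:, None, :]
    return Ensemble(r, group, m, seed)


def adp_from_ensemble(e: Ensemble, about: str = "mean") -> ADPSet:
    """Per-atom ADPs as second moments of the ensemble displacements.

    ``U_n = (1/M) sum_m (r_nm - ref_n)(r_nm - ref_n)^t`` with the reference
    either the per-atom ensemble mean (``about="mean"``, the proper
    covariance and the default) or the template position
    (``about="template"``).  For anharmonic librations the two differ: a
    finite rotation pulls the mean position off the template, and measuring
    about the template folds that offset into U.  Both conventions are kept
    for sensitivity checks; within the harmonic regime the difference is
    below the sampling-noise floor.
    """
    if e.n_models < 2:
        raise InvalidInputError("at least two models are needed for ADPs")
    if about == "mean":
        ref = e.coords.mean(axis=0)
    elif about == "template":
        ref = e.template.coords
    else:
        raise InvalidInputError(f"about must be 'mean' or 'template', got {about!r}")
    dx = e.coords - ref
    u = np.einsum("mni,mnj->nij", dx, dx) / e.n_models
    return ADPSet(0.5 * (u + u.transpose(0, 2, 1)))
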