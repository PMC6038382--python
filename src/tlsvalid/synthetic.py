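"""Synthetic fixtures: calibration scenarios and random valid motion sets.

Everything the test battery needs is generated here at run time: the
single-atom vibration and libration systems used to calibrate ensemble
sizes and the R_U noise floor, random elemental-motion sets guaranteed
decomposable by construction, and a helical pseudo-backbone whose geometry
keeps all three libration axes well conditioned.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .model import AtomGroup, ElementalMotions

__all__ = [
    "single_atom_vibration",
    "single_atom_libration",
    "random_valid_motions",
    "toy_chain",
]


def single_atom_vibration(t: float) -> Tuple[ElementalMotions, AtomGroup]:
    """One atom at the origin vibrating along x with RMS amplitude ``t`` (A).

    The analytic ADP is ``diag(t^2, 0, 0)``; comparing it with the ensemble
    estimate isolates pure sampling noise, since a Gaussian shift along a
    fixed axis is exactly harmonic at any amplitude.
    """
    if t < 0:
        raise ValueError("amplitude must be non-negative")
    m = ElementalMotions(
        d=np.zeros(3), l_axes=np.eye(3), w_points=np.zeros((3, 3)),
        s=np.zeros(3), t=np.array([t, 0.0, 0.0]), v_axes=np.eye(3),
        origin=np.zeros(3))
    return m, AtomGroup.from_coords([[0.0, 0.0, 0.0]])


def single_atom_libration(d: float, radius: float = 1.0
                          ) -> Tuple[ElementalMotions, AtomGroup]:
    """One atom at ``(radius, 0, 0)`` librating about z through the origin.

    RMS amplitude ``d`` is in rad; no screw, no vibration.  The linearized
    ADP is ``U_yy = d^2 radius^2`` and nothing else; the finite-rotation
    ensemble instead moves the atom on a circular arc, so the relative
    analytic-vs-ensemble discrepancy depends only on ``d`` (the radius
    scales both sets) and grows once ``d`` leaves the harmonic regime.
    The default radius of 1 A is arbitrary for exactly that reason.
    """
    if d < 0:
        raise ValueError("amplitude must be non-negative")
    m = ElementalMotions(
        d=np.array([0.0, 0.0, d]), l_axes=np.eye(3), w_points=np.zeros((3, 3)),
        s=np.zeros(3), t=np.zeros(3), v_axes=np.eye(3), origin=np.zeros(3))
    return m, AtomGroup.from_coords([[radius, 0.0, 0.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR with sign fixing."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def random_valid_motions(
    seed: int,
    d_max: float = 0.1,
    t_max: float = 0.5,
    s_max: float = 5.0,
    w_max: float = 10.0,
) -> ElementalMotions:
    """A random elemental-motion set that decomposes cleanly by construction.

    Amplitudes are drawn uniformly below the caps (librations within the
    harmonic regime by default, 0.1 rad) and kept strictly positive so all
    screw pitches are defined; axis points are offset perpendicular to their
    axes by up to ``w_max`` A.  Composing these motions and re-decomposing
    at any feasible gauge must succeed: the residual vibration matrix at the
    composing gauge is the PSD vibration term itself.
    """
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    rot_l = _random_rotation(rng)
    rot_v = _random_rotation(rng)
    d = rng.uniform(0.2 * d_max, d_max, size=3)
    t = rng.uniform(0.1 * t_max, t_max, size=3)
    s = rng.uniform(-s_max, s_max, size=3)
    origin = rng.uniform(-5.0, 5.0, size=3)
    l_axes = rot_l  # rows
    # perpendicular offsets: random vector minus its along-axis component
    raw = rng.uniform(-w_max, w_max, size=(3, 3))
    perp = raw - (np.einsum("ki,ki->k", raw, l_axes)[:, None] * l_axes)
    return ElementalMotions(
        d=d, l_axes=l_axes, w_points=origin + perp, s=s,
        t=np.sort(t), v_axes=rot_v, origin=origin)


def toy_chain(n_atoms: int = 56, seed: int = 0, rise: float = 1.5,
              turn_deg: float = 100.0, radius: float = 2.3) -> AtomGroup:
    """Helical pseudo-backbone of ``n_atoms`` points.

    Roughly one point per residue of an alpha-helical trace (1.5 A rise,
    ~100 deg turn, 2.3 A radius), jittered by a small seeded perturbation so
    no accidental symmetry degenerates the libration axes.  56 points
    matches a typical single-domain C-alpha group.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    i = np.arange(n_atoms)
    phi = np.deg2rad(turn_deg) * i
    coords = np.column_stack([
        radius * np.cos(phi), radius * np.sin(phi), rise * i])
    coords = coords - coords.mean(axis=0)
    coords = coords + 0.05 * rng.standard_normal(coords.shape)
    return AtomGroup.from_coords(coords)
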