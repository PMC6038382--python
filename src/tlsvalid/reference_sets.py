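"""Published elemental-motion parameter sets for two deposited structures.

These are the rigid-group analyses of PDB entry 2igd (IgG-binding domain
III core, residues 6-61, as a C-alpha-only group ``2igd_ca`` and a
main-chain group ``2igd_mc``) and of TLS group 6 of PDB entry 4muy
(residues 65-77, chain A), each decomposed under two sigma gauges: the
feasibility-constrained trace gauge (``t_min``) and the screw-pitch
minimizing gauge (``s_min``).  The 4muy group is the canonical pathology:
at the ``t_min`` gauge its weakest libration (d = 0.001 rad) carries a
screw pitch of 303.63 A/rad, while the ``s_min`` gauge shrinks that pitch
to order 0.1 by moving sigma.

Amplitudes are in rad (d) and A (t); screw pitches in A/rad.  Libration
and vibration axes are printed to three decimals in the tables these sets
come from, so they are re-orthonormalized here (closest rotation in the
Frobenius sense); axis points are printed in the [L] basis relative to the
group centre of mass, which is taken as the origin.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .model import ElementalMotions

__all__ = ["reference_motions", "REFERENCE_ENTRIES", "REFERENCE_STRATEGIES"]

REFERENCE_ENTRIES = ("2igd_ca", "2igd_mc", "4muy_group6")
REFERENCE_STRATEGIES = ("t_min", "s_min")

# entry -> strategy -> raw printed values
_TABLES: Dict[str, Dict[str, dict]] = {
    "2igd_ca": {
        "t_min": {
            "t": [0.163, 0.278, 0.304],
            "v": [[-0.085, 0.437, 0.896],
                  [0.905, 0.410, -0.114],
                  [-0.417, 0.801, -0.430]],
            "d": [0.011, 0.019, 0.027],
            "l": [[-0.262, 0.915, -0.308],
                  [-0.067, 0.301, 0.951],
                  [0.963, 0.270, -0.017]],
            "w": [[-12.67, -0.39, 16.71],
                  [1.65, 0.97, 8.55],
                  [-4.67, -3.47, 0.76]],
            "s": [-2.07, -0.88, 0.80],
        },
        "s_min": {
            "t": [0.163, 0.279, 0.305],
            "v": [[-0.085, 0.433, 0.897],
                  [0.902, 0.417, -0.116],
                  [-0.424, 0.799, -0.426]],
            "d": [0.011, 0.019, 0.027],
            "l": [[-0.262, 0.915, -0.308],
                  [-0.067, 0.301, 0.951],
                  [0.963, 0.270, -0.017]],
            "w": [[-12.67, -0.39, 16.71],
                  [1.65, 0.97, 8.55],
                  [-4.67, -3.47, 0.76]],
            "s": [-0.09, -0.30, 1.12],
        },
    },
    "2igd_mc": {
        "t_min": {
            "t": [0.089, 0.277, 0.314],
            "v": [[-0.082, 0.334, 0.939],
                  [0.948, 0.316, -0.030],
                  [-0.306, 0.888, -0.343]],
            "d": [0.010, 0.020, 0.027],
            "l": [[-0.272, 0.943, -0.193],
                  [-0.113, 0.168, 0.979],
                  [0.956, 0.288, 0.061]],
            "w": [[-14.16, -1.74, 22.42],
                  [0.49, 0.11, 11.77],
                  [-4.92, -3.54, -0.25]],
            "s": [-5.70, -0.24, 0.89],
        },
        "s_min": {
            "t": [0.083, 0.282, 0.314],
            "v": [[-0.078, 0.332, 0.940],
                  [0.931, 0.362, -0.051],
                  [-0.357, 0.871, -0.337]],
            "d": [0.010, 0.020, 0.027],
            "l": [[-0.272, 0.943, -0.193],
                  [-0.113, 0.168, 0.979],
                  [0.956, 0.288, 0.061]],
            "w": [[-14.16, -1.74, 22.42],
                  [0.49, 0.11, 11.77],
                  [-4.92, -3.54, -0.25]],
            "s": [-0.43, 0.97, 1.58],
        },
    },
    "4muy_group6": {
        "t_min": {
            "t": [0.0, 0.257, 0.363],
            "v": [[0.951, 0.286, -0.117],
                  [-0.220, 0.893, 0.393],
                  [0.216, -0.348, 0.912]],
            "d": [0.001, 0.008, 0.014],
            "l": [[0.649, 0.500, -0.573],
                  [-0.633, 0.773, -0.042],
                  [0.421, 0.390, 0.819]],
            "w": [[-219.91, -11.67, -256.03],
                  [-49.29, 57.65, -1.63],
                  [-72.36, -52.48, -124.89]],
            "s": [303.63, 2.90, -3.11],
        },
        "s_min": {
            "t": [0.241, 0.321, 0.396],
            "v": [[0.227, 0.947, 0.225],
                  [-0.582, -0.053, 0.811],
                  [0.780, -0.316, 0.540]],
            "d": [0.001, 0.008, 0.014],
            "l": [[0.649, 0.500, -0.573],
                  [-0.633, 0.773, -0.042],
                  [0.421, 0.390, 0.819]],
            "w": [[-219.91, -11.67, -256.03],
                  [-49.29, 57.65, -1.63],
                  [-72.36, -52.48, -124.89]],
            "s": [0.11, -3.38, -5.14],
        },
    },
}


def _closest_rotation(rows: np.ndarray) -> np.ndarray:
    """Orthonormalize printed (3-decimal) axis rows: nearest orthogonal
    matrix in the Frobenius sense, preserving the printed sign structure."""
    u, _, vt = np.linalg.svd(np.asarray(rows, dtype=float))
    return u @ vt


def reference_motions(entry: str, strategy: str = "t_min") -> ElementalMotions:
    """Elemental motions of a published reference set.

    Parameters
    ----------
    entry
        One of ``2igd_ca``, ``2igd_mc``, ``4muy_group6``.
    strategy
        ``t_min`` or ``s_min`` — which published gauge the set was
        decomposed under.
    """
    try:
        raw = _TABLES[entry][strategy]
    except KeyError:
        raise KeyError(
            f"unknown reference set {entry!r}/{strategy!r}; entries: "
            f"{REFERENCE_ENTRIES}, strategies: {REFERENCE_STRATEGIES}") from None
    l_axes = _closest_rotation(np.array(raw["l"]))
    v_axes = _closest_rotation(np.array(raw["v"]))
    origin = np.zeros(3)  # group centre of mass, the frame the axes refer to
    w_points = ElementalMotions.w_from_l_basis(np.array(raw["w"]), l_axes, origin)
    return ElementalMotions(
        d=np.array(raw["d"]), l_axes=l_axes, w_points=w_points,
        s=np.array(raw["s"]), t=np.array(raw["t"]), v_axes=v_axes,
        origin=origin)
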