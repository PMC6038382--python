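"""Single-atom calibration experiments.

Two numerical experiments pin down how many ensemble models are needed and
what R_U noise floor to expect.

*Vibration*: one atom with a Gaussian shift along x.  The motion is exactly
harmonic, so the entire R_U is sampling noise; it falls off as M^(-1/2) and
reaches ~0.01 around M = 10^4 models.

*Libration*: one atom on a 1 A arm rotating about z.  Below the harmonic
limit (~0.15 rad RMS) the mean R_U at M = 5000 sits on a plateau of ~0.02;
beyond it the finite-rotation curvature makes the analytic (linearized)
ADP systematically wrong and R_U climbs monotonically.  The R_U <= 0.05
acceptance threshold used by the validation battery comes from this
plateau plus headroom.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .ensemble import adp_from_ensemble, generate_ensemble
from .metrics import r_u
from .model import adp_from_motions
from .synthetic import single_atom_libration, single_atom_vibration

__all__ = ["vibration_convergence", "libration_scan"]


def _trial_seed(root: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(root), spawn_key=tuple(key))


def vibration_convergence(
    n_models_list: Sequence[int] = (100, 1000, 10_000),
    n_trials: int = 100,
    amplitude_range=(0.1, 0.5),
    seed: int = 0,
) -> Dict[int, float]:
    """Mean R_U of the single-atom vibration versus ensemble size.

    Each trial draws its RMS amplitude uniformly from ``amplitude_range``
    (the result is amplitude independent: both the ADP and its sampling
    noise scale as t^2) and its own random seed.  Returns
    ``{n_models: mean R_U over trials}``.
    """
    out: Dict[int, float] = {}
    for i_m, n_models in enumerate(n_models_list):
        vals = np.empty(n_trials)
        for trial in range(n_trials):
            ss = _trial_seed(seed, i_m, trial)
            t = float(np.random.Generator(np.random.Philox(ss)).uniform(
                *amplitude_range))
            m, group = single_atom_vibration(t)
            u_tls = adp_from_motions(m, group)
            ens = generate_ensemble(m, group, n_models,
                                    _trial_seed(seed, i_m, trial, 1))
            vals[trial] = r_u(u_tls, adp_from_ensemble(ens))
        out[int(n_models)] = float(vals.mean())
    return out


def libration_scan(
    d_values: Sequence[float] = (0.02, 0.05, 0.10, 0.15),
    n_models: int = 5000,
    n_seeds: int = 20,
    radius: float = 1.0,
    seed: int = 0,
) -> Dict[float, float]:
    """Mean R_U of the single-atom pure libration versus RMS amplitude.

    Returns ``{d: mean R_U over n_seeds}`` at fixed ensemble size.
    """
    out: Dict[float, float] = {}
    for i_d, d in enumerate(d_values):
        m, group = single_atom_libration(float(d), radius=radius)
        u_tls = adp_from_motions(m, group)
        vals = np.empty(n_seeds)
        for trial in range(n_seeds):
            ens = generate_ensemble(m, group, n_models,
                                    _trial_seed(seed, i_d, trial))
            vals[trial] = r_u(u_tls, adp_from_ensemble(ens))
        out[float(d)] = float(vals.mean())
    return out
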