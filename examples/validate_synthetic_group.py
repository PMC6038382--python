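"""Validate two synthetic TLS groups: a healthy one and a screw pathology.

The validation battery compares analytic against ensemble-sampled ADPs for
the full motion and for each diagnostic subset.  The planted failure — a
tiny libration about a distant axis carrying a 300 A/rad screw pitch —
fails exactly on its screw subset while the pure rotation stays healthy.
"""

import numpy as np

from tlsvalid import ElementalMotions, matrices_from_motions, validate_group
from tlsvalid.synthetic import random_valid_motions, toy_chain

group = toy_chain(20, seed=1)

healthy = random_valid_motions(1, s_max=0.1, w_max=1.0)
plant = ElementalMotions(
    d=[0.001, 0.05, 0.08], l_axes=np.eye(3),
    w_points=[[0.0, 150.0, 150.0], [0, 0, 0], [0, 0, 0]],
    s=[300.0, 0.0, 0.0], t=[0.3, 0.4, 0.5], v_axes=np.eye(3),
    origin=np.zeros(3))

for label, motions, strategy in [("healthy group", healthy, "s_min"),
                                 ("screw pathology (trace gauge)", plant, "trace"),
                                 ("screw pathology (s_min gauge)", plant, "s_min")]:
    rep = validate_group(matrices_from_motions(motions), group,
                         strategy=strategy, n_models=10_000, seed=5)
    print(f"\n{label}: verdict = {rep.verdict.value} "
          f"(threshold R_U <= {rep.threshold})")
    for s in rep.subsets:
        print(f"  {s.subset.value:18s} R_U = {s.r_u:.3f}  "
              f"{'pass' if s.passed else 'FAIL'}")

print("\nThe s_min gauge absorbs the pathological pitch into sigma (no ADP")
print("changes), so the same deposited matrices validate cleanly.")
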