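"""Decompose a deposited-style TLS group under the three sigma gauges.

Builds a REMARK 3 header from the published motion set of PDB entry 4muy,
TLS group 6 (the canonical screw pathology), parses it back and compares
the screw pitches extracted under each gauge choice.
"""

import numpy as np

from tlsvalid import decompose, matrices_from_motions, reference_motions
from tlsvalid.pdb_io import from_internal_units, parse_tls_records, \
    to_internal_units, write_tls_records

# compose TLS matrices from the published elemental motions and round-trip
# them through a REFMAC-style REMARK 3 header (deposition units)
from tlsvalid.pdb_io import ResidueRange

tls = matrices_from_motions(reference_motions("4muy_group6", "t_min"))
rec_out = from_internal_units(tls, group_id=6,
                              ranges=[ResidueRange("A", 65, 77)])
text = write_tls_records([rec_out])
rec = parse_tls_records(text)[0]
tls_back = to_internal_units(rec)

print("deposited-style header round trip: group", rec.group_id,
      "flags:", rec.flags or "none")
for label, kwargs in [("composing gauge (sigma=0)", {"sigma_override": 0.0}),
                      ("trace gauge", {"strategy": "trace"}),
                      ("|s|-minimizing gauge", {"strategy": "s_min"})]:
    res = decompose(tls_back, **kwargs)
    with np.printoptions(precision=2, suppress=True):
        print(f"{label:28s} sigma={res.sigma * 1e5:7.1f}e-5 A.rad   "
              f"s = {res.motions.s} A/rad")
print("\nThe 0.001 rad libration carries a ~300 A/rad screw pitch at the")
print("deposited gauge; moving sigma by a few tens of 1e-5 A.rad (which")
print("changes no ADP) collapses it to ~0.05 A/rad.")
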