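"""Per-residue descriptors: pLDDT, SASA and relative accessibility.

Builds a small synthetic chain, runs Shrake-Rupley SASA, normalizes by the
Tien max-ASA scale and classifies burial at the 0.7 rASA threshold.
"""

import numpy as np

from afmissense import simulate_structure
from afmissense.sasa import annotate_model

model = simulate_structure(15, plddt_profile=list(np.linspace(35, 95, 15).round(1)))
table = annotate_model(model)
print(table.to_string(index=False, float_format=lambda v: f"{v:7.2f}"))
n_buried = (table["burial"] == "less_accessible").sum()
print(f"\n{n_buried}/{len(table)} positions fall below the 0.7 rASA burial threshold")
# sasa is the residue's solvent-accessible surface in A^2; rasa divides it by
# the amino acid's reference maximum, so values near 1 are fully exposed.
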