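"""Load per-tool ddG tables and harmonize their sign conventions.

Writes two tiny predictor exports (mCSM and MAESTRO), loads them, and shows
that MAESTRO's scores are negated onto the unified convention
(positive = stabilizing, negative = destabilizing) while mCSM passes through.
"""

import tempfile
from pathlib import Path

from afmissense import load_ddg_table

with tempfile.TemporaryDirectory() as tmp:
    mcsm = Path(tmp) / "mcsm.csv"
    mcsm.write_text("uniprot,mutation,ddg\nP04637,R175H,-1.8\nP04637,P72R,0.3\n")
    maestro = Path(tmp) / "maestro.csv"
    maestro.write_text("uniprot,mutation,score\nP04637,R175H,1.1\nP04637,P72R,NA\n")

    for name, path in (("mcsm", mcsm), ("maestro", maestro)):
        preds, skipped = load_ddg_table(path, name)
        for p in preds:
            print(f"{name:8s} {p.wildtype_aa}{p.position}{p.mutant_aa}: "
                  f"raw {p.raw_value:+.2f} -> harmonized {p.harmonized_value:+.2f}")
        for s in skipped:
            print(f"{name:8s} row {s.row} skipped ({s.reason})")
# MAESTRO natively reports negative = stabilizing, so its +1.1 (destabilizing)
# becomes -1.1 under the unified convention; mCSM values are unchanged; the
# NA row is reported, never silently dropped.
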