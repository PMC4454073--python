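"""Motif-window extraction, class assignment and the residue-level rules.

Shows the fine-grained layer under the family classifiers: the five
isofunctional motif classes, extraction of a catalytic window by profile
alignment, consensus rebuilding from a window stack, and the Rab
substrate-compatibility rule.

Run:  python examples/02_motifs_and_rules.py
"""

import numpy as np

from ampyscan.motifs import (
    assign_motif_class,
    consensus_motif,
    extract_motif_window,
    shipped_classes,
)
from ampyscan.phmm import build_profile
from ampyscan.rules import rab_compatibility, synthetic_rab1b_reference
from ampyscan.seqio import AMINO_ACIDS, Alignment, SequenceRecord

# 1. The five shipped motif classes
print("shipped motif classes:")
for cls in shipped_classes():
    print(f"  {cls.name:12s} {cls.to_string():22s} {cls.clade_note}")

# 2. Extract the catalytic window of a query by profile alignment:
#    embed the canonical Fic window in random flanks, build a tiny family
#    profile, align, read the window off the anchor column
window = "HPFLEGNGRATR"
rng = np.random.default_rng(0)
row = "".join(rng.choice(list(AMINO_ACIDS), 40)) + window + "".join(
    rng.choice(list(AMINO_ACIDS), 40)
)
profile = build_profile(Alignment(ids=["a", "b", "c"], rows=[row] * 3), name="fic")
anchor = profile.match_state_for_reference_position(41)  # the His column
extracted, start = extract_motif_window(SequenceRecord("query", row), profile, anchor)
assignment = assign_motif_class(extracted, seq_id="query", start=start)
print(f"\nextracted window {extracted} at position {start} "
      f"-> class {assignment.class_name}")

# 3. Rebuild a consensus pattern from a stack of observed windows
windows = [window] * 6 + ["HPFLDGNGRATR"] * 4  # E/D split at position 5
pattern, _ = consensus_motif(windows)
print(f"consensus of {len(windows)} windows: {pattern}")

# 4. Rab substrate compatibility: Tyr77 plus a net-positive 53-58 stretch
ref = synthetic_rab1b_reference()
mutant = SequenceRecord("rab_F77", ref.residues[:76] + "F" + ref.residues[77:])
for query in (SequenceRecord("rab_ok", ref.residues), mutant):
    verdict = rab_compatibility(query, ref)
    ev = verdict.evidence
    print(f"{query.id}: {verdict.verdict} "
          f"(residue77 {ev['residue_at_77']}, stretch {ev['stretch_53_58']} "
          f"charge {ev['net_charge']:+d})")
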