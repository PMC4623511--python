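"""Design a pre-miRNA hairpin and judge it with the discovery criteria.

Builds a 21-nt mature miRNA on one arm of a designed stem-loop, folds the
precursor, derives the miRNA* (duplex partner with 2-nt 3' overhangs), and
prints the criteria a Mireap-style screen applies: duplex pairs and
mismatches, bulge, asymmetry, MFE, MFEI and A+U content.
"""

import numpy as np

from saltmir import evaluate_candidate
from saltmir.discovery import CandidateWindow
from saltmir.synthetic_data import design_hairpin

rng = np.random.default_rng(42)
rec, mature_iv, star_iv, arm = design_hairpin(
    mature_len=21, duplex_mismatches=1, loop_len=10, rng=rng, name="example"
)

window = CandidateWindow(
    chrom="example", start=0, end=len(rec.sequence), strand="+",
    sequence=rec.sequence, tag_offset=mature_iv[0], tag_len=21, tag_id="example",
)
cand = evaluate_candidate(window)

print(f"precursor ({len(rec.sequence)} nt): {rec.sequence}")
print(f"structure: {cand.fold.structure}")
print(f"mature [{mature_iv[0]}, {mature_iv[1]}) on the {arm} arm: {cand.mature_seq}")
print(f"star    [{star_iv[0]}, {star_iv[1]}): {cand.star_seq}")
print(f"duplex: {cand.paired_bp} bp, {cand.duplex_mismatches} mismatches, "
      f"bulge {cand.largest_bulge}, asymmetry {cand.asymmetry}")
print(f"MFE {cand.mfe:.2f} kcal/mol (must be <= -18), "
      f"MFEI {cand.mfei:.2f}, A+U {100 * cand.au_fraction:.1f}% (30-70%)")
print(f"verdict: {cand.verdict}")
# The verdict is ACCEPT only when every hairpin criterion holds at once.
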