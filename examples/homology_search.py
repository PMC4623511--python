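"""Find conserved miRNA hairpins in a transcriptome by homology.

A reference precursor is copied verbatim into a synthetic cDNA; the seeded
search finds it at full identity and re-validates the hairpin with the same
candidate criteria used for de novo discovery.
"""

import numpy as np

from saltmir import search_homologs
from saltmir.iofmt import SequenceRecord
from saltmir.synthetic_data import design_hairpin

rng = np.random.default_rng(3)
precursor, m_iv, s_iv, arm = design_hairpin(21, 0, 10, rng, name="osa-miR172a")

flank = "".join(rng.choice(list("ACGT"), size=150))
cdna = SequenceRecord(id="transcript_1", sequence=flank + precursor.sequence + flank)
decoy = SequenceRecord(id="transcript_2",
                       sequence="".join(rng.choice(list("ACGT"), size=500)))

hits = search_homologs([precursor], [cdna, decoy])
for h in hits:
    print(f"{h.query} -> {h.transcript}:{h.start}-{h.end}({h.strand}) "
          f"identity={h.identity:.2f} coverage={h.coverage:.2f} "
          f"validated={h.validated}")
# identity 1.0 with a validated hairpin marks an in-silico conserved miRNA;
# the decoy transcript yields no hit at the 90% identity / 90% coverage floor.
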