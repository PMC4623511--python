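"""Predict miRNA targets, map the slice site, and test GO enrichment.

A transcript carries a perfect complement of the miRNA: the duplex scores
expectation 0 and AGO-style cleavage is predicted between the target bases
paired to miRNA positions 10 and 11.  A small GO universe shows the
hypergeometric singular enrichment analysis (FDR < 0.05).
"""

import pandas as pd

from saltmir import scan_transcriptome, score_duplex, sea_enrichment
from saltmir.iofmt import SequenceRecord, revcomp

mirna = "TGACAGAAGAGAGTGAGCACA"            # 21 nt, written in DNA space
site = revcomp(mirna)
transcript = SequenceRecord(id="LOC_Os05g41010",
                            sequence="G" * 100 + site + "G" * 60)

expectation, alignment, inhibition, _ = score_duplex(mirna, site)
print(f"expectation {expectation} ({inhibition})")
print(alignment)

hits = scan_transcriptome({"oco-miR393a": mirna}, [transcript])
best = min(hits, key=lambda h: h.expectation)
print(f"\nsite {best.transcript}:{best.start}-{best.end}, "
      f"cleavage between transcript bases {best.cleavage_site - 1} and "
      f"{best.cleavage_site}")
# Those two bases pair miRNA positions 11 and 10 - the canonical slice site.

targets = ["LOC_Os05g41010", "LOC_Os02g53620", "LOC_Os04g43910"]
go_map = pd.DataFrame(
    [(g, "GO:0006950", "response to stress", "BP") for g in targets]
    + [(f"gene{i}", "GO:0008150", "biological process", "BP") for i in range(17)],
    columns=["gene", "term", "name", "ontology"])
background = targets + [f"gene{i}" for i in range(17)]
results = sea_enrichment(targets, background, go_map)
for r in results:
    print(f"{r.term} {r.name!r}: k={r.k}/{r.n}, K={r.K}/{r.N}, "
          f"p={r.pvalue:.3g}, FDR={r.fdr:.3g}, significant={r.significant}")
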