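from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_target_scan, hypergeom_sf_exact
from saltmir.config import TargetConfig
from saltmir.iofmt import SequenceRecord, revcomp
from saltmir.targets import (TargetError, predict_cleavage, scan_transcriptome,
                             score_duplex, sea_enrichment)

MIR = "TGACAGAAGAGAGTGAGCACA"   # 21 nt
SITE = revcomp(MIR)
CFG = TargetConfig()


def mutate_site(pos_from_5p, kind="mismatch"):
    """Mutate the target base paired to the given miRNA position."""
    w = list(SITE)
    idx = len(MIR) - pos_from_5p            # antiparallel pairing
    base = MIR[pos_from_5p - 1]
    if kind == "mismatch":
        w[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[base]
    else:                                    # G:U wobble
        assert base in "GT"
        w[idx] = "T" if base == "G" else "G"
    return "".join(w)


class TestScoreDuplex:
    def test_perfect_complement(self):
        e, aln, inh, cols = score_duplex(MIR, SITE)
        assert e == 0.0 and inh == "cleavage"
        assert len(cols) == 21

    def test_single_wobble_outside_seed(self):
        e, _, inh, _ = score_duplex(MIR, mutate_site(15, "wobble"))
        assert e == pytest.approx(0.5)
        assert inh == "cleavage"

    def test_single_mismatch_in_seed_doubled(self):
        e, _, _, _ = score_duplex(MIR, mutate_site(5))
        assert e == pytest.approx(2.0)

    def test_mismatch_outside_seed_not_doubled(self):
        e, _, _, _ = score_duplex(MIR, mutate_site(18))
        assert e == pytest.approx(1.0)

    def test_central_mismatch_switches_to_translation(self):
        e, _, inh, _ = score_duplex(MIR, mutate_site(10))
        assert inh == "translation"

    def test_monotone_in_edits(self):
        scores = [score_duplex(MIR, SITE)[0]]
        w = SITE
        for pos in (15, 16, 18):
            w = list(w)
            idx = len(MIR) - pos
            w[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[pos - 1]]
            w = "".join(w)
            scores.append(score_duplex(MIR, w)[0])
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_window_length_precondition(self):
        with pytest.raises(TargetError):
            score_duplex(MIR, SITE + "ACGTA")


class TestCleavage:
    def test_perfect_site_cut_between_bases_opposite_11_and_10(self):
        tx = SequenceRecord(id="t", sequence="G" * 100 + SITE + "G" * 60)
        hits = scan_transcriptome({"m": MIR}, [tx])
        exact = next(h for h in hits if (h.start, h.end) == (100, 121))
        # bases opposite miRNA 11 and 10 sit at transcript 110 and 111
        assert exact.cleavage_site == 111

    def test_target_bulge_5prime_of_site_shifts_cut(self):
        # extra target base in the region pairing the miRNA 3' half
        bulged = SITE[:5] + "A" + SITE[5:]    # bulge before the cut site
        tx = SequenceRecord(id="t", sequence="G" * 100 + bulged + "G" * 60)
        hits = scan_transcriptome({"m": MIR}, [tx])
        best = min((h for h in hits), key=lambda h: h.expectation)
        assert best.expectation == pytest.approx(2.0)   # one non-seed gap
        assert best.cleavage_site == 112                # shifted +1

    def test_translation_mode_has_no_cleavage_site(self):
        tx = SequenceRecord(id="t",
                            sequence="G" * 60 + mutate_site(10) + "G" * 60)
        hits = scan_transcriptome({"m": MIR}, [tx])
        central = [h for h in hits if h.inhibition == "translation"]
        assert central and all(h.cleavage_site is None for h in central)

    def test_cleavage_undefined_when_pos10_gapped(self):
        cols = [(i, 20 - (i - 1), "match") for i in range(1, 22) if i != 10]
        cols.insert(9, (10, None, "gap"))
        with pytest.raises(TargetError):
            predict_cleavage(cols, 0)


class TestScan:
    def test_planted_perfect_site_exact(self):
        tx = SequenceRecord(id="t", sequence="G" * 50 + SITE + "G" * 50)
        hits = scan_transcriptome({"m": MIR}, [tx])
        assert any(h.start == 50 and h.end == 71 and h.expectation == 0.0
                   for h in hits)

    def test_no_spurious_hits_in_random_sequence(self, rng):
        tx = SequenceRecord(
            id="t", sequence="".join(rng.choice(list("ACGT"), size=2000)))
        hits = scan_transcriptome({"m": MIR}, [tx])
        for h in hits:
            assert h.expectation <= CFG.expectation_cutoff

    def test_two_mirnas_one_transcript(self):
        mir2 = "GGCATCGATCGTAGCTAGCTA"
        tx = SequenceRecord(
            id="t",
            sequence="C" * 30 + SITE + "C" * 30 + revcomp(mir2) + "C" * 30)
        hits = scan_transcriptome({"m1": MIR, "m2": mir2}, [tx])
        assert {h.mirna for h in hits if h.expectation == 0.0} == {"m1", "m2"}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equivalent_to_bruteforce_scorer(self, seed):
        rng = np.random.default_rng(seed)
        tseq = "".join(rng.choice(list("ACGT"), size=400))
        # plant a perfect and a slightly damaged site
        tseq = tseq[:100] + SITE + tseq[121:300] + mutate_site(16) + tseq[321:]
        tx = SequenceRecord(id="t", sequence=tseq)
        hits = scan_transcriptome({"m": MIR}, [tx])
        oracle = brute_force_target_scan(MIR, tseq)
        reported = {h.end: h.expectation for h in hits}
        for e, best in oracle.items():
            if best <= CFG.expectation_cutoff:
                assert reported.get(e) == pytest.approx(best), e
            else:
                assert e not in reported


class TestEnrichment:
    def go_map(self, rows):
        return pd.DataFrame(rows, columns=["gene", "term", "name", "ontology"])

    def test_universal_term_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        gm = self.go_map([(g, "GO:1", "all", "BP") for g in genes])
        (res,) = sea_enrichment(genes[:4], genes, gm)
        assert res.pvalue == pytest.approx(1.0)

    def test_closed_form_extreme(self):
        genes = [f"g{i}" for i in range(20)]
        gm = self.go_map([(g, "GO:1", "x", "BP") for g in genes[:5]])
        res = next(r for r in sea_enrichment(genes[:5], genes, gm)
                   if r.term == "GO:1")
        assert res.pvalue == pytest.approx(1 / 15504, rel=1e-9)

    def test_bh_adjustment(self):
        # spread three terms across targets/background so raw p's differ;
        # check the BH arithmetic on the reported p-vector directly
        from saltmir.expression import bh_qvalues

        q = bh_qvalues([0.01, 0.02, 0.9])
        assert np.allclose(q, [0.03, 0.03, 0.9])

    @pytest.mark.parametrize("N,K,n,k", [
        (30, 8, 10, 5), (50, 25, 12, 9), (15, 3, 6, 1), (40, 10, 10, 0),
    ])
    def test_pvalues_match_exact_rational(self, N, K, n, k):
        genes = [f"g{i}" for i in range(N)]
        term_genes = genes[:K]
        targets = term_genes[:k] + genes[K : K + (n - k)]
        gm = self.go_map([(g, "GO:1", "x", "BP") for g in term_genes])
        res = next(r for r in sea_enrichment(targets, genes, gm)
                   if r.term == "GO:1")
        exact = float(hypergeom_sf_exact(k, N, K, n))
        assert res.pvalue == pytest.approx(exact, abs=1e-10)

    def test_target_outside_background_is_error(self):
        gm = self.go_map([("g1", "GO:1", "x", "BP")])
        with pytest.raises(TargetError, match="gX"):
            sea_enrichment(["gX"], ["g1", "g2"], gm)
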