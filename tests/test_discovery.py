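import numpy as np
import pytest

from saltmir.config import DiscoveryConfig
from saltmir.discovery import (CandidateWindow, classify_context,
                               evaluate_candidate, excise_candidates,
                               name_and_deduplicate)
from saltmir.folding import FoldResult, fold
from saltmir.iofmt import GeneModel, dna_to_rna
from saltmir.mapping import TagAlignment
from saltmir.synthetic_data import design_hairpin

CFG = DiscoveryConfig()


def window_for(rec, m_iv):
    return CandidateWindow(
        chrom="h", start=0, end=len(rec.sequence), strand="+",
        sequence=rec.sequence, tag_offset=m_iv[0],
        tag_len=m_iv[1] - m_iv[0], tag_id="h",
    )


def passing_candidate(seed=1, **kwargs):
    rng = np.random.default_rng(seed)
    rec, m_iv, s_iv, arm = design_hairpin(21, 0, 10, rng, **kwargs)
    return rec, m_iv


class TestExcision:
    def make_alignment(self, start=1000, L=21, strand="+"):
        return TagAlignment("t0", "chr1", start, start + L, strand, 0)

    def test_two_windows_with_flanks(self):
        genome = {"chr1": "A" * 5000}
        a = self.make_alignment()
        ws = excise_candidates([a], {"t0": "mapped"}, {"t0"}, genome, CFG)
        spans = {(w.start, w.end) for w in ws}
        assert (1000 - 20, 1000 - 20 + 320) in spans
        assert (1021 + 20 - 320, 1021 + 20) in spans
        for w in ws:
            assert w.sequence == genome["chr1"][w.start : w.end]
            assert w.sequence[w.tag_offset : w.tag_offset + 21] == "A" * 21

    def test_clipping_at_chromosome_start(self):
        genome = {"chr1": "C" * 400}
        a = self.make_alignment(start=10)
        ws = excise_candidates([a], {"t0": "mapped"}, {"t0"}, genome, CFG)
        assert ws and all(w.start >= 0 and w.end <= 400 for w in ws)

    def test_tag_length_outside_18_26_excluded(self):
        genome = {"chr1": "G" * 2000}
        a = self.make_alignment(L=17)
        assert excise_candidates([a], {"t0": "mapped"}, {"t0"}, genome, CFG) == []

    def test_only_unannotated_mapped_tags(self):
        genome = {"chr1": "G" * 2000}
        a = self.make_alignment()
        assert excise_candidates([a], {"t0": "mapped"}, set(), genome, CFG) == []
        assert excise_candidates([a], {"t0": "over_copy_cap"}, {"t0"}, genome,
                                 CFG) == []

    def test_minus_strand_window_contains_tag_on_its_strand(self):
        rng = np.random.default_rng(8)
        chrom = "".join(rng.choice(list("ACGT"), size=3000))
        from saltmir.iofmt import revcomp

        tag = revcomp(chrom[1500:1522])
        a = TagAlignment("t0", "chr1", 1500, 1522, "-", 0)
        ws = excise_candidates([a], {"t0": "mapped"}, {"t0"}, {"chr1": chrom}, CFG)
        for w in ws:
            assert w.sequence[w.tag_offset : w.tag_offset + 22] == tag


class TestEvaluateCandidate:
    def test_designed_hairpin_accepts_with_manifest_star(self):
        rng = np.random.default_rng(2)
        rec, m_iv, s_iv, arm = design_hairpin(22, 1, 11, rng)
        cand = evaluate_candidate(window_for(rec, m_iv), CFG)
        assert cand.verdict == "ACCEPT"
        assert cand.mature == m_iv and cand.star == s_iv

    def test_mfe_threshold_boundary_via_injected_energy(self):
        """The energy filter flips exactly at the configured -18 kcal/mol."""
        rec, m_iv = passing_candidate()
        true_fold = fold(dna_to_rna(rec.sequence))
        verdicts = {}
        for mfe in (-17.0, -17.9, -18.0, -18.1, -25.0):
            backend = lambda seq, _m=mfe: FoldResult(true_fold.structure, _m)
            cand = evaluate_candidate(window_for(rec, m_iv),
                                      DiscoveryConfig(mfei_min=0.0),
                                      fold_backend=backend)
            verdicts[mfe] = cand.verdict
            if cand.verdict == "REJECT":
                assert cand.rejection_reasons == ["mfe_above_threshold"]
        assert verdicts == {-17.0: "REJECT", -17.9: "REJECT", -18.0: "ACCEPT",
                            -18.1: "ACCEPT", -25.0: "ACCEPT"}

    def test_au_range_boundaries(self):
        cfg = DiscoveryConfig(mfei_min=0.0)
        rng = np.random.default_rng(3)
        for au, accept in [(0.29, False), (0.30, True), (0.70, True),
                           (0.71, False)]:
            rec, m_iv, s_iv, _ = design_hairpin(
                21, 0, 48, rng, au_fraction=au, cfg=cfg, require_accept=accept
            )
            cand = evaluate_candidate(window_for(rec, m_iv), cfg)
            assert cand.au_fraction == pytest.approx(au, abs=1e-9)
            assert (cand.verdict == "ACCEPT") is accept
            if not accept:
                assert cand.rejection_reasons == ["au_out_of_range"]

    def test_min_paired_boundary(self):
        cfg = DiscoveryConfig(mfei_min=0.0)
        rng = np.random.default_rng(4)
        results = {}
        for pb in (17, 18, 19, 20, 21):
            rec, m_iv, s_iv, _ = design_hairpin(
                pb + 2, 0, 10, rng, paired_bp=pb, cfg=cfg,
                require_accept=pb >= 19,
            )
            cand = evaluate_candidate(window_for(rec, m_iv), cfg)
            assert cand.paired_bp == pb
            results[pb] = cand.verdict
        assert results == {17: "REJECT", 18: "REJECT", 19: "ACCEPT",
                           20: "ACCEPT", 21: "ACCEPT"}

    def test_duplex_mismatch_cap(self):
        permissive = DiscoveryConfig(max_duplex_mismatch=3, mfei_min=0.0)
        rng = np.random.default_rng(6)
        rec, m_iv, s_iv, _ = design_hairpin(24, 3, 10, rng, cfg=permissive)
        cand = evaluate_candidate(window_for(rec, m_iv),
                                  DiscoveryConfig(mfei_min=0.0))
        assert cand.verdict == "REJECT"
        assert "too_many_duplex_mismatches" in cand.rejection_reasons

    def test_all_tests_run_full_diagnosis(self):
        # an implausible window: homopolymer -> no hairpin, bad energy, bad AU
        w = CandidateWindow(chrom="x", start=0, end=80, strand="+",
                            sequence="A" * 80, tag_offset=20, tag_len=21,
                            tag_id="x")
        cand = evaluate_candidate(w, CFG)
        assert cand.verdict == "REJECT"
        assert {"no_hairpin", "mfe_above_threshold", "au_out_of_range"} <= set(
            cand.rejection_reasons
        )

    def test_tightening_mfe_threshold_never_grows_accepted_set(self):
        rng = np.random.default_rng(7)
        windows = []
        for i in range(6):
            rec, m_iv, s_iv, _ = design_hairpin(21 + i % 3, 0, 10, rng)
            windows.append(window_for(rec, m_iv))
        loose = {i for i, w in enumerate(windows)
                 if evaluate_candidate(w, DiscoveryConfig()).verdict == "ACCEPT"}
        tight = {i for i, w in enumerate(windows)
                 if evaluate_candidate(
                     w, DiscoveryConfig(max_mfe=-25.0)).verdict == "ACCEPT"}
        assert tight <= loose


class TestContext:
    GENE = GeneModel(gene_id="g1", chrom="chr1", strand="+",
                     exons=[(100, 400), (700, 1000)],
                     utr5=[(100, 200)], utr3=[(900, 1000)])

    def cand_at(self, start, end):
        from saltmir.discovery import PrecursorCandidate

        return PrecursorCandidate(
            chrom="chr1", start=start, end=end, strand="+", sequence="A",
            fold=FoldResult(".", 0.0), mature=(0, 1), star=None, arm="5p",
            paired_bp=0, duplex_mismatches=0, largest_bulge=0, asymmetry=0,
            mfe=0.0, mfei=0.0, au_fraction=0.5, verdict="ACCEPT",
        )

    def test_intergenic_when_no_overlap(self):
        assert classify_context(self.cand_at(2000, 2080), [self.GENE]) == "intergenic"

    def test_intronic(self):
        assert classify_context(self.cand_at(500, 580), [self.GENE]) == "intron"

    def test_majority_rule_exon_over_intron(self):
        # 60% in exon [100,400), 40% in intron
        assert classify_context(self.cand_at(340, 440), [self.GENE]) == "exon"

    def test_utr_beats_exon_on_ties_and_majority(self):
        assert classify_context(self.cand_at(120, 180), [self.GENE]) == "5'UTR"
        assert classify_context(self.cand_at(920, 980), [self.GENE]) == "3'UTR"


class TestNaming:
    def accepted(self, chrom, start, end, arm, mature_seq, strand="+"):
        from saltmir.discovery import PrecursorCandidate

        seq = mature_seq + "ACGAT" * 12
        return PrecursorCandidate(
            chrom=chrom, start=start, end=end, strand=strand,
            sequence=seq, fold=FoldResult("." * len(seq), -20.0),
            mature=(0, len(mature_seq)), star=None, arm=arm, paired_bp=19,
            duplex_mismatches=0, largest_bulge=0, asymmetry=0, mfe=-20.0,
            mfei=-1.0, au_fraction=0.5, verdict="ACCEPT", tag_id="t",
        )

    def test_same_precursor_two_arms_share_number(self):
        c1 = self.accepted("chr1", 100, 180, "5p", "GCATGCATGCATGCATGCATG")
        c2 = self.accepted("chr1", 120, 200, "3p", "TTGCATGCATGCATGCATGCA")
        out = name_and_deduplicate([c1, c2])
        assert [n.name for n in out] == ["oco-miR001-5p", "oco-miR001-3p"]

    def test_identical_mature_merged_with_counts(self):
        mature = "GCATGCATGCATGCATGCATG"
        c1 = self.accepted("chr1", 100, 180, "5p", mature)
        c2 = self.accepted("chr1", 100, 180, "5p", mature)
        out = name_and_deduplicate([c1, c2], tag_counts={mature: (3, 4)})
        assert len(out) == 1
        assert (out[0].count_control, out[0].count_treated) == (3, 4)

    def test_disjoint_loci_numbered_by_position(self):
        c1 = self.accepted("chr2", 500, 580, "5p", "AACCGGTTAACCGGTTAACCG")
        c2 = self.accepted("chr1", 900, 980, "5p", "GGTTAACCGGTTAACCGGTTA")
        c3 = self.accepted("chr1", 100, 180, "3p", "CCGGTTAACCGGTTAACCGGT")
        out = name_and_deduplicate([c1, c2, c3])
        assert [n.name for n in out] == ["oco-miR001-3p", "oco-miR002-5p",
                                         "oco-miR003-5p"]
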