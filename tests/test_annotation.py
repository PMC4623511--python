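import numpy as np
import pandas as pd
import pytest

from saltmir.annotation import (classify_tags, detect_star, identify_known)
from saltmir.config import AnnotationConfig
from saltmir.folding import FoldResult
from saltmir.iofmt import SequenceRecord, revcomp
from saltmir.mapping import TagAlignment, build_index, map_tags
from saltmir.iofmt import GeneModel
from saltmir.preprocess import SmallRNATag, TagSet
from saltmir.synthetic_data import design_hairpin


def tagset_of(seqs_counts):
    tags = [SmallRNATag(f"t{i}", s, c, t) for i, (s, c, t) in enumerate(seqs_counts)]
    return TagSet(tags, sum(c for _, c, _ in seqs_counts),
                  sum(t for _, _, t in seqs_counts))


class TestDetectStar:
    def test_perfect_stem_5p(self):
        # mature [0,21) pairing [31,52) in a perfect stem: star shifted +2
        n = 52
        structure = "(" * 21 + "." * 10 + ")" * 21
        star, arm = detect_star((0, 21), FoldResult(structure, -20.0))
        assert arm == "5p"
        assert star == (33, 54)   # partner [31,52) + 2

    def test_perfect_stem_3p(self):
        structure = "(" * 21 + "." * 10 + ")" * 21
        star, arm = detect_star((31, 52), FoldResult(structure, -20.0))
        assert arm == "3p"
        assert star == (2, 23)    # partner [0,21) + 2

    def test_mature_spanning_the_loop_is_flagged(self):
        structure = "(" * 10 + "." * 6 + ")" * 10
        star, flag = detect_star((4, 22), FoldResult(structure, -5.0))
        assert star is None and flag == "spans_loop"

    def test_unpaired_mature_is_flagged(self):
        star, flag = detect_star((2, 8), FoldResult("." * 20, 0.0))
        assert star is None and flag == "unpaired"


class TestIdentifyKnown:
    def refs(self):
        rng = np.random.default_rng(21)
        rec, m_iv, s_iv, arm = design_hairpin(21, 0, 10, rng, name="osa-miR169a")
        mature = rec.sequence[m_iv[0] : m_iv[1]]
        star = rec.sequence[s_iv[0] : s_iv[1]]
        mature_refs = [
            SequenceRecord(id="osa-miR169a", sequence=mature),
            SequenceRecord(id="osa-miR169g",
                           sequence="GCGGCTAGCTAGCTAGGCTAG"),
        ]
        prec_refs = [SequenceRecord(id="osa-miR169a-prec", sequence=rec.sequence,
                                    description=rec.description)]
        return mature, star, mature_refs, prec_refs

    def test_exact_tag_matches_reference(self):
        mature, star, mature_refs, prec_refs = self.refs()
        tagset = tagset_of([(mature, 5, 2)])
        records, matched = identify_known(tagset, mature_refs, prec_refs)
        assert "t0" in matched
        rec = next(r for r in records if not r.is_star)
        assert rec.family == "miR169"
        assert (rec.count_control, rec.count_treated) == (5, 2)

    def test_three_mismatches_not_known(self):
        mature, _, mature_refs, prec_refs = self.refs()
        mutated = list(mature)
        for pos in (3, 9, 15):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        tagset = tagset_of([("".join(mutated), 4, 0)])
        _, matched = identify_known(tagset, mature_refs, prec_refs)
        assert matched == set()

    def test_family_grouping_strips_letter_suffix(self):
        _, _, mature_refs, _ = self.refs()
        tagset = tagset_of([(mature_refs[0].sequence, 1, 0),
                            (mature_refs[1].sequence, 2, 0)])
        records, _ = identify_known(tagset, mature_refs, [])
        families = {r.family for r in records}
        assert families == {"miR169"}
        assert len(records) == 2

    def test_star_counts_can_exceed_mature_counts(self):
        mature, star, mature_refs, prec_refs = self.refs()
        tagset = tagset_of([(mature, 2, 0), (star, 17092, 0)])
        records, _ = identify_known(tagset, mature_refs, prec_refs)
        star_rec = next(r for r in records if r.is_star)
        mature_rec = next(r for r in records if not r.is_star)
        assert star_rec.count_control == 17092
        assert mature_rec.count_control == 2

    def test_end_shift_tolerance(self):
        mature, _, mature_refs, prec_refs = self.refs()
        shifted = mature[2:]            # 2-nt 5' shift, 19 nt
        tagset = tagset_of([(shifted, 1, 0)])
        _, matched = identify_known(tagset, mature_refs, [])
        assert "t0" in matched


class TestClassifyTags:
    def build_world(self):
        rng = np.random.default_rng(33)
        decoy = "".join(rng.choice(list("ACGT"), size=120))
        repeat = "".join(rng.choice(list("ACGT"), size=90))
        exonic = "".join(rng.choice(list("ACGT"), size=400))
        genome_seq = decoy + exonic + repeat + "".join(
            rng.choice(list("ACGT"), size=300))
        gene = GeneModel(gene_id="g1", chrom="chr1", strand="+",
                         exons=[(120, 320), (420, 520)])
        return genome_seq, decoy, repeat, gene

    def classify(self, tag_seqs, genome_seq, decoy, repeat, gene):
        tagset = tagset_of([(s, 1, 0) for s in tag_seqs])
        index = build_index([SequenceRecord(id="chr1", sequence=genome_seq)])
        alignments, status = map_tags(tagset, index, max_hits=50)
        return classify_tags(
            tagset, alignments, status,
            [SequenceRecord(id="rRNA_1", sequence=decoy, description="class=rRNA")],
            [],
            [], [],
            [SequenceRecord(id="rep1", sequence=repeat)],
            [gene],
        )

    def test_priority_rrna_beats_gene_overlap(self):
        genome_seq, decoy, repeat, gene = self.build_world()
        # a tag from the decoy locus, which also lies inside the gene span?
        tag = decoy[10:34]
        records, _ = self.classify([tag], genome_seq, decoy, repeat, gene)
        assert records[0].category == "rRNA_etc"
        assert records[0].subcategory == "rRNA"
        assert records[0].evidence_source == "genbank_like"

    def test_repeat_beats_exon(self):
        genome_seq, decoy, repeat, gene = self.build_world()
        # repeat locus [510, 600) overlaps exon 2 [420, 520)
        tag = repeat[2:26]
        records, _ = self.classify([tag], genome_seq, decoy, repeat, gene)
        assert records[0].category == "repeat"

    def test_exon_and_intron_from_gene_models(self):
        genome_seq, decoy, repeat, gene = self.build_world()
        exon_tag = genome_seq[150:172]
        intron_tag = genome_seq[330:352]
        records, _ = self.classify([exon_tag, intron_tag], genome_seq, decoy,
                                   repeat, gene)
        cats = {r.tag_id: r.category for r in records}
        assert set(cats.values()) == {"exon", "intron"}

    def test_unmatched_tag_is_unannotated(self):
        genome_seq, decoy, repeat, gene = self.build_world()
        tag = genome_seq[620:645]
        records, _ = self.classify([tag], genome_seq, decoy, repeat, gene)
        assert records[0].category == "unannotated"

    def test_priority_monotone_under_added_low_priority_refs(self):
        genome_seq, decoy, repeat, gene = self.build_world()
        tag = decoy[10:34]
        with_repeats, _ = self.classify([tag], genome_seq, decoy, repeat, gene)
        # adding the repeat reference (lower priority) must not change rRNA_etc
        assert with_repeats[0].category == "rRNA_etc"
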