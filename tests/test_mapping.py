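import numpy as np
import pytest

from oracles import brute_force_map
from saltmir.iofmt import SequenceRecord, revcomp
from saltmir.mapping import MappingError, build_index, map_tags
from saltmir.preprocess import SmallRNATag


def rand_genome(rng, sizes):
    return {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=n))
        for i, n in enumerate(sizes)
    }


def records(genome):
    return [SequenceRecord(id=c, sequence=s) for c, s in genome.items()]


def tags_of(seqs):
    return [SmallRNATag(f"t{i}", s, 1, 0) for i, s in enumerate(seqs)]


def hits_as_set(alignments):
    return {(a.tag_id, a.chrom, a.start, a.strand, a.mismatches) for a in alignments}


class TestIndex:
    def test_forward_seed_positions_single_chromosome(self, rng):
        genome = rand_genome(rng, [1000])
        index = build_index(records(genome), seed_len=12)
        sizes = index.table_sizes()
        for k, count in sizes.items():
            assert count == 1000 - k + 1

    def test_identical_fasta_identical_index(self, rng):
        genome = rand_genome(rng, [2000])
        i1 = build_index(records(genome))
        i2 = build_index(records(genome))
        assert i1.signature() == i2.signature()

    def test_seed_len_cap(self, rng):
        with pytest.raises(MappingError):
            build_index(records(rand_genome(rng, [100])), seed_len=17)

    def test_kmer_lookup_matches_brute_scan(self, rng):
        from saltmir.mapping import _encode_kmers, encode_dna

        genome = rand_genome(rng, [3000])
        index = build_index(records(genome))
        seq = genome["chr1"]
        for start in (0, 512, 1777, 2988):
            kmer = seq[start : start + 12]
            truth = {i for i in range(len(seq) - 11) if seq[i : i + 12] == kmer}
            (code,) = _encode_kmers(encode_dna(kmer), [0], 12)
            (positions,) = index.lookup(np.array([code]), 12)
            found = {index.global_to_chrom(int(p))[1] for p in positions}
            assert found == truth


class TestMapping:
    def test_equivalence_with_brute_force(self, rng):
        genome = rand_genome(rng, [2500, 1500])
        index = build_index(records(genome))
        seqs = []
        for _ in range(25):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            L = int(rng.integers(16, 37))
            s = int(rng.integers(0, len(genome[chrom]) - L))
            frag = genome[chrom][s : s + L]
            frag = list(frag)
            for _ in range(int(rng.integers(0, 4))):   # 0-3 substitutions
                pos = int(rng.integers(L))
                frag[pos] = "ACGT"[int(rng.integers(4))]
            seq = "".join(frag)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            seqs.append(seq)
        seqs += ["".join(rng.choice(list("ACGT"), size=24)) for _ in range(10)]
        tags = tags_of(sorted(set(seqs)))
        alignments, status = map_tags(tags, index, max_mismatch=2, max_hits=10**6)
        for tag in tags:
            expected = {
                (tag.tag_id, chrom, start, strand, mism)
                for chrom, start, strand, mism in brute_force_map(genome, tag.sequence, 2)
            }
            got = {h for h in hits_as_set(alignments) if h[0] == tag.tag_id}
            assert got == expected, tag.sequence

    def test_three_substitutions_unmapped(self, rng):
        genome = rand_genome(rng, [3000])
        index = build_index(records(genome))
        frag = list(genome["chr1"][100:121])
        for pos in (2, 9, 16):
            frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[pos]]
        mutated = "".join(frag)
        if brute_force_map(genome, mutated, 2):
            pytest.skip("random genome happened to contain a 2-mismatch copy")
        _, status = map_tags(tags_of([mutated]), index)
        assert status["t0"] == "unmapped"

    def test_copy_number_cap(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=21))
        spacer = lambda: "".join(rng.choice(list("ACGT"), size=40))
        chrom = spacer()
        for _ in range(21):
            chrom += unit + spacer()
        index = build_index([SequenceRecord(id="chr1", sequence=chrom)])
        alignments, status = map_tags(tags_of([unit]), index, max_hits=20)
        assert status["t0"] == "over_copy_cap"
        assert all(a.tag_id != "t0" for a in alignments)

    def test_strand_symmetry(self, rng):
        # hits of t in G correspond to hits of revcomp(t) in revcomp(G) at
        # mirrored positions (the strand label is preserved)
        genome = rand_genome(rng, [1200])
        rc_genome = {"chr1": revcomp(genome["chr1"])}
        index_f = build_index(records(genome))
        index_r = build_index(records(rc_genome))
        tag = genome["chr1"][300:322]
        fwd, _ = map_tags(tags_of([tag]), index_f, max_hits=10**6)
        rev, _ = map_tags(tags_of([revcomp(tag)]), index_r, max_hits=10**6)
        n = 1200
        mirrored = {(a.chrom, n - a.end, a.strand, a.mismatches) for a in rev}
        assert {(a.chrom, a.start, a.strand, a.mismatches) for a in fwd} == mirrored

    def test_n_in_genome_never_matches(self):
        genome = {"chr1": "ACGT" * 10 + "N" * 20 + "ACGT" * 10}
        index = build_index(records(genome))
        tag = "ACGT" * 5
        alignments, _ = map_tags(tags_of([tag]), index, max_mismatch=2,
                                 max_hits=1000)
        for a in alignments:
            window = genome["chr1"][a.start : a.end]
            assert "N" not in window or a.mismatches >= window.count("N")

    def test_tag_length_bounds_enforced(self, rng):
        genome = rand_genome(rng, [500])
        index = build_index(records(genome))
        with pytest.raises(MappingError):
            map_tags(tags_of(["ACGTACGTACGT"]), index)   # 12 nt < 16
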