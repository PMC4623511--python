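"""Ungapped tag-to-genome alignment with a mismatch cap and copy-number cap.

Tags are aligned on both strands allowing at most ``max_mismatch``
substitutions (default 2).  Completeness is guaranteed by pigeonhole
seeding: a tag of length L is split into ``max_mismatch + 1`` non-overlapping
parts, so any placement within the mismatch budget leaves at least one part
exact; the index therefore keeps k-mer tables for every part length
floor(L/3) that can arise (5..12 for 16-36-nt tags).  N in the genome never
matches; N in a tag always counts as a mismatch.

A tag with more than ``max_hits`` placements (default 20, the genome
copy-number cap) is flagged ``over_copy_cap`` and excluded from discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import MappingConfig
from .iofmt import SequenceRecord, revcomp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

TAG_MIN_LEN = 16
TAG_MAX_LEN = 36


class MappingError(ValueError):
    pass


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA as uint8 (A=0 C=1 G=2 T=3, anything else 255 = never matches)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class TagAlignment:
    tag_id: str
    chrom: str
    start: int            # 0-based half-open
    end: int
    strand: str           # '+' or '-'
    mismatches: int

    def sort_key(self):
        return (self.tag_id, self.chrom, self.start, self.strand)


class GenomeIndex:
    """k-mer seed tables over the forward strand of a genome.

    For each seed length k in ``seed_lengths`` the index holds a sorted array
    of (kmer code, position) usable by binary search; reverse-strand hits are
    found by looking up the reverse complement of the query.  Construction is
    deterministic: identical FASTA input yields identical tables.
    """

    def __init__(self, chroms: dict[str, np.ndarray], seed_lengths: Sequence[int]):
        self.chrom_names = list(chroms)
        self.chrom_arrays = chroms
        self.chrom_lengths = {name: len(arr) for name, arr in chroms.items()}
        self.seed_lengths = sorted(set(seed_lengths))
        # concatenate chromosomes with per-chrom offsets for global positions
        self._offsets = {}
        total = 0
        parts = []
        for name in self.chrom_names:
            self._offsets[name] = total
            parts.append(chroms[name])
            # spacer of N so seeds never span chromosomes
            parts.append(np.full(max(self.seed_lengths), 255, dtype=np.uint8))
            total += len(chroms[name]) + max(self.seed_lengths)
        self._genome = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._bounds = np.array(
            [self._offsets[n] for n in self.chrom_names] + [total], dtype=np.int64
        )
        self._tables = {k: self._build_table(k) for k in self.seed_lengths}

    def _build_table(self, k: int):
        g = self._genome.astype(np.int64)
        n = len(g)
        if n < k:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        valid = g < 4
        ok = np.ones(n - k + 1, dtype=bool)
        code = np.zeros(n - k + 1, dtype=np.int64)
        for j in range(k):
            code = code * 4 + g[j : n - k + 1 + j]
            ok &= valid[j : n - k + 1 + j]
        positions = np.nonzero(ok)[0]
        codes = code[positions]
        order = np.argsort(codes, kind="stable")
        return codes[order], positions[order]

    def lookup(self, kmer_codes: np.ndarray, k: int) -> list[np.ndarray]:
        """Global positions of each k-mer code (sorted ascending per query)."""
        codes, positions = self._tables[k]
        lo = np.searchsorted(codes, kmer_codes, side="left")
        hi = np.searchsorted(codes, kmer_codes, side="right")
        return [np.sort(positions[a:b]) for a, b in zip(lo, hi)]

    def global_to_chrom(self, pos: int) -> tuple[str, int]:
        idx = int(np.searchsorted(self._bounds, pos, side="right")) - 1
        name = self.chrom_names[idx]
        return name, pos - self._offsets[name]

    def slice(self, gpos: int, length: int) -> np.ndarray:
        return self._genome[gpos : gpos + length]

    def table_sizes(self) -> dict[int, int]:
        return {k: len(self._tables[k][0]) for k in self.seed_lengths}

    def signature(self) -> bytes:
        """Deterministic digest of the serialized index (rebuild check)."""
        import hashlib

        h = hashlib.sha256()
        for name in self.chrom_names:
            h.update(name.encode())
            h.update(self.chrom_arrays[name].tobytes())
        for k in self.seed_lengths:
            codes, positions = self._tables[k]
            h.update(codes.tobytes())
            h.update(positions.tobytes())
        return h.digest()

    def save(self, path) -> None:
        arrays = {f"chrom_{name}": arr for name, arr in self.chrom_arrays.items()}
        np.savez(path, seed_lengths=np.array(self.seed_lengths), **arrays)

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        data = np.load(path)
        chroms = {
            key[len("chrom_"):]: data[key] for key in data.files if key.startswith("chrom_")
        }
        return cls(chroms, [int(k) for k in data["seed_lengths"]])


def _part_lengths(max_mismatch: int, seed_len: int) -> list[int]:
    lengths = set()
    for L in range(TAG_MIN_LEN, TAG_MAX_LEN + 1):
        lengths.add(min(seed_len, L // (max_mismatch + 1)))
    return sorted(lengths)


def build_index(
    genome: Iterable[SequenceRecord],
    seed_len: int = 12,
    max_mismatch: int = 2,
) -> GenomeIndex:
    """Build the seed index for a genome (seed_len is the maximum seed length)."""
    if seed_len > TAG_MIN_LEN:
        raise MappingError(f"seed_len {seed_len} > shortest tag ({TAG_MIN_LEN})")
    chroms = {}
    for rec in genome:
        chroms[rec.id] = encode_dna(rec.sequence)
    if not chroms:
        raise MappingError("empty genome")
    return GenomeIndex(chroms, _part_lengths(max_mismatch, seed_len))


def _encode_kmers(enc: np.ndarray, starts: Sequence[int], k: int) -> np.ndarray:
    codes = []
    for s in starts:
        window = enc[s : s + k].astype(np.int64)
        if (window >= 4).any():
            codes.append(-1)
        else:
            c = 0
            for b in window:
                c = c * 4 + int(b)
            codes.append(c)
    return np.array(codes, dtype=np.int64)


def _map_one_strand(index: GenomeIndex, enc: np.ndarray, max_mismatch: int):
    """All placements of an encoded tag on the indexed (forward) strand."""
    L = len(enc)
    parts = max_mismatch + 1
    f = min(max(index.seed_lengths), L // parts)
    starts = [i * f for i in range(parts)]
    codes = _encode_kmers(enc, starts, f)
    candidates = set()
    for off, (code, hits) in zip(starts, zip(codes, index.lookup(codes, f))):
        if code < 0:
            continue
        for pos in hits:
            candidates.add(int(pos) - off)
    if not candidates:
        return []
    cand = np.array(sorted(c for c in candidates if c >= 0), dtype=np.int64)
    if len(cand) == 0:
        return []
    gather = cand[:, None] + np.arange(L)[None, :]
    in_range = gather[:, -1] < len(index._genome)
    cand = cand[in_range]
    gather = gather[in_range]
    windows = index._genome[gather]
    mism = (windows != enc[None, :]).sum(axis=1)
    mism += ((windows == enc[None, :]) & (windows >= 4)).sum(axis=1)  # N==N still mismatch
    keep = mism <= max_mismatch
    return [(int(c), int(m)) for c, m in zip(cand[keep], mism[keep])]


def map_tags(
    tags,
    index: GenomeIndex,
    max_mismatch: int = 2,
    max_hits: int = 20,
):
    """Map a TagSet (or iterable of tags) to the genome.

    Returns ``(alignments, status)`` where status maps tag_id to one of
    ``mapped``, ``unmapped`` or ``over_copy_cap``.  All placements with
    <= max_mismatch mismatches on both strands are reported, in deterministic
    (tag_id, chrom, start, strand) order.
    """
    alignments: list[TagAlignment] = []
    status: dict[str, str] = {}
    for tag in tags:
        L = len(tag.sequence)
        if not (TAG_MIN_LEN <= L <= TAG_MAX_LEN):
            raise MappingError(f"tag {tag.tag_id} length {L} outside 16-36")
        fwd = encode_dna(tag.sequence)
        rev = encode_dna(revcomp(tag.sequence))
        hits = []
        for strand, enc in (("+", fwd), ("-", rev)):
            for gpos, mism in _map_one_strand(index, enc, max_mismatch):
                chrom, cpos = index.global_to_chrom(gpos)
                if cpos + L <= index.chrom_lengths[chrom]:
                    hits.append(
                        TagAlignment(
                            tag_id=tag.tag_id,
                            chrom=chrom,
                            start=cpos,
                            end=cpos + L,
                            strand=strand,
                            mismatches=mism,
                        )
                    )
        if not hits:
            status[tag.tag_id] = "unmapped"
        elif len(hits) > max_hits:
            status[tag.tag_id] = "over_copy_cap"
        else:
            status[tag.tag_id] = "mapped"
            alignments.extend(hits)
    alignments.sort(key=TagAlignment.sort_key)
    return alignments, status


def alignments_to_frame(alignments, status):
    """Alignments + per-tag status as a DataFrame (start reported 1-based)."""
    import pandas as pd

    rows = [
        {
            "tag_id": a.tag_id,
            "chrom": a.chrom,
            "start": a.start + 1,
            "end": a.end,
            "strand": a.strand,
            "mismatches": a.mismatches,
            "status": status[a.tag_id],
        }
        for a in alignments
    ]
    unplaced = [
        {"tag_id": t, "chrom": ".", "start": 0, "end": 0, "strand": ".", "mismatches": -1,
         "status": s}
        for t, s in sorted(status.items())
        if s != "mapped"
    ]
    return pd.DataFrame(rows + unplaced,
                        columns=["tag_id", "chrom", "start", "end", "strand",
                                 "mismatches", "status"])
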