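"""Hierarchical tag annotation and known-miRNA identification.

Every mapped tag receives exactly one annotation class by the priority rule

    rRNA etc. (GenBank-like > Rfam-like) > known miRNAs > repeats > exons > introns

with tags matching nothing left ``unannotated`` (the input to novel-miRNA
discovery).  A tag "matches" a reference class when it aligns to a member
sequence with at most 2 mismatches — the same ungapped matcher used for
genome mapping.

Known miRNAs are identified against a miRBase-like reference of mature and
precursor sequences; precursors are folded to locate the miRNA* (star)
species, the duplex partner of the mature offset to leave the canonical
2-nt 3' overhang on each strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .config import AnnotationConfig
from .folding import FoldResult, fold
from .iofmt import SequenceRecord, dna_to_rna
from .mapping import GenomeIndex, build_index, encode_dna, map_tags
from .preprocess import TagSet

CATEGORIES = ("rRNA_etc", "known_miRNA", "repeat", "exon", "intron", "unannotated")


@dataclass(frozen=True)
class AnnotationRecord:
    tag_id: str
    category: str
    subcategory: str = ""
    evidence_source: str = ""


@dataclass
class KnownMiRNA:
    name: str
    family: str
    arm: str                  # 5p / 3p / unknown
    is_star: bool
    count_control: int
    count_treated: int
    matched_tags: list = field(default_factory=list)


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# miRNA* geometry
# ---------------------------------------------------------------------------

def detect_star(mature: tuple[int, int], fold_result: FoldResult | np.ndarray):
    """Locate the miRNA* interval for a mature miRNA on a folded precursor.

    The star is the duplex partner of the mature: the interval of positions
    pairing with the mature, shifted +2 nt along the precursor so both duplex
    strands carry the canonical 2-nt 3' overhang left by Dicer.

    Returns ``(star_interval, arm)`` with arm ``5p``/``3p``; returns
    ``(None, flag)`` when no star is defined (``unpaired`` if no mature base
    pairs, ``spans_loop`` if the mature pairs with itself, i.e. crosses the
    terminal loop).
    """
    pairs = (
        fold_result.pair_map() if isinstance(fold_result, FoldResult) else np.asarray(fold_result)
    )
    lo, hi = mature
    partners = [int(pairs[i]) for i in range(lo, hi) if pairs[i] >= 0]
    if not partners:
        return None, "unpaired"
    if any(lo <= p < hi for p in partners):
        return None, "spans_loop"
    qlo, qhi = min(partners), max(partners) + 1
    arm = "5p" if hi <= qlo else "3p"
    star = (qlo + 2, qhi + 2)
    return star, arm


def star_sequence(precursor: str, star: tuple[int, int]) -> str:
    lo, hi = max(0, star[0]), min(len(precursor), star[1])
    return precursor[lo:hi]


# ---------------------------------------------------------------------------
# Reference matching (same matcher as genome mapping)
# ---------------------------------------------------------------------------

def _match_tags_to_refs(tagset: TagSet, refs: list[SequenceRecord], max_mismatch: int):
    """Map every tag against a reference set; returns tag_id -> list of
    (ref_id, start, end, strand, mismatches)."""
    usable = [r for r in refs if len(r.sequence) >= 16]
    if not usable:
        return {}
    index = build_index(usable, seed_len=5, max_mismatch=max_mismatch)
    matches: dict[str, list] = {}
    mappable = [t for t in tagset if any(len(t.sequence) <= len(r.sequence) for r in usable)]
    alignments, status = map_tags(mappable, index, max_mismatch=max_mismatch, max_hits=10**9)
    for a in alignments:
        matches.setdefault(a.tag_id, []).append(
            (a.chrom, a.start, a.end, a.strand, a.mismatches)
        )
    return matches


def _family_of(name: str) -> str:
    m = re.search(r"(miR|MIR)[-]?(\d+)", name)
    return f"miR{m.group(2)}" if m else name


def _parse_mature_annotation(rec: SequenceRecord):
    """Precursor headers carry ``mature=start-end`` (1-based inclusive)."""
    m = re.search(r"mature=(\d+)-(\d+)", rec.description)
    if not m:
        return None
    return int(m.group(1)) - 1, int(m.group(2))


def identify_known(
    tagset: TagSet,
    mature_refs: list[SequenceRecord],
    precursor_refs: list[SequenceRecord] | None = None,
    cfg: AnnotationConfig | None = None,
    fold_backend="nn",
):
    """Identify known miRNAs (and their stars) among the tags.

    A tag is a known miRNA if it matches a reference mature sequence with at
    most ``cfg.max_mismatch`` mismatches and end shifts of at most
    ``cfg.max_end_shift`` nt, or if it lies on a reference precursor
    overlapping the annotated mature position (or the derived star position)
    within ``cfg.star_slop`` nt.

    Returns ``(records, matched_tag_ids)`` where records is a list of
    :class:`KnownMiRNA` sorted by name.
    """
    cfg = cfg or AnnotationConfig()
    precursor_refs = precursor_refs or []
    results: dict[tuple[str, bool], KnownMiRNA] = {}
    claimed: dict[str, tuple] = {}   # tag_id -> (mismatches, name, is_star)

    def claim(tag, name, arm, is_star, mismatches):
        prev = claimed.get(tag.tag_id)
        cand = (mismatches, is_star, name)
        if prev is not None and prev[:3] <= cand:
            return
        claimed[tag.tag_id] = (mismatches, is_star, name, arm)

    # route 1: direct match to mature references
    mature_by_seq = [(r, encode_dna(r.sequence)) for r in mature_refs]
    arm_from_name = {r.id: ("5p" if r.id.endswith("5p") else "3p" if r.id.endswith("3p") else "unknown")
                     for r in mature_refs}
    for tag in tagset:
        tenc = encode_dna(tag.sequence)
        L = len(tenc)
        for ref, renc in mature_by_seq:
            M = len(renc)
            if abs(L - M) > 2 * cfg.max_end_shift:
                continue
            best = None
            for shift in range(-cfg.max_end_shift, cfg.max_end_shift + 1):
                # tag start sits at ref position `shift`
                end_shift = (shift + L) - M
                if abs(end_shift) > cfg.max_end_shift:
                    continue
                lo = max(0, shift)
                hi = min(M, shift + L)
                if hi - lo < min(L, M) - cfg.max_end_shift:
                    continue
                overhang = (lo - shift) + (shift + L - hi)   # tag bases off the ref
                mism = int((tenc[lo - shift : hi - shift] != renc[lo:hi]).sum()) + overhang
                if mism <= cfg.max_mismatch and (best is None or mism < best):
                    best = mism
            if best is not None:
                claim(tag, ref.id, arm_from_name[ref.id], False, best)

    # route 2: placement on an annotated precursor (mature or star position)
    star_cache = {}
    for ref in precursor_refs:
        mature_iv = _parse_mature_annotation(ref)
        if mature_iv is None:
            continue   # skipped: no mature annotation
        fr = fold(dna_to_rna(ref.sequence), backend=fold_backend)
        star_iv, arm = detect_star(mature_iv, fr)
        star_cache[ref.id] = (mature_iv, star_iv, arm)
    usable_precursors = [r for r in precursor_refs if r.id in star_cache]
    prec_matches = _match_tags_to_refs(tagset, usable_precursors, cfg.max_mismatch)
    slop = cfg.star_slop
    tag_by_id = {t.tag_id: t for t in tagset}
    for tag_id, hits in prec_matches.items():
        for ref_id, start, end, strand, mism in hits:
            if strand != "+":
                continue
            mature_iv, star_iv, arm = star_cache[ref_id]
            if mature_iv[0] - slop <= start and end <= mature_iv[1] + slop:
                claim(tag_by_id[tag_id], ref_id, arm, False, mism)
            elif star_iv is not None and star_iv[0] - slop <= start and end <= star_iv[1] + slop:
                star_arm = "3p" if arm == "5p" else "5p" if arm == "3p" else "unknown"
                claim(tag_by_id[tag_id], ref_id, star_arm, True, mism)

    for tag_id, (mism, is_star, name, arm) in claimed.items():
        tag = tag_by_id.get(tag_id) or next(t for t in tagset if t.tag_id == tag_id)
        key = (name, is_star)
        if key not in results:
            results[key] = KnownMiRNA(
                name=name + ("*" if is_star else ""),
                family=_family_of(name),
                arm=arm,
                is_star=is_star,
                count_control=0,
                count_treated=0,
            )
        rec = results[key]
        rec.count_control += tag.count_control
        rec.count_treated += tag.count_treated
        rec.matched_tags.append(tag_id)

    records = sorted(results.values(), key=lambda r: (r.name, r.is_star))
    return records, set(claimed)


# ---------------------------------------------------------------------------
# Priority classification
# ---------------------------------------------------------------------------

def classify_tags(
    tagset: TagSet,
    alignments,
    status: dict[str, str],
    genbank_ncrna: list[SequenceRecord],
    rfam_ncrna: list[SequenceRecord],
    mature_refs: list[SequenceRecord],
    precursor_refs: list[SequenceRecord],
    repeat_refs: list[SequenceRecord],
    gene_models,
    cfg: AnnotationConfig | None = None,
    fold_backend="nn",
):
    """Assign each mapped tag exactly one category by the priority rule.

    Returns ``(records, known_mirnas)``; the partition over mapped tags is
    exhaustive and exclusive.
    """
    cfg = cfg or AnnotationConfig()
    mapped_ids = {t for t, s in status.items() if s == "mapped"}

    def subcat(rec: SequenceRecord) -> str:
        m = re.search(r"class=(\w+)", rec.description)
        return m.group(1) if m else ""

    genbank_hits = _match_tags_to_refs(tagset, genbank_ncrna, cfg.max_mismatch)
    rfam_hits = _match_tags_to_refs(tagset, rfam_ncrna, cfg.max_mismatch)
    repeat_hits = _match_tags_to_refs(tagset, repeat_refs, cfg.max_mismatch)
    known, known_ids = identify_known(
        tagset, mature_refs, precursor_refs, cfg, fold_backend=fold_backend
    )
    sub_by_ref = {r.id: subcat(r) for r in genbank_ncrna + rfam_ncrna}

    # exon/intron lookup from genome placements
    by_tag_alignments: dict[str, list] = {}
    for a in alignments:
        by_tag_alignments.setdefault(a.tag_id, []).append(a)
    exon_iv: dict[str, list] = {}
    gene_iv: dict[str, list] = {}
    for gm in gene_models or []:
        for a, b in gm.exons:
            exon_iv.setdefault(gm.chrom, []).append((a, b))
        s, e = gm.span
        gene_iv.setdefault(gm.chrom, []).append((s, e))

    def overlaps(chrom, start, end, table):
        return any(a < end and start < b for a, b in table.get(chrom, ()))

    records = []
    for tag in tagset:
        if tag.tag_id not in mapped_ids:
            continue
        if tag.tag_id in genbank_hits:
            ref_id = genbank_hits[tag.tag_id][0][0]
            records.append(AnnotationRecord(tag.tag_id, "rRNA_etc",
                                            sub_by_ref.get(ref_id, ""), "genbank_like"))
        elif tag.tag_id in rfam_hits:
            ref_id = rfam_hits[tag.tag_id][0][0]
            records.append(AnnotationRecord(tag.tag_id, "rRNA_etc",
                                            sub_by_ref.get(ref_id, ""), "rfam_like"))
        elif tag.tag_id in known_ids:
            records.append(AnnotationRecord(tag.tag_id, "known_miRNA", "", "mirbase_like"))
        elif tag.tag_id in repeat_hits:
            records.append(AnnotationRecord(tag.tag_id, "repeat", "", "repeat_set"))
        else:
            placements = by_tag_alignments.get(tag.tag_id, [])
            if any(overlaps(a.chrom, a.start, a.end, exon_iv) for a in placements):
                records.append(AnnotationRecord(tag.tag_id, "exon", "", "gff"))
            elif any(overlaps(a.chrom, a.start, a.end, gene_iv) for a in placements):
                records.append(AnnotationRecord(tag.tag_id, "intron", "", "gff"))
            else:
                records.append(AnnotationRecord(tag.tag_id, "unannotated", "", ""))
    return records, known
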