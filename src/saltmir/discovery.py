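"""Novel miRNA discovery from unannotated mapped tags.

For each unannotated tag placement two candidate windows are excised (tag at
the 5' end extending 3', and tag at the 3' end extending 5', bounded by the
maximum miRNA..miRNA* span plus 20-nt flanks).  Each window is folded; the
miRNA* is derived from the pairing partner of the tag; the precursor is then
trimmed to the hairpin (duplex plus flanks), refolded, and judged against
the full candidate rule set:

* stem-loop with the mature entirely on one arm, star without loop or break,
* duplex: >= 19 base pairs, <= 2 mismatches, bulge <= 8, asymmetry <= 4,
  mature..star distance <= 300 nt,
* precursor: MFE <= -18 kcal/mol, 30-70% A+U, |MFEI| above the configured
  floor (MFEI = (MFE / length x 100) / GC%).

Every failed test appends a distinct rejection reason; rejection is data,
not an error.  Accepted candidates are classified by genomic context
(majority overlap with gene models; intergenic when none) and named
sequentially with -5p/-3p arm suffixes, two matures from one precursor
sharing a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import detect_star
from .config import DiscoveryConfig
from .folding import FoldResult, fold
from .iofmt import GeneModel, dna_to_rna, revcomp

REJECTION_REASONS = (
    "mature_length_out_of_range",
    "no_hairpin",
    "mature_spans_loop",
    "star_out_of_bounds",
    "star_overlaps_mature",
    "star_spans_loop",
    "too_few_paired",
    "too_many_duplex_mismatches",
    "bulge_too_large",
    "asymmetry_too_large",
    "duplex_too_far",
    "mfe_above_threshold",
    "au_out_of_range",
    "mfei_below_threshold",
)


@dataclass
class CandidateWindow:
    """An excised genomic window with the originating tag's position."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str            # DNA, 5'->3' on the alignment strand
    tag_offset: int          # mature start within the window
    tag_len: int
    tag_id: str


@dataclass
class PrecursorCandidate:
    chrom: str
    start: int               # precursor locus, 0-based half-open, genome coords
    end: int
    strand: str
    sequence: str            # DNA, 5'->3' on its strand
    fold: FoldResult
    mature: tuple[int, int]  # precursor coordinates
    star: tuple[int, int] | None
    arm: str
    paired_bp: int
    duplex_mismatches: int
    largest_bulge: int
    asymmetry: int
    mfe: float
    mfei: float
    au_fraction: float
    verdict: str             # ACCEPT / REJECT
    rejection_reasons: list = field(default_factory=list)
    tag_id: str = ""
    count_control: int = 0
    count_treated: int = 0

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature[0] : self.mature[1]]

    @property
    def star_seq(self) -> str:
        if self.star is None:
            return ""
        lo, hi = max(0, self.star[0]), min(len(self.sequence), self.star[1])
        return self.sequence[lo:hi]


@dataclass
class NovelMiRNA:
    name: str
    mature_seq: str
    star_seq: str
    chrom: str
    start: int
    end: int
    strand: str
    arm: str
    context: str
    precursor_len: int
    mfe: float
    mfei: float
    au_fraction: float
    count_control: int
    count_treated: int
    structure: str


# ---------------------------------------------------------------------------
# Window excision
# ---------------------------------------------------------------------------

def excise_candidates(
    alignments,
    status: dict[str, str],
    unannotated_ids: set[str],
    genome: dict[str, str],
    cfg: DiscoveryConfig | None = None,
) -> list[CandidateWindow]:
    """Excise candidate precursor windows around unannotated tag placements.

    Two windows per placement (tag at either end of a putative precursor),
    clipped at chromosome edges, deduplicated on (locus, mature position).
    """
    cfg = cfg or DiscoveryConfig()
    windows: dict[tuple, CandidateWindow] = {}
    for a in alignments:
        if status.get(a.tag_id) != "mapped" or a.tag_id not in unannotated_ids:
            continue
        L = a.end - a.start
        if not (cfg.min_mature_len <= L <= cfg.max_mature_len):
            continue
        chrom_seq = genome[a.chrom]
        clen = len(chrom_seq)
        if a.strand == "+":
            # tag at the 5' end extending 3', then tag at the 3' end extending 5'
            spans = [
                (a.start - cfg.flank, a.start - cfg.flank + cfg.max_precursor),
                (a.end + cfg.flank - cfg.max_precursor, a.end + cfg.flank),
            ]
        else:
            spans = [
                (a.end + cfg.flank - cfg.max_precursor, a.end + cfg.flank),
                (a.start - cfg.flank, a.start - cfg.flank + cfg.max_precursor),
            ]
        for w_start, w_end in spans:
            w_start = max(0, w_start)
            w_end = min(clen, w_end)
            if w_end - w_start < L:
                continue
            raw = chrom_seq[w_start:w_end]
            if a.strand == "+":
                seq = raw
                offset = a.start - w_start
            else:
                seq = revcomp(raw)
                offset = w_end - a.end
            key = (a.chrom, w_start, w_end, a.strand, offset)
            if key not in windows:
                windows[key] = CandidateWindow(
                    chrom=a.chrom,
                    start=w_start,
                    end=w_end,
                    strand=a.strand,
                    sequence=seq,
                    tag_offset=offset,
                    tag_len=L,
                    tag_id=a.tag_id,
                )
    return [windows[k] for k in sorted(windows)]


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

def _duplex_stats(pairs: np.ndarray, mature: tuple[int, int], star: tuple[int, int]):
    """Duplex geometry: paired count, per-strand unpaired (3'-overhang excluded),
    largest one-strand unpaired run, asymmetry."""
    mlo, mhi = mature
    slo, shi = star

    def core_positions(lo, hi):
        return range(lo, max(lo, hi - 2))   # exclude the 2-nt 3' overhang

    paired_bp = sum(
        1 for i in range(mlo, mhi) if pairs[i] >= 0 and not (mlo <= pairs[i] < mhi)
    )
    u_m = sum(1 for i in core_positions(mlo, mhi) if pairs[i] < 0)
    u_s = sum(1 for i in core_positions(slo, shi) if 0 <= i < len(pairs) and pairs[i] < 0)

    def longest_run(lo, hi):
        run = best = 0
        for i in core_positions(lo, hi):
            if 0 <= i < len(pairs) and pairs[i] < 0:
                run += 1
                best = max(best, run)
            else:
                run = 0
        return best

    bulge = max(longest_run(mlo, mhi), longest_run(slo, shi))
    return paired_bp, min(u_m, u_s), bulge, abs(u_m - u_s)


def _au_fraction(seq: str) -> float:
    return (seq.count("A") + seq.count("T") + seq.count("U")) / len(seq)


def _mfei(mfe: float, seq: str) -> float:
    gc_pct = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    if gc_pct == 0:
        return 0.0
    return (mfe / len(seq) * 100.0) / gc_pct


def evaluate_candidate(
    window: CandidateWindow,
    cfg: DiscoveryConfig | None = None,
    fold_backend=None,
) -> PrecursorCandidate:
    """Fold a candidate window and judge it against all criteria.

    All tests run (no short-circuit); each failure appends a distinct
    rejection reason, so a rejected candidate carries its full diagnosis.
    """
    cfg = cfg or DiscoveryConfig()
    backend = fold_backend if fold_backend is not None else cfg.fold_backend
    reasons: list[str] = []
    mature = (window.tag_offset, window.tag_offset + window.tag_len)
    if not (cfg.min_mature_len <= window.tag_len <= cfg.max_mature_len):
        reasons.append("mature_length_out_of_range")

    fr = fold(dna_to_rna(window.sequence), backend=backend)
    star, arm = detect_star(mature, fr)
    seq = window.sequence
    g_start, g_end = window.start, window.end

    if star is None:
        reasons.append("no_hairpin" if arm == "unpaired" else "mature_spans_loop")
    else:
        # trim the precursor to the hairpin (duplex extent plus flanks), refold
        lo = max(0, min(mature[0], star[0]) - cfg.flank)
        hi = min(len(seq), max(mature[1], star[1]) + cfg.flank)
        if hi - lo < len(seq):
            seq = seq[lo:hi]
            mature = (mature[0] - lo, mature[1] - lo)
            if window.strand == "+":
                g_start, g_end = window.start + lo, window.start + hi
            else:
                g_start, g_end = window.end - hi, window.end - lo
            fr = fold(dna_to_rna(seq), backend=backend)
            star, arm = detect_star(mature, fr)
            if star is None:
                reasons.append("no_hairpin" if arm == "unpaired" else "mature_spans_loop")

    paired_bp = duplex_mm = bulge = asym = 0
    if star is not None:
        pairs = fr.pair_map()
        if star[0] < 0 or star[1] > len(seq):
            reasons.append("star_out_of_bounds")
        if star[0] < mature[1] and mature[0] < star[1]:
            reasons.append("star_overlaps_mature")
        slo, shi = max(0, star[0]), min(len(seq), star[1])
        if any(slo <= pairs[i] < shi for i in range(slo, shi) if pairs[i] >= 0):
            reasons.append("star_spans_loop")
        paired_bp, duplex_mm, bulge, asym = _duplex_stats(pairs, mature, star)
        if paired_bp < cfg.min_paired:
            reasons.append("too_few_paired")
        if duplex_mm > cfg.max_duplex_mismatch:
            reasons.append("too_many_duplex_mismatches")
        if bulge > cfg.max_bulge:
            reasons.append("bulge_too_large")
        if asym > cfg.max_asymmetry:
            reasons.append("asymmetry_too_large")
        distance = max(star[0], mature[0]) - min(star[1], mature[1])
        if distance > cfg.max_duplex_distance:
            reasons.append("duplex_too_far")

    mfe = fr.mfe
    au = _au_fraction(seq)
    mfei = _mfei(mfe, seq)
    if mfe > cfg.max_mfe:
        reasons.append("mfe_above_threshold")
    if not (cfg.min_au <= au <= cfg.max_au):
        reasons.append("au_out_of_range")
    if cfg.mfei_min > 0 and abs(mfei) < cfg.mfei_min:
        reasons.append("mfei_below_threshold")

    return PrecursorCandidate(
        chrom=window.chrom,
        start=g_start,
        end=g_end,
        strand=window.strand,
        sequence=seq,
        fold=fr,
        mature=mature,
        star=star,
        arm=arm if star is not None else "unknown",
        paired_bp=paired_bp,
        duplex_mismatches=duplex_mm,
        largest_bulge=bulge,
        asymmetry=asym,
        mfe=mfe,
        mfei=mfei,
        au_fraction=au,
        verdict="ACCEPT" if not reasons else "REJECT",
        rejection_reasons=reasons,
        tag_id=window.tag_id,
    )


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

_CONTEXT_PRECEDENCE = ("5'UTR", "3'UTR", "exon", "intron")


def classify_context(candidate: PrecursorCandidate, gene_models: list[GeneModel]) -> str:
    """Genomic context of the precursor locus by majority overlap.

    Ties break 5'UTR > 3'UTR > exon > intron; no gene overlap -> intergenic.
    """
    lo, hi = candidate.start, candidate.end
    overlap = {k: 0 for k in _CONTEXT_PRECEDENCE}

    def ov(intervals):
        return sum(max(0, min(hi, b) - max(lo, a)) for a, b in intervals)

    for gm in gene_models:
        if gm.chrom != candidate.chrom:
            continue
        s, e = gm.span
        if not (s < hi and lo < e):
            continue
        u5 = ov(gm.utr5)
        u3 = ov(gm.utr3)
        ex = ov(gm.exons) - u5 - u3
        intr = ov(gm.introns)
        overlap["5'UTR"] += u5
        overlap["3'UTR"] += u3
        overlap["exon"] += max(0, ex)
        overlap["intron"] += intr
    if all(v == 0 for v in overlap.values()):
        return "intergenic"
    best = max(overlap.values())
    for ctx in _CONTEXT_PRECEDENCE:
        if overlap[ctx] == best:
            return ctx
    return "intergenic"


# ---------------------------------------------------------------------------
# Naming and deduplication
# ---------------------------------------------------------------------------

def name_and_deduplicate(
    accepted: list[PrecursorCandidate],
    gene_models: list[GeneModel] | None = None,
    tag_counts: dict[str, tuple[int, int]] | None = None,
    prefix: str = "oco-miR",
) -> list[NovelMiRNA]:
    """Merge candidates with identical mature sequence and assign names.

    ``tag_counts`` maps tag *sequences* to (control, treated) counts.
    Precursor groups (overlapping loci, same strand) share a sequential
    number; the two arms of one precursor get -5p / -3p suffixes.  Ordering
    is deterministic (by locus).
    """
    gene_models = gene_models or []
    by_mature: dict[str, PrecursorCandidate] = {}
    for cand in sorted(accepted, key=lambda c: (c.chrom, c.start, c.end, c.strand)):
        if tag_counts:
            # counts belong to the tag whose sequence is the mature itself
            cc, ct = tag_counts.get(cand.mature_seq, (0, 0))
            cand = replace(cand, count_control=cc, count_treated=ct)
        seq = cand.mature_seq
        if seq in by_mature:
            prev = by_mature[seq]
            prev.count_control = max(prev.count_control, cand.count_control)
            prev.count_treated = max(prev.count_treated, cand.count_treated)
        else:
            by_mature[seq] = replace(cand, rejection_reasons=list(cand.rejection_reasons))

    uniques = sorted(by_mature.values(), key=lambda c: (c.chrom, c.start, c.end, c.strand))
    # group overlapping precursor loci on the same strand
    groups: list[list[PrecursorCandidate]] = []
    for cand in uniques:
        placed = False
        for group in groups:
            g = group[0]
            if (
                g.chrom == cand.chrom
                and g.strand == cand.strand
                and g.start < cand.end
                and cand.start < g.end
            ):
                group.append(cand)
                placed = True
                break
        if not placed:
            groups.append([cand])

    out: list[NovelMiRNA] = []
    for number, group in enumerate(groups, 1):
        used = {}
        for cand in group:
            suffix = f"-{cand.arm}"
            if suffix in used:
                used[suffix] += 1
                suffix = f"{suffix}.{used[suffix]}"
            else:
                used[suffix] = 1
            out.append(
                NovelMiRNA(
                    name=f"{prefix}{number:03d}{suffix}",
                    mature_seq=cand.mature_seq,
                    star_seq=cand.star_seq,
                    chrom=cand.chrom,
                    start=cand.start,
                    end=cand.end,
                    strand=cand.strand,
                    arm=cand.arm,
                    context=classify_context(cand, gene_models),
                    precursor_len=len(cand.sequence),
                    mfe=cand.mfe,
                    mfei=cand.mfei,
                    au_fraction=cand.au_fraction,
                    count_control=cand.count_control,
                    count_treated=cand.count_treated,
                    structure=cand.fold.structure,
                )
            )
    return out
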