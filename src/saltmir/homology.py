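"""Conserved-miRNA discovery by homology search against a transcriptome.

Reference precursor (or mature-only) sequences are searched against a cDNA
set with a seeded, ungapped full-query matcher on both strands: the word
size is adapted per query so that any placement within the mismatch budget
implied by ``min_identity`` is guaranteed to contain an exact seed
(pigeonhole), making the search exactly equivalent to a brute-force
sliding-window identity scan.  Precursor hits are re-folded and validated
with the same candidate criteria as de novo discovery (genomic-context
checks do not apply); mature-only hits are reported unvalidated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .config import DiscoveryConfig, HomologyConfig
from .discovery import CandidateWindow, PrecursorCandidate, evaluate_candidate
from .iofmt import SequenceRecord, revcomp
from .mapping import encode_dna


@dataclass
class HomologyHit:
    query: str
    transcript: str
    start: int               # alignment interval on the transcript (forward coords)
    end: int
    strand: str
    identity: float
    coverage: float
    query_kind: str          # precursor / mature_only
    validated: bool = False
    candidate: PrecursorCandidate | None = None


def _mature_annotation(rec: SequenceRecord):
    m = re.search(r"mature=(\d+)-(\d+)", rec.description)
    if m:
        return int(m.group(1)) - 1, int(m.group(2))
    return None


def _word_size(qlen: int, min_identity: float, min_coverage: float, cap: int) -> int:
    """Largest word size that still guarantees an exact seed inside any
    qualifying (possibly edge-clipped) placement, by pigeonhole."""
    mmax = math.floor(qlen * (1.0 - min_identity))
    span = math.ceil(qlen * min_coverage)
    return max(4, min(cap, (span - mmax) // (mmax + 1)))


def _scan_query(qenc: np.ndarray, tenc: np.ndarray, min_identity: float,
                min_coverage: float, word: int):
    """All full-query ungapped placements (clipped at edges) meeting the
    identity/coverage thresholds.  Returns list of (start, identity, coverage)."""
    L, T = len(qenc), len(tenc)
    if T < max(word, int(math.ceil(min_coverage * L))):
        return []
    mmax = math.floor(L * (1.0 - min_identity))
    # seed table over the transcript
    valid = tenc < 4
    code = np.zeros(T - word + 1, dtype=np.int64)
    ok = np.ones(T - word + 1, dtype=bool)
    t64 = tenc.astype(np.int64)
    for j in range(word):
        code = code * 4 + t64[j : T - word + 1 + j]
        ok &= valid[j : T - word + 1 + j]
    order = np.argsort(code[ok], kind="stable")
    codes_sorted = code[ok][order]
    pos_sorted = np.nonzero(ok)[0][order]
    # query seeds at every offset
    starts = set()
    q64 = qenc.astype(np.int64)
    for off in range(0, L - word + 1):
        win = q64[off : off + word]
        if (win >= 4).any():
            continue
        c = 0
        for b in win:
            c = c * 4 + int(b)
        lo = int(np.searchsorted(codes_sorted, c, side="left"))
        hi = int(np.searchsorted(codes_sorted, c, side="right"))
        for p in pos_sorted[lo:hi]:
            starts.add(int(p) - off)
    hits = []
    min_span = int(math.ceil(min_coverage * L))
    for s in sorted(starts):
        lo = max(0, s)
        hi = min(T, s + L)
        span = hi - lo
        if span < min_span:
            continue
        q_slice = qenc[lo - s : hi - s]
        t_slice = tenc[lo:hi]
        matches = int(((q_slice == t_slice) & (t_slice < 4)).sum())
        identity = matches / span
        if identity >= min_identity:
            hits.append((s, identity, span / L))
    return hits


def search_homologs(
    queries: list[SequenceRecord],
    transcriptome: list[SequenceRecord],
    cfg: HomologyConfig | None = None,
    disc_cfg: DiscoveryConfig | None = None,
    fold_backend=None,
) -> list[HomologyHit]:
    """Search precursor/mature queries against a transcriptome FASTA.

    Queries of 40 nt or more are treated as precursors (validated by hairpin
    evaluation when they carry a ``mature=`` annotation); shorter queries are
    mature-only and reported without validation.  Empty transcriptome ->
    empty result.
    """
    cfg = cfg or HomologyConfig()
    disc_cfg = disc_cfg or DiscoveryConfig()
    hits: list[HomologyHit] = []
    t_enc = [(t, encode_dna(t.sequence), encode_dna(revcomp(t.sequence)))
             for t in transcriptome]
    for q in queries:
        qenc = encode_dna(q.sequence)
        kind = "precursor" if len(q.sequence) >= 40 else "mature_only"
        word = _word_size(len(qenc), cfg.min_identity, cfg.min_coverage, cfg.word_size)
        mature_iv = _mature_annotation(q) if kind == "precursor" else None
        for trec, fwd, rev in t_enc:
            T = len(fwd)
            for strand, enc in (("+", fwd), ("-", rev)):
                for s, ident, cov in _scan_query(qenc, enc, cfg.min_identity,
                                                 cfg.min_coverage, word):
                    lo, hi = max(0, s), min(T, s + len(qenc))
                    if strand == "-":
                        f_lo, f_hi = T - hi, T - lo
                    else:
                        f_lo, f_hi = lo, hi
                    hit = HomologyHit(
                        query=q.id, transcript=trec.id, start=f_lo, end=f_hi,
                        strand=strand, identity=round(ident, 4),
                        coverage=round(cov, 4), query_kind=kind,
                    )
                    if kind == "precursor" and mature_iv is not None:
                        m_lo, m_hi = mature_iv
                        # mature position mapped through the ungapped alignment
                        off = lo - s
                        sub_lo, sub_hi = m_lo - off, m_hi - off
                        if 0 <= sub_lo and sub_hi <= hi - lo:
                            region = (trec.sequence if strand == "+"
                                      else revcomp(trec.sequence))[lo:hi]
                            window = CandidateWindow(
                                chrom=trec.id, start=f_lo, end=f_hi,
                                strand=strand, sequence=region,
                                tag_offset=sub_lo, tag_len=m_hi - m_lo,
                                tag_id=q.id,
                            )
                            cand = evaluate_candidate(window, disc_cfg,
                                                      fold_backend=fold_backend)
                            hit.candidate = cand
                            hit.validated = cand.verdict == "ACCEPT"
                    hits.append(hit)
    hits.sort(key=lambda h: (h.query, h.transcript, h.start, h.strand))
    return hits


def presence_table(hits: list[HomologyHit], mature_counts: dict[str, tuple[int, int]]):
    """Partition validated hits by library presence (control only / treated
    only / both / neither) given per-query mature tag counts."""
    out = {}
    for h in hits:
        if not h.validated:
            continue
        cc, ct = mature_counts.get(h.query, (0, 0))
        if cc and ct:
            out[h.query] = "both"
        elif cc:
            out[h.query] = "control_only"
        elif ct:
            out[h.query] = "treated_only"
        else:
            out[h.query] = "neither"
    return out
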