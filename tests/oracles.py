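"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (exhaustive enumeration, sliding-window
scans, exact rational arithmetic) and shares no code path with the package
implementations it checks, except for the published scoring tables that
define the respective models.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from saltmir.folding import MIN_HAIRPIN, score_structure

_CANPAIR = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enumerate_structures(seq: str):
    """Yield every non-crossing pair map with hairpin loops >= 3 nt."""
    n = len(seq)

    def rec(positions):
        if not positions:
            yield []
            return
        i = positions[0]
        rest = positions[1:]
        # i unpaired
        yield from rec(rest)
        for idx, k in enumerate(rest):
            if k - i > MIN_HAIRPIN and seq[i] + seq[k] in _CANPAIR:
                inner = [p for p in rest if i < p < k]
                outer = [p for p in rest if p > k]
                for a in rec(inner):
                    for b in rec(outer):
                        yield [(i, k)] + a + b

    for plist in rec(list(range(n))):
        pm = np.full(n, -1, dtype=np.int64)
        for a, b in plist:
            pm[a], pm[b] = b, a
        yield pm


def min_energy_by_enumeration(seq: str) -> float:
    best = 0.0
    for pm in enumerate_structures(seq):
        e = score_structure(seq, pm)
        if e < best:
            best = e
    return best


def brute_force_map(genome: dict[str, str], tag: str, max_mismatch: int = 2):
    """All ungapped placements of a tag (both strands) by sliding Hamming scan.

    Returns a set of (chrom, start, strand, mismatches).  N never matches.
    """
    from saltmir.iofmt import revcomp

    out = set()
    L = len(tag)
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        for chrom, seq in genome.items():
            for s in range(0, len(seq) - L + 1):
                window = seq[s : s + L]
                mism = sum(
                    1 for a, b in zip(query, window)
                    if a != b or a == "N" or b == "N"
                )
                if mism <= max_mismatch:
                    out.add((chrom, s, strand, mism))
    return out


def audic_claverie_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided tail p-value by direct term accumulation (no vectorised
    log-sum-exp): twice the smaller of the two conditional lower tails."""

    def lower_tail(a, b, f):
        logf, log1pf = math.log(f), math.log1p(f)
        return sum(
            math.exp(
                k * logf
                + math.lgamma(a + k + 1)
                - math.lgamma(a + 1)
                - math.lgamma(k + 1)
                - (a + k + 1) * log1pf
            )
            for k in range(0, b + 1)
        )

    lower = lower_tail(x, y, n2 / n1)
    upper = lower_tail(y, x, n1 / n2)
    return min(1.0, 2.0 * min(lower, upper))


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for a hypergeometric(N, K, n), in exact rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return total


def brute_force_target_scan(mirna: str, transcript: str, cfg=None):
    """Best expectation per site end by scoring every window explicitly."""
    from saltmir.config import TargetConfig
    from saltmir.targets import score_duplex

    cfg = cfg or TargetConfig()
    L = len(mirna)
    best = {}
    for e in range(1, len(transcript) + 1):
        scores = []
        for d in range(L - cfg.max_gaps, L + cfg.max_gaps + 1):
            s = e - d
            if s < 0 or d < 1:
                continue
            expectation, _, _, _ = score_duplex(mirna, transcript[s:e], cfg)
            scores.append(expectation)
        if scores:
            best[e] = min(scores)
    return best
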