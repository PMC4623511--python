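"""RNA secondary-structure prediction by nearest-neighbour free-energy minimisation.

The bundled backend is a Zuker-style dynamic program over a compiled-in
integer parameter table (units of 0.01 kcal/mol at 37 degC): Watson-Crick and
G:U stacking energies, length-dependent hairpin/bulge/internal-loop
penalties with logarithmic extrapolation and a Ninio asymmetry term, and an
affine multibranch-loop model.  The DP is guaranteed optimal under its own
table: for any sequence, ``fold(seq).mfe`` equals the minimum of
:func:`score_structure` over all non-crossing structures with hairpin loops
of at least 3 nt (the exhaustive-enumeration property exercised in the test
suite on short sequences).

The model deliberately omits dangling ends, coaxial stacking and special
tetraloop bonuses; absolute energies therefore approximate, rather than
reproduce, full thermodynamic folders.  ViennaRNA (if importable) can be
selected as an alternative backend; the acceptance thresholds (e.g. the
-18 kcal/mol precursor cutoff) apply to whichever backend is configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Parameter table (integer centi-kcal/mol)
# ---------------------------------------------------------------------------

INF = 1 << 28
MIN_HAIRPIN = 3        # smallest hairpin loop, nt
MAXLOOP = 30           # largest bulge/internal loop (total unpaired nt)
_TABLE_LEN = 2048      # longest sequence the bundled backend accepts

BASES = "ACGU"
_ENC = {b: i for i, b in enumerate(BASES)}

# pair type indices: CG GC UA AU GU UG ; -1 = cannot pair
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _i, (_a, _b) in enumerate([("C", "G"), ("G", "C"), ("U", "A"), ("A", "U"), ("G", "U"), ("U", "G")]):
    _PAIR_TYPE[_ENC[_a], _ENC[_b]] = _i

# stacking energies, outer pair (row) on inner pair (column)
_STACK = np.array(
    [
        # CG    GC    UA    AU    GU    UG
        [-330, -340, -210, -240, -210, -140],   # CG
        [-240, -330, -210, -220, -250, -150],   # GC
        [-210, -230, -90, -110, -90, -100],     # UA
        [-220, -240, -130, -90, -60, -140],     # AU
        [-150, -250, -100, -140, -50, -40],     # GU
        [-140, -210, -60, -90, -40, -50],       # UG
    ],
    dtype=np.int64,
)

_LXC = 107.86          # 1.75 * RT at 37 degC, centi-kcal, for loop extrapolation


def _loop_tables(n: int = _TABLE_LEN):
    hairpin = np.full(n, INF, dtype=np.int64)
    bulge = np.full(n, INF, dtype=np.int64)
    internal = np.full(n, INF, dtype=np.int64)
    h_small = {3: 540, 4: 560, 5: 570, 6: 540, 7: 600, 8: 550, 9: 640}
    b_small = {1: 380, 2: 280, 3: 320, 4: 360, 5: 400, 6: 440}
    i_small = {2: 170, 3: 180, 4: 200, 5: 220, 6: 230}
    for size in range(3, n):
        hairpin[size] = h_small.get(size) or int(round(640 + _LXC * math.log(size / 9)))
    for size in range(1, n):
        bulge[size] = b_small.get(size) or int(round(440 + _LXC * math.log(size / 6)))
    for size in range(2, n):
        internal[size] = i_small.get(size) or int(round(230 + _LXC * math.log(size / 6)))
    return hairpin, bulge, internal


_HAIRPIN, _BULGE, _INTERNAL = _loop_tables()

ML_CLOSE = 340         # multibranch loop closing penalty
ML_BRANCH = 40         # per branch (closing pair counts as one branch)
ML_UNPAIRED = 10       # per unpaired nt inside a multibranch loop
NINIO = 48             # internal-loop asymmetry, per nt
NINIO_MAX = 300


class FoldError(ValueError):
    """Raised for sequences the folding backend cannot handle."""


@dataclass(frozen=True)
class FoldResult:
    """Dot-bracket structure and minimum free energy (kcal/mol)."""

    structure: str
    mfe: float

    def pair_map(self) -> np.ndarray:
        return pairs_from_dotbracket(self.structure)


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA string as ints (A=0 C=1 G=2 U=3); invalid letters error."""
    try:
        return np.array([_ENC[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise FoldError(f"invalid RNA base {exc.args[0]!r} (alphabet ACGU)") from None


def pairs_from_dotbracket(structure: str) -> np.ndarray:
    """Pair map: partner index per position, -1 if unpaired.  Errors on imbalance."""
    pairs = np.full(len(structure), -1, dtype=np.int64)
    stack = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FoldError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise FoldError(f"invalid structure character {ch!r}")
    if stack:
        raise FoldError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def dotbracket_from_pairs(pairs) -> str:
    out = []
    for i, j in enumerate(pairs):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


# ---------------------------------------------------------------------------
# Reference scorer (defines the energy model)
# ---------------------------------------------------------------------------

def _interior_energy(pt_outer: int, pt_inner: int, n1: int, n2: int) -> int:
    """Energy of the loop closed by an outer pair with exactly one inner pair."""
    if n1 == 0 and n2 == 0:
        return int(_STACK[pt_outer, pt_inner])
    if n1 + n2 > MAXLOOP:
        return INF
    if n1 == 0 or n2 == 0:
        return int(_BULGE[n1 + n2])
    asym = min(NINIO_MAX, NINIO * abs(n1 - n2))
    return int(_INTERNAL[n1 + n2]) + asym


def score_structure(seq: str, structure) -> float:
    """Free energy (kcal/mol) of a given structure under the bundled table.

    ``structure`` is a dot-bracket string or a pair map.  Non-canonical pairs
    and hairpin loops < 3 nt score +inf.  This is the model definition: the
    DP below returns the minimum of this function over all structures.
    """
    pairs = (
        pairs_from_dotbracket(structure) if isinstance(structure, str) else np.asarray(structure)
    )
    enc = encode_rna(seq)
    n = len(enc)
    total = 0
    for i in range(n):
        j = pairs[i]
        if j <= i:
            continue
        pt = _PAIR_TYPE[enc[i], enc[j]]
        if pt < 0:
            return math.inf
        # walk the loop closed by (i, j)
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            elif pairs[k] == -1:
                unpaired += 1
                k += 1
            else:
                return math.inf   # malformed (crossing) structure
        if not children:
            loop = j - i - 1
            if loop < MIN_HAIRPIN:
                return math.inf
            total += int(_HAIRPIN[loop])
        elif len(children) == 1:
            (k1, l1) = children[0]
            pt_in = _PAIR_TYPE[enc[k1], enc[l1]]
            e = _interior_energy(pt, pt_in, k1 - i - 1, j - l1 - 1)
            if e >= INF:
                return math.inf
            total += e
        else:
            total += ML_CLOSE + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired
    return total / 100.0


# ---------------------------------------------------------------------------
# Dynamic program (numba kernel) + traceback
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill(enc, ptab, stack_e, hairpin_e, bulge_e, internal_e):
    n = enc.size
    V = np.full((n, n), INF, dtype=np.int64)
    M = np.full((n, n), INF, dtype=np.int64)
    M1 = np.full((n, n), INF, dtype=np.int64)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            pt = ptab[enc[i], enc[j]]
            if pt >= 0:
                best = hairpin_e[span - 1]
                # stack / bulge / internal loop with inner pair (k, l)
                kmax = min(i + 2 + MAXLOOP, j - MIN_HAIRPIN - 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - n1))
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        pt_in = ptab[enc[k], enc[l]]
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            e = stack_e[pt, pt_in]
                        elif n1 == 0 or n2 == 0:
                            e = bulge_e[n1 + n2]
                        else:
                            asym = NINIO * abs(n1 - n2)
                            if asym > NINIO_MAX:
                                asym = NINIO_MAX
                            e = internal_e[n1 + n2] + asym
                        cand = V[k, l] + e
                        if cand < best:
                            best = cand
                # multibranch loop: >= 2 branches inside
                for k in range(i + 2, j - MIN_HAIRPIN - 1):
                    if M[i + 1, k - 1] < INF and M1[k, j - 1] < INF:
                        cand = ML_CLOSE + ML_BRANCH + M[i + 1, k - 1] + M1[k, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M1: exactly one branch starting at i, optional trailing unpaired
            best1 = INF
            if V[i, j] < INF:
                best1 = V[i, j] + ML_BRANCH
            if j > i and M1[i, j - 1] < INF:
                cand = M1[i, j - 1] + ML_UNPAIRED
                if cand < best1:
                    best1 = cand
            M1[i, j] = best1
            # M: one or more branches
            bestm = best1
            if M[i + 1, j] < INF:
                cand = M[i + 1, j] + ML_UNPAIRED
                if cand < bestm:
                    bestm = cand
            for k in range(i + 1, j):
                if M[i, k - 1] < INF and M1[k, j] < INF:
                    cand = M[i, k - 1] + M1[k, j]
                    if cand < bestm:
                        bestm = cand
            M[i, j] = bestm
    # external loop
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(j - 1):
            if V[i, j - 1] < INF:
                cand = W[i] + V[i, j - 1]
                if cand < best:
                    best = cand
        W[j] = best
    return V, M, M1, W


def _traceback(enc, V, M, M1, W):
    n = enc.size
    pairs = np.full(n, -1, dtype=np.int64)
    tasks = [("W", n)]
    while tasks:
        task = tasks.pop()
        kind = task[0]
        if kind == "W":
            j = task[1]
            if j == 0:
                continue
            if W[j] == W[j - 1]:
                tasks.append(("W", j - 1))
                continue
            for i in range(j - 1):
                if V[i, j - 1] < INF and W[j] == W[i] + V[i, j - 1]:
                    tasks.append(("W", i))
                    tasks.append(("V", i, j - 1))
                    break
        elif kind == "V":
            i, j = task[1], task[2]
            pairs[i], pairs[j] = j, i
            pt = _PAIR_TYPE[enc[i], enc[j]]
            if V[i, j] == _HAIRPIN[j - i - 1]:
                continue
            found = False
            kmax = min(i + 2 + MAXLOOP, j - MIN_HAIRPIN - 1)
            for k in range(i + 1, kmax + 1):
                if found:
                    break
                n1 = k - i - 1
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - n1))
                for l in range(lmin, j):
                    if V[k, l] >= INF:
                        continue
                    pt_in = _PAIR_TYPE[enc[k], enc[l]]
                    n2 = j - l - 1
                    e = _interior_energy(pt, pt_in, n1, n2)
                    if e < INF and V[i, j] == V[k, l] + e:
                        tasks.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            for k in range(i + 2, j - MIN_HAIRPIN - 1):
                if (
                    M[i + 1, k - 1] < INF
                    and M1[k, j - 1] < INF
                    and V[i, j] == ML_CLOSE + ML_BRANCH + M[i + 1, k - 1] + M1[k, j - 1]
                ):
                    tasks.append(("M", i + 1, k - 1))
                    tasks.append(("M1", k, j - 1))
                    break
        elif kind == "M1":
            i, j = task[1], task[2]
            if j > i and M1[i, j - 1] < INF and M1[i, j] == M1[i, j - 1] + ML_UNPAIRED:
                tasks.append(("M1", i, j - 1))
            else:
                tasks.append(("V", i, j))
        else:  # M
            i, j = task[1], task[2]
            if M[i, j] == M1[i, j]:
                tasks.append(("M1", i, j))
                continue
            if M[i + 1, j] < INF and M[i, j] == M[i + 1, j] + ML_UNPAIRED:
                tasks.append(("M", i + 1, j))
                continue
            for k in range(i + 1, j):
                if M[i, k - 1] < INF and M1[k, j] < INF and M[i, j] == M[i, k - 1] + M1[k, j]:
                    tasks.append(("M", i, k - 1))
                    tasks.append(("M1", k, j))
                    break
    return pairs


@lru_cache(maxsize=4096)
def _fold_nn_cached(seq: str) -> FoldResult:
    enc = encode_rna(seq)
    n = len(enc)
    if n < MIN_HAIRPIN + 2:
        return FoldResult("." * n, 0.0)
    V, M, M1, W = _fill(enc, _PAIR_TYPE, _STACK, _HAIRPIN, _BULGE, _INTERNAL)
    mfe = int(W[n])
    if mfe >= 0:
        return FoldResult("." * n, 0.0)
    pairs = _traceback(enc, V, M, M1, W)
    return FoldResult(dotbracket_from_pairs(pairs), mfe / 100.0)


def _fold_vienna(seq: str) -> FoldResult:
    try:
        import RNA
    except ImportError as exc:   # pragma: no cover - environment dependent
        raise FoldError("ViennaRNA python bindings not available") from exc
    structure, mfe = RNA.fold(seq)
    return FoldResult(structure, float(mfe))


def fold(seq: str, backend="nn") -> FoldResult:
    """Fold an RNA sequence; returns dot-bracket structure and MFE (kcal/mol).

    ``backend`` is ``"nn"`` (bundled nearest-neighbour DP, default),
    ``"vienna"`` (ViennaRNA, if installed) or any callable
    ``seq -> FoldResult``.
    """
    seq = str(seq)
    if not seq:
        raise FoldError("empty sequence")
    if callable(backend):
        result = backend(seq)
        if len(result.structure) != len(seq):
            raise FoldError("backend returned structure of wrong length")
        pairs_from_dotbracket(result.structure)   # validity check
        return result
    if backend == "nn":
        if len(seq) > _TABLE_LEN:
            raise FoldError(f"sequence longer than {_TABLE_LEN} nt")
        return _fold_nn_cached(seq)
    if backend == "vienna":
        return _fold_vienna(seq)
    raise FoldError(f"unknown folding backend {backend!r}")
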