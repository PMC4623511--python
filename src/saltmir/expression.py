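"""Differential expression of sequencing-tag counts between two libraries.

Counts are normalised to tags per million (TPM = count / library total x 1e6),
fold-change is log2(treated / control) on TPMs (a small floor stands in for
zeros), and significance comes from the Audic-Claverie exact test for the
comparison of two counts under Poisson sampling:

    P(k | x) = (N2/N1)^k * (x + k)! / (x! k! (1 + N2/N1)^(x + k + 1))

summed in log-space over the two tails; the two-sided p-value is twice the
smaller tail (capped at 1).  A miRNA is called up-regulated at
log2FC >= 1 and P <= 0.05, down-regulated at log2FC <= -1 and P <= 0.05
(boundaries inclusive), neutral otherwise.  Raw p-values drive the calls;
Benjamini-Hochberg q-values are reported alongside.

A comparative-Ct (2^-ddCt) utility supports qRT-PCR cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionRecord:
    mirna: str
    kind: str                 # known / novel
    count_control: int
    count_treated: int
    n_control: int
    n_treated: int
    tpm_control: float
    tpm_treated: float
    log2fc: float
    pvalue: float
    qvalue: float = float("nan")
    call: str = "neutral"


@dataclass
class CtRecord:
    """One qRT-PCR well: target and reference (U6) Ct for a sample replicate."""

    mirna: str
    sample: str               # control / treated
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ExpressionError("Ct values must be positive")


def normalize_tpm(count: int, library_total: int) -> float:
    """Tags per million: count / library_total x 1e6 (zeros stay zero here)."""
    if library_total <= 0:
        raise ExpressionError("library_total must be > 0")
    if count < 0:
        raise ExpressionError("negative count")
    return count / library_total * 1_000_000.0


def log2_fold_change(tpm_treated: float, tpm_control: float,
                     zero_floor: float = 0.01) -> float:
    """log2(treated / control) with the zero floor applied to both arguments."""
    if tpm_treated < 0 or tpm_control < 0:
        raise ExpressionError("negative TPM")
    return math.log2(max(tpm_treated, zero_floor) / max(tpm_control, zero_floor))


def _log_pmf(k: np.ndarray, x: int, log_f: float, log_1pf: float) -> np.ndarray:
    return (
        k * log_f
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log_1pf
    )


def _lower_tail(x: int, y: int, n1: int, n2: int) -> float:
    """P(K <= y | x) under the Audic-Claverie predictive distribution."""
    f = n2 / n1
    ks = np.arange(0, y + 1)
    log_lower = float(logsumexp(_log_pmf(ks, x, math.log(f), math.log1p(f))))
    return math.exp(min(0.0, log_lower))


def count_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie exact p-value for counts x (library 1, total
    n1) vs y (library 2, total n2), computed by log-space tail summation.

    The two tails are the lower tails of the two conditionings,
    P(K <= y | x) and P(K <= x | y); these sum exactly to 1, so the doubled
    minimum is exchange-symmetric: p(x, y, n1, n2) == p(y, x, n2, n1).
    The observed count is assigned to one tail only.
    """
    if x < 0 or y < 0:
        raise ExpressionError("negative counts")
    if n1 <= 0 or n2 <= 0:
        raise ExpressionError("library totals must be > 0")
    lower = _lower_tail(x, y, n1, n2)
    upper = _lower_tail(y, x, n2, n1)    # == P(K >= y | x) + P(y|x) complement
    return min(1.0, 2.0 * min(lower, upper))


def classify(log2fc: float, pvalue: float, up: float = 1.0, down: float = -1.0,
             max_p: float = 0.05) -> str:
    """Up / down / neutral call; thresholds applied with inclusive boundaries."""
    if pvalue <= max_p:
        if log2fc >= up:
            return "up"
        if log2fc <= down:
            return "down"
    return "neutral"


def bh_qvalues(pvalues) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: dict[str, tuple[int, int]],
    n_control: int,
    n_treated: int,
    kinds: dict[str, str] | None = None,
    zero_floor: float = 0.01,
    up: float = 1.0,
    down: float = -1.0,
    max_p: float = 0.05,
) -> list[ExpressionRecord]:
    """Full DE analysis for a set of miRNAs with (control, treated) counts."""
    kinds = kinds or {}
    records = []
    for name in sorted(counts):
        cc, ct = counts[name]
        tpm_c = normalize_tpm(cc, n_control)
        tpm_t = normalize_tpm(ct, n_treated)
        lfc = log2_fold_change(tpm_t, tpm_c, zero_floor)
        p = count_pvalue(cc, ct, n_control, n_treated)
        records.append(
            ExpressionRecord(
                mirna=name,
                kind=kinds.get(name, ""),
                count_control=cc,
                count_treated=ct,
                n_control=n_control,
                n_treated=n_treated,
                tpm_control=round(tpm_c, 4),
                tpm_treated=round(tpm_t, 4),
                log2fc=round(lfc, 4),
                pvalue=p,
            )
        )
    qvals = bh_qvalues([r.pvalue for r in records])
    for rec, q in zip(records, qvals):
        rec.qvalue = float(q)
        rec.call = classify(rec.log2fc, rec.pvalue, up, down, max_p)
    return records


def relative_quantity(ct_records: list[CtRecord]):
    """Comparative-Ct relative quantification (RQ = 2^-ddCt) per target.

    dCt = Ct_target - Ct_reference within each sample (replicates averaged on
    the Ct scale); ddCt = dCt(treated) - dCt(control); the replicate standard
    deviations of the dCt values propagate in quadrature.
    Returns ``{mirna: {"rq": ..., "ddct": ..., "sd": ...}}``.
    """
    by_target: dict[str, dict[str, list[float]]] = {}
    for rec in ct_records:
        if rec.sample not in ("control", "treated"):
            raise ExpressionError(f"unknown sample {rec.sample!r}")
        by_target.setdefault(rec.mirna, {"control": [], "treated": []})[
            rec.sample
        ].append(rec.ct_target - rec.ct_reference)
    out = {}
    for mirna, groups in sorted(by_target.items()):
        if not groups["control"] or not groups["treated"]:
            raise ExpressionError(f"{mirna}: both samples need at least one replicate")
        dct_c = float(np.mean(groups["control"]))
        dct_t = float(np.mean(groups["treated"]))
        sd = math.sqrt(
            float(np.var(groups["control"], ddof=0))
            + float(np.var(groups["treated"], ddof=0))
        )
        ddct = dct_t - dct_c
        out[mirna] = {"rq": 2.0 ** (-ddct), "ddct": ddct, "sd": sd}
    return out
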