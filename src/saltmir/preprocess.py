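"""Raw-read cleaning and tag collapsing.

Reads are filtered by seven ordered elimination rules — (i) low quality,
(ii) 5' primer contaminant, (iii) missing 3' adapter, (iv) missing insert,
(v) poly-A insert, (vi) insert length outside 16-36 nt — each read being
charged to the FIRST rule it violates, then adapter-trimmed and collapsed to
unique tags with per-library counts.  Every raw read is accounted for exactly
once (clean, or one removal rule).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .config import CleaningConfig
from .iofmt import ReadRecord

REMOVAL_RULES = (
    "low_quality",
    "adapter5_contaminant",
    "no_adapter3",
    "no_insert",
    "polyA",
    "length_out_of_range",
)


@dataclass
class CleaningStats:
    """Per-library read accounting through the cleaning rules."""

    raw_reads: int = 0
    removed: dict = field(default_factory=lambda: {rule: 0 for rule in REMOVAL_RULES})
    clean_reads: int = 0
    unique_tags: int = 0

    def check_conservation(self) -> bool:
        return self.raw_reads == self.clean_reads + sum(self.removed.values())

    def as_rows(self):
        rows = [("raw_reads", self.raw_reads)]
        rows += [(f"removed_{rule}", n) for rule, n in self.removed.items()]
        rows += [("clean_reads", self.clean_reads), ("unique_tags", self.unique_tags)]
        return rows


@dataclass(frozen=True)
class SmallRNATag:
    """A unique cleaned insert sequence with per-library counts."""

    tag_id: str
    sequence: str
    count_control: int
    count_treated: int

    def __post_init__(self):
        if self.count_control < 0 or self.count_treated < 0:
            raise ValueError("negative tag count")
        if self.count_control + self.count_treated < 1:
            raise ValueError("tag with zero total count")

    @property
    def total(self) -> int:
        return self.count_control + self.count_treated


@dataclass
class TagSet:
    tags: list[SmallRNATag]
    clean_control: int
    clean_treated: int

    def __iter__(self) -> Iterator[SmallRNATag]:
        return iter(self.tags)

    def __len__(self) -> int:
        return len(self.tags)

    def by_sequence(self) -> dict[str, SmallRNATag]:
        return {t.sequence: t for t in self.tags}


def _find_adapter3(seq: str, adapter: str, cfg: CleaningConfig) -> int:
    """Leftmost start of the 3' adapter, trying prefixes of decreasing length.

    Longest prefix wins; within a prefix length the leftmost occurrence wins.
    Returns -1 if no prefix of at least ``adapter3_min_prefix`` nt is found.
    """
    top = min(cfg.adapter3_max_prefix, len(adapter))
    for plen in range(top, cfg.adapter3_min_prefix - 1, -1):
        pos = seq.find(adapter[:plen])
        if pos >= 0:
            return pos
    return -1


def _is_adapter5_contaminant(seq: str, cfg: CleaningConfig) -> bool:
    prefix = cfg.adapter5[: cfg.adapter5_prefix]
    if len(seq) < len(prefix) or len(prefix) < cfg.adapter5_prefix:
        return False
    mismatches = sum(a != b for a, b in zip(seq, prefix))
    return mismatches <= cfg.adapter5_mismatches


def classify_read(read: ReadRecord, cfg: CleaningConfig):
    """Return ``(rule_name, None)`` for a removed read or ``(None, insert)``.

    Rules are tested in the published order (i)->(vi); the first violated
    rule is charged.
    """
    qual = read.quality
    if qual:
        mean_q = sum(qual) / len(qual)
        frac_low = sum(q < 10 for q in qual) / len(qual)
    else:
        mean_q, frac_low = 0.0, 1.0
    if mean_q < cfg.min_mean_phred or frac_low > cfg.max_frac_below_q10:
        return "low_quality", None
    if _is_adapter5_contaminant(read.sequence, cfg):
        return "adapter5_contaminant", None
    pos = _find_adapter3(read.sequence, cfg.adapter3, cfg)
    if pos < 0:
        return "no_adapter3", None
    insert = read.sequence[:pos]
    if len(insert) == 0:
        return "no_insert", None
    if insert.count("A") / len(insert) >= cfg.polya_fraction:
        return "polyA", None
    if not (cfg.min_len <= len(insert) <= cfg.max_len):
        return "length_out_of_range", None
    return None, insert


def clean_reads(reads: Iterable[ReadRecord], cfg: CleaningConfig | None = None):
    """Apply the elimination rules; returns ``(list of clean inserts, CleaningStats)``."""
    cfg = cfg or CleaningConfig()
    stats = CleaningStats()
    inserts: list[str] = []
    for read in reads:
        stats.raw_reads += 1
        rule, insert = classify_read(read, cfg)
        if rule is None:
            inserts.append(insert)
            stats.clean_reads += 1
        else:
            stats.removed[rule] += 1
    stats.unique_tags = len(set(inserts))
    assert stats.check_conservation()
    return inserts, stats


def collapse_tags(control_inserts: Iterable[str], treated_inserts: Iterable[str]) -> TagSet:
    """Collapse cleaned inserts from both libraries into unique counted tags.

    Tag ids are assigned in lexicographic sequence order (deterministic).
    """
    control = Counter(control_inserts)
    treated = Counter(treated_inserts)
    tags = []
    for idx, seq in enumerate(sorted(set(control) | set(treated)), 1):
        tags.append(
            SmallRNATag(
                tag_id=f"tag{idx:06d}",
                sequence=seq,
                count_control=control.get(seq, 0),
                count_treated=treated.get(seq, 0),
            )
        )
    return TagSet(
        tags=tags,
        clean_control=sum(control.values()),
        clean_treated=sum(treated.values()),
    )


def length_distribution(tagset: TagSet, min_len: int = 16, max_len: int = 36) -> dict[int, int]:
    """Clean-read counts by insert length (weighted by counts, not unique tags)."""
    hist = {length: 0 for length in range(min_len, max_len + 1)}
    for tag in tagset:
        hist.setdefault(len(tag.sequence), 0)
        hist[len(tag.sequence)] += tag.total
    return hist
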