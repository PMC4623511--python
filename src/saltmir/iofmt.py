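"""Readers and writers for the sequence and annotation formats the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere.  GFF3 files and
  human-readable reports use 1-based inclusive coordinates; the conversion
  happens at exactly one point (here).
* DNA is the storage alphabet.  Folding code converts T->U explicitly at its
  boundary; the conversion helpers below never run silently.
* FASTQ is strict 4-line Phred+33.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an input file violates its declared grammar."""


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (DNA or RNA), uppercase, non-empty."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        if seq != self.sequence:
            object.__setattr__(self, "sequence", seq)
        letters = set(seq)
        if not (letters <= DNA_ALPHABET or letters <= RNA_ALPHABET):
            bad = sorted(letters - (DNA_ALPHABET | RNA_ALPHABET))
            raise FormatError(f"record {self.id!r}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self):
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class GeneModel:
    """One mRNA's exon/intron/UTR structure in 0-based half-open coordinates.

    ``introns`` is derived: the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise FormatError(f"{self.gene_id}: empty exon interval [{a},{b})")
        for (_, b), (c, _) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise FormatError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (b, c)
            for (_, b), (c, _) in zip(self.exons, self.exons[1:])
            if c > b
        ]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from a FASTA file (empty file -> empty stream)."""
    with _open_text(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError(f"{path}: sequence data before first FASTA header")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        yield SequenceRecord(id=rec.id, sequence=seq, description=desc)


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (strict 4-line, Phred+33)
# ---------------------------------------------------------------------------

PHRED_OFFSET = 33


def read_fastq(path, phred_offset: int = PHRED_OFFSET) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a strict 4-line FASTQ file.

    Truncated or malformed records raise :class:`FormatError` naming the
    offending line number.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"{path}:{lineno}: truncated FASTQ record {header[1:]!r}")
            lineno += 3
            seq = seq.rstrip("\n").upper()
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            rid = header[1:].split()[0] if len(header) > 1 else ""
            yield ReadRecord(
                id=rid,
                sequence=seq,
                quality=tuple(ord(c) - phred_offset for c in qual),
            )


def write_fastq(path, reads: Iterable[ReadRecord], phred_offset: int = PHRED_OFFSET) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + phred_offset) for q in read.quality)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon/CDS/UTR subset)
# ---------------------------------------------------------------------------

_GENEMODEL_FEATURES = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def _parse_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file into one GeneModel per mRNA.

    GFF3 columns are 1-based inclusive; intervals are converted to 0-based
    half-open here.  An exon outside its gene's span is a format error.
    """
    genes: dict[str, tuple[str, int, int]] = {}      # gene_id -> (chrom, start, end)
    mrnas: dict[str, dict] = {}                      # mrna_id -> skeleton
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
            chrom, _, ftype, start1, end1, _, strand, _, attrs_col = cols
            try:
                start = int(start1) - 1   # 1-based inclusive -> 0-based half-open
                end = int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval {start1}..{end1}")
            attrs = _parse_attributes(attrs_col)
            if ftype == "gene":
                genes[attrs.get("ID", f"gene:{lineno}")] = (chrom, start, end)
            elif ftype == "mRNA":
                mid = attrs.get("ID", f"mRNA:{lineno}")
                mrnas[mid] = {
                    "gene_id": mid,
                    "parent": attrs.get("Parent", ""),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                }
            elif ftype in _GENEMODEL_FEATURES:
                parent = attrs.get("Parent", "")
                if parent not in mrnas:
                    raise FormatError(f"{path}:{lineno}: {ftype} with unknown Parent {parent!r}")
                mrnas[parent][_GENEMODEL_FEATURES[ftype]].append((start, end))

    models = []
    for mid, skel in mrnas.items():
        parent_gene = genes.get(skel["parent"])
        if parent_gene is not None:
            gchrom, gstart, gend = parent_gene
            for a, b in skel["exons"]:
                if a < gstart or b > gend:
                    raise FormatError(
                        f"{path}: exon [{a},{b}) of {mid} outside gene span "
                        f"[{gstart},{gend})"
                    )
        models.append(
            GeneModel(
                gene_id=mid,
                chrom=skel["chrom"],
                strand=skel["strand"],
                exons=skel["exons"],
                cds=sorted(skel["cds"]),
                utr5=sorted(skel["utr5"]),
                utr3=sorted(skel["utr3"]),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.span, m.gene_id))
    return models


def write_gff3(path, models: Sequence[GeneModel], source: str = "saltmir") -> None:
    """Write gene models as GFF3 (gene + mRNA + exon/CDS/UTR rows)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            gene_id = f"{m.gene_id}.gene"
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\t{source}\tmRNA\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent={gene_id}\n"
            )
            for ftype, key in (
                ("exon", "exons"),
                ("CDS", "cds"),
                ("five_prime_UTR", "utr5"),
                ("three_prime_UTR", "utr3"),
            ):
                for a, b in getattr(m, key):
                    fh.write(
                        f"{m.chrom}\t{source}\t{ftype}\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                        f"Parent={m.gene_id}\n"
                    )


# ---------------------------------------------------------------------------
# TSV result tables with '#'-prefixed metadata
# ---------------------------------------------------------------------------

def write_tsv(path, frame, metadata: dict | None = None) -> None:
    """Write a pandas DataFrame as TSV with optional '# key: value' metadata."""
    with _open_text(path, "wt") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
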