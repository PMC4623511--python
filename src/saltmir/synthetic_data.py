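"""Synthetic genome, annotations and differential small-RNA libraries with
a complete ground-truth manifest.

The generator emulates the study design this pipeline targets: a 12-chromosome
plant genome; a miRBase-like reference of known miRNA hairpins planted in the
genome; novel hairpins planted across all genomic contexts (intergenic,
intronic, exonic, 5'UTR, 3'UTR); decoy ncRNA loci (rRNA/tRNA/snoRNA/snRNA/
scRNA) and multi-copy repeats; and two libraries (control vs salt-treated) of
adapter-ligated reads whose clean-length distribution peaks at 24 nt with a
secondary mode at 21 nt, with planted per-miRNA log2 fold-changes and exact
per-rule contaminant counts.

Every generated read is classified through the same cleaning rules the
pipeline applies, and the manifest records what actually went into the
libraries — the manifest is the oracle for all recovery tests.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import CleaningConfig, DiscoveryConfig, SyntheticConfig
from .discovery import CandidateWindow, evaluate_candidate, excise_candidates
from .iofmt import GeneModel, ReadRecord, SequenceRecord, revcomp
from .mapping import TagAlignment
from .preprocess import classify_read

_READ_TAIL = "ATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"

# clean-read insert length profile (the 24-nt dominant / 21-nt secondary modes
# typical of plant small-RNA libraries)
_LENGTH_PROFILE = {
    24: 0.46, 21: 0.08, 22: 0.07, 23: 0.07, 20: 0.07, 19: 0.05, 25: 0.05,
    18: 0.04, 17: 0.03, 16: 0.02, 26: 0.02, 27: 0.015, 28: 0.015,
    29: 0.005, 30: 0.005,
}

_MIRNA_FAMILIES = [156, 160, 164, 166, 167, 169, 171, 172, 319, 390, 393,
                   396, 398, 408, 444, 528, 820, 1425, 1861, 2275]


class SyntheticError(ValueError):
    pass


class ParameterError(SyntheticError):
    pass


class CapacityError(SyntheticError):
    pass


# non-pairing substitution for introducing duplex mismatches (DNA space):
# the replacement can pair neither Watson-Crick nor G:U with the mature base
_NONPAIR = {"A": "C", "C": "A", "G": "A", "T": "C"}


def _rand_dna(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# Hairpin design
# ---------------------------------------------------------------------------

def design_hairpin(
    mature_len: int,
    duplex_mismatches: int,
    loop_len: int,
    rng,
    arm: str = "5p",
    cfg: DiscoveryConfig | None = None,
    au_fraction: float | None = None,
    paired_bp: int | None = None,
    name: str = "hairpin",
    max_attempts: int = 60,
    require_accept: bool = True,
):
    """Design a precursor hairpin that passes candidate evaluation.

    The mature sits on one arm of a designed stem; the star carries the
    canonical 2-nt 3' overhang.  ``duplex_mismatches`` star-side substitutions
    create mismatched duplex positions; ``paired_bp`` (optional) shortens the
    stem to an exact duplex pair count; ``au_fraction`` (optional) targets an
    exact precursor A+U fraction.  The design is validated by the discovery
    module itself (rejection sampling, bounded attempts).

    Returns ``(precursor SequenceRecord, mature interval, star interval, arm)``
    in precursor coordinates (DNA storage alphabet).
    """
    cfg = cfg or DiscoveryConfig()
    if not (cfg.min_mature_len <= mature_len <= cfg.max_mature_len):
        raise ParameterError(f"mature length {mature_len} outside "
                             f"{cfg.min_mature_len}-{cfg.max_mature_len}")
    if duplex_mismatches > cfg.max_duplex_mismatch:
        raise ParameterError(
            f"duplex_mismatches {duplex_mismatches} > configured maximum "
            f"{cfg.max_duplex_mismatch}"
        )
    if loop_len < 3:
        raise ParameterError("loop_len must be >= 3")
    if arm not in ("5p", "3p"):
        raise ParameterError("arm must be '5p' or '3p'")
    stem = mature_len if paired_bp is None else int(paired_bp)
    if stem > mature_len - 2 and paired_bp is not None:
        raise ParameterError("paired_bp cannot exceed mature_len - 2")
    if au_fraction is not None and paired_bp is not None:
        raise ParameterError("au_fraction and paired_bp cannot be combined")

    flank5 = flank3 = 5
    for attempt in range(max_attempts):
        if au_fraction is None:
            mature = _rand_dna(rng, mature_len, gc=0.60)
            if stem < mature_len:
                # non-pairing tail (the mature 3'-overhang positions), so the
                # duplex pair count equals the designed stem exactly
                tail = "".join(rng.choice(list("AC"), size=mature_len - stem))
                mature = mature[:stem] + tail
            f5 = "".join(rng.choice(list("AC"), size=flank5))
            f3 = "".join(rng.choice(list("AC"), size=flank3))
            loop = "".join(rng.choice(list("AC"), size=loop_len))
        else:
            n_total = flank5 + flank3 + loop_len + mature_len + stem
            target = int(round(au_fraction * n_total))
            free = flank5 + flank3 + loop_len + (mature_len - stem)
            # a = AT pairs in the stem; the rest of the AU budget goes to
            # unpaired A's (flanks/loop are drawn from {A, C})
            a = max(0, min(stem, math.ceil((target - free) / 2)))
            k = target - 2 * a
            if not (0 <= k <= free):
                raise ParameterError(
                    f"A+U fraction {au_fraction} unattainable at this geometry"
                )
            kinds = ["AT"] * a + ["GC"] * (stem - a)
            kinds = [kinds[i] for i in rng.permutation(stem)]
            bases = []
            for i, kind in enumerate(kinds):
                bases.append(("A" if i % 2 else "T") if kind == "AT"
                             else ("G" if i % 2 else "C"))
            mature = "".join(bases) + "T" * (mature_len - stem)
            freebases = ["A"] * k + ["C"] * (free - (mature_len - stem) - k)
            freebases = [freebases[i] for i in rng.permutation(len(freebases))]
            f5 = "".join(freebases[:flank5])
            f3 = "".join(freebases[flank5 : flank5 + flank3])
            loop = "".join(freebases[flank5 + flank3 :])
            if len(loop) != loop_len:
                raise ParameterError("A+U fraction infeasible for these lengths")

        pair_region = revcomp(mature[:stem])
        if duplex_mismatches:
            positions = rng.choice(
                np.arange(3, stem - 4), size=duplex_mismatches, replace=False
            )
            pr = list(pair_region)
            for p in sorted(int(x) for x in positions):
                # pair_region index pairing mature position p is stem-1-p
                pr[stem - 1 - p] = _NONPAIR[mature[p]]
            pair_region = "".join(pr)

        if arm == "5p":
            precursor = f5 + mature + loop + pair_region + f3
            mature_iv = (flank5, flank5 + mature_len)
        else:
            precursor = f5 + pair_region + loop + mature + f3
            mature_iv = (flank5 + stem + loop_len, flank5 + stem + loop_len + mature_len)

        window = CandidateWindow(
            chrom=name, start=0, end=len(precursor), strand="+",
            sequence=precursor, tag_offset=mature_iv[0], tag_len=mature_len,
            tag_id=name,
        )
        cand = evaluate_candidate(window, cfg)
        ok = cand.verdict == "ACCEPT" if require_accept else cand.star is not None
        if ok and cand.sequence == precursor and cand.mature == mature_iv:
            rec = SequenceRecord(
                id=name,
                sequence=precursor,
                description=f"mature={mature_iv[0] + 1}-{mature_iv[1]} arm={cand.arm}",
            )
            return rec, mature_iv, cand.star, cand.arm
    raise SyntheticError(
        f"no passing hairpin after {max_attempts} attempts "
        f"(mature_len={mature_len}, mismatches={duplex_mismatches}, "
        f"loop={loop_len}, au={au_fraction}, paired={paired_bp})"
    )


# ---------------------------------------------------------------------------
# Ground truth manifest
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    seed: int = 0
    planted_known: list = field(default_factory=list)
    planted_novel: list = field(default_factory=list)
    decoys: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    expression: dict = field(default_factory=dict)   # name -> truth dict
    contaminants: dict = field(default_factory=dict) # lib -> rule -> count
    clean_totals: dict = field(default_factory=dict) # lib -> reads
    unique_tags: dict = field(default_factory=dict)  # lib -> unique inserts
    realized_counts: dict = field(default_factory=dict)  # sequence -> [c, t]
    target_sites: list = field(default_factory=list)
    transcript_only: list = field(default_factory=list)
    contexts: dict = field(default_factory=dict)     # context -> [novel names]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    def to_frame(self):
        import pandas as pd

        rows = []
        for section in ("planted_known", "planted_novel", "decoys", "repeats",
                        "target_sites", "transcript_only"):
            for entry in getattr(self, section):
                if isinstance(entry, dict):
                    for key, val in entry.items():
                        rows.append((section, str(entry.get("name", "")), key, str(val)))
                else:
                    rows.append((section, str(entry), "", ""))
        for name, truth in self.expression.items():
            for key, val in truth.items():
                rows.append(("expression", name, key, str(val)))
        for lib, rules in self.contaminants.items():
            for rule, count in rules.items():
                rows.append(("contaminants", lib, rule, str(count)))
        for lib, n in self.clean_totals.items():
            rows.append(("clean_totals", lib, "clean_reads", str(n)))
        for lib, n in self.unique_tags.items():
            rows.append(("unique_tags", lib, "unique_tags", str(n)))
        return pd.DataFrame(rows, columns=["section", "name", "key", "value"])


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass
class PoolEntry:
    sequence: str
    source_class: str        # intergenic / decoy:<sub> / repeat / exon / intron
    expected_control: float = 0.0
    expected_treated: float = 0.0


@dataclass
class GenomeBundle:
    genome: dict                       # chrom -> str
    gene_models: list
    annotation_gene_models: list       # the subset known to the annotation DB
    mature_refs: list
    precursor_refs: list
    genbank_ncrna: list
    rfam_ncrna: list
    repeat_refs: list
    transcripts: list
    go_map: object                     # DataFrame: gene, term, name, ontology
    manifest: GroundTruthManifest
    pool: list = field(default_factory=list)

    def genome_records(self):
        return [SequenceRecord(id=c, sequence=s) for c, s in self.genome.items()]


class _Allocator:
    def __init__(self, chrom_lens: dict[str, int], rng):
        self.chrom_lens = chrom_lens
        self.rng = rng
        self.occupied: list[tuple[str, int, int, str]] = []

    def overlaps(self, chrom, lo, hi, kinds=None):
        for c, a, b, kind in self.occupied:
            if c == chrom and a < hi and lo < b and (kinds is None or kind in kinds):
                return True
        return False

    def place(self, length, kind, within=None, margin=10, tries=200):
        for _ in range(tries):
            if within is None:
                chrom = list(self.chrom_lens)[int(self.rng.integers(len(self.chrom_lens)))]
                clen = self.chrom_lens[chrom]
                if clen < length + 2 * margin:
                    continue
                pos = int(self.rng.integers(margin, clen - length - margin))
            else:
                chrom, flo, fhi = within
                if fhi - flo < length:
                    continue
                pos = int(self.rng.integers(flo, fhi - length + 1))
            avoid = None if within is None else {"element"}
            if not self.overlaps(chrom, pos - margin, pos + length + margin, avoid):
                self.occupied.append((chrom, pos, pos + length, "element"))
                return chrom, pos
        raise CapacityError(f"cannot place element of length {length} (kind={kind})")

    def reserve(self, chrom, lo, hi, kind):
        self.occupied.append((chrom, lo, hi, kind))


def _insert_ok(insert: str, clean_cfg: CleaningConfig) -> bool:
    """Would this insert survive cleaning unchanged, with safety margins?"""
    if not (clean_cfg.min_len <= len(insert) <= clean_cfg.max_len):
        return False
    if insert.count("A") / len(insert) > clean_cfg.polya_fraction - 0.10:
        return False
    prefix = clean_cfg.adapter5[: clean_cfg.adapter5_prefix]
    if sum(a != b for a, b in zip(insert, prefix)) < clean_cfg.adapter5_mismatches + 2:
        return False
    probe = clean_cfg.adapter3[: clean_cfg.adapter3_min_prefix]
    # no near-match (>=5/6) to the adapter prefix anywhere in the insert
    for i in range(len(insert) - len(probe) + 1):
        if sum(a != b for a, b in zip(insert[i : i + len(probe)], probe)) <= 1:
            return False
    return True


def _make_gene(rng, chrom, start, strand):
    u5 = int(rng.integers(120, 200))
    cds1 = int(rng.integers(120, 220))
    i1 = int(rng.integers(350, 600))
    ex2 = int(rng.integers(250, 400))
    i2 = int(rng.integers(350, 600))
    cds3 = int(rng.integers(120, 220))
    u3 = int(rng.integers(120, 200))
    e1 = (start, start + u5 + cds1)
    e2 = (e1[1] + i1, e1[1] + i1 + ex2)
    e3 = (e2[1] + i2, e2[1] + i2 + cds3 + u3)
    if strand == "+":
        utr5 = [(e1[0], e1[0] + u5)]
        utr3 = [(e3[1] - u3, e3[1])]
    else:
        utr5 = [(e3[1] - u5, e3[1])]
        utr3 = [(e1[0], e1[0] + u3)]
    return GeneModel(
        gene_id=f"{chrom}.g{start}",
        chrom=chrom,
        strand=strand,
        exons=[e1, e2, e3],
        cds=[],
        utr5=utr5,
        utr3=utr3,
    ), e3[1] - start


def build_genome(cfg: SyntheticConfig | None = None, rng=None,
                 clean_cfg: CleaningConfig | None = None,
                 disc_cfg: DiscoveryConfig | None = None) -> GenomeBundle:
    """Generate the toy genome with all planted elements and references."""
    cfg = cfg or SyntheticConfig()
    clean_cfg = clean_cfg or CleaningConfig()
    disc_cfg = disc_cfg or DiscoveryConfig()
    rng = rng if rng is not None else np.random.default_rng(0)

    for copies in cfg.repeat_copies:
        if copies > cfg.max_repeat_copies:
            raise CapacityError(
                f"repeat at {copies} copies exceeds the {cfg.max_repeat_copies}-copy cap"
            )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome = {
        c: bytearray(_rand_dna(rng, cfg.chrom_len).encode()) for c in chrom_names
    }
    alloc = _Allocator({c: cfg.chrom_len for c in chrom_names}, rng)
    manifest = GroundTruthManifest()

    def plant(chrom, pos, seq, strand):
        placed = seq if strand == "+" else revcomp(seq)
        genome[chrom][pos : pos + len(seq)] = placed.encode()

    # --- gene models -------------------------------------------------------
    gene_models = []
    for _ in range(cfg.n_genes):
        for _try in range(100):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(100, cfg.chrom_len - 3500))
            strand = "+" if rng.random() < 0.5 else "-"
            gm, span = _make_gene(rng, chrom, start, strand)
            if not alloc.overlaps(chrom, start - 50, start + span + 50):
                alloc.reserve(chrom, start, start + span, "gene")
                gene_models.append(gm)
                break
        else:
            raise CapacityError("cannot place gene models")
    gene_models.sort(key=lambda g: (g.chrom, g.span))

    planted_seqs: set[str] = set()

    def design_ok(mature_len, mismatches, loop, seed_name, au=None):
        for _ in range(30):
            rec, m_iv, s_iv, a = design_hairpin(
                mature_len, mismatches, loop, rng, arm="5p" if rng.random() < 0.5 else "3p",
                cfg=disc_cfg, au_fraction=au, name=seed_name,
            )
            mature = rec.sequence[m_iv[0] : m_iv[1]]
            star = rec.sequence[max(0, s_iv[0]) : s_iv[1]]
            if (
                _insert_ok(mature, clean_cfg)
                and _insert_ok(star, clean_cfg)
                and mature not in planted_seqs
                and star not in planted_seqs
            ):
                return rec, m_iv, s_iv, a
        raise SyntheticError("hairpin design failed insert screening")

    def in_context_ok(chrom, pos, strand, rec, m_iv) -> bool:
        """Would discovery, run on the planted genome, accept this hairpin
        with the exact planted mature?  (Emulates excision + evaluation at
        the mature's true placement.)"""
        L = len(rec.sequence)
        mature = rec.sequence[m_iv[0] : m_iv[1]]
        if strand == "+":
            a_start, a_end = pos + m_iv[0], pos + m_iv[1]
        else:
            a_start, a_end = pos + L - m_iv[1], pos + L - m_iv[0]
        probe = TagAlignment("probe", chrom, a_start, a_end, strand, 0)
        ctx = {chrom: bytes(genome[chrom]).decode()}
        windows = excise_candidates([probe], {"probe": "mapped"}, {"probe"},
                                    ctx, disc_cfg)
        for w in windows:
            cand = evaluate_candidate(w, disc_cfg)
            if cand.verdict == "ACCEPT" and cand.mature_seq == mature:
                return True
        return False

    # --- known miRNA hairpins ---------------------------------------------
    mature_refs, precursor_refs = [], []
    letters = "abcdefghij"
    fam_counter: dict[int, int] = {}
    for i in range(cfg.n_known):
        fam = _MIRNA_FAMILIES[i % len(_MIRNA_FAMILIES)]
        fam_counter[fam] = fam_counter.get(fam, 0) + 1
        name = f"osa-miR{fam}{letters[fam_counter[fam] - 1]}"
        known_len = (21, 20, 21, 22)[i % 4]
        rec, m_iv, s_iv, a = design_ok(known_len, int(rng.integers(0, 2)), 10, name)
        chrom, pos = alloc.place(len(rec.sequence), "known")
        strand = "+" if rng.random() < 0.5 else "-"
        plant(chrom, pos, rec.sequence, strand)
        mature = rec.sequence[m_iv[0] : m_iv[1]]
        star = rec.sequence[max(0, s_iv[0]) : s_iv[1]]
        planted_seqs.add(mature)
        planted_seqs.add(star)
        mature_refs.append(SequenceRecord(id=name, sequence=mature))
        precursor_refs.append(
            SequenceRecord(id=f"{name}-prec", sequence=rec.sequence,
                           description=rec.description)
        )
        manifest.planted_known.append(
            dict(name=name, family=f"miR{fam}", mature=mature, star=star,
                 chrom=chrom, start=pos, end=pos + len(rec.sequence),
                 strand=strand, arm=a, precursor=rec.sequence,
                 mature_iv=list(m_iv), star_iv=list(s_iv))
        )

    # --- novel hairpins across genomic contexts ---------------------------
    novel_contexts = (
        ["intronic"] * 4 + ["exonic"] * 3 + ["5'UTR"] * 2 + ["3'UTR"] * 2
    )
    novel_contexts += ["intergenic"] * (cfg.n_novel - len(novel_contexts))
    host_genes: set[str] = set()
    novel_lengths = [22, 23, 24] * (cfg.n_novel // 3 + 1)
    gene_cycle = list(rng.permutation(len(gene_models)))
    for i, ctx in enumerate(novel_contexts[: cfg.n_novel]):
        name = f"novel{i + 1:03d}"
        max_len = 90   # longest hairpin we try to host (UTRs are ~120-200 nt)
        if ctx == "intergenic":
            chrom, pos = alloc.place(max_len, "novel")
        else:
            feature = None
            for gi in list(gene_cycle):
                gm = gene_models[gi]
                ivs = {"intronic": gm.introns, "exonic": [gm.exons[1]],
                       "5'UTR": gm.utr5, "3'UTR": gm.utr3}[ctx]
                ivs = [iv for iv in ivs if iv[1] - iv[0] >= max_len + 4]
                if ivs:
                    feature = (gm, ivs[0])
                    gene_cycle.remove(gi)
                    break
            if feature is None:
                raise CapacityError(f"no gene feature can host a {ctx} hairpin")
            gm, (flo, fhi) = feature
            chrom, pos = alloc.place(max_len, "novel", within=(gm.chrom, flo + 2, fhi - 2))
            host_genes.add(gm.gene_id)
        # design until the hairpin is accepted *in its genomic context*
        planted = False
        for _redesign in range(25):
            rec, m_iv, s_iv, a = design_ok(
                novel_lengths[i], int(rng.integers(0, 2)), int(rng.integers(8, 14)),
                name,
            )
            L = len(rec.sequence)
            if L > max_len:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            saved = bytes(genome[chrom][pos : pos + L])
            plant(chrom, pos, rec.sequence, strand)
            if in_context_ok(chrom, pos, strand, rec, m_iv):
                planted = True
                break
            genome[chrom][pos : pos + L] = saved   # un-plant and redesign
        if not planted:
            raise SyntheticError(f"could not plant {name} ({ctx}) in context")
        mature = rec.sequence[m_iv[0] : m_iv[1]]
        star = rec.sequence[max(0, s_iv[0]) : s_iv[1]]
        planted_seqs.add(mature)
        planted_seqs.add(star)
        manifest.planted_novel.append(
            dict(name=name, mature=mature, star=star, chrom=chrom, start=pos,
                 end=pos + len(rec.sequence), strand=strand, arm=a,
                 context=ctx, precursor=rec.sequence,
                 mature_iv=list(m_iv), star_iv=list(s_iv))
        )
        manifest.contexts.setdefault(ctx, []).append(name)

    annotation_gene_models = [g for g in gene_models if g.gene_id not in host_genes]

    # --- decoy ncRNA loci --------------------------------------------------
    decoy_plan = (
        [("rRNA", "genbank_like")] * cfg.n_decoys_rrna
        + [("tRNA", "rfam_like")] * cfg.n_decoys_trna
        + [("snoRNA", "rfam_like")] * cfg.n_decoys_snorna
        + [("snRNA", "rfam_like")] * cfg.n_decoys_snrna
        + [("scRNA", "rfam_like")] * cfg.n_decoys_scrna
    )
    genbank_ncrna, rfam_ncrna = [], []
    for i, (klass, source) in enumerate(decoy_plan):
        length = int(rng.integers(90, 280))
        seq = _rand_dna(rng, length)
        chrom, pos = alloc.place(length, "decoy")
        plant(chrom, pos, seq, "+")
        ref = SequenceRecord(id=f"{klass}_{i + 1}", sequence=seq,
                             description=f"class={klass}")
        (genbank_ncrna if source == "genbank_like" else rfam_ncrna).append(ref)
        manifest.decoys.append(
            dict(name=ref.id, klass=klass, source=source, chrom=chrom,
                 start=pos, end=pos + length)
        )

    # --- repeats ------------------------------------------------------------
    repeat_refs = []
    for fi in range(cfg.n_repeat_families):
        copies = cfg.repeat_copies[fi % len(cfg.repeat_copies)]
        seq = _rand_dna(rng, 180)
        loci = []
        for _ in range(copies):
            chrom, pos = alloc.place(len(seq), "repeat")
            plant(chrom, pos, seq, "+")
            loci.append((chrom, pos))
        repeat_refs.append(SequenceRecord(id=f"repeat_fam{fi + 1}", sequence=seq))
        manifest.repeats.append(
            dict(name=f"repeat_fam{fi + 1}", copies=copies,
                 loci=[f"{c}:{p}" for c, p in loci])
        )

    genome_str = {c: bytes(b).decode() for c, b in genome.items()}

    # --- degradation-tag pool ----------------------------------------------
    lengths = np.array(sorted(_LENGTH_PROFILE), dtype=int)
    probs = np.array([_LENGTH_PROFILE[k] for k in lengths])
    probs = probs / probs.sum()
    pool: list[PoolEntry] = []
    class_weights = [("intergenic", 0.50), ("decoy", 0.20), ("exon", 0.15),
                     ("repeat", 0.10), ("intron", 0.05)]
    classes = [c for c, _ in class_weights]
    cw = np.array([w for _, w in class_weights])
    attempts = 0
    while len(pool) < cfg.n_other_tags and attempts < cfg.n_other_tags * 60:
        attempts += 1
        klass = classes[int(rng.choice(len(classes), p=cw))]
        L = int(rng.choice(lengths, p=probs))
        if klass == "intergenic":
            try:
                chrom, pos = alloc.place(L, "pool", margin=2, tries=20)
            except CapacityError:
                continue
            frag = genome_str[chrom][pos : pos + L]
            label = "intergenic"
        elif klass == "decoy":
            d = manifest.decoys[int(rng.integers(len(manifest.decoys)))]
            if d["end"] - d["start"] < L:
                continue
            off = int(rng.integers(d["start"], d["end"] - L + 1))
            frag = genome_str[d["chrom"]][off : off + L]
            label = f"decoy:{d['klass']}"
        elif klass == "repeat":
            r = manifest.repeats[int(rng.integers(len(manifest.repeats)))]
            chrom, pos = r["loci"][0].split(":")
            pos = int(pos)
            off = int(rng.integers(pos, pos + 180 - L + 1))
            frag = genome_str[chrom][off : off + L]
            label = "repeat"
        else:
            gm = annotation_gene_models[int(rng.integers(len(annotation_gene_models)))]
            ivs = gm.exons if klass == "exon" else gm.introns
            ivs = [iv for iv in ivs if iv[1] - iv[0] >= L]
            if not ivs:
                continue
            lo, hi = ivs[int(rng.integers(len(ivs)))]
            off = int(rng.integers(lo, hi - L + 1))
            frag = genome_str[gm.chrom][off : off + L]
            label = klass
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if "N" in frag or not _insert_ok(frag, clean_cfg) or frag in planted_seqs:
            continue
        planted_seqs.add(frag)
        pool.append(PoolEntry(sequence=frag, source_class=label))
    if len(pool) < cfg.n_other_tags:
        raise CapacityError("could not assemble the degradation-tag pool")

    # --- expression truth ---------------------------------------------------
    de_known_up = min(cfg.de_known_up, cfg.n_known)
    de_known_down = min(cfg.de_known_down, max(0, cfg.n_known - de_known_up))
    de_novel_up = min(cfg.de_novel_up, cfg.n_novel)
    de_novel_down = min(cfg.de_novel_down, max(0, cfg.n_novel - de_novel_up))
    lfc = cfg.de_log2fc

    def assign(names, n_up, n_down, section):
        order = list(rng.permutation(len(names)))
        ups = set(order[:n_up])
        downs = set(order[n_up : n_up + n_down])
        for idx, name in enumerate(names):
            if idx in ups:
                c = float(rng.uniform(50, 150))
                truth_lfc = lfc
            elif idx in downs:
                c = float(rng.uniform(200, 400))
                truth_lfc = -lfc
            else:
                c = float(rng.uniform(3, 80))
                truth_lfc = 0.0
            t = c * 2.0 ** truth_lfc
            entry = next(e for e in getattr(manifest, section) if e["name"] == name)
            manifest.expression[name] = dict(
                kind=section, mature=entry["mature"], star=entry["star"],
                expected_control=round(c, 2), expected_treated=round(t, 2),
                true_log2fc=truth_lfc,
                star_expected=round(max(1.0, 0.08 * min(c, t)), 2),
            )

    assign([e["name"] for e in manifest.planted_known], de_known_up, de_known_down,
           "planted_known")
    assign([e["name"] for e in manifest.planted_novel], de_novel_up, de_novel_down,
           "planted_novel")
    if manifest.planted_known:
        # showcase: a star species far more abundant than its mature
        showcase = manifest.planted_known[0]["name"]
        manifest.expression[showcase].update(
            expected_control=2.0, expected_treated=2.0, true_log2fc=0.0,
            star_expected=1500.0,
        )

    # --- transcripts, homology-only precursors, target sites, GO map -------
    transcripts = []
    for gm in gene_models:
        parts = [genome_str[gm.chrom][a:b] for a, b in gm.exons]
        seq = "".join(parts)
        if gm.strand == "-":
            seq = revcomp(seq)
        transcripts.append(SequenceRecord(id=gm.gene_id, sequence=seq))

    for i in range(cfg.n_transcript_only_precursors):
        name = f"osa-miR{_MIRNA_FAMILIES[i]}z"
        rec, m_iv, s_iv, a = design_hairpin(
            21, 0, 10, rng, arm="5p", cfg=disc_cfg, name=name
        )
        precursor_refs.append(
            SequenceRecord(id=f"{name}-prec", sequence=rec.sequence,
                           description=rec.description)
        )
        mature_refs.append(
            SequenceRecord(id=name, sequence=rec.sequence[m_iv[0] : m_iv[1]])
        )
        ctx_seq = _rand_dna(rng, 140) + rec.sequence + _rand_dna(rng, 140)
        transcripts.append(
            SequenceRecord(id=f"cdna_extra{i + 1}", sequence=ctx_seq,
                           description="synthetic transcript with conserved hairpin")
        )
        manifest.transcript_only.append(
            dict(name=f"{name}-prec", transcript=f"cdna_extra{i + 1}",
                 offset=140, length=len(rec.sequence))
        )

    de_names = [n for n, tr in manifest.expression.items() if tr["true_log2fc"] != 0]
    target_mirnas = de_names[: min(12, len(de_names))]
    gene_ids = [t.id for t in transcripts if not t.id.startswith("cdna_extra")]
    target_genes = []
    for i, mname in enumerate(target_mirnas):
        mature = manifest.expression[mname]["mature"]
        site = revcomp(mature)   # perfect complement in transcript space
        tid = gene_ids[i % len(gene_ids)]
        trec = next(t for t in transcripts if t.id == tid)
        offset = 40 + 3 * i
        new_seq = (trec.sequence[:offset] + site
                   + trec.sequence[offset + len(site):])
        transcripts[transcripts.index(trec)] = SequenceRecord(
            id=trec.id, sequence=new_seq, description=trec.description
        )
        cleavage = offset + len(mature) - 10
        manifest.target_sites.append(
            dict(name=mname, mirna=mname, mature=mature, transcript=tid,
                 start=offset, end=offset + len(site), cleavage=cleavage)
        )
        target_genes.append(tid)

    import pandas as pd

    go_rows = []
    for gid in sorted(set(target_genes)):
        go_rows.append((gid, "GO:0006950", "response to stress", "BP"))
    extra = [g for g in gene_ids if g not in set(target_genes)]
    for gid in extra[:2]:
        go_rows.append((gid, "GO:0006950", "response to stress", "BP"))
    for i, gid in enumerate(gene_ids):
        go_rows.append((gid, "GO:0008150", "biological process", "BP"))
        if i % 3 == 0:
            go_rows.append((gid, "GO:0003700", "DNA-binding transcription factor", "MF"))
        if i % 4 == 0:
            go_rows.append((gid, "GO:0016301", "kinase activity", "MF"))
    go_map = pd.DataFrame(go_rows, columns=["gene", "term", "name", "ontology"])

    return GenomeBundle(
        genome=genome_str,
        gene_models=gene_models,
        annotation_gene_models=annotation_gene_models,
        mature_refs=mature_refs,
        precursor_refs=precursor_refs,
        genbank_ncrna=genbank_ncrna,
        rfam_ncrna=rfam_ncrna,
        repeat_refs=repeat_refs,
        transcripts=transcripts,
        go_map=go_map,
        manifest=manifest,
        pool=pool,
    )


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def _assemble_read(insert: str, rid: str, rng, cfg: SyntheticConfig,
                   clean_cfg: CleaningConfig, low_quality: bool = False) -> ReadRecord:
    body = insert + clean_cfg.adapter3 + _READ_TAIL
    seq = body[: cfg.read_length]
    if low_quality:
        qual = rng.integers(5, 20, size=len(seq))
    else:
        qual = rng.integers(32, 41, size=len(seq))
    return ReadRecord(id=rid, sequence=seq, quality=tuple(int(q) for q in qual))


def _apply_errors(insert: str, rng, rate: float) -> str:
    if rate <= 0:
        return insert
    out = list(insert)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


def simulate_libraries(bundle: GenomeBundle, cfg: SyntheticConfig | None = None,
                       rng=None, clean_cfg: CleaningConfig | None = None):
    """Simulate the control and salt-treated FASTQ libraries.

    Returns ``(control_reads, treated_reads, manifest)``; the manifest gains
    exact per-rule contaminant counts, clean totals and realized per-sequence
    tag counts (each generated read is classified through the same cleaning
    rules the pipeline applies, so these numbers are exact by construction).
    Deterministic under a fixed seed.
    """
    cfg = cfg or SyntheticConfig()
    clean_cfg = clean_cfg or CleaningConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(clean_cfg.adapter3) < 6:
        raise ParameterError("3' adapter shorter than 6 nt is untrimmable")
    manifest = bundle.manifest

    n_contam = {
        "low_quality": int(round(cfg.frac_low_quality * cfg.reads_per_library)),
        "adapter5_contaminant": int(round(cfg.frac_adapter5 * cfg.reads_per_library)),
        "no_adapter3": int(round(cfg.frac_no_adapter3 * cfg.reads_per_library)),
        "no_insert": int(round(cfg.frac_no_insert * cfg.reads_per_library)),
        "polyA": int(round(cfg.frac_polya * cfg.reads_per_library)),
        "length_out_of_range": int(round(cfg.frac_bad_length * cfg.reads_per_library)),
    }
    contam_total = sum(n_contam.values())

    planted = []   # (sequence, expected_control, expected_treated)
    for truth in manifest.expression.values():
        planted.append((truth["mature"], truth["expected_control"],
                        truth["expected_treated"]))
        planted.append((truth["star"], truth["star_expected"], truth["star_expected"]))
    planted_sum_c = sum(p[1] for p in planted)
    planted_sum_t = sum(p[2] for p in planted)

    weights = rng.lognormal(0.0, 1.0, size=len(bundle.pool))
    weights = weights / weights.sum()
    budget_c = max(0.0, cfg.reads_per_library - contam_total - planted_sum_c)
    budget_t = max(0.0, cfg.reads_per_library - contam_total - planted_sum_t)
    for entry, w in zip(bundle.pool, weights):
        entry.expected_control = float(budget_c * w)
        entry.expected_treated = float(budget_t * w)

    libraries = {}
    for lib in ("control", "treated"):
        reads: list[ReadRecord] = []
        serial = 0

        def next_id():
            nonlocal serial
            serial += 1
            return f"{lib}_{serial:06d}"

        # clean-class reads: planted miRNA/star tags + degradation pool
        emit = []
        for seq, ec, et in planted:
            n = int(rng.poisson(ec if lib == "control" else et))
            emit.extend([seq] * n)
        for entry in bundle.pool:
            mean = entry.expected_control if lib == "control" else entry.expected_treated
            emit.extend([entry.sequence] * int(rng.poisson(mean)))
        for insert in emit:
            insert = _apply_errors(insert, rng, cfg.error_rate)
            reads.append(_assemble_read(insert, next_id(), rng, cfg, clean_cfg))

        # contaminant reads, one block per cleaning rule
        for _ in range(n_contam["low_quality"]):
            insert = _rand_dna(rng, int(rng.integers(20, 27)))
            reads.append(_assemble_read(insert, next_id(), rng, cfg, clean_cfg,
                                        low_quality=True))
        prefix = clean_cfg.adapter5[: clean_cfg.adapter5_prefix]
        for _ in range(n_contam["adapter5_contaminant"]):
            seq = (prefix + _rand_dna(rng, cfg.read_length))[: cfg.read_length]
            qual = tuple(int(q) for q in rng.integers(32, 41, size=len(seq)))
            reads.append(ReadRecord(id=next_id(), sequence=seq, quality=qual))
        probe = clean_cfg.adapter3[: clean_cfg.adapter3_min_prefix]
        emitted = 0
        while emitted < n_contam["no_adapter3"]:
            seq = _rand_dna(rng, cfg.read_length)
            if probe in seq or seq.startswith(prefix[:4]):
                continue
            mism = sum(a != b for a, b in zip(seq, prefix))
            if mism <= clean_cfg.adapter5_mismatches:
                continue
            qual = tuple(int(q) for q in rng.integers(32, 41, size=len(seq)))
            reads.append(ReadRecord(id=next_id(), sequence=seq, quality=qual))
            emitted += 1
        for _ in range(n_contam["no_insert"]):
            reads.append(_assemble_read("", next_id(), rng, cfg, clean_cfg))
        for _ in range(n_contam["polyA"]):
            L = int(rng.integers(20, 26))
            pos = sorted(rng.choice(np.arange(1, L), size=2, replace=False))
            insert = "".join(
                "C" if i in set(int(p) for p in pos) else "A" for i in range(L)
            )
            reads.append(_assemble_read(insert, next_id(), rng, cfg, clean_cfg))
        emitted = 0
        while emitted < n_contam["length_out_of_range"]:
            L = int(rng.integers(8, 16))
            insert = _rand_dna(rng, L)
            if insert.count("A") / L >= clean_cfg.polya_fraction or probe in insert:
                continue
            reads.append(_assemble_read(insert, next_id(), rng, cfg, clean_cfg))
            emitted += 1

        order = rng.permutation(len(reads))
        reads = [reads[int(i)] for i in order]
        libraries[lib] = reads

        # classify every read exactly as the pipeline will
        rule_counts = Counter()
        insert_counts = Counter()
        for read in reads:
            rule, insert = classify_read(read, clean_cfg)
            if rule is None:
                insert_counts[insert] += 1
            else:
                rule_counts[rule] += 1
        manifest.contaminants[lib] = {
            rule: int(rule_counts.get(rule, 0))
            for rule in ("low_quality", "adapter5_contaminant", "no_adapter3",
                         "no_insert", "polyA", "length_out_of_range")
        }
        manifest.clean_totals[lib] = int(sum(insert_counts.values()))
        manifest.unique_tags[lib] = len(insert_counts)
        col = 0 if lib == "control" else 1
        for seq, count in insert_counts.items():
            manifest.realized_counts.setdefault(seq, [0, 0])[col] = int(count)

    return libraries["control"], libraries["treated"], manifest
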