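"""End-to-end pipeline orchestration with resumable file-backed stages.

Stage order: simulate -> clean -> map -> annotate -> discover -> homology ->
de -> targets -> enrich.  Every stage writes its artifacts into the output
directory and is skipped on rerun if they already exist (delete a stage's
outputs to recompute them); all randomness flows from the single seed in the
run configuration, so identical config + seed give identical result tables.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import discovery as disc
from . import expression as expr
from . import homology as hom
from . import mapping as mapg
from . import preprocess as prep
from . import synthetic_data as synth
from . import targets as targ
from .config import RunConfig, save_config
from .iofmt import (SequenceRecord, read_fasta, read_fastq, read_gff3,
                    read_tsv, write_fasta, write_fastq, write_gff3, write_tsv)

log = logging.getLogger("saltmir")

STAGES = ("simulate", "clean", "map", "annotate", "discover", "homology",
          "de", "targets", "enrich")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _outputs_exist(outdir: Path, names) -> bool:
    return all((outdir / n).exists() for n in names)


def run_pipeline(cfg: RunConfig, outdir=None, force: bool = False) -> Path:
    """Run all enabled stages; returns the output directory."""
    cfg.validate()
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")
    t0 = time.time()
    enabled = [s for s in STAGES if s in cfg.stages]
    for stage in enabled:
        fn = globals()[f"stage_{stage}"]
        try:
            started = time.time()
            skipped = fn(cfg, outdir, force)
            log.info("stage %s %s (%.1fs)", stage,
                     "skipped (outputs exist)" if skipped else "done",
                     time.time() - started)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
    stage_report(cfg, outdir, force=True)
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return outdir


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path, force=False) -> bool:
    names = ["genome.fa", "genes.gff3", "control.fastq", "treated.fastq",
             "manifest.tsv", "manifest.json", "transcripts.fa", "go_map.tsv"]
    if not force and _outputs_exist(outdir, names):
        return True
    rng = np.random.default_rng(cfg.seed)
    bundle = synth.build_genome(cfg.synthetic, rng, cfg.clean, cfg.discovery)
    control, treated, manifest = synth.simulate_libraries(
        bundle, cfg.synthetic, rng, cfg.clean
    )
    manifest.seed = cfg.seed
    write_fasta(outdir / "genome.fa", bundle.genome_records())
    write_gff3(outdir / "genes.gff3", bundle.gene_models)
    write_gff3(outdir / "genes_annotation_db.gff3", bundle.annotation_gene_models)
    write_fasta(outdir / "refs_mature.fa", bundle.mature_refs)
    write_fasta(outdir / "refs_precursor.fa", bundle.precursor_refs)
    write_fasta(outdir / "refs_ncrna_genbank.fa", bundle.genbank_ncrna)
    write_fasta(outdir / "refs_ncrna_rfam.fa", bundle.rfam_ncrna)
    write_fasta(outdir / "refs_repeats.fa", bundle.repeat_refs)
    write_fasta(outdir / "transcripts.fa", bundle.transcripts)
    write_tsv(outdir / "go_map.tsv", bundle.go_map)
    write_fastq(outdir / "control.fastq", control)
    write_fastq(outdir / "treated.fastq", treated)
    write_tsv(outdir / "manifest.tsv", manifest.to_frame(), {"seed": cfg.seed})
    manifest.to_json(outdir / "manifest.json")
    return False


def stage_clean(cfg: RunConfig, outdir: Path, force=False) -> bool:
    names = ["tags.fa", "cleaning_stats.tsv"]
    if not force and _outputs_exist(outdir, names):
        return True
    inserts = {}
    stats = {}
    for lib in ("control", "treated"):
        path = outdir / f"{lib}.fastq"
        if not path.exists():
            raise StageError("clean", f"missing input {path}")
        inserts[lib], stats[lib] = prep.clean_reads(read_fastq(path), cfg.clean)
    tagset = prep.collapse_tags(inserts["control"], inserts["treated"])
    rows = []
    for lib in ("control", "treated"):
        for key, val in stats[lib].as_rows():
            rows.append((lib, key, val))
    write_tsv(outdir / "cleaning_stats.tsv",
              pd.DataFrame(rows, columns=["library", "metric", "value"]))
    write_fasta(
        outdir / "tags.fa",
        [SequenceRecord(id=t.tag_id, sequence=t.sequence,
                        description=f"{t.count_control} {t.count_treated}")
         for t in tagset],
    )
    hist = prep.length_distribution(tagset)
    write_tsv(outdir / "length_distribution.tsv",
              pd.DataFrame(sorted(hist.items()), columns=["length", "reads"]))
    return False


def load_tagset(outdir: Path) -> prep.TagSet:
    tags = []
    control_total = treated_total = 0
    for rec in read_fasta(outdir / "tags.fa"):
        cc, ct = (int(x) for x in rec.description.split())
        tags.append(prep.SmallRNATag(rec.id, rec.sequence, cc, ct))
        control_total += cc
        treated_total += ct
    return prep.TagSet(tags, control_total, treated_total)


def stage_map(cfg: RunConfig, outdir: Path, force=False) -> bool:
    if not force and _outputs_exist(outdir, ["alignments.tsv"]):
        return True
    tagset = load_tagset(outdir)
    index = mapg.build_index(read_fasta(outdir / "genome.fa"),
                             seed_len=cfg.mapping.seed_len,
                             max_mismatch=cfg.mapping.max_mismatch)
    alignments, status = mapg.map_tags(tagset, index,
                                       max_mismatch=cfg.mapping.max_mismatch,
                                       max_hits=cfg.mapping.max_hits)
    write_tsv(outdir / "alignments.tsv", mapg.alignments_to_frame(alignments, status))
    return False


def load_alignments(outdir: Path):
    frame = read_tsv(outdir / "alignments.tsv")
    alignments = []
    status = {}
    for row in frame.itertuples(index=False):
        status[row.tag_id] = row.status
        if row.status == "mapped" and row.chrom != ".":
            alignments.append(
                mapg.TagAlignment(row.tag_id, row.chrom, int(row.start) - 1,
                                  int(row.end), row.strand, int(row.mismatches))
            )
    return alignments, status


def stage_annotate(cfg: RunConfig, outdir: Path, force=False) -> bool:
    names = ["annotation.tsv", "known_mirnas.tsv"]
    if not force and _outputs_exist(outdir, names):
        return True
    tagset = load_tagset(outdir)
    alignments, status = load_alignments(outdir)
    gff_path = outdir / "genes_annotation_db.gff3"
    if not gff_path.exists():
        gff_path = outdir / "genes.gff3"
    records, known = ann.classify_tags(
        tagset, alignments, status,
        list(read_fasta(outdir / "refs_ncrna_genbank.fa")),
        list(read_fasta(outdir / "refs_ncrna_rfam.fa")),
        list(read_fasta(outdir / "refs_mature.fa")),
        list(read_fasta(outdir / "refs_precursor.fa")),
        list(read_fasta(outdir / "refs_repeats.fa")),
        read_gff3(gff_path),
        cfg.annotation,
        fold_backend=cfg.discovery.fold_backend,
    )
    write_tsv(outdir / "annotation.tsv", pd.DataFrame(
        [(r.tag_id, r.category, r.subcategory, r.evidence_source) for r in records],
        columns=["tag_id", "category", "subcategory", "evidence"]))
    write_tsv(outdir / "known_mirnas.tsv", pd.DataFrame(
        [(k.name, k.family, k.arm, k.is_star, k.count_control, k.count_treated,
          ";".join(k.matched_tags)) for k in known],
        columns=["name", "family", "arm", "is_star", "count_control",
                 "count_treated", "tags"]))
    return False


def stage_discover(cfg: RunConfig, outdir: Path, force=False) -> bool:
    names = ["novel_mirnas.tsv", "rejections.tsv", "novel_precursors.fa"]
    if not force and _outputs_exist(outdir, names):
        return True
    tagset = load_tagset(outdir)
    alignments, status = load_alignments(outdir)
    annot = read_tsv(outdir / "annotation.tsv")
    unannotated = set(annot.loc[annot.category == "unannotated", "tag_id"])
    genome = {r.id: r.sequence for r in read_fasta(outdir / "genome.fa")}
    windows = disc.excise_candidates(alignments, status, unannotated, genome,
                                     cfg.discovery)
    candidates = [disc.evaluate_candidate(w, cfg.discovery) for w in windows]
    accepted = [c for c in candidates if c.verdict == "ACCEPT"]
    gene_models = read_gff3(outdir / "genes.gff3")
    tag_counts = {t.sequence: (t.count_control, t.count_treated) for t in tagset}
    novel = disc.name_and_deduplicate(accepted, gene_models, tag_counts)
    write_tsv(outdir / "novel_mirnas.tsv", pd.DataFrame(
        [(n.name, n.chrom, n.start + 1, n.end, n.strand, n.arm, n.mature_seq,
          n.star_seq, n.precursor_len, round(n.mfe, 2), round(n.mfei, 3),
          round(100 * n.au_fraction, 1), n.context, n.count_control,
          n.count_treated) for n in novel],
        columns=["name", "chrom", "start", "end", "strand", "arm", "mature",
                 "star", "precursor_len", "mfe", "mfei", "au_pct", "context",
                 "count_control", "count_treated"]))
    reasons = pd.DataFrame(
        [(c.tag_id, c.chrom, c.start + 1, c.end, c.strand,
          ";".join(c.rejection_reasons)) for c in candidates
         if c.verdict == "REJECT"],
        columns=["tag_id", "chrom", "start", "end", "strand", "reasons"])
    write_tsv(outdir / "rejections.tsv", reasons)
    with open(outdir / "novel_precursors.fa", "w") as fh:
        for n in novel:
            fh.write(f">{n.name} {n.chrom}:{n.start + 1}-{n.end}({n.strand})\n")
            prec = next(c for c in accepted
                        if (c.chrom, c.start, c.end) == (n.chrom, n.start, n.end))
            fh.write(prec.sequence + "\n" + prec.fold.structure
                     + f" ({prec.mfe:.2f})\n")
    return False


def stage_homology(cfg: RunConfig, outdir: Path, force=False) -> bool:
    if not force and _outputs_exist(outdir, ["homology_hits.tsv"]):
        return True
    queries = list(read_fasta(outdir / "refs_precursor.fa"))
    transcripts = list(read_fasta(outdir / "transcripts.fa"))
    hits = hom.search_homologs(queries, transcripts, cfg.homology, cfg.discovery,
                               fold_backend=cfg.discovery.fold_backend)
    write_tsv(outdir / "homology_hits.tsv", pd.DataFrame(
        [(h.query, h.transcript, h.start + 1, h.end, h.strand, h.identity,
          h.coverage, h.query_kind, h.validated) for h in hits],
        columns=["query", "transcript", "start", "end", "strand", "identity",
                 "coverage", "query_kind", "validated"]))
    return False


def _mirna_counts(outdir: Path):
    counts: dict[str, tuple[int, int]] = {}
    kinds: dict[str, str] = {}
    known = read_tsv(outdir / "known_mirnas.tsv")
    for row in known.itertuples(index=False):
        if bool(row.is_star):
            continue
        counts[row.name] = (int(row.count_control), int(row.count_treated))
        kinds[row.name] = "known"
    novel_path = outdir / "novel_mirnas.tsv"
    if novel_path.exists():
        novel = read_tsv(novel_path)
        for row in novel.itertuples(index=False):
            counts[row.name] = (int(row.count_control), int(row.count_treated))
            kinds[row.name] = "novel"
    return counts, kinds


def stage_de(cfg: RunConfig, outdir: Path, force=False) -> bool:
    if not force and _outputs_exist(outdir, ["expression.tsv"]):
        return True
    tagset = load_tagset(outdir)
    counts, kinds = _mirna_counts(outdir)
    records = expr.differential_expression(
        counts, tagset.clean_control, tagset.clean_treated, kinds,
        zero_floor=cfg.expression.zero_floor_tpm,
        up=cfg.expression.log2fc_up, down=cfg.expression.log2fc_down,
        max_p=cfg.expression.max_pvalue,
    )
    write_tsv(outdir / "expression.tsv", pd.DataFrame(
        [(r.mirna, r.kind, r.count_control, r.count_treated, r.tpm_control,
          r.tpm_treated, r.log2fc, r.pvalue, r.qvalue, r.call)
         for r in records],
        columns=["mirna", "kind", "count_control", "count_treated",
                 "tpm_control", "tpm_treated", "log2fc", "pvalue", "qvalue",
                 "call"]))
    return False


def stage_targets(cfg: RunConfig, outdir: Path, force=False) -> bool:
    if not force and _outputs_exist(outdir, ["targets.tsv"]):
        return True
    exp = read_tsv(outdir / "expression.tsv")
    de = exp[exp.call != "neutral"]
    mirnas = {}
    mature_by_name = {}
    known = {r.id: r.sequence for r in read_fasta(outdir / "refs_mature.fa")}
    novel_path = outdir / "novel_mirnas.tsv"
    if novel_path.exists():
        for row in read_tsv(novel_path).itertuples(index=False):
            mature_by_name[row.name] = row.mature
    for name in de.mirna:
        base = name.rstrip("*")
        if base in known:
            mirnas[name] = known[base]
        elif name in mature_by_name:
            mirnas[name] = mature_by_name[name]
    transcripts = list(read_fasta(outdir / "transcripts.fa"))
    hits = targ.scan_transcriptome(mirnas, transcripts, cfg.targets)
    write_tsv(outdir / "targets.tsv", pd.DataFrame(
        [(h.mirna, h.transcript, h.start + 1, h.end, h.expectation,
          h.inhibition, "" if h.cleavage_site is None else h.cleavage_site,
          h.alignment.replace("\n", " / ")) for h in hits],
        columns=["mirna", "transcript", "start", "end", "expectation",
                 "inhibition", "cleavage_site", "alignment"]))
    return False


def stage_enrich(cfg: RunConfig, outdir: Path, force=False) -> bool:
    if not force and _outputs_exist(outdir, ["enrichment.tsv"]):
        return True
    hits = read_tsv(outdir / "targets.tsv")
    go_map = read_tsv(outdir / "go_map.tsv")
    background = sorted({r.id for r in read_fasta(outdir / "transcripts.fa")})
    target_genes = sorted(set(hits.transcript) & set(background))
    results = targ.sea_enrichment(target_genes, background, go_map,
                                  cfg.targets.fdr_threshold)
    write_tsv(outdir / "enrichment.tsv", pd.DataFrame(
        [(r.term, r.name, r.k, r.n, r.K, r.N, r.pvalue, r.fdr, r.significant)
         for r in results],
        columns=["term", "name", "k", "n", "K", "N", "pvalue", "fdr",
                 "significant"]))
    return False


def stage_report(cfg: RunConfig, outdir: Path, force=False) -> bool:
    """Summary table mirroring the published per-library accounting rows."""
    stats = read_tsv(outdir / "cleaning_stats.tsv")
    annot_path = outdir / "annotation.tsv"
    rows = []
    tagset = load_tagset(outdir)
    by_seq = {}
    for t in tagset:
        by_seq[t.tag_id] = t
    counts_by_cat = {}
    if annot_path.exists():
        annot = read_tsv(annot_path)
        for row in annot.itertuples(index=False):
            t = by_seq.get(row.tag_id)
            if t is None:
                continue
            cc, ct = counts_by_cat.get(row.category, (0, 0))
            counts_by_cat[row.category] = (cc + t.count_control, ct + t.count_treated)
    for lib in ("control", "treated"):
        sub = stats[stats.library == lib].set_index("metric")["value"]
        raw = int(sub["raw_reads"])
        clean = int(sub["clean_reads"])
        removed = raw - clean
        col = 0 if lib == "control" else 1
        rows.append((lib, "raw_reads", raw))
        rows.append((lib, "removed_total", removed))
        rows.append((lib, "clean_reads", clean))
        rows.append((lib, "unique_tags", int(sub["unique_tags"])))
        for cat in ("rRNA_etc", "known_miRNA", "repeat", "exon", "intron",
                    "unannotated"):
            rows.append((lib, f"reads_{cat}", counts_by_cat.get(cat, (0, 0))[col]))
    novel_path = outdir / "novel_mirnas.tsv"
    if novel_path.exists():
        novel = read_tsv(novel_path)
        rows.append(("both", "novel_mirnas", len(novel)))
    write_tsv(outdir / "summary.tsv",
              pd.DataFrame(rows, columns=["library", "metric", "value"]))
    return False
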