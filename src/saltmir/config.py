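"""Run configuration: every tunable threshold in the pipeline, with defaults.

Defaults follow the published small-RNA analysis protocol this pipeline
implements: genome mapping with at most 2 mismatches and a 20-copy cap,
Mireap-style hairpin criteria (precursor MFE <= -18 kcal/mol, miRNA/miRNA*
distance <= 300 nt, >= 19 duplex base pairs, bulge <= 8, asymmetry <= 4,
20-nt precursor flanks, mature length 18-26 nt), 30-70% A+U content, and
differential-expression calls at |log2FC| >= 1 with P <= 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid range."""


@dataclass
class CleaningConfig:
    adapter3: str = "TGGAATTCTCGG"        # 3' adapter, fixed documented 12-mer
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_len: int = 16                     # rule (vi): shortest insert kept
    max_len: int = 36                     # rule (vi): longest insert kept
    min_mean_phred: float = 20.0          # rule (i)
    max_frac_below_q10: float = 0.10      # rule (i)
    adapter5_prefix: int = 8              # rule (ii): >=8-nt prefix, <=1 mismatch
    adapter5_mismatches: int = 1
    adapter3_max_prefix: int = 12         # rule (iii): prefix search 12 -> 6
    adapter3_min_prefix: int = 6
    polya_fraction: float = 0.80          # rule (v)


@dataclass
class MappingConfig:
    seed_len: int = 12                    # maximum k-mer seed length
    max_mismatch: int = 2                 # genome mapping mismatch cap
    max_hits: int = 20                    # genome copy-number cap


@dataclass
class AnnotationConfig:
    max_mismatch: int = 2                 # reference matching, same as mapping
    max_end_shift: int = 2                # known-miRNA end-shift tolerance (nt)
    star_slop: int = 2                    # miRNA* interval tolerance (nt)


@dataclass
class DiscoveryConfig:
    min_mature_len: int = 18              # (i) minimum miRNA length
    max_mature_len: int = 26              # (ii) maximum miRNA length
    min_ref_len: int = 20                 # (iii) minimum reference miRNA length
    max_ref_len: int = 24                 # (iv) maximum reference miRNA length
    max_copy: int = 20                    # (v) genome copy cap
    max_mfe: float = -18.0                # (vi) precursor MFE threshold, kcal/mol
    max_duplex_distance: int = 300        # (vii) miRNA..miRNA* span
    min_paired: int = 19                  # (viii) duplex base pairs
    max_bulge: int = 8                    # (ix)
    max_asymmetry: int = 4                # (x)
    flank: int = 20                       # (xi) precursor flank length, nt
    max_duplex_mismatch: int = 2          # candidate criterion (iii)
    min_au: float = 0.30                  # criterion (v): A+U content range
    max_au: float = 0.70
    mfei_min: float = 0.85                # |MFEI| floor; 0 disables the filter
    max_precursor: int = 320              # candidate window length, nt
    fold_backend: str = "nn"              # "nn" (bundled) or "vienna"


@dataclass
class HomologyConfig:
    word_size: int = 11
    min_identity: float = 0.90
    min_coverage: float = 0.90


@dataclass
class ExpressionConfig:
    zero_floor_tpm: float = 0.01          # stand-in TPM for zero counts in log2FC
    log2fc_up: float = 1.0                # call thresholds (boundaries inclusive)
    log2fc_down: float = -1.0
    max_pvalue: float = 0.05


@dataclass
class TargetConfig:
    expectation_cutoff: float = 3.0
    wobble_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_penalty: float = 2.0
    seed_start: int = 2                   # seed region (5' numbering), inclusive
    seed_end: int = 13
    seed_multiplier: float = 2.0
    translation_start: int = 9            # central positions deciding inhibition
    translation_end: int = 11
    max_gaps: int = 2
    fdr_threshold: float = 0.05           # SEA significance


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 12               # mirrors the 12 rice chromosomes
    chrom_len: int = 50_000
    n_known: int = 30
    n_novel: int = 24
    n_genes: int = 30
    n_decoys_rrna: int = 4
    n_decoys_trna: int = 6
    n_decoys_snorna: int = 4
    n_decoys_snrna: int = 3
    n_decoys_scrna: int = 2
    n_repeat_families: int = 3
    repeat_copies: tuple = (5, 10, 20)
    max_repeat_copies: int = 20
    read_length: int = 50
    error_rate: float = 0.001             # uniform substitution rate, insert only
    n_other_tags: int = 150               # degradation-tag pool size
    reads_per_library: int = 25_000
    frac_low_quality: float = 0.03        # contaminant fractions, rules (i)-(vi)
    frac_adapter5: float = 0.01
    frac_no_adapter3: float = 0.02
    frac_no_insert: float = 0.01
    frac_polya: float = 0.01
    frac_bad_length: float = 0.015
    de_log2fc: float = 2.0                # planted effect size for DE miRNAs
    de_known_up: int = 8                  # differentially expressed plantings
    de_known_down: int = 5
    de_novel_up: int = 4
    de_novel_down: int = 4
    n_transcript_only_precursors: int = 5 # conserved hairpins present only in cDNA


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "saltmir_out"
    stages: tuple = (
        "simulate", "clean", "map", "annotate", "discover",
        "homology", "de", "targets", "enrich",
    )
    clean: CleaningConfig = field(default_factory=CleaningConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> "RunConfig":
        d = self.discovery
        if d.min_mature_len > d.max_mature_len:
            raise ConfigError("min_mature_len > max_mature_len")
        if d.max_mfe > 0:
            raise ConfigError("max_mfe must be <= 0 (kcal/mol)")
        if not (0 <= d.min_au <= d.max_au <= 1):
            raise ConfigError("A+U content range must satisfy 0 <= min <= max <= 1")
        if self.mapping.seed_len > 16:
            raise ConfigError("seed_len must be <= 16 (shortest tag)")
        if len(self.clean.adapter3) < 6:
            raise ConfigError("3' adapter must be at least 6 nt")
        if self.clean.min_len > self.clean.max_len:
            raise ConfigError("cleaning min_len > max_len")
        if not (0 < self.expression.zero_floor_tpm < 1):
            raise ConfigError("zero_floor_tpm must be in (0, 1)")
        return self


_SECTION_TYPES = {
    "clean": CleaningConfig,
    "mapping": MappingConfig,
    "annotation": AnnotationConfig,
    "discovery": DiscoveryConfig,
    "homology": HomologyConfig,
    "expression": ExpressionConfig,
    "targets": TargetConfig,
    "synthetic": SyntheticConfig,
}


def config_to_dict(cfg: RunConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["stages"] = list(cfg.stages)
    out["synthetic"]["repeat_copies"] = list(cfg.synthetic.repeat_copies)
    return out


def config_from_dict(data: dict) -> RunConfig:
    kwargs = {}
    for key, value in (data or {}).items():
        if key in _SECTION_TYPES:
            section_cls = _SECTION_TYPES[key]
            fields = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(value) - fields
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            if key == "synthetic" and "repeat_copies" in value:
                value = dict(value, repeat_copies=tuple(value["repeat_copies"]))
            kwargs[key] = section_cls(**value)
        elif key == "stages":
            kwargs[key] = tuple(value)
        elif key in {"seed", "outdir"}:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    return RunConfig(**kwargs).validate()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
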