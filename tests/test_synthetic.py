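import numpy as np
import pytest

from saltmir.config import DiscoveryConfig, SyntheticConfig
from saltmir.discovery import CandidateWindow, evaluate_candidate
from saltmir.iofmt import write_fastq
from saltmir.synthetic_data import (CapacityError, ParameterError,
                                    build_genome, design_hairpin,
                                    simulate_libraries)
from conftest import mini_synthetic_config


class TestDesignHairpin:
    def test_designed_precursor_is_accepted(self):
        rng = np.random.default_rng(1)
        rec, m_iv, s_iv, arm = design_hairpin(21, 0, 10, rng)
        window = CandidateWindow(
            chrom="h", start=0, end=len(rec.sequence), strand="+",
            sequence=rec.sequence, tag_offset=m_iv[0],
            tag_len=m_iv[1] - m_iv[0], tag_id="h",
        )
        cand = evaluate_candidate(window, DiscoveryConfig())
        assert cand.verdict == "ACCEPT"
        assert cand.star == s_iv

    def test_star_has_2nt_3prime_overhang(self):
        rng = np.random.default_rng(5)
        for arm in ("5p", "3p"):
            rec, m_iv, s_iv, got_arm = design_hairpin(22, 0, 12, rng, arm=arm)
            assert got_arm == arm
            window = CandidateWindow(
                chrom="h", start=0, end=len(rec.sequence), strand="+",
                sequence=rec.sequence, tag_offset=m_iv[0], tag_len=22, tag_id="h",
            )
            cand = evaluate_candidate(window, DiscoveryConfig())
            pairs = cand.fold.pair_map()
            partners = [int(pairs[i]) for i in range(*m_iv) if pairs[i] >= 0]
            q_lo, q_hi = min(partners), max(partners) + 1
            assert s_iv == (q_lo + 2, q_hi + 2)   # partner interval shifted +2

    def test_mismatches_above_cap_is_parameter_error(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ParameterError):
            design_hairpin(21, 3, 10, rng)

    def test_same_seed_same_precursor(self):
        a = design_hairpin(21, 1, 10, np.random.default_rng(42))
        b = design_hairpin(21, 1, 10, np.random.default_rng(42))
        assert a == b

    def test_duplex_mismatch_count_realised(self):
        rng = np.random.default_rng(9)
        for mism in (0, 1, 2):
            rec, m_iv, s_iv, _ = design_hairpin(23, mism, 10, rng)
            window = CandidateWindow(
                chrom="h", start=0, end=len(rec.sequence), strand="+",
                sequence=rec.sequence, tag_offset=m_iv[0], tag_len=23, tag_id="h",
            )
            cand = evaluate_candidate(window, DiscoveryConfig())
            assert cand.duplex_mismatches == mism


class TestBuildGenome:
    def test_mini_genome_plants_everything(self):
        cfg = mini_synthetic_config()
        bundle = build_genome(cfg, np.random.default_rng(2))
        man = bundle.manifest
        assert len(man.planted_known) == cfg.n_known
        assert len(man.planted_novel) == cfg.n_novel
        # every planted locus lies within the genome and carries its sequence
        for entry in man.planted_known + man.planted_novel:
            chrom_seq = bundle.genome[entry["chrom"]]
            placed = chrom_seq[entry["start"] : entry["end"]]
            expect = entry["precursor"]
            if entry["strand"] == "-":
                from saltmir.iofmt import revcomp
                expect = revcomp(expect)
            assert placed == expect

    def test_default_contexts_all_present(self, default_run):
        import json

        man = json.loads(
            (default_run["outdir"] / "manifest.json").read_text()
        )
        assert set(man["contexts"]) == {
            "intergenic", "intronic", "exonic", "5'UTR", "3'UTR"
        }

    def test_no_planted_elements_gives_empty_manifest(self):
        cfg = SyntheticConfig(
            n_chromosomes=1, chrom_len=8000, n_known=0, n_novel=0, n_genes=0,
            n_decoys_rrna=0, n_decoys_trna=0, n_decoys_snorna=0,
            n_decoys_snrna=0, n_decoys_scrna=0, n_repeat_families=0,
            n_other_tags=0, n_transcript_only_precursors=0,
        )
        bundle = build_genome(cfg, np.random.default_rng(3))
        man = bundle.manifest
        assert man.planted_known == [] and man.planted_novel == []
        assert len(bundle.genome["chr1"]) == 8000

    def test_repeat_copies_above_cap_is_capacity_error(self):
        cfg = mini_synthetic_config()
        cfg.repeat_copies = (21,)
        with pytest.raises(CapacityError):
            build_genome(cfg, np.random.default_rng(2))


class TestSimulateLibraries:
    def test_deterministic_fastq_bytes(self, tmp_path):
        cfg = mini_synthetic_config()
        outputs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            bundle = build_genome(cfg, rng)
            control, treated, _ = simulate_libraries(bundle, cfg, rng)
            p = tmp_path / "c.fastq"
            write_fastq(p, control)
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]

    def test_zero_contaminant_fractions(self):
        cfg = mini_synthetic_config()
        for f in ("frac_low_quality", "frac_adapter5", "frac_no_adapter3",
                  "frac_no_insert", "frac_polya", "frac_bad_length"):
            setattr(cfg, f, 0.0)
        rng = np.random.default_rng(4)
        bundle = build_genome(cfg, rng)
        _, _, man = simulate_libraries(bundle, cfg, rng)
        for lib in ("control", "treated"):
            assert sum(man.contaminants[lib].values()) == 0

    def test_short_adapter_is_parameter_error(self):
        from saltmir.config import CleaningConfig

        cfg = mini_synthetic_config()
        rng = np.random.default_rng(4)
        bundle = build_genome(cfg, rng)
        bad = CleaningConfig(adapter3="TGGAA")
        with pytest.raises(ParameterError):
            simulate_libraries(bundle, cfg, rng, clean_cfg=bad)
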