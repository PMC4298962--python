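import math
from collections import Counter

import numpy as np
import pytest

from armsurvey import pipeline, simgen
from armsurvey.simgen import (ConfigError, InputError, Rearrangement, SimConfig,
                              simulate_reads, simulate_reference_genomes,
                              simulate_wheat_arm)


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(repeat_fraction=1.2)
        with pytest.raises(ConfigError):
            SimConfig(purity=-0.1)
        with pytest.raises(ConfigError):
            SimConfig(coverage_fold=0)

    def test_genic_plus_repeat_budget_must_fit(self):
        with pytest.raises(ConfigError, match="genic"):
            SimConfig(arm_size=100_000, n_genes=200, repeat_fraction=0.9)

    def test_rearrangement_coercion_and_validation(self):
        cfg = SimConfig(rearrangement_spec=[("inversion", 10, 20)])
        assert cfg.rearrangement_spec[0] == Rearrangement("inversion", 10, 20)
        with pytest.raises(ConfigError):
            SimConfig(rearrangement_spec=[("sideways", 0, 5)])
        with pytest.raises(ConfigError):
            SimConfig(rearrangement_spec=[("inversion", 5, 5)])


class TestReferenceGenomes:
    def test_determinism_byte_identical(self, tmp_path, small_cfg):
        for sub in ("a", "b"):
            sim = pipeline.simulate_all(small_cfg)
            simgen.write_simulation(tmp_path / sub, sim["panel"], sim["arm"],
                                    sim["reads"], sim["markers"],
                                    sim["transcripts"])
        for name in ("reads.fasta", "repeats.fasta", "markers.tsv",
                     "transcripts.fasta", "truth.json",
                     "references/bd.cds.fasta", "references/os.pos.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_no_divergence_gives_full_colinearity(self):
        cfg = SimConfig(n_genes=30, lineage_loss_rate=0.0, lineage_move_rate=0.0,
                        arm_size=400_000, repeat_fraction=0.3)
        panel = simulate_reference_genomes(cfg)
        for g in ("A", "B", "C"):
            main = panel.genomes[g].chromosome_genes(simgen.CHROM_MAIN)
            assert len(main) == 30
            assert [x.anc for x in main] == list(range(30))  # ancestral order kept

    def test_planted_conservation_classes_match_truth_labels(self):
        classes = {"ABC": 0.5, "AB": 0.25, "A": 0.25}
        cfg = SimConfig(n_genes=40, conservation_classes=classes,
                        arm_size=500_000, repeat_fraction=0.3,
                        lineage_move_rate=0.0)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        counts = Counter("".join(sorted(r.origins)) for r in arm.truth.gene_records
                         if r.syntenic)
        assert counts == {"ABC": 20, "AB": 10, "A": 10}

    def test_min_genes_precondition(self):
        with pytest.raises(ConfigError):
            simulate_reference_genomes(SimConfig(n_genes=5))


class TestWheatArm:
    def test_repeat_fraction_conserved_within_two_points(self, small_sim):
        truth = small_sim["arm"].truth
        frac = sum(e - s for s, e, _ in truth.repeat_intervals) / truth.arm_size
        assert abs(frac - small_sim["arm"].config.repeat_fraction) < 0.02

    def test_repeat_intervals_in_bounds_half_open(self, small_sim):
        truth = small_sim["arm"].truth
        for s, e, _ in truth.repeat_intervals:
            assert 0 <= s < e <= truth.arm_size

    def test_inversion_recorded_in_segment_structure(self):
        cfg = SimConfig(n_genes=30, arm_size=400_000, repeat_fraction=0.2,
                        rearrangement_spec=[("inversion", 10, 20)],
                        n_nonsyntenic_insertions=0)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        assert arm.truth.segment_structure == [(0, "+"), (1, "-"), (2, "+")]

    def test_out_of_bounds_rearrangement_rejected(self):
        cfg = SimConfig(n_genes=30, arm_size=400_000, repeat_fraction=0.2)
        cfg.rearrangement_spec = [Rearrangement("inversion", 10, 99)]
        panel = simulate_reference_genomes(cfg)
        with pytest.raises(ConfigError, match="out of bounds"):
            simulate_wheat_arm(cfg, panel)

    def test_telomere_bias_meets_binomial_lower_bound(self):
        cfg = SimConfig(seed=17, n_genes=200, arm_size=3_000_000,
                        repeat_fraction=0.2, nonsyntenic_telomere_bias=0.8,
                        n_nonsyntenic_pool=60, n_nonsyntenic_insertions=50)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        truth = arm.truth
        distal_start = 0.9 * truth.arm_size
        n_distal = sum(1 for r in truth.gene_records
                       if not r.syntenic and r.arm_start >= distal_start)
        # binomial(50, 0.8) 95% lower bound
        lower = 50 * 0.8 - 1.645 * math.sqrt(50 * 0.8 * 0.2)
        assert n_distal >= lower


class TestReads:
    def test_read_count_arithmetic(self):
        cfg = SimConfig(seed=2, arm_size=1_000_000, n_genes=20,
                        repeat_fraction=0.5, mean_read_len=347.0,
                        coverage_fold=1.61, purity=1.0, artifact_rate=0.0,
                        read_len_sd=0.0)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        reads = simulate_reads(arm, None, cfg)
        S = len(arm.sequence)
        assert len(reads) == round(1.61 * S / 347.0)

    def test_full_purity_no_artifacts_gives_empty_truth_sets(self):
        cfg = SimConfig(seed=2, arm_size=400_000, n_genes=20,
                        repeat_fraction=0.4, purity=1.0, artifact_rate=0.0)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        simulate_reads(arm, None, cfg)
        assert arm.truth.contaminant_read_ids == set()
        assert arm.truth.artifact_pairs == []

    def test_every_read_labelled_exactly_once(self, small_sim):
        truth = small_sim["arm"].truth
        cats = Counter(truth.read_category(r.read_id) for r in small_sim["reads"])
        assert sum(cats.values()) == len(small_sim["reads"])
        assert set(cats) <= {"target", "contaminant", "organelle"}

    def test_artifact_pairs_are_byte_identical(self, small_sim):
        by_id = {r.read_id: r for r in small_sim["reads"]}
        pairs = small_sim["arm"].truth.artifact_pairs
        assert pairs
        for a, b in pairs:
            assert by_id[a].sequence == by_id[b].sequence

    def test_empty_arm_rejected(self, small_cfg):
        arm = simgen.SimulatedArm("x", "", simgen.TruthSet(arm_size=0), {}, "A" * 100,
                                  small_cfg)
        with pytest.raises(InputError):
            simulate_reads(arm, None, small_cfg)

    def test_impure_sample_requires_contaminant_source(self):
        cfg = SimConfig(seed=2, arm_size=400_000, n_genes=20,
                        repeat_fraction=0.4, purity=0.8, organelle_fraction=0.0)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        with pytest.raises(InputError):
            simulate_reads(arm, None, cfg)


class TestMarkersTranscripts:
    def test_marker_bin_matches_gene_position(self, small_sim):
        truth = small_sim["arm"].truth
        bins = {b: (s, e) for b, s, e in truth.bin_boundaries}
        by_anc = {r.anc: r for r in truth.gene_records}
        for m in small_sim["markers"]:
            anc = int(m.marker_id[2:])
            rec = by_anc[anc]
            s, e = bins[m.bin]
            assert s <= (rec.arm_start + rec.arm_end) // 2 < e

    def test_marker_sequence_is_gene_subsequence(self, small_sim):
        seqs = small_sim["arm"].wheat_gene_seqs
        for m in small_sim["markers"]:
            anc = int(m.marker_id[2:])
            assert m.sequence in seqs[anc]

    def test_transcript_classes_follow_config_fractions(self):
        cfg = SimConfig(seed=4, arm_size=2_000_000, n_genes=150,
                        repeat_fraction=0.2, transcript_fraction_high=1.0,
                        transcript_fraction_low=0.0)
        panel = simulate_reference_genomes(cfg)
        arm = simulate_wheat_arm(cfg, panel)
        simgen.simulate_markers_and_transcripts(arm, cfg)
        assert all(r.transcript_class == "high" for r in arm.truth.gene_records)

    def test_requires_bin_boundaries(self, small_cfg):
        arm = simgen.SimulatedArm("x", "ACGT" * 100, simgen.TruthSet(arm_size=400),
                                  {}, "A" * 100, small_cfg)
        with pytest.raises(InputError):
            simgen.simulate_markers_and_transcripts(arm, small_cfg)
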