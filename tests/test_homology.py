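from collections import Counter

import numpy as np
import pytest

from armsurvey import homology
from armsurvey.homology import (build_gene_catalogue, contrast_arms,
                                dedup_artifacts, filter_nucleotide_hits,
                                filter_organellar, filter_protein_hits,
                                reciprocal_best)
from armsurvey.seqio import AlignmentHit, SurveyRead


def hit(q, s, db="genomeA", ev=1e-40, ident=90.0, sim=None, ln=120,
        qs=0, qe=120, ss=0, se=120):
    return AlignmentHit(q, s, ident, ln, ev, qs, qe, ss, se, db,
                        pct_similarity=sim)


class TestOrganellarFilter:
    def test_threshold_rules(self):
        reads = [SurveyRead("r1", "a", "A" * 100), SurveyRead("r2", "a", "A" * 100)]
        hits = [hit("r1", "chl", db="organelle", ident=96.0, qs=0, qe=80),
                hit("r2", "chl", db="organelle", ident=96.0, qs=0, qe=50)]
        out = filter_organellar(reads, hits)
        assert out["removed_ids"] == ["r1"]          # 96% over 80% of read
        assert [r.read_id for r in out["reads"]] == ["r2"]

    def test_identity_below_threshold_kept(self):
        reads = [SurveyRead("r1", "a", "A" * 100)]
        hits = [hit("r1", "chl", db="organelle", ident=94.0, qs=0, qe=100)]
        assert filter_organellar(reads, hits)["removed_ids"] == []

    def test_planted_organellar_contaminants_all_removed(self, small_sim,
                                                         small_hom):
        truth = small_sim["arm"].truth
        removed = set(small_hom["removed_organellar"])
        survived = truth.organelle_read_ids - removed
        # every organellar read either repeat-filtered upstream or removed here
        upstream = {r.read_id for r in small_hom["reads"]}
        assert not (survived & upstream)
        # no target reads removed by the organellar rule
        assert all(rid in truth.organelle_read_ids for rid in removed)


class TestProteinFilter:
    @pytest.mark.parametrize("ev,sim,ln,kept", [
        (1e-7, 80.0, 35, True),
        (1e-7, 80.0, 29, False),     # one residue short
        (1e-7, 74.9, 35, False),
        (1e-5, 80.0, 35, False),     # e-value too weak
        (1e-6, 75.0, 30, True),      # inclusive boundaries
    ])
    def test_boundaries(self, ev, sim, ln, kept):
        hits = [hit("r", "p", db="uniprot", ev=ev, sim=sim, ln=ln)]
        assert bool(filter_protein_hits(hits)) is kept

    def test_missing_similarity_errors(self):
        with pytest.raises(ValueError, match="similarity"):
            filter_protein_hits([hit("r", "p", db="uniprot", sim=None)])

    def test_idempotent(self):
        hits = [hit("r", "p", db="uniprot", sim=80.0),
                hit("r2", "p", db="uniprot", sim=60.0)]
        once = filter_protein_hits(hits)
        assert filter_protein_hits(once) == once


class TestNucleotideFilter:
    def test_other_species_vs_same_species_identity_floor(self):
        h = [hit("r", "u", db="unigene", ev=1e-31, ident=80.0, ln=100)]
        assert filter_nucleotide_hits(h, same_species=False) == h
        assert filter_nucleotide_hits(h, same_species=True) == []

    def test_best_hit_selection_matches_min_evalue_scan(self, rng):
        hits = []
        for q in range(8):
            for s in range(6):
                hits.append(hit(f"q{q}", f"s{s}", db="unigene",
                                ev=float(rng.uniform(1e-60, 1e-31)),
                                ident=85.0, ln=150))
        best = filter_nucleotide_hits(hits)
        # oracle: exhaustive min-evalue scan per query
        for q in range(8):
            mine = [h for h in best if h.query_id == f"q{q}"]
            assert len(mine) == 1
            want = min((h for h in hits if h.query_id == f"q{q}"),
                       key=lambda h: (h.evalue, -h.aln_len, h.subject_id))
            assert mine[0].subject_id == want.subject_id


class TestReciprocalBest:
    def test_mutual_best_toy(self):
        fwd = [hit("r1", "g1")]
        rev = [hit("g1", "r1")]
        assert len(reciprocal_best(fwd, rev)) == 1

    def test_read_dropped_when_reverse_prefers_other_gene(self):
        fwd = [hit("r1", "g1", ev=1e-40)]
        rev = [hit("g2", "r1", ev=1e-50), hit("g1", "r1", ev=1e-40)]
        assert reciprocal_best(fwd, rev) == []

    def test_matches_double_argmax_oracle_on_random_matrix(self, rng):
        n = 20
        fwd_scores = rng.uniform(1e-60, 1e-10, size=(n, n))
        rev_scores = rng.uniform(1e-60, 1e-10, size=(n, n))
        fwd = [hit(f"r{i}", f"g{j}", ev=float(fwd_scores[i, j]))
               for i in range(n) for j in range(n)]
        rev = [hit(f"g{j}", f"r{i}", ev=float(rev_scores[i, j]), ss=0, se=120)
               for i in range(n) for j in range(n)]
        got = {(h.query_id, h.subject_id) for h in reciprocal_best(fwd, rev)}
        want = set()
        for i in range(n):
            jf = int(np.argmin(fwd_scores[i]))
            jr = int(np.argmin(rev_scores[i]))
            if jf == jr:
                want.add((f"r{i}", f"g{jf}"))
        assert got == want


class TestDedup:
    def test_identical_reads_same_coords_collapse_to_one(self):
        seqs = {"r1": "ACGT" * 30, "r2": "ACGT" * 30, "r3": "ACGT" * 30}
        hits = [hit(r, "g1", ss=10, se=130) for r in seqs]
        out = dedup_artifacts(hits, seqs)
        assert [h.query_id for h in out["assignments"]] == ["r1"]
        assert sorted(out["dropped_read_ids"]) == ["r2", "r3"]

    def test_identical_reads_different_coords_both_survive(self):
        seqs = {"r1": "ACGT" * 30, "r2": "ACGT" * 30}
        hits = [hit("r1", "g1", ss=10, se=130), hit("r2", "g1", ss=20, se=140)]
        out = dedup_artifacts(hits, seqs)
        assert len(out["assignments"]) == 2

    def test_planted_artifacts_collapsed_no_genuine_loss(self, small_sim,
                                                         small_hom):
        truth = small_sim["arm"].truth
        for db, hits in small_hom["assignments_by_db"].items():
            kept = {h.query_id for h in hits}
            for a, b in truth.artifact_pairs:
                assert not ({a, b} <= kept), f"artifact pair survived in {db}"


class TestCatalogue:
    def test_single_read_gene_absent(self):
        out = build_gene_catalogue({"genomeA": [hit("r1", "g1")]})
        assert out["catalogue"] == {}

    def test_unigene_boundary_at_50_reads(self):
        hits_50 = [hit(f"r{i:03d}", "u1", db="unigene") for i in range(50)]
        hits_51 = [hit(f"r{i:03d}", "u2", db="unigene") for i in range(51)]
        out = build_gene_catalogue({"unigene": hits_50 + hits_51})
        keys = {k[1] for k in out["catalogue"]}
        assert keys == {"u1"}       # 51 reads -> excluded as probable repeat

    def test_venn_counts_planted_classes(self):
        # locus 1 conserved ABC, locus 2 only AB, locus 3 only in A
        dbs = {"genomeA": [hit("r1", "a1"), hit("r2", "a1"),
                           hit("r3", "a2"), hit("r4", "a2"),
                           hit("r5", "a3"), hit("r6", "a3")],
               "genomeB": [hit("r1", "b1", db="genomeB"), hit("r2", "b1", db="genomeB"),
                           hit("r3", "b2", db="genomeB"), hit("r4", "b2", db="genomeB")],
               "genomeC": [hit("r1", "c1", db="genomeC"), hit("r2", "c1", db="genomeC")]}
        out = build_gene_catalogue(dbs)
        assert out["venn"] == {"A": 1, "B": 0, "C": 0, "AB": 1, "AC": 0,
                               "BC": 0, "ABC": 1}

    def test_simulated_venn_equals_planted_class_counts(self):
        from armsurvey import pipeline, simgen
        cfg = simgen.SimConfig(
            seed=3, arm_size=500_000, n_genes=40, repeat_fraction=0.0,
            coverage_fold=6.0, purity=1.0, artifact_rate=0.0,
            conservation_classes={"ABC": 0.5, "AB": 0.2, "BC": 0.1, "A": 0.2},
            n_nonsyntenic_pool=20, n_nonsyntenic_insertions=0,
            n_contaminant_genes=5)
        sim = pipeline.simulate_all(cfg)
        hom = pipeline.run_homology(sim["reads"], sim["panel"])
        planted = Counter("".join(sorted(r.origins))
                          for r in sim["arm"].truth.gene_records)
        for cls in ("A", "B", "C", "AB", "AC", "BC", "ABC"):
            assert hom["venn"][cls] == planted.get(cls, 0)

    def test_cascade_idempotent_on_catalogue_support(self, small_hom):
        # re-applying the support rules to the retained assignments changes nothing
        out1 = build_gene_catalogue(small_hom["assignments_by_db"])
        retained = {
            db: [h for h in hits
                 if (db, h.subject_id) in out1["catalogue"]]
            for db, hits in small_hom["assignments_by_db"].items()}
        out2 = build_gene_catalogue(retained)
        assert out1["venn"] == out2["venn"]

    def test_arm_contrast_fisher(self):
        venn1 = {"A": 10, "B": 5, "C": 5, "AB": 10, "AC": 5, "BC": 5, "ABC": 60}
        venn2 = {"A": 10, "B": 5, "C": 5, "AB": 10, "AC": 5, "BC": 5, "ABC": 60}
        ps = contrast_arms(venn1, venn2)
        assert all(p == pytest.approx(1.0) for p in ps.values())
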