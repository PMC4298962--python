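import numpy as np
import pandas as pd
import pytest

from armsurvey import zipper as zp
from armsurvey.homology import GeneEvidence
from armsurvey.zipper import (ZipperRow, bin_synteny_stats, call_syntenic_blocks,
                              compare_zippers, detect_rearrangements,
                              window_density)


def row(i, gene, pos, syntenic=True, bin=None, chrom="1"):
    return ZipperRow(i, gene, chrom, pos, set(), bin, None, syntenic)


class TestWindowDensity:
    def test_colocated_genes_counted_in_every_covering_window(self):
        track = window_density({"1": [1_000_000] * 10}, window=500_000, step=50_000)
        starts, counts = track["1"]
        covering = (starts <= 1_000_000) & (starts + 500_000 > 1_000_000)
        assert (counts[covering] == 10).all()
        assert (counts[~covering] == 0).all()

    def test_empty_chromosome_all_zero(self):
        starts, counts = window_density({"1": []})["1"]
        assert counts.sum() == 0

    def test_matches_brute_force_recount(self, rng):
        positions = sorted(int(x) for x in rng.integers(0, 3_000_000, 1000))
        starts, counts = window_density({"1": positions})["1"]
        for w_start, c in zip(starts[::7], counts[::7]):
            brute = sum(w_start <= p < w_start + 500_000 for p in positions)
            assert c == brute

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            window_density({"1": [1]}, window=100, step=200)


class TestSyntenicBlocks:
    @staticmethod
    def tracks_with_uniform_density(genes_per_mb, length_mb, n_species=2):
        spacing = int(1e6 / genes_per_mb)
        positions = list(range(0, int(length_mb * 1e6), spacing))
        track = window_density({"1": positions})
        return {f"sp{i}": track for i in range(n_species)}, positions

    def test_dense_region_two_species_single_block(self):
        tracks, positions = self.tracks_with_uniform_density(60, 2.0)
        blocks = call_syntenic_blocks(tracks, gene_positions={"1": positions})
        assert len(blocks) == 1
        assert blocks[0].start == 0
        assert blocks[0].end >= 2.0e6 - 500_000
        assert blocks[0].gene_count >= 50

    def test_density_below_threshold_gives_no_blocks(self):
        tracks, _ = self.tracks_with_uniform_density(40, 2.0)
        assert call_syntenic_blocks(tracks) == []

    def test_min_species_requirement(self):
        tracks, _ = self.tracks_with_uniform_density(60, 2.0, n_species=1)
        assert call_syntenic_blocks(tracks, min_species=2) == []
        assert call_syntenic_blocks(tracks, min_species=1)


class TestDetectRearrangements:
    @staticmethod
    def zipper_from_order(order, ref):
        return [row(i, g, 100 * ref.index(g)) for i, g in enumerate(order)]

    def test_identity_permutation_single_plus_segment(self):
        ref = [f"g{i}" for i in range(20)]
        model = detect_rearrangements(self.zipper_from_order(ref, ref), ref)
        assert len(model["segments"]) == 1
        assert model["segments"][0]["orientation"] == "+"
        assert model["translocations"] == []

    def test_three_block_reversal_reported_in_reversed_order(self):
        ref = [f"g{i:02d}" for i in range(30)]
        order = ref[20:] + ref[10:20] + ref[:10]     # 1-2-3 -> 3-2-1
        model = detect_rearrangements(self.zipper_from_order(order, ref), ref)
        assert [s["orientation"] for s in model["segments"]] == ["+", "+", "+"]
        assert [s["genes"][0] for s in model["segments"]] == ["g20", "g10", "g00"]
        assert len(model["breakpoints"]) == 2

    def test_single_reversed_interval_flagged_as_inversion(self):
        ref = [f"g{i:02d}" for i in range(30)]
        order = ref[:10] + ref[10:20][::-1] + ref[20:]
        model = detect_rearrangements(self.zipper_from_order(order, ref), ref)
        assert [s["orientation"] for s in model["segments"]] == ["+", "-", "+"]

    def test_short_runs_reported_as_translocations(self):
        ref = [f"g{i:02d}" for i in range(30)]
        order = ref[:13] + [ref[28]] + ref[13:28] + [ref[29]]
        model = detect_rearrangements(self.zipper_from_order(order, ref), ref)
        assert any(t["n_genes"] < 5 for t in model["translocations"])

    def test_fewer_than_two_genes_empty_model(self):
        ref = ["g0", "g1"]
        model = detect_rearrangements([row(0, "g0", 0)], ref)
        assert model == {"segments": [], "translocations": [],
                         "breakpoints": [], "runs": []}

    def test_segment_model_reproduces_zipper_order(self):
        ref = [f"g{i:02d}" for i in range(40)]
        order = ref[27:] + [ref[1]] + ref[13:27][::-1] + ref[2:13]
        model = detect_rearrangements(self.zipper_from_order(order, ref), ref)
        rebuilt = zp.apply_segment_model(model["runs"])
        assert rebuilt == order


class TestBuildZipper:
    @staticmethod
    def make_catalogue(n=40, chrom="1", spacing=2_000):
        cat = {}
        for i in range(n):
            gid = f"bd1g{i:05d}"
            cat[("genomeA", gid)] = GeneEvidence(
                gid, "A", chrom, i * spacing, supporting_reads={f"r{i}a", f"r{i}b"},
                conservation_profile={"A", "B", "C"})
        return cat

    def test_unrearranged_zipper_reproduces_reference_order(self):
        cat = self.make_catalogue()
        ref_order = [f"bd1g{i:05d}" for i in range(40)]
        anchors = {f"bd1g{i:05d}": ("bin1" if i < 20 else "bin2", None)
                   for i in range(0, 40, 3)}
        rows = zp.build_zipper(cat, ref_order, [], ["bin1", "bin2"],
                               blocks=[zp.SyntenicBlock("1", 0, 100_000)],
                               anchors=anchors)
        assert [r.ref_gene for r in rows] == ref_order

    def test_minus_oriented_segment_reverses_reference_order(self):
        cat = self.make_catalogue()
        ref_order = [f"bd1g{i:05d}" for i in range(40)]
        # bins descend along the reference: the arm carries this block inverted
        anchors = {f"bd1g{i:05d}": (f"bin{4 - i // 10}", None)
                   for i in range(0, 40, 2)}
        rows = zp.build_zipper(cat, ref_order, [], ["bin1", "bin2", "bin3", "bin4"],
                               blocks=[zp.SyntenicBlock("1", 0, 100_000)],
                               anchors=anchors)
        assert [r.ref_gene for r in rows] == ref_order[::-1]

    def test_unknown_marker_bin_rejected(self):
        cat = self.make_catalogue(10)
        ref_order = [f"bd1g{i:05d}" for i in range(10)]
        with pytest.raises(ValueError, match="absent from declared bin order"):
            zp.build_zipper(cat, ref_order, [], ["bin1"],
                            blocks=[zp.SyntenicBlock("1", 0, 100_000)],
                            anchors={"bd1g00000": ("binX", None)})

    def test_nonsyntenic_genes_appended_with_bin_only_placement(self):
        cat = self.make_catalogue(10)
        out_gene = GeneEvidence("bd3g00001", "A", "3", 500,
                                supporting_reads={"x1", "x2"},
                                conservation_profile={"A", "B", "C"})
        cat[("genomeA", "bd3g00001")] = out_gene
        ref_order = [f"bd1g{i:05d}" for i in range(10)]
        anchors = {"bd1g00000": ("bin1", None), "bd3g00001": ("bin2", 7.5)}
        rows = zp.build_zipper(cat, ref_order, [], ["bin1", "bin2"],
                               blocks=[zp.SyntenicBlock("1", 0, 100_000)],
                               anchors=anchors)
        assert rows[-1].ref_gene == "bd3g00001"
        assert rows[-1].syntenic is False
        assert rows[-1].bin == "bin2"


class TestBinSynteny:
    def test_identical_composition_gives_p_one(self):
        rows = []
        i = 0
        for b in ("bin1", "bin2"):
            for syn in [True] * 10 + [False] * 10:
                rows.append(row(i, f"g{i}", i, syntenic=syn, bin=b))
                i += 1
        out = bin_synteny_stats(rows)
        assert out["fisher_p"].tolist() == pytest.approx([1.0, 1.0])

    def test_two_by_two_matches_hypergeometric_oracle(self):
        import math

        def enumerate_fisher(a, b, c, d):
            r1, r2, c1 = a + b, c + d, a + c
            denom = math.comb(r1 + r2, c1)
            p_obs = math.comb(r1, a) * math.comb(r2, c) / denom
            return min(sum(
                math.comb(r1, x) * math.comb(r2, c1 - x) / denom
                for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                if math.comb(r1, x) * math.comb(r2, c1 - x) / denom
                <= p_obs * (1 + 1e-9)), 1.0)
        rows = []
        i = 0
        for b, syn_n, non_n in (("bin1", 10, 30), ("bin2", 60, 40)):
            for syn in [True] * syn_n + [False] * non_n:
                rows.append(row(i, f"g{i}", i, syntenic=syn, bin=b))
                i += 1
        out = bin_synteny_stats(rows).set_index("bin")
        assert out.loc["bin1", "fisher_p"] == pytest.approx(
            enumerate_fisher(10, 30, 60, 40), rel=1e-7)

    def test_low_power_bins_flagged(self):
        rows = [row(0, "g0", 0, True, "bin1"), row(1, "g1", 1, False, "bin1"),
                row(2, "g2", 2, True, "bin2"), row(3, "g3", 3, True, "bin2"),
                row(4, "g4", 4, True, "bin2"), row(5, "g5", 5, False, "bin2"),
                row(6, "g6", 6, False, "bin2")]
        out = bin_synteny_stats(rows).set_index("bin")
        assert bool(out.loc["bin1", "low_power"]) is True
        assert bool(out.loc["bin2", "low_power"]) is False


class TestCompareZippers:
    def test_identical_zippers_all_center(self):
        rows = [row(i, f"g{i}", i) for i in range(12)]
        out = compare_zippers(rows, rows, rows)
        assert out["venn"]["z1z2z3"] == 12
        assert sum(v for k, v in out["venn"].items() if k != "z1z2z3") == 0

    def test_disjoint_zippers_empty_center(self):
        z1 = [row(i, f"a{i}", i) for i in range(5)]
        z2 = [row(i, f"b{i}", i) for i in range(5)]
        z3 = [row(i, f"c{i}", i) for i in range(5)]
        out = compare_zippers(z1, z2, z3)
        assert out["venn"]["z1z2z3"] == 0
        assert out["venn"]["z1"] == 5

    def test_link_table_positions(self):
        z1 = [row(0, "g1", 0), row(1, "g2", 1)]
        z2 = [row(0, "g2", 0)]
        z3 = []
        out = compare_zippers(z1, z2, z3)
        links = out["links"].set_index("gene")
        assert links.loc["g2", "pos_z1"] == 1
        assert links.loc["g2", "pos_z2"] == 0
        assert pd.isna(links.loc["g1", "pos_z2"])
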