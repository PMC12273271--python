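"""PMD post-processing and DMR annotation/enrichment."""

import numpy as np
import pandas as pd
import pytest

from cgibench import dmr, ingest, pmd
from cgibench.intervals import ChromSizes, make_tiles
from conftest import max_overlap_oracle


def frame(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestPmdMergeFilter:
    @pytest.mark.parametrize(
        "gap,merged", [(150_000, True), (200_000, True), (200_001, False)])
    def test_merge_gap_inclusive(self, gap, merged):
        raw = frame([("chr1", 0, 250_000), ("chr1", 250_000 + gap, 600_000 + gap)])
        out = pmd.merge_pmd_calls(raw)
        assert (len(out) == 1) == merged

    @pytest.mark.parametrize("length,kept", [(200_000, False), (200_001, True)])
    def test_size_filter_strict(self, length, kept):
        out = pmd.filter_pmd_size(frame([("chr1", 0, length)]))
        assert (len(out) == 1) == kept

    def test_empty_input(self):
        empty = frame([])
        assert pmd.filter_pmd_size(pmd.merge_pmd_calls(empty)).empty

    def test_merge_then_filter_idempotent(self):
        rng = np.random.default_rng(31)
        starts = np.sort(rng.choice(5_000_000, size=12, replace=False))
        raw = frame([("chr1", int(s), int(s + rng.integers(50_000, 400_000)))
                     for s in starts])
        once = pmd.filter_pmd_size(pmd.merge_pmd_calls(raw))
        twice = pmd.filter_pmd_size(pmd.merge_pmd_calls(once))
        pd.testing.assert_frame_equal(once, twice)


class TestHmdComplement:
    def test_complement_and_gap_exclusion(self):
        sizes = ChromSizes({"chr1": 1_000_000})
        pmds = frame([("chr1", 100_000, 400_000)])
        gaps = frame([("chr1", 600_000, 750_000), ("chr1", 900_000, 950_000)])
        hmds, excluded = pmd.hmd_complement(pmds, gaps, sizes)
        assert excluded[["start", "end"]].to_numpy().tolist() == [[600_000, 750_000]]
        got = hmds[["start", "end"]].to_numpy().tolist()
        # the 50-kb run stays HMD; the 150-kb run is excluded from both classes
        assert got == [[0, 100_000], [400_000, 600_000], [750_000, 1_000_000]]

    def test_no_gaps_plain_complement(self):
        sizes = ChromSizes({"chr1": 500_000})
        hmds, excluded = pmd.hmd_complement(
            frame([("chr1", 0, 200_000)]), frame([]), sizes)
        assert hmds[["start", "end"]].to_numpy().tolist() == [[200_000, 500_000]]
        assert excluded.empty


class TestClassifyTiles:
    def test_majority_and_tie_to_hmd(self):
        tiles = frame([("chr1", 0, 100_000), ("chr1", 100_000, 200_000),
                       ("chr1", 200_000, 300_000)])
        pmds = frame([("chr1", 0, 60_000), ("chr1", 100_000, 150_000)])
        hmds = frame([("chr1", 60_000, 100_000), ("chr1", 150_000, 200_000)])
        labels = pmd.classify_tiles(tiles, pmds, hmds)
        assert labels.tolist() == ["PMD", "HMD", "unlabeled"]

    def test_matches_per_base_majority_random_layouts(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            length = 1_000_000
            sizes = ChromSizes({"chr1": length})
            edges = np.sort(rng.choice(length, size=7, replace=False))
            segs, prev, labels_pool = [], 0, ["PMD", "HMD", "none"]
            for e in list(edges) + [length]:
                if e > prev:
                    segs.append((prev, int(e), labels_pool[int(rng.integers(3))]))
                    prev = int(e)
            pmds = frame([("chr1", s, e) for s, e, l in segs if l == "PMD"])
            hmds = frame([("chr1", s, e) for s, e, l in segs if l == "HMD"])
            tiles = make_tiles(sizes, 100_000)
            got = pmd.classify_tiles(tiles, pmds, hmds)
            for i, t in enumerate(tiles.itertuples()):
                counted = [(s, e, l) for s, e, l in segs if l in ("PMD", "HMD")]
                want = max_overlap_oracle((t.start, t.end), counted,
                                          none_label="unlabeled")
                # the library tie rule is HMD, the oracle breaks ties
                # lexicographically — identical for the {HMD, PMD} label pair
                assert got.iloc[i] == want


class TestNaivePmdSeeds:
    def methylome(self, levels, spacing=100):
        calls = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(len(levels)) * spacing,
            "meth": levels,
            "cov": 30.0,
        })
        return ingest.Methylome("s", ingest.WGBS, calls=calls)

    def test_uniformly_methylated_has_no_calls(self):
        m = self.methylome(np.full(2_000, 0.9))
        assert pmd.naive_pmd_seeds(m).empty

    def test_degenerate_threshold_calls_everything(self):
        m = self.methylome(np.full(2_000, 0.9))
        out = pmd.naive_pmd_seeds(m, threshold=1.01)
        assert len(out) == 1 and out.loc[0, "start"] == 0

    def test_planted_block_recovered(self):
        levels = np.full(10_000, 0.9)
        levels[4_000:9_000] = 0.5  # 500 kb at 100 bp spacing
        m = self.methylome(levels)
        out = pmd.naive_pmd_seeds(m)
        assert len(out) == 1
        called = out.loc[0]
        inter = min(called["end"], 900_000) - max(called["start"], 400_000)
        assert inter / 500_000 >= 0.9

    def test_window_too_small_errors(self):
        with pytest.raises(ValueError, match="window"):
            pmd.naive_pmd_seeds(self.methylome(np.full(100, 0.5)), window=5)


class TestDmrTable:
    def write(self, tmp_path, rows):
        p = tmp_path / "dmrs.tsv"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_parse_filter_and_direction(self, tmp_path):
        p = self.write(tmp_path, [
            ("chr1", 100, 900, 0.05, 0.3, 12, 0.5, 0.2),
            ("chr1", 2_000, 2_500, 0.01, -0.3, 15, 0.2, 0.5),
            ("chr2", 10, 400, 0.002, 0.25, 11, 0.4, 0.15),
        ])
        records = dmr.read_dmr_table(p)
        assert records["direction"].tolist() == ["hyper", "hypo", "hyper"]
        kept = dmr.filter_dmrs(records)
        assert len(kept) == 2  # q = 0.05 dropped (strict)

    def test_non_numeric_q_errors(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 1, 2, "bad", 0.3, 10, 0.5, 0.2)])
        with pytest.raises(ValueError, match="non-numeric q"):
            dmr.read_dmr_table(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert dmr.read_dmr_table(p).empty


class TestDmrAssignment:
    def test_max_overlap_and_state_grouping(self):
        dmrs = frame([("chr1", 0, 1_000), ("chr1", 5_000, 5_100)])
        part = frame([("chr1", 0, 700, "open_water"), ("chr1", 700, 1_000, "shore"),
                      ("chr1", 5_000, 5_100, "13_ReprPC")],
                     cols=("chrom", "start", "end", "context"))
        got = dmr.assign_dmr_features(dmrs, part, state_grouping=dmr.STATE_GROUPS)
        assert got.tolist() == ["open_water", "Polycomb-repressed"]

    def test_tie_lexicographic_and_unassigned(self):
        dmrs = frame([("chr1", 0, 1_000), ("chr2", 0, 100)])
        part = frame([("chr1", 0, 500, "b_class"), ("chr1", 500, 1_000, "a_class")],
                     cols=("chrom", "start", "end", "context"))
        got = dmr.assign_dmr_features(dmrs, part)
        assert got.tolist() == ["a_class", "unassigned"]

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(41)
        labels = ["cgi", "shore", "shelf", "open_water"]
        for _ in range(100):
            edges = np.sort(rng.choice(20_000, size=9, replace=False))
            segs, prev = [], 0
            for e in list(edges) + [20_000]:
                if e > prev:
                    segs.append((prev, int(e), labels[int(rng.integers(4))]))
                    prev = int(e)
            part = frame([("chr1", s, e, l) for s, e, l in segs],
                         cols=("chrom", "start", "end", "context"))
            dmrs = frame([("chr1", int(s), int(s + rng.integers(50, 3_000)))
                          for s in rng.integers(0, 18_000, size=5)])
            got = dmr.assign_dmr_features(dmrs, part)
            for i, d in enumerate(dmrs.itertuples()):
                assert got.iloc[i] == max_overlap_oracle((d.start, d.end), segs)


class TestBackgroundDmrs:
    def test_length_matched_and_deterministic(self):
        sizes = ChromSizes({"chr1": 1_000_000, "chr2": 500_000})
        dmrs = frame([("chr1", 100, 900), ("chr2", 0, 2_000)])
        a = dmr.sample_background_dmrs(dmrs, sizes, n_per_dmr=5, seed=11)
        b = dmr.sample_background_dmrs(dmrs, sizes, n_per_dmr=5, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert ((a["end"] - a["start"]).to_numpy() == [800] * 5 + [2_000] * 5).all()
        assert (a.loc[:4, "chrom"] == "chr1").all()

    def test_short_chromosome_fallback(self):
        sizes = ChromSizes({"chr1": 1_000_000, "chr2": 1_000})
        dmrs = frame([("chr2", 0, 5_000)])
        out = dmr.sample_background_dmrs(dmrs, sizes, n_per_dmr=3, seed=2)
        assert (out["chrom"] == "chr1").all() and out["fallback"].all()

    def test_class_fractions_track_genome_composition(self):
        sizes = ChromSizes({"chr1": 1_000_000})
        part = frame([("chr1", 0, 250_000, "A"), ("chr1", 250_000, 1_000_000, "B")],
                     cols=("chrom", "start", "end", "context"))
        dmrs = frame([("chr1", 500_000, 500_500)] * 40)
        bg = dmr.sample_background_dmrs(dmrs, sizes, n_per_dmr=25, seed=8)
        classes = dmr.assign_dmr_features(bg, part)
        frac_a = (classes == "A").mean()
        assert frac_a == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / 1000))


class TestEnrichment:
    def test_log2_ratio_values(self):
        table = dmr.feature_enrichment(["x", "x", "y", "y"], ["x", "y", "y", "y"])
        assert table.loc["x", "log2_enrichment"] == pytest.approx(1.0)

    def test_self_enrichment_zero(self):
        classes = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        table = dmr.feature_enrichment(classes, classes)
        assert np.allclose(table["log2_enrichment"], 0.0)

    def test_zero_fraction_sentinels(self):
        table = dmr.feature_enrichment(["a"], ["b"])
        assert table.loc["a", "log2_enrichment"] == np.inf
        assert table.loc["b", "log2_enrichment"] == -np.inf


class TestSetOverlap:
    def test_merged_region_membership(self):
        out = dmr.dmr_set_overlap({
            "s1": frame([("chr1", 0, 100)]),
            "s2": frame([("chr1", 50, 150)]),
        })
        assert out[["start", "end"]].to_numpy().tolist() == [[0, 150]]
        assert bool(out.loc[0, "s1"]) and bool(out.loc[0, "s2"])

    def test_disjoint_sets_block_diagonal(self):
        out = dmr.dmr_set_overlap({
            "s1": frame([("chr1", 0, 100)]),
            "s2": frame([("chr1", 500, 600)]),
        })
        assert out["s1"].tolist() == [True, False]
        assert out["s2"].tolist() == [False, True]

    def test_self_overlap_idempotent(self):
        df = frame([("chr1", 0, 100), ("chr1", 300, 400)])
        out = dmr.dmr_set_overlap({"a": df, "b": df})
        assert out["a"].all() and out["b"].all()
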