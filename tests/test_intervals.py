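"""Genome annotation: context partition, promoters, states, tiles, projection."""

import io

import numpy as np
import pandas as pd
import pytest

from cgibench import intervals as iv
from conftest import context_label_oracle, expand_partition, max_overlap_oracle


def frame(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestReadBed:
    def test_parses_and_sorts(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# header\nchr1\t300\t400\tB\nchr1\t100\t200\tA\n")
        df = iv.read_bed(p)
        assert df.loc[0, ["start", "end", "name"]].tolist() == [100, 200, "A"]

    def test_malformed_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(iv.BedParseError, match=":1:"):
            iv.read_bed(p)

    def test_clipping_and_unknown_chrom(self, tmp_path, toy_sizes):
        p = tmp_path / "c.bed"
        p.write_text("chr1\t99990\t100500\nchrx_alt\t0\t10\n")
        df = iv.read_bed(p, toy_sizes)
        assert len(df) == 1 and df.loc[0, "end"] == 100_000


class TestContextPartition:
    def test_single_cgi_definition(self):
        sizes = iv.ChromSizes({"chr1": 100_000})
        ctx = iv.derive_cgi_context(frame([("chr1", 10_000, 11_000)]), sizes)
        by = {c: set(map(tuple, sub[["start", "end"]].to_numpy()))
              for c, sub in ctx.groupby("context")}
        assert by["cgi"] == {(10_000, 11_000)}
        assert by["shore"] == {(8_000, 10_000), (11_000, 13_000)}
        assert by["shelf"] == {(6_000, 8_000), (13_000, 15_000)}
        assert by["open_water"] == {(0, 6_000), (15_000, 100_000)}

    def test_close_cgis_gap_is_all_shore(self):
        sizes = iv.ChromSizes({"chr1": 100_000})
        cgis = frame([("chr1", 10_000, 11_000), ("chr1", 12_000, 13_000)])
        ctx = iv.derive_cgi_context(cgis, sizes)
        gap = ctx[(ctx["start"] >= 11_000) & (ctx["end"] <= 12_000)]
        assert set(gap["context"]) == {"shore"}
        assert gap["end"].sum() - gap["start"].sum() == 1_000

    def test_edge_truncation(self):
        sizes = iv.ChromSizes({"chr1": 100_000})
        ctx = iv.derive_cgi_context(frame([("chr1", 500, 1_500)]), sizes)
        left = ctx[(ctx["context"] == "shore") & (ctx["end"] == 500)]
        assert left["start"].tolist() == [0]
        assert not ((ctx["context"] == "shelf") & (ctx["end"] <= 500)).any()

    def test_partition_covers_every_base_once_random(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            length = int(rng.integers(20_000, 100_000))
            sizes = iv.ChromSizes({"chr1": length})
            n = int(rng.integers(1, 6))
            starts = np.sort(rng.integers(0, length - 500, size=n))
            cgis = frame([("chr1", int(s), int(s + rng.integers(200, 2_000)))
                          for s in starts])
            cgis["end"] = np.minimum(cgis["end"], length)
            ctx = iv.derive_cgi_context(cgis, sizes)
            covered = np.zeros(length, dtype=int)
            for _, row in ctx.iterrows():
                covered[row["start"]:row["end"]] += 1
            assert (covered == 1).all(), "each base labeled exactly once"
            expected = context_label_oracle(
                iv.merge_intervals(cgis)[["start", "end"]].to_numpy(), length)
            got = expand_partition(ctx, "chr1", length)
            assert (got == expected).all()


class TestPromoters:
    def test_strand_definitions_and_clip(self):
        genes = pd.DataFrame({
            "chrom": ["chr1"] * 3, "tss": [10_000, 10_000, 1_000],
            "strand": ["+", "-", "+"], "name": ["a", "b", "c"],
        })
        prom = iv.define_promoters(genes).set_index("name")
        assert prom.loc["a", ["start", "end"]].tolist() == [8_500, 10_500]
        assert prom.loc["b", ["start", "end"]].tolist() == [9_500, 11_500]
        assert prom.loc["c", ["start", "end"]].tolist() == [0, 1_500]

    def test_missing_strand_errors(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [5_000], "strand": [None]})
        with pytest.raises(ValueError, match="strand"):
            iv.define_promoters(genes)


class TestPromoterCgiFlag:
    @pytest.mark.parametrize(
        "cgi,promoter,expected",
        [
            # 20% of the 1 kb CGI overlapped: boundary inclusive
            (("chr1", 1_000, 2_000), ("chr1", 1_800, 3_800), True),
            # 150 < 200 (CGI side) and 150 < 400 (promoter side)
            (("chr1", 1_000, 2_000), ("chr1", 1_850, 3_850), False),
            # promoter side qualifies: 400 >= 0.2 * 2000
            (("chr1", 0, 5_000), ("chr1", 4_600, 6_600), True),
        ],
    )
    def test_boundary_semantics(self, cgi, promoter, expected):
        flags = iv.flag_promoter_cgis(frame([cgi]), frame([promoter]))
        assert flags[0] == expected

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cgis = frame([("chr1", int(s), int(s + rng.integers(200, 3_000)))
                          for s in rng.integers(0, 50_000, size=5)])
            proms = frame([("chr1", int(s), int(s + 2_000))
                           for s in rng.integers(0, 50_000, size=5)])
            flags = iv.flag_promoter_cgis(cgis, proms)
            for i, c in cgis.iterrows():
                want = any(
                    (ov := min(c.end, p.end) - max(c.start, p.start)) > 0
                    and (ov >= 0.2 * (c.end - c.start) or ov >= 0.2 * (p.end - p.start))
                    for p in proms.itertuples()
                )
                assert flags[i] == want


class TestChromatinState:
    def test_largest_overlap_and_tie(self):
        cgis = frame([("chr1", 0, 1_000), ("chr1", 2_000, 3_000)])
        segs = frame(
            [("chr1", 0, 600, "A"), ("chr1", 600, 1_000, "B"),
             ("chr1", 2_000, 2_500, "15_Quies"), ("chr1", 2_500, 3_000, "13_ReprPC")],
            cols=("chrom", "start", "end", "name"),
        )
        states = iv.assign_chromatin_state(cgis, segs)
        assert states.tolist() == ["A", "13_ReprPC"]

    def test_zero_overlap_unassigned(self):
        states = iv.assign_chromatin_state(
            frame([("chr2", 0, 100)]), frame([("chr1", 0, 100, "A")],
                                             cols=("chrom", "start", "end", "name")))
        assert states.tolist() == ["unassigned"]

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        labels = ["1_TssA", "13_ReprPC", "15_Quies", "9_Het"]
        for _ in range(100):
            cgis = frame([("chr1", int(s), int(s + rng.integers(100, 1_500)))
                          for s in np.sort(rng.choice(20_000, size=3, replace=False))])
            edges = np.sort(rng.integers(0, 25_000, size=19))
            segs = []
            prev = 0
            for e in list(edges) + [25_000]:
                if e > prev:
                    segs.append(("chr1", prev, int(e), labels[int(rng.integers(4))]))
                    prev = int(e)
            seg_df = frame(segs, cols=("chrom", "start", "end", "name"))
            got = iv.assign_chromatin_state(cgis, seg_df)
            for i, c in enumerate(cgis.itertuples()):
                want = max_overlap_oracle(
                    (c.start, c.end), [(s, e, l) for _, s, e, l in segs])
                assert got.iloc[i] == want


class TestPrc2Flags:
    def test_state_based(self):
        cgis = frame([("chr1", 0, 1_000)] * 3)
        states = pd.Series(["13_ReprPC", "1_TssA", "10_TssBiv"])
        promoter = np.array([True, True, False])
        flags = iv.flag_prc2_targets(cgis, "state_based", states=states,
                                     promoter_flag=promoter)
        # the PRC2 set is reduced to promoter CGIs
        assert flags.tolist() == [True, False, False]

    def test_domain_based_boundary(self):
        cgis = frame([("chr1", 0, 1_000), ("chr1", 2_000, 3_000)])
        domains = frame([("chr1", 0, 190), ("chr1", 2_000, 2_200)])
        flags = iv.flag_prc2_targets(cgis, "domain_based", h3k27me3_domains=domains)
        assert flags.tolist() == [False, True]  # 0.19 < 0.2 <= 0.20

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            iv.flag_prc2_targets(frame([("chr1", 0, 10)]), "other")


class TestTiles:
    def test_partial_tile_retained(self):
        tiles = iv.make_tiles(iv.ChromSizes({"chr1": 2_500}), 1_000)
        assert tiles[["start", "end"]].to_numpy().tolist() == [[0, 1000], [1000, 2000], [2000, 2500]]

    def test_autosomes_only(self, toy_sizes):
        tiles = iv.make_tiles(toy_sizes, 10_000, autosomes_only=True)
        assert "chrX" not in set(tiles["chrom"])
        assert len(tiles[tiles["chrom"] == "chr1"]) == 10


class TestProjection:
    def _target(self):
        return frame([("chr1", 0, 1_000, "H1"), ("chr1", 2_000, 3_000, "H2")],
                     cols=("chrom", "start", "end", "name"))

    def test_multi_overlap_keeps_all_pairs(self):
        lifted = frame([("chr1", 900, 2_100, "M1")], cols=("chrom", "start", "end", "name"))
        res = iv.project_hyper_set_across_species(lifted, self._target(), {"H1"})
        assert res.selected == {"M1"}
        assert set(res.mapping["target_cgi"]) == {"H1", "H2"}

    def test_no_overlap_excluded_and_unknown_chrom_counted(self):
        lifted = frame([("chr1", 5_000, 6_000, "M1"), ("chr9", 0, 100, "M2")],
                       cols=("chrom", "start", "end", "name"))
        res = iv.project_hyper_set_across_species(lifted, self._target(), {"H1"})
        assert res.selected == frozenset() and res.n_excluded == 1

    def test_monotone_in_hyper_set(self):
        rng = np.random.default_rng(5)
        lifted = frame([("chr1", int(s), int(s + 500), f"M{i}")
                        for i, s in enumerate(rng.integers(0, 9_500, size=20))],
                       cols=("chrom", "start", "end", "name"))
        target = frame([("chr1", int(s), int(s + 400), f"H{i}")
                        for i, s in enumerate(rng.integers(0, 9_600, size=15))],
                       cols=("chrom", "start", "end", "name"))
        small = iv.project_hyper_set_across_species(lifted, target, {"H1", "H2"})
        large = iv.project_hyper_set_across_species(
            lifted, target, {f"H{i}" for i in range(10)})
        assert small.selected <= large.selected
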