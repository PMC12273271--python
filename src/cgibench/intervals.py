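"""Genomic interval primitives and CGI-centric feature annotation.

All coordinates are 0-based half-open ([start, end)) internally; BED input is
native, 1-based dialects are shifted at the reader boundary. Interval sets are
plain :class:`pandas.DataFrame` objects with at least ``chrom``, ``start`` and
``end`` columns, sorted by (chrom, start).

The feature classes derived here follow the standard CGI-centric vocabulary:
shores are the 2 kb flanking each side of a CGI, shelves the outer 2 kb beyond
each shore, and the remainder of the genome is "open water". Promoters span
1500 bp upstream to 500 bp downstream of the TSS. A CGI is a promoter CGI when
at least 20% of either the CGI or the promoter overlaps, and a PRC2 target
when its dominant chromatin state is bivalent/Polycomb (human) or when an
H3K27me3 domain covers at least 20% of it (mouse); the final PRC2 set is
restricted to promoter CGIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end"]

#: ChromHMM states that mark PRC2 regulation in hESCs (bivalent + Polycomb).
PRC2_STATES = frozenset(
    {"10_TssBiv", "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk"}
)

_NON_AUTOSOME_SUFFIXES = {"x", "y", "m", "mt"}


class BedParseError(ValueError):
    """A malformed record in a BED-like file, carrying the line number."""


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome lengths plus the autosome subset.

    Autosomes default to every chromosome whose name (after stripping a
    ``chr`` prefix) is not X/Y/M/MT.
    """

    sizes: Mapping[str, int]
    autosomes: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        if not self.autosomes:
            object.__setattr__(
                self, "autosomes", frozenset(c for c in self.sizes if _is_autosome(c))
            )
        if not self.autosomes:
            raise ValueError("autosome set is empty")

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    @classmethod
    def read_tsv(cls, path) -> "ChromSizes":
        """Read a two-column (chrom, length) TSV."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "length"], comment="#"
        )
        return cls(sizes=dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.sizes.items():
                fh.write(f"{chrom}\t{length}\n")


def _is_autosome(chrom: str) -> bool:
    name = chrom.lower()
    if name.startswith("chr"):
        name = name[3:]
    return name not in _NON_AUTOSOME_SUFFIXES


def intervals_frame(records: Iterable[tuple], columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Build a sorted interval frame from (chrom, start, end, ...) tuples."""
    cols = list(columns) if columns is not None else BED_COLUMNS
    df = pd.DataFrame(records, columns=cols)
    return sort_intervals(df)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def interval_lengths(df: pd.DataFrame) -> np.ndarray:
    return (df["end"] - df["start"]).to_numpy()


def read_bed(path, chrom_sizes: ChromSizes | None = None) -> pd.DataFrame:
    """Read a BED3/4/6 file into a sorted interval frame.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Records
    with ``start >= end`` raise :class:`BedParseError` with the line number.
    When ``chrom_sizes`` is given, records on unknown chromosomes are skipped
    (counted in a warning) and intervals are clipped to chromosome bounds.
    """
    rows = []
    skipped_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: malformed interval {chrom}:{start}-{end} (start >= end)"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    skipped_unknown += 1
                    continue
                start = max(start, 0)
                end = min(end, chrom_sizes[chrom])
                if start >= end:
                    skipped_unknown += 1
                    continue
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else None
            rows.append((chrom, start, end, name, strand))
    if skipped_unknown:
        log.warning("%s: skipped %d records on unknown chromosomes", path, skipped_unknown)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return sort_intervals(df)


def write_bed(df: pd.DataFrame, path, extra_columns: Sequence[str] = ()) -> None:
    cols = BED_COLUMNS + [c for c in extra_columns if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is <= ``gap`` bp (0 merges touching/overlapping)."""
    if df.empty:
        return df[BED_COLUMNS].copy()
    df = sort_intervals(df[BED_COLUMNS])
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def complement_intervals(
    df: pd.DataFrame, chrom_sizes: ChromSizes, autosomes_only: bool = False
) -> pd.DataFrame:
    """Genome minus the (merged) intervals, over every chromosome in ``chrom_sizes``."""
    merged = merge_intervals(df)
    out = []
    for chrom in chrom_sizes:
        if autosomes_only and chrom not in chrom_sizes.autosomes:
            continue
        length = chrom_sizes[chrom]
        sub = merged[merged["chrom"] == chrom]
        prev = 0
        for s, e in zip(sub["start"], sub["end"]):
            s, e = max(s, 0), min(e, length)
            if s > prev:
                out.append((chrom, prev, s))
            prev = max(prev, e)
        if prev < length:
            out.append((chrom, prev, length))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Bases of ``a`` not covered by ``b`` (both merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for chrom, sub in a.groupby("chrom", sort=True):
        cuts = b[b["chrom"] == chrom]
        cs, ce = cuts["start"].to_numpy(), cuts["end"].to_numpy()
        for s, e in zip(sub["start"], sub["end"]):
            pos = s
            idx = np.searchsorted(ce, pos, side="right")
            while pos < e and idx < len(cs) and cs[idx] < e:
                if cs[idx] > pos:
                    out.append((chrom, pos, cs[idx]))
                pos = max(pos, ce[idx])
                idx += 1
            if pos < e:
                out.append((chrom, pos, e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def overlap_join(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All overlapping pairs between two interval frames.

    Returns a frame with ``a_index``, ``b_index`` (positional indices into the
    input frames) and ``overlap`` (bp).
    """
    trees: dict[str, IntervalTree] = {}
    for j, (chrom, s, e) in enumerate(zip(b["chrom"], b["start"], b["end"])):
        trees.setdefault(chrom, IntervalTree()).addi(s, e, j)
    rows = []
    for i, (chrom, s, e) in enumerate(zip(a["chrom"], a["start"], a["end"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(s, e):
            ov = min(e, hit.end) - max(s, hit.begin)
            if ov > 0:
                rows.append((i, hit.data, ov))
    return pd.DataFrame(rows, columns=["a_index", "b_index", "overlap"]).sort_values(
        ["a_index", "b_index"]
    ).reset_index(drop=True)


def total_overlap(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Per interval of ``a``: total bp overlapped by (merged) ``b``."""
    pairs = overlap_join(a, merge_intervals(b))
    out = np.zeros(len(a), dtype=int)
    if not pairs.empty:
        np.add.at(out, pairs["a_index"].to_numpy(), pairs["overlap"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# CGI context partition
# ---------------------------------------------------------------------------

def derive_cgi_context(
    cgis: pd.DataFrame,
    chrom_sizes: ChromSizes,
    shore_width: int = 2000,
    shelf_width: int = 2000,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Partition the genome into CGI / shore / shelf / open-water intervals.

    Every base is labeled by its distance to the nearest CGI base: 0 is CGI,
    up to ``shore_width`` is shore, up to ``shore_width + shelf_width`` is
    shelf, the remainder open water. This realizes the precedence
    CGI > shore > shelf with colliding flanks of neighboring CGIs split at the
    midpoint of the gap (the left CGI takes the extra base of odd gaps).
    Overlapping input CGIs are merged first.
    """
    merged = merge_intervals(cgis)
    shelf_reach = shore_width + shelf_width
    rows: list[tuple[str, int, int, str]] = []

    def bands(anchor_start: int, anchor_end: int, outward: int, left: bool):
        """Label [anchor_start, anchor_end) by distance from a CGI edge."""
        # distance d in [0, outward): shore if d < shore_width, shelf if < shelf_reach
        segs = []
        d0 = 0
        for width, label in ((shore_width, "shore"), (shelf_width, "shelf")):
            d1 = min(d0 + width, outward)
            if d1 > d0:
                segs.append((d0, d1, label))
            d0 = d1
        if outward > d0:
            segs.append((d0, outward, "open_water"))
        for a, b, label in segs:
            if left:
                segs_start, segs_end = anchor_end - b, anchor_end - a
            else:
                segs_start, segs_end = anchor_start + a, anchor_start + b
            yield segs_start, segs_end, label

    for chrom in chrom_sizes:
        if autosomes_only and chrom not in chrom_sizes.autosomes:
            continue
        length = chrom_sizes[chrom]
        sub = merged[merged["chrom"] == chrom]
        starts = np.clip(sub["start"].to_numpy(), 0, length)
        ends = np.clip(sub["end"].to_numpy(), 0, length)
        if len(starts) == 0:
            rows.append((chrom, 0, length, "open_water"))
            continue
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), "cgi"))
        # leading gap [0, starts[0]): owned by the first CGI (right anchor)
        if starts[0] > 0:
            for a, b, label in bands(0, int(starts[0]), int(starts[0]), left=True):
                rows.append((chrom, a, b, label))
        # inner gaps: split at midpoint, left CGI gets the extra base
        for i in range(len(starts) - 1):
            g0, g1 = int(ends[i]), int(starts[i + 1])
            if g1 <= g0:
                continue
            mid = g0 + (g1 - g0 + 1) // 2
            for a, b, label in bands(g0, mid, mid - g0, left=False):
                rows.append((chrom, a, b, label))
            for a, b, label in bands(mid, g1, g1 - mid, left=True):
                rows.append((chrom, a, b, label))
        # trailing gap
        if ends[-1] < length:
            for a, b, label in bands(int(ends[-1]), length, length - int(ends[-1]), left=False):
                rows.append((chrom, a, b, label))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "context"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    # coalesce adjacent same-label pieces (e.g. the two halves of a wide gap)
    out = []
    for (chrom, label), sub in df.groupby(["chrom", "context"], sort=False):
        merged_sub = merge_intervals(sub)
        for s, e in zip(merged_sub["start"], merged_sub["end"]):
            out.append((chrom, s, e, label))
    res = pd.DataFrame(out, columns=["chrom", "start", "end", "context"])
    return res.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def define_promoters(
    genes: pd.DataFrame,
    upstream: int = 1500,
    downstream: int = 500,
    chrom_sizes: ChromSizes | None = None,
) -> pd.DataFrame:
    """Promoter intervals around each TSS (strand-aware), clipped at 0.

    ``genes`` needs columns ``chrom``, ``tss`` and ``strand``; a ``name``
    column is carried through when present.
    """
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene record needs a '+' or '-' strand")
    tss = genes["tss"].to_numpy()
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    start = np.maximum(start, 0)
    df = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "name": genes["name"].to_numpy() if "name" in genes else None,
            "strand": genes["strand"].to_numpy(),
        }
    )
    if chrom_sizes is not None:
        lengths = df["chrom"].map(dict(chrom_sizes.sizes)).to_numpy()
        df["end"] = np.minimum(df["end"], lengths)
        df = df[df["start"] < df["end"]]
    return sort_intervals(df)


def flag_promoter_cgis(
    cgis: pd.DataFrame, promoters: pd.DataFrame, min_frac: float = 0.2
) -> np.ndarray:
    """True per CGI iff some promoter overlaps >= ``min_frac`` of the CGI or
    of that promoter (inclusive, evaluated per promoter)."""
    flags = np.zeros(len(cgis), dtype=bool)
    pairs = overlap_join(cgis, promoters)
    if pairs.empty:
        return flags
    cgi_len = interval_lengths(cgis)[pairs["a_index"].to_numpy()]
    prom_len = interval_lengths(promoters)[pairs["b_index"].to_numpy()]
    ov = pairs["overlap"].to_numpy()
    ok = (ov >= min_frac * cgi_len) | (ov >= min_frac * prom_len)
    flags[np.unique(pairs["a_index"].to_numpy()[ok])] = True
    return flags


def assign_chromatin_state(
    cgis: pd.DataFrame, state_segments: pd.DataFrame, state_column: str = "name"
) -> pd.Series:
    """Per CGI, the chromatin state with the largest total overlap.

    Ties break to the lexicographically smallest state label; CGIs with no
    overlapping segment get ``"unassigned"``.
    """
    pairs = overlap_join(cgis, state_segments)
    labels = pd.Series(["unassigned"] * len(cgis), index=cgis.index)
    if pairs.empty:
        return labels
    pairs = pairs.assign(state=state_segments[state_column].to_numpy()[pairs["b_index"]])
    totals = pairs.groupby(["a_index", "state"])["overlap"].sum().reset_index()
    totals = totals.sort_values(
        ["a_index", "overlap", "state"], ascending=[True, False, True], kind="stable"
    )
    best = totals.drop_duplicates("a_index", keep="first")
    labels.iloc[best["a_index"].to_numpy()] = best["state"].to_numpy()
    return labels


def flag_prc2_targets(
    cgis: pd.DataFrame,
    mode: str,
    *,
    states: pd.Series | None = None,
    h3k27me3_domains: pd.DataFrame | None = None,
    promoter_flag: np.ndarray | None = None,
    min_frac: float = 0.2,
) -> np.ndarray:
    """Flag PRC2-target CGIs.

    ``state_based`` (human): the assigned chromatin state is one of the five
    bivalent/Polycomb states. ``domain_based`` (mouse): an H3K27me3 domain
    covers >= ``min_frac`` of the CGI. When ``promoter_flag`` is supplied the
    final set is intersected with promoter CGIs.
    """
    if mode == "state_based":
        if states is None:
            raise ValueError("state_based mode requires per-CGI states")
        flags = states.isin(PRC2_STATES).to_numpy()
    elif mode == "domain_based":
        if h3k27me3_domains is None:
            raise ValueError("domain_based mode requires H3K27me3 domains")
        ov = total_overlap(cgis, h3k27me3_domains)
        flags = ov >= min_frac * interval_lengths(cgis)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if promoter_flag is not None:
        flags = flags & np.asarray(promoter_flag, dtype=bool)
    return flags


def make_tiles(
    chrom_sizes: ChromSizes, width: int, autosomes_only: bool = False
) -> pd.DataFrame:
    """Non-overlapping [k*w, (k+1)*w) tiles per chromosome; the final partial
    tile is retained."""
    if width <= 0:
        raise ValueError("tile width must be positive")
    rows = []
    for chrom in chrom_sizes:
        if autosomes_only and chrom not in chrom_sizes.autosomes:
            continue
        length = chrom_sizes[chrom]
        edges = list(range(0, length, width)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


@dataclass
class ProjectionResult:
    """Cross-species projection of a hyper-CGI set.

    ``selected`` holds the ids of source CGIs whose lifted interval overlaps
    at least one target CGI in the hyper set; ``mapping`` records every
    (source, target) overlap pair (many-to-many, hyper or not);
    ``n_excluded`` counts lifted intervals on chromosomes absent from the
    target annotation.
    """

    selected: frozenset[str]
    mapping: pd.DataFrame
    n_excluded: int


def project_hyper_set_across_species(
    source_cgis_lifted: pd.DataFrame,
    target_cgis: pd.DataFrame,
    target_hyper_set: Iterable[str],
) -> ProjectionResult:
    """Project a target-genome hyper-CGI set back onto lifted source CGIs.

    The lift itself is external input: ``source_cgis_lifted`` are source CGIs
    already expressed in target coordinates (with a ``name`` column of source
    ids). When a lifted CGI overlaps multiple target CGIs, all pairs are kept.
    """
    hyper = frozenset(target_hyper_set)
    target_chroms = set(target_cgis["chrom"])
    on_known = source_cgis_lifted["chrom"].isin(target_chroms).to_numpy()
    n_excluded = int((~on_known).sum())
    kept = source_cgis_lifted[on_known].reset_index(drop=True)
    pairs = overlap_join(kept, target_cgis)
    src_names = kept["name"].to_numpy()
    tgt_names = target_cgis["name"].to_numpy()
    mapping = pd.DataFrame(
        {
            "source_cgi": src_names[pairs["a_index"]] if not pairs.empty else [],
            "target_cgi": tgt_names[pairs["b_index"]] if not pairs.empty else [],
            "overlap": pairs["overlap"] if not pairs.empty else [],
        }
    )
    if mapping.empty:
        return ProjectionResult(frozenset(), mapping, n_excluded)
    selected = frozenset(mapping.loc[mapping["target_cgi"].isin(hyper), "source_cgi"])
    return ProjectionResult(selected, mapping, n_excluded)
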