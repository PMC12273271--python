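"""Parsing per-CpG methylation calls into a uniform :class:`Methylome`.

Supported dialects: bedGraph (0-based, fraction only), Bismark coverage
(1-based, percent + methylated/unmethylated counts) and a generic TSV with an
explicit column map. Array beta tables come with a probe manifest mapping
probe ids to genomic positions. Whenever read counts are present the
methylation fraction is recomputed as count_M / (count_M + count_U); the
percent column is never trusted.

Coverage filters follow the assay: WGBS keeps CpGs covered by 10-150 reads,
RRBS 5-150, both bounds inclusive; array betas carry no coverage and pass the
filter untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import ChromSizes

log = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "meth", "cov"]

CONDITIONS = ("healthy", "precursor", "tumor", "model", "xenograft")


@dataclass(frozen=True)
class AssayProfile:
    """Per-assay coverage bounds and the minimum CpGs per feature."""

    assay: str
    min_cov: int | None
    max_cov: int | None
    min_cpgs_per_feature: int

    def __post_init__(self) -> None:
        if self.min_cov is not None and self.max_cov is not None:
            if self.min_cov > self.max_cov:
                raise ValueError("min_cov must be <= max_cov")
        if self.min_cpgs_per_feature < 1:
            raise ValueError("min_cpgs_per_feature must be >= 1")


WGBS = AssayProfile("wgbs", 10, 150, 3)
RRBS = AssayProfile("rrbs", 5, 150, 3)
# Coverage bounds for the targeted-enrichment panel are not separately
# specified; it defaults to the WGBS profile and stays configurable.
ENRICHMENT = AssayProfile("enrichment", 10, 150, 3)
ARRAY = AssayProfile("array", None, None, 1)

PROFILES = {p.assay: p for p in (WGBS, RRBS, ENRICHMENT, ARRAY)}


@dataclass
class Methylome:
    """One sample's per-CpG methylation calls.

    ``calls`` has columns chrom, pos (0-based), meth in [0,1] and cov (float;
    NaN when the assay carries no read counts), unique and sorted within each
    chromosome.
    """

    sample_id: str
    assay_profile: AssayProfile
    condition: str = "healthy"
    group: str = ""
    calls: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.calls is None:
            self.calls = pd.DataFrame(columns=CALL_COLUMNS)
        self.calls = _canonical_calls(self.calls)

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def _canonical_calls(df: pd.DataFrame) -> pd.DataFrame:
    df = df[CALL_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["meth"] = df["meth"].astype(float)
    df["cov"] = df["cov"].astype(float)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate CpG positions within a methylome")
    return df


def _check_meth_range(meth: np.ndarray, what: str) -> None:
    bad = (meth < 0) | (meth > 1)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{what}: methylation value {meth[idx]} outside [0, 1] (record {idx})")


def read_cpg_calls(
    path,
    dialect: str,
    assay_profile: AssayProfile,
    *,
    sample_id: str | None = None,
    condition: str = "healthy",
    group: str = "",
    column_map: Mapping[str, str] | None = None,
    one_based: bool = False,
    chrom_whitelist: Iterable[str] | None = None,
) -> Methylome:
    """Read per-CpG calls in one of the supported dialects.

    Zero-read records are dropped (counted in the log) rather than erroring.
    ``chrom_whitelist`` keeps only the listed chromosomes, e.g. to restrict a
    xenograft sample to the host genome's chromosomes.
    """
    sample_id = sample_id or str(path)
    if dialect == "bismark_cov":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "count_m", "count_u"],
            comment="#",
        )
        total = df["count_m"] + df["count_u"]
        n_zero = int((total == 0).sum())
        if n_zero:
            log.info("%s: dropped %d zero-read records", path, n_zero)
        df = df[total > 0]
        total = total[total > 0]
        calls = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(np.int64) - 1,  # Bismark is 1-based
                "meth": (df["count_m"] / total).astype(float),
                "cov": total.astype(float),
            }
        )
    elif dialect == "bedgraph":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "meth"],
            comment="#",
        )
        calls = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(np.int64),
                "meth": df["meth"].astype(float),
                "cov": np.nan,
            }
        )
    elif dialect == "generic_tsv":
        if column_map is None:
            raise ValueError("generic_tsv requires a column map")
        df = pd.read_csv(path, sep="\t", comment="#")
        calls = pd.DataFrame(
            {
                "chrom": df[column_map["chrom"]].astype(str),
                "pos": df[column_map["pos"]].astype(np.int64) - (1 if one_based else 0),
                "meth": df[column_map["meth"]].astype(float),
                "cov": df[column_map["cov"]].astype(float)
                if column_map.get("cov") and column_map["cov"] in df
                else np.nan,
            }
        )
        if "cov" in calls and calls["cov"].notna().any():
            n_zero = int((calls["cov"] == 0).sum())
            if n_zero:
                log.info("%s: dropped %d zero-read records", path, n_zero)
            calls = calls[(calls["cov"].isna()) | (calls["cov"] > 0)]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    _check_meth_range(calls["meth"].to_numpy(), str(path))
    if chrom_whitelist is not None:
        calls = calls[calls["chrom"].isin(set(chrom_whitelist))]
    return Methylome(sample_id, assay_profile, condition, group, calls)


def filter_coverage(methylome: Methylome) -> Methylome:
    """Keep calls with min_cov <= cov <= max_cov (inclusive both ends).

    No-op for assays without coverage bounds (arrays); calls with missing
    coverage fail any active bound.
    """
    prof = methylome.assay_profile
    calls = methylome.calls
    if prof.min_cov is None and prof.max_cov is None:
        return replace(methylome, calls=calls.copy())
    cov = calls["cov"]
    keep = cov.notna()
    if prof.min_cov is not None:
        keep &= cov >= prof.min_cov
    if prof.max_cov is not None:
        keep &= cov <= prof.max_cov
    return replace(methylome, calls=calls[keep].reset_index(drop=True))


def restrict_autosomes(methylome: Methylome, chrom_sizes: ChromSizes) -> Methylome:
    keep = methylome.calls["chrom"].isin(chrom_sizes.autosomes)
    return replace(methylome, calls=methylome.calls[keep].reset_index(drop=True))


def merge_replicates(methylomes: Sequence[Methylome], sample_id: str | None = None) -> Methylome:
    """Merge replicate methylomes by summing read counts per position.

    Merging must precede coverage filtering. Positions present in any
    replicate are retained; mixed assays are an error, as are calls without
    read counts (count-free betas cannot be count-merged).
    """
    if len(methylomes) < 2:
        raise ValueError("need at least two methylomes to merge")
    assays = {m.assay_profile.assay for m in methylomes}
    if len(assays) > 1:
        raise ValueError(f"cannot merge mixed assays: {sorted(assays)}")
    frames = []
    for m in methylomes:
        if m.calls["cov"].isna().any():
            raise ValueError("replicate merging requires read counts on every call")
        f = m.calls.copy()
        f["meth_reads"] = f["meth"] * f["cov"]
        frames.append(f[["chrom", "pos", "cov", "meth_reads"]])
    merged = (
        pd.concat(frames)
        .groupby(["chrom", "pos"], as_index=False)[["cov", "meth_reads"]]
        .sum()
    )
    merged["meth"] = merged["meth_reads"] / merged["cov"]
    first = methylomes[0]
    calls = merged[["chrom", "pos", "meth", "cov"]]
    return Methylome(
        sample_id or first.sample_id,
        first.assay_profile,
        first.condition,
        first.group,
        calls,
    )


def read_array_betas(
    path,
    manifest,
    *,
    sample_id: str | None = None,
    condition: str = "healthy",
    group: str = "",
    beta_column: str = "beta",
    probe_column: str = "probe_id",
) -> Methylome:
    """Read an array beta table (probe id, beta) positioned via a manifest.

    ``manifest`` is a path or DataFrame with probe_id, chrom, pos (0-based).
    Probes missing from the manifest are skipped (counted); duplicate probe
    ids are an error.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    betas = pd.read_csv(path, sep="\t")
    if betas[probe_column].duplicated().any():
        raise ValueError("duplicate probe ids in beta table")
    if manifest[probe_column].duplicated().any():
        raise ValueError("duplicate probe ids in manifest")
    _check_meth_range(betas[beta_column].to_numpy(dtype=float), str(path))
    joined = betas.merge(manifest, on=probe_column, how="left")
    missing = joined["chrom"].isna()
    if missing.any():
        log.info("%s: skipped %d probes absent from manifest", path, int(missing.sum()))
    joined = joined[~missing]
    calls = pd.DataFrame(
        {
            "chrom": joined["chrom"].astype(str),
            "pos": joined["pos"].astype(np.int64),
            "meth": joined[beta_column].astype(float),
            "cov": np.nan,
        }
    )
    return Methylome(sample_id or str(path), ARRAY, condition, group, calls)


def collapse_strand_pairs(methylome: Methylome) -> Methylome:
    """Optionally collapse +/- strand CpG calls one bp apart into one call.

    Calls are assumed destranded already (plus-strand coordinates); this
    helper sums counts of adjacent pairs for callers that emit both strands.
    """
    calls = methylome.calls
    if calls["cov"].isna().any():
        raise ValueError("strand collapsing requires read counts")
    anchor = calls["pos"].to_numpy().copy()
    chroms = calls["chrom"].to_numpy()
    # a call whose predecessor on the same chromosome sits at pos-1 is folded in
    prev_same = np.zeros(len(calls), dtype=bool)
    if len(calls) > 1:
        prev_same[1:] = (chroms[1:] == chroms[:-1]) & (anchor[1:] == anchor[:-1] + 1)
    anchor[prev_same] = anchor[prev_same] - 1
    f = calls.assign(anchor=anchor, meth_reads=calls["meth"] * calls["cov"])
    merged = f.groupby(["chrom", "anchor"], as_index=False)[["cov", "meth_reads"]].sum()
    merged["meth"] = merged["meth_reads"] / merged["cov"]
    merged = merged.rename(columns={"anchor": "pos"})
    return replace(methylome, calls=merged[CALL_COLUMNS])


def write_methylome(methylome: Methylome, path) -> None:
    """Write the canonical per-sample TSV (chrom, pos0, meth, cov)."""
    out = methylome.calls.copy()
    out["meth"] = out["meth"].map(lambda v: f"{v:.6f}")
    out["cov"] = out["cov"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_canonical(path, assay_profile: AssayProfile, **kwargs) -> Methylome:
    return read_cpg_calls(
        path,
        "generic_tsv",
        assay_profile,
        column_map={"chrom": "chrom", "pos": "pos", "meth": "meth", "cov": "cov"},
        **kwargs,
    )


def write_bismark_cov(methylome: Methylome, path) -> None:
    """Write calls in the Bismark coverage dialect (1-based, counts)."""
    calls = methylome.calls
    if calls["cov"].isna().any():
        raise ValueError("Bismark coverage output requires read counts")
    cov = calls["cov"].to_numpy().astype(np.int64)
    count_m = np.rint(calls["meth"].to_numpy() * cov).astype(np.int64)
    count_u = cov - count_m
    pct = np.where(cov > 0, 100.0 * count_m / cov, 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"] + 1,
            "end": calls["pos"] + 1,
            "pct": [f"{v:.6f}" for v in pct],
            "count_m": count_m,
            "count_u": count_u,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
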