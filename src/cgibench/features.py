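"""Feature-level methylation summaries.

Per-feature means are arithmetic means over the CpG calls falling inside each
feature interval, reported only when at least ``min_cpgs`` CpGs are covered
(3 for sequencing assays, 1 for arrays). Missing values are NaN throughout and
are excluded from medians and fractions. A CGI counts as methylated when its
mean methylation is strictly above 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import Methylome

METHYLATED_THRESHOLD = 0.2


@dataclass
class FeatureMethylMatrix:
    """Features x samples mean methylation with explicit missingness.

    ``values`` holds the mean methylation (NaN = missing, i.e. fewer than the
    required CpGs were covered); ``n_cpgs`` the covered-CpG count per cell.
    """

    values: pd.DataFrame
    n_cpgs: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("feature means must lie in [0, 1]")


def feature_means(
    methylome: Methylome,
    features: pd.DataFrame,
    min_cpgs: int | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Mean methylation per feature for one sample.

    ``features`` is a sorted interval frame with disjoint intervals per
    chromosome (CGIs, tiles) and a ``name`` column of feature ids. Returns
    (means, counts) indexed by feature id; means are NaN where the covered-CpG
    count is below ``min_cpgs`` (default: the assay profile's minimum).
    """
    if min_cpgs is None:
        min_cpgs = methylome.assay_profile.min_cpgs_per_feature
    names = features["name"].to_numpy()
    sums = np.zeros(len(features))
    counts = np.zeros(len(features), dtype=int)
    calls = methylome.calls
    feat_by_chrom = {c: sub for c, sub in features.reset_index(drop=True).groupby("chrom")}
    row_of = {c: sub.index.to_numpy() for c, sub in feat_by_chrom.items()}
    for chrom, sub in calls.groupby("chrom", sort=False):
        feats = feat_by_chrom.get(chrom)
        if feats is None:
            continue
        starts = feats["start"].to_numpy()
        ends = feats["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        rows = row_of[chrom][order]
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        idx = idx[inside]
        np.add.at(sums, rows[idx], meth[inside])
        np.add.at(counts, rows[idx], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= min_cpgs, sums / np.maximum(counts, 1), np.nan)
    return (
        pd.Series(means, index=names, name=methylome.sample_id),
        pd.Series(counts, index=names, name=methylome.sample_id),
    )


def build_matrix(
    methylomes: Sequence[Methylome],
    features: pd.DataFrame,
    min_cpgs: int | None = None,
) -> FeatureMethylMatrix:
    """Stack per-sample feature means into a features x samples matrix."""
    means, counts = [], []
    for m in methylomes:
        mu, n = feature_means(m, features, min_cpgs)
        means.append(mu)
        counts.append(n)
    return FeatureMethylMatrix(pd.concat(means, axis=1), pd.concat(counts, axis=1))


def classify_methylated(
    values: pd.DataFrame | pd.Series, threshold: float = METHYLATED_THRESHOLD
):
    """Strictly-above-threshold methylated flags; missing values propagate."""
    flags = values > threshold
    return flags.mask(values.isna())


@dataclass
class HealthySignature:
    """Per-feature median over healthy samples, the hyper-call reference."""

    median: pd.Series
    n_samples: pd.Series


def healthy_signature(
    matrix: FeatureMethylMatrix, healthy_sample_ids: Iterable[str]
) -> HealthySignature:
    """Median of healthy-sample feature means (midpoint rule for even counts);
    NaN where no healthy sample contributed."""
    ids = list(healthy_sample_ids)
    if not ids:
        raise ValueError("at least one healthy sample is required")
    sub = matrix.values[ids]
    return HealthySignature(
        median=sub.median(axis=1, skipna=True),
        n_samples=sub.notna().sum(axis=1),
    )


def set_summary(
    values: pd.DataFrame,
    cgi_set: Iterable[str],
    threshold: float = METHYLATED_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample median methylation and fraction methylated over a CGI set.

    The fraction's denominator is the number of evaluable (non-missing) set
    CGIs for that sample; samples with no evaluable CGI get NaN rows.
    """
    ids = [i for i in cgi_set]
    missing = set(ids) - set(values.index)
    if missing:
        raise ValueError(f"CGI set contains unknown features, e.g. {sorted(missing)[:3]}")
    sub = values.loc[ids]
    n_eval = sub.notna().sum(axis=0)
    median = sub.median(axis=0, skipna=True)
    frac = (sub > threshold).sum(axis=0) / n_eval.where(n_eval > 0)
    return pd.DataFrame(
        {"median": median, "fraction_methylated": frac, "n_evaluable": n_eval}
    )


def average_by_group(values: pd.DataFrame, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Average sample columns per group (e.g. per cell type), ignoring NaN."""
    missing = [s for s in values.columns if s not in grouping]
    if missing:
        raise ValueError(f"grouping lacks samples, e.g. {missing[:3]}")
    groups = pd.Series({s: grouping[s] for s in values.columns})
    return values.T.groupby(groups).mean().T


def solo_wcgw_score(methylome: Methylome, solo_sites: pd.DataFrame) -> tuple[float, int]:
    """Mean methylation over covered solo-WCGW CpG sites.

    Solo-WCGW CpGs are isolated CpGs (no close neighbor) inside common PMDs;
    their mean tracks global hypomethylation. ``solo_sites`` is a BED-like
    frame of single-bp positions. Returns (score, n_sites_used); score is NaN
    when no site is covered.
    """
    calls = methylome.calls
    used = 0
    total = 0.0
    for chrom, sub in solo_sites.groupby("chrom"):
        cc = calls[calls["chrom"] == chrom]
        hit = cc[cc["pos"].isin(set(sub["start"].astype(int)))]
        used += len(hit)
        total += float(hit["meth"].sum())
    if used == 0:
        return float("nan"), 0
    return total / used, used
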