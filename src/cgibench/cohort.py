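"""Cohort-level statistics: saturation resampling, CpG-level methylation
shifts and most-variable-CpG selection.

Saturation analysis asks how quickly randomly sampled tumors cover a tumor
type's full hyper-CGI repertoire: within each iteration ``n_draw`` samples
are drawn without replacement and the cumulative union size, relative to the
full cohort's union, is recorded; curves are averaged over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ingest import Methylome
from .intervals import ChromSizes, complement_intervals, merge_intervals

LEVEL_EDGES = np.arange(1, 10) / 10.0  # inner edges of the ten 0.1-wide bins


@dataclass
class SaturationCurve:
    tumor_type: str
    mean_curve: np.ndarray  # cumulative fraction at m = 1..n_draw
    n_iterations: int
    n_samples: int
    denominator: int


def saturation_curve(
    per_sample_hyper_sets: Mapping[str, Iterable[str]],
    n_iter: int = 100,
    n_draw: int = 100,
    seed: int | np.random.Generator = 0,
    tumor_type: str = "",
) -> SaturationCurve:
    """Mean cumulative hyper-CGI coverage over random sample orderings.

    The denominator is the union of hyper CGIs over the full cohort, so the
    curve measures coverage of the type's observed repertoire. Samples are
    drawn without replacement within an iteration; iterations are independent
    draws from one seeded generator.
    """
    ids = list(per_sample_hyper_sets)
    sets = {s: frozenset(per_sample_hyper_sets[s]) for s in ids}
    if n_draw > len(ids):
        raise ValueError(f"cannot draw {n_draw} of {len(ids)} samples without replacement")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    denominator = len(frozenset().union(*sets.values())) if sets else 0
    if denominator == 0:
        raise ValueError("the cohort union of hyper CGIs is empty")
    curves = np.zeros((n_iter, n_draw))
    for it in range(n_iter):
        order = rng.choice(len(ids), size=n_draw, replace=False)
        seen: set[str] = set()
        for m, j in enumerate(order):
            seen |= sets[ids[j]]
            curves[it, m] = len(seen)
    curves /= denominator
    return SaturationCurve(tumor_type, curves.mean(axis=0), n_iter, len(ids), denominator)


def background_mask(
    cgis: pd.DataFrame, chrom_sizes: ChromSizes, flank: int = 4000
) -> pd.DataFrame:
    """Genomic background: everything outside CGIs and their 4 kb flanks."""
    padded = cgis[["chrom", "start", "end"]].copy()
    padded["start"] = np.maximum(padded["start"] - flank, 0)
    padded["end"] = padded["end"] + flank
    for chrom in set(padded["chrom"]):
        if chrom in chrom_sizes:
            sel = padded["chrom"] == chrom
            padded.loc[sel, "end"] = np.minimum(padded.loc[sel, "end"], chrom_sizes[chrom])
    return complement_intervals(merge_intervals(padded), chrom_sizes)


def _mask_calls(methylome: Methylome, mask: pd.DataFrame) -> np.ndarray:
    """Methylation values of calls inside the (merged) mask intervals."""
    mask = merge_intervals(mask)
    keep = []
    for chrom, sub in methylome.calls.groupby("chrom", sort=False):
        m = mask[mask["chrom"] == chrom]
        if m.empty:
            continue
        starts = m["start"].to_numpy()
        ends = m["end"].to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        keep.append(sub["meth"].to_numpy()[inside])
    return np.concatenate(keep) if keep else np.empty(0)


def _level_fractions(meth: np.ndarray) -> np.ndarray:
    """Fraction of CpGs per 0.1-wide methylation level; the last bin is
    closed at 1.0."""
    bins = np.digitize(meth, LEVEL_EDGES)
    counts = np.bincount(bins, minlength=10).astype(float)
    return counts / counts.sum()


@dataclass
class LevelShift:
    """Tumor-vs-healthy shift of the CpG methylation-level distribution."""

    bin_edges: np.ndarray
    healthy_fraction: np.ndarray  # averaged across healthy samples
    tumor_fraction: pd.DataFrame  # bins x tumor samples
    shift: pd.DataFrame  # tumor_fraction minus healthy_fraction


def level_shift(
    healthy_methylomes: Iterable[Methylome],
    tumor_methylomes: Iterable[Methylome],
    region_mask: pd.DataFrame,
) -> LevelShift:
    """CpG methylation levels in 0.1 steps, healthy-averaged then subtracted.

    Per sample, CpGs inside the mask (the genomic background or a hyper-CGI
    set) are binned into [0,0.1), ..., [0.9,1.0]; the per-level fractions are
    averaged across healthy samples and subtracted from each tumor sample's
    fractions, so each tumor column of ``shift`` sums to zero.
    """
    healthy = list(healthy_methylomes)
    tumors = list(tumor_methylomes)
    if not healthy:
        raise ValueError("at least one healthy methylome is required")
    h_fracs = []
    for m in healthy:
        meth = _mask_calls(m, region_mask)
        if meth.size == 0:
            raise ValueError(f"no CpGs inside mask for healthy sample {m.sample_id}")
        h_fracs.append(_level_fractions(meth))
    healthy_mean = np.mean(h_fracs, axis=0)
    t_cols = {}
    for m in tumors:
        meth = _mask_calls(m, region_mask)
        if meth.size == 0:
            raise ValueError(f"no CpGs inside mask for tumor sample {m.sample_id}")
        t_cols[m.sample_id] = _level_fractions(meth)
    edges = np.concatenate([[0.0], LEVEL_EDGES, [1.0]])
    bins = [f"[{edges[i]:.1f},{edges[i + 1]:.1f})" for i in range(9)] + ["[0.9,1.0]"]
    tumor_fraction = pd.DataFrame(t_cols, index=bins)
    shift = tumor_fraction.sub(pd.Series(healthy_mean, index=bins), axis=0)
    return LevelShift(edges, healthy_mean, tumor_fraction, shift)


def top_variable_cpgs(
    cpg_matrix: pd.DataFrame,
    n: int = 5000,
    scope: str = "genome",
    cgis: pd.DataFrame | None = None,
    context: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select the n most variable CpGs across a cohort.

    ``cpg_matrix`` is CpGs x samples with a (chrom, pos) MultiIndex in
    genomic order. Only complete-case CpGs (non-missing in every sample) are
    eligible; variance uses the unbiased (n-1) estimator and ties break by
    genomic order. ``scope='cgi'`` restricts to CpGs inside the supplied CGI
    intervals. When a context partition is given, each selected CpG is
    annotated with its context class.
    """
    if scope not in ("genome", "cgi"):
        raise ValueError("scope must be 'genome' or 'cgi'")
    complete = cpg_matrix.dropna(axis=0)
    if scope == "cgi":
        if cgis is None:
            raise ValueError("scope='cgi' requires CGI intervals")
        keep = _positions_in(complete.index, cgis)
        complete = complete[keep]
    var = complete.var(axis=1, ddof=1)
    order = np.argsort(-var.to_numpy(), kind="stable")  # stable: genomic-order ties
    if len(order) < n:
        import logging

        logging.getLogger(__name__).warning(
            "only %d eligible CpGs for top_variable_cpgs(n=%d)", len(order), n
        )
    sel = complete.index[order[:n]]
    out = pd.DataFrame({"variance": var.loc[sel]}, index=sel)
    if context is not None:
        keep = {}
        for label in context["context"].unique():
            sub = context[context["context"] == label]
            inside = _positions_in(out.index, sub)
            for idx in out.index[inside]:
                keep[idx] = label
        out["context"] = [keep.get(idx, "unassigned") for idx in out.index]
    return out


def _positions_in(index: pd.MultiIndex, intervals: pd.DataFrame) -> np.ndarray:
    chroms = index.get_level_values(0).to_numpy()
    pos = index.get_level_values(1).to_numpy()
    merged = merge_intervals(intervals)
    inside = np.zeros(len(index), dtype=bool)
    for chrom in np.unique(chroms):
        m = merged[merged["chrom"] == chrom]
        if m.empty:
            continue
        sel = chroms == chrom
        p = pos[sel]
        idx = np.searchsorted(m["start"].to_numpy(), p, side="right") - 1
        ok = (idx >= 0) & (p < m["end"].to_numpy()[np.clip(idx, 0, None)])
        inside[np.flatnonzero(sel)[ok]] = True
    return inside
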