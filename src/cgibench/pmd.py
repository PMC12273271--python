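"""Partially methylated domain (PMD) post-processing.

Raw PMD calls (from an external HMM caller, or the naive seed caller below)
are merged when closer than 200 kb, filtered to > 200 kb, and complemented
into highly methylated domains (HMDs), excluding uncovered stretches longer
than 100 kb (e.g. centromeres). 100-kb tiles are then labeled PMD or HMD by
largest overlap (ties to HMD).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import Methylome
from .intervals import (
    ChromSizes,
    merge_intervals,
    overlap_join,
    subtract_intervals,
    complement_intervals,
)

MERGE_GAP = 200_000
MIN_PMD_SIZE = 200_000
UNCOVERED_GAP_MIN = 100_000


def merge_pmd_calls(raw_pmds: pd.DataFrame, gap: int = MERGE_GAP) -> pd.DataFrame:
    """Merge PMD calls whose gap is <= ``gap`` bp (inclusive, as in bedtools
    merge -d), e.g. to avoid classifying a single spanned gene body as HMD."""
    return merge_intervals(raw_pmds, gap=gap)


def filter_pmd_size(pmds: pd.DataFrame, min_size: int = MIN_PMD_SIZE) -> pd.DataFrame:
    """Keep PMDs strictly longer than ``min_size`` bp."""
    keep = (pmds["end"] - pmds["start"]) > min_size
    return pmds[keep].reset_index(drop=True)


def uncovered_runs(
    methylome: Methylome, chrom_sizes: ChromSizes, gap_min: int = UNCOVERED_GAP_MIN
) -> pd.DataFrame:
    """Maximal runs without covered CpGs longer than ``gap_min`` bp."""
    rows = []
    by_chrom = dict(tuple(methylome.calls.groupby("chrom")))
    for chrom in chrom_sizes:
        length = chrom_sizes[chrom]
        sub = by_chrom.get(chrom)
        if sub is None or sub.empty:
            if length > gap_min:
                rows.append((chrom, 0, length))
            continue
        pos = sub["pos"].to_numpy()
        bounds = np.concatenate([[-1], pos, [length]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            run_start, run_end = a + 1, b
            if run_end - run_start > gap_min:
                rows.append((chrom, int(run_start), int(run_end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def hmd_complement(
    pmds: pd.DataFrame,
    uncovered: pd.DataFrame,
    chrom_sizes: ChromSizes,
    gap_min: int = UNCOVERED_GAP_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HMDs = genome - PMDs - uncovered runs > ``gap_min``.

    ``uncovered`` may include shorter runs; only those above the threshold
    are excluded. Returns (hmds, excluded_gaps).
    """
    if uncovered.empty:
        excluded = uncovered.copy()
    else:
        long_enough = (uncovered["end"] - uncovered["start"]) > gap_min
        excluded = uncovered[long_enough].reset_index(drop=True)
    hmds = complement_intervals(pmds, chrom_sizes)
    if not excluded.empty:
        hmds = subtract_intervals(hmds, excluded)
    return hmds.reset_index(drop=True), excluded


def classify_tiles(
    tiles: pd.DataFrame, pmds: pd.DataFrame, hmds: pd.DataFrame
) -> pd.Series:
    """Label each tile PMD or HMD by the larger overlap.

    Ties go to HMD (conservative: avoids inflating PMD hypomethylation);
    tiles overlapping neither class (e.g. fully inside excluded gaps) are
    labeled 'unlabeled'.
    """
    pmd_bp = _overlap_bp(tiles, pmds)
    hmd_bp = _overlap_bp(tiles, hmds)
    labels = np.where(
        (pmd_bp == 0) & (hmd_bp == 0),
        "unlabeled",
        np.where(pmd_bp > hmd_bp, "PMD", "HMD"),
    )
    return pd.Series(labels, index=tiles.index)


def _overlap_bp(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    pairs = overlap_join(a, merge_intervals(b))
    out = np.zeros(len(a), dtype=int)
    if not pairs.empty:
        np.add.at(out, pairs["a_index"].to_numpy(), pairs["overlap"].to_numpy())
    return out


def naive_pmd_seeds(
    methylome: Methylome,
    cgis: pd.DataFrame | None = None,
    window: int = 50,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Sliding-window seed caller for PMD-like hypomethylated stretches.

    A deliberately simple stand-in for a dedicated PMD HMM so the pipeline
    runs end to end: maximal unions of ``window``-CpG sliding windows whose
    mean methylation over non-CGI CpGs is below ``threshold``. Returns raw
    calls meant to be fed through merge + size filtering.
    """
    if window < 10:
        raise ValueError("window must cover at least 10 CpGs")
    calls = methylome.calls
    if cgis is not None and not cgis.empty:
        keep = np.ones(len(calls), dtype=bool)
        merged = merge_intervals(cgis)
        for chrom, sub in calls.groupby("chrom", sort=False):
            m = merged[merged["chrom"] == chrom]
            if m.empty:
                continue
            pos = sub["pos"].to_numpy()
            idx = np.searchsorted(m["start"].to_numpy(), pos, side="right") - 1
            inside = (idx >= 0) & (pos < m["end"].to_numpy()[np.clip(idx, 0, None)])
            keep[sub.index.to_numpy()[inside]] = False
        calls = calls[keep]
    rows = []
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy()
        if len(pos) < window:
            continue
        csum = np.concatenate([[0.0], np.cumsum(meth)])
        win_mean = (csum[window:] - csum[:-window]) / window
        low = win_mean < threshold
        if not low.any():
            continue
        w_start = pos[:-window + 1][low] if window > 1 else pos[low]
        w_end = pos[window - 1:][low] + 1
        cur_s, cur_e = w_start[0], w_end[0]
        for s, e in zip(w_start[1:], w_end[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        rows.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-pair Jaccard index between two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    len_a = int((a["end"] - a["start"]).sum())
    len_b = int((b["end"] - b["start"]).sum())
    pairs = overlap_join(a, b)
    inter = int(pairs["overlap"].sum()) if not pairs.empty else 0
    union = len_a + len_b - inter
    return inter / union if union else float("nan")
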