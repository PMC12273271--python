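"""Shared fixtures: simulated cohorts and per-base brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cgibench import features
from cgibench.intervals import ChromSizes
from cgibench.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 30 healthy / 30 tumor, K=200 planted
    PRC2-target CGIs, p_include=0.8, gain 0.6, fixed seed."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    c = default_cohort
    return features.build_matrix(c.methylomes, c.annotation.cgis)


@pytest.fixture(scope="session")
def two_tissue_cohort():
    """Two tumor types whose healthy methylated-CGI repertoires overlap 90%
    (150 constitutive + 8 tissue-specific each: 150/166)."""
    cfg = SimulationConfig(n_healthy=12, n_tumor=12, seed=3)
    return simulate_cohort(cfg, n_types=2)


@pytest.fixture()
def toy_sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 60_000, "chrX": 50_000})


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the library's interval machinery)
# ---------------------------------------------------------------------------

def context_label_oracle(cgi_intervals, length, shore=2000, shelf=2000) -> np.ndarray:
    """Per-base context labels by distance to the nearest CGI base."""
    covered = np.zeros(length, dtype=bool)
    for s, e in cgi_intervals:
        covered[max(s, 0):min(e, length)] = True
    cgi_pos = np.flatnonzero(covered)
    labels = np.full(length, "open_water", dtype=object)
    if len(cgi_pos) == 0:
        return labels
    pos = np.arange(length)
    idx = np.searchsorted(cgi_pos, pos)
    big = np.iinfo(np.int64).max
    left = np.where(idx > 0, pos - cgi_pos[np.clip(idx - 1, 0, None)], big)
    right = np.where(idx < len(cgi_pos), cgi_pos[np.clip(idx, 0, len(cgi_pos) - 1)] - pos, big)
    d = np.minimum(left, right)
    labels[d == 0] = "cgi"
    labels[(d > 0) & (d <= shore)] = "shore"
    labels[(d > shore) & (d <= shore + shelf)] = "shelf"
    return labels


def expand_partition(partition: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    """Per-base labels from an interval partition frame."""
    labels = np.full(length, "", dtype=object)
    sub = partition[partition["chrom"] == chrom]
    for _, row in sub.iterrows():
        labels[row["start"]:row["end"]] = row["context"]
    return labels


def max_overlap_oracle(interval, segments, tie="lex", none_label="unassigned") -> str:
    """Per-base majority label for one interval over labeled segments."""
    s, e = interval
    counts: dict[str, int] = {}
    for seg_s, seg_e, label in segments:
        ov = min(e, seg_e) - max(s, seg_s)
        if ov > 0:
            counts[label] = counts.get(label, 0) + ov
    if not counts:
        return none_label
    best = max(counts.values())
    winners = sorted(k for k, v in counts.items() if v == best)
    return winners[0]


def feature_mean_oracle(calls: pd.DataFrame, feature, min_cpgs: int):
    """O(n*m) loop over all calls for one feature interval."""
    chrom, s, e = feature
    vals = [
        row.meth
        for row in calls.itertuples()
        if row.chrom == chrom and s <= row.pos < e
    ]
    if len(vals) < min_cpgs:
        return float("nan"), len(vals)
    return sum(vals) / len(vals), len(vals)
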