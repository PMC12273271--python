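"""DMR table ingestion, filtering, annotation and background enrichment.

DMRs arrive in the metilene output dialect (chrom, start, end, q-value, mean
methylation difference, number of CpGs, group means); the segmentation
statistic itself is external. Records are filtered at q < 0.05, assigned to
the feature (CGI context class or grouped chromatin state) with the maximum
overlap, and compared against length-matched random background regions via
log2 fraction ratios.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import ChromSizes, merge_intervals, overlap_join

METILENE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "q_value",
    "mean_diff",
    "n_cpgs",
    "mean_g1",
    "mean_g2",
]

#: Grouping of the 15 ChromHMM states into eight interpretable classes.
STATE_GROUPS: dict[str, str] = {
    "1_TssA": "Active TSS",
    "2_TssAFlnk": "Active TSS",
    "10_TssBiv": "Bivalent TSS",
    "11_BivFlnk": "Bivalent TSS",
    "3_TxFlnk": "Transcript",
    "4_Tx": "Transcript",
    "5_TxWk": "Transcript",
    "6_EnhG": "Enhancer",
    "7_Enh": "Enhancer",
    "12_EnhBiv": "Bivalent enhancer",
    "8_ZNF/Rpts": "Heterochromatin",
    "9_Het": "Heterochromatin",
    "13_ReprPC": "Polycomb-repressed",
    "14_ReprPCWk": "Polycomb-repressed",
    "15_Quies": "Quiescent",
}


def read_dmr_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a metilene-dialect DMR table.

    The default column order is metilene's documented output; ``column_map``
    (ours -> theirs) overrides it for dialect drift. The direction column is
    derived from the sign of the mean difference (group1 - group2):
    positive -> hyper, negative -> hypo.
    """
    if column_map is None:
        df = pd.read_csv(path, sep="\t", header=None, names=METILENE_COLUMNS, comment="#")
    else:
        raw = pd.read_csv(path, sep="\t", comment="#")
        df = pd.DataFrame({ours: raw[theirs] for ours, theirs in column_map.items()})
    if df.empty:
        df = pd.DataFrame(columns=METILENE_COLUMNS)
    q = pd.to_numeric(df.get("q_value", pd.Series(dtype=float)), errors="coerce")
    if len(df) and q.isna().any():
        bad = int(q.isna().idxmax())
        raise ValueError(f"{path}: non-numeric q value at record {bad}")
    df["q_value"] = q
    if len(df) and ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ValueError(f"{path}: q values must lie in [0, 1]")
    df["direction"] = np.where(df["mean_diff"].astype(float) >= 0, "hyper", "hypo")
    df.loc[df["mean_diff"].astype(float) == 0, "direction"] = "none"
    return df.reset_index(drop=True)


def filter_dmrs(records: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Keep DMRs with q strictly below ``q_max``."""
    return records[records["q_value"] < q_max].reset_index(drop=True)


def assign_dmr_features(
    dmrs: pd.DataFrame,
    feature_partition: pd.DataFrame,
    label_column: str = "context",
    state_grouping: Mapping[str, str] | None = None,
) -> pd.Series:
    """Assign each DMR the feature class with the maximum overlap.

    ``feature_partition`` is a labeled interval frame (CGI context classes or
    a chromatin-state segmentation). When ``state_grouping`` is given, labels
    are mapped through it first (e.g. 13_ReprPC -> Polycomb-repressed). Ties
    break to the lexicographically smallest class; zero overlap yields
    'unassigned'.
    """
    part = feature_partition.copy()
    labels = part[label_column].astype(str)
    if state_grouping is not None:
        labels = labels.map(lambda s: state_grouping.get(s, s))
    part = part.assign(_label=labels.to_numpy())
    pairs = overlap_join(dmrs, part)
    assigned = pd.Series(["unassigned"] * len(dmrs), index=dmrs.index)
    if pairs.empty:
        return assigned
    pairs = pairs.assign(label=part["_label"].to_numpy()[pairs["b_index"]])
    totals = pairs.groupby(["a_index", "label"])["overlap"].sum().reset_index()
    totals = totals.sort_values(
        ["a_index", "overlap", "label"], ascending=[True, False, True], kind="stable"
    )
    best = totals.drop_duplicates("a_index", keep="first")
    assigned.iloc[best["a_index"].to_numpy()] = best["label"].to_numpy()
    return assigned


def sample_background_dmrs(
    dmrs: pd.DataFrame,
    chrom_sizes: ChromSizes,
    excluded: pd.DataFrame | None = None,
    n_per_dmr: int = 10,
    seed: int | np.random.Generator = 0,
    max_tries: int = 100,
) -> pd.DataFrame:
    """Length-matched random background regions for a DMR set.

    For each DMR, ``n_per_dmr`` intervals of identical length are placed
    uniformly on the same chromosome (falling back to a random autosome with
    capacity when the chromosome is too short, flagged in the ``fallback``
    column). Placements overlapping ``excluded`` regions are rejection-sampled
    up to ``max_tries`` before being accepted with a flag. Deterministic
    under a fixed seed.
    """
    if n_per_dmr < 1:
        raise ValueError("n_per_dmr must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl = merge_intervals(excluded) if excluded is not None and len(excluded) else None
    autosomes = sorted(chrom_sizes.autosomes)
    rows = []
    for _, dmr in dmrs.iterrows():
        length = int(dmr["end"] - dmr["start"])
        for _ in range(n_per_dmr):
            chrom = dmr["chrom"]
            fallback = False
            if chrom not in chrom_sizes or chrom_sizes[chrom] <= length:
                candidates = [c for c in autosomes if chrom_sizes[c] > length]
                if not candidates:
                    raise ValueError(f"no chromosome can hold a region of length {length}")
                chrom = candidates[int(rng.integers(len(candidates)))]
                fallback = True
            limit = chrom_sizes[chrom] - length
            start = int(rng.integers(0, limit + 1))
            forced = False
            if excl is not None:
                sub = excl[excl["chrom"] == chrom]
                tries = 0
                while _hits(sub, start, start + length) and tries < max_tries:
                    start = int(rng.integers(0, limit + 1))
                    tries += 1
                forced = tries >= max_tries and _hits(sub, start, start + length)
            rows.append((chrom, start, start + length, fallback, forced))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fallback", "in_excluded"])


def _hits(sub: pd.DataFrame, start: int, end: int) -> bool:
    if sub.empty:
        return False
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    return bool(np.any((s < end) & (start < e)))


def feature_enrichment(
    dmr_classes: Sequence[str], background_classes: Sequence[str]
) -> pd.DataFrame:
    """Log2 ratio of DMR vs background class fractions.

    Classes absent from the background get a +inf sentinel, classes absent
    from the DMR set -inf; identical distributions yield 0 everywhere.
    """
    dmr_classes = pd.Series(list(dmr_classes))
    background_classes = pd.Series(list(background_classes))
    if dmr_classes.empty or background_classes.empty:
        raise ValueError("both class vectors must be non-empty")
    classes = sorted(set(dmr_classes) | set(background_classes))
    frac_dmr = dmr_classes.value_counts(normalize=True).reindex(classes, fill_value=0.0)
    frac_bg = background_classes.value_counts(normalize=True).reindex(classes, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frac_dmr.to_numpy() / frac_bg.to_numpy()
        log2 = np.where(
            frac_bg.to_numpy() == 0,
            np.inf,
            np.where(frac_dmr.to_numpy() == 0, -np.inf, np.log2(np.where(ratio > 0, ratio, 1.0))),
        )
    return pd.DataFrame(
        {"fraction_dmr": frac_dmr, "fraction_background": frac_bg, "log2_enrichment": log2},
        index=pd.Index(classes, name="feature_class"),
    )


def dmr_set_overlap(named_dmr_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Membership matrix of merged regions across several DMR sets.

    All sets (hyper and hypo should be supplied separately) are merged into
    disjoint union regions; membership is any-overlap of each set with each
    region. Returns a frame with chrom/start/end plus one boolean column per
    set name.
    """
    if len(named_dmr_sets) < 1:
        raise ValueError("at least one DMR set is required")
    union = merge_intervals(
        pd.concat([df[["chrom", "start", "end"]] for df in named_dmr_sets.values()])
    )
    out = union.copy()
    for name, df in named_dmr_sets.items():
        member = np.zeros(len(union), dtype=bool)
        pairs = overlap_join(union, df)
        if not pairs.empty:
            member[np.unique(pairs["a_index"].to_numpy())] = True
        out[name] = member
    return out
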