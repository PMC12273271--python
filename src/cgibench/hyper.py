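"""Hyper-CGI calling against a healthy median signature.

A CGI is called hyper in a tumor sample when it is unmethylated in the
healthy reference (signature <= 0.2), methylated in the sample (> 0.2), and
gains more than 0.1 over the signature. Per-type "common" sets collect CGIs
hyper in at least 50% of that type's samples; CGIs common in at least 30% of
tumor types form the pan-cancer set. Comparisons are exactly as stated — no
floating-point epsilon on the 0.2 / 0.1 thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMethylMatrix, HealthySignature

UNMETH_MAX = 0.2
METH_MIN = 0.2
MIN_DELTA = 0.1


@dataclass(frozen=True)
class HyperCallSet:
    """One tumor sample's hyper-CGI calls plus the eligible universe used."""

    sample_id: str
    called: frozenset[str]
    eligible: frozenset[str]

    def __post_init__(self) -> None:
        if not self.called <= self.eligible:
            raise ValueError("called CGIs must lie in the eligible universe")


@dataclass(frozen=True)
class CommonHyperSet:
    """CGIs hyper in >= min_fraction of a tumor type's samples."""

    tumor_type: str
    cgis: frozenset[str]
    n_samples: int
    min_fraction: float
    counts: Mapping[str, int]


@dataclass(frozen=True)
class PanCancerSet:
    """CGIs common to >= min_types of the examined tumor types."""

    cgis: frozenset[str]
    counts: Mapping[str, int]
    n_types: int
    min_types: int


def _inclusive_ceil(fraction: float, n: int) -> int:
    # count/n >= fraction with "at least" inclusive; the tiny guard only
    # protects against float products like 0.3 * 10 landing above 3.
    return max(1, math.ceil(fraction * n - 1e-9))


def call_sample_hyper(
    tumor_means: pd.Series,
    signature: HealthySignature | pd.Series,
    *,
    unmeth_max: float = UNMETH_MAX,
    meth_min: float = METH_MIN,
    min_delta: float = MIN_DELTA,
    sample_id: str | None = None,
) -> HyperCallSet:
    """Call hyper CGIs for one tumor sample against a healthy signature.

    Eligibility requires non-missing values in both inputs and a signature
    <= ``unmeth_max``; a CGI unmeasurable in the control cannot be classified
    as unmethylated in the healthy condition.
    """
    sig = signature.median if isinstance(signature, HealthySignature) else signature
    shared = tumor_means.index.intersection(sig.index)
    if len(shared) == 0:
        raise ValueError("tumor and signature CGI universes are disjoint")
    t = tumor_means.loc[shared]
    s = sig.loc[shared]
    present = t.notna() & s.notna()
    eligible = present & (s <= unmeth_max)
    called = eligible & (t > meth_min) & ((t - s) > min_delta)
    return HyperCallSet(
        sample_id=sample_id or str(tumor_means.name),
        called=frozenset(shared[called.to_numpy()]),
        eligible=frozenset(shared[eligible.to_numpy()]),
    )


def call_cohort_hyper(
    matrix: FeatureMethylMatrix,
    signature: HealthySignature,
    tumor_sample_ids: Iterable[str],
    **thresholds,
) -> dict[str, HyperCallSet]:
    return {
        s: call_sample_hyper(matrix.values[s], signature, sample_id=s, **thresholds)
        for s in tumor_sample_ids
    }


def common_hyper_set(
    call_sets: Mapping[str, HyperCallSet] | Sequence[HyperCallSet],
    min_fraction: float = 0.5,
    tumor_type: str = "",
) -> CommonHyperSet:
    """CGIs called hyper in at least ``min_fraction`` of the samples."""
    sets = list(call_sets.values()) if isinstance(call_sets, Mapping) else list(call_sets)
    if not sets:
        raise ValueError("at least one sample call set is required")
    n = len(sets)
    counts: dict[str, int] = {}
    for cs in sets:
        for cgi in cs.called:
            counts[cgi] = counts.get(cgi, 0) + 1
    threshold = _inclusive_ceil(min_fraction, n)
    members = frozenset(c for c, k in counts.items() if k >= threshold)
    return CommonHyperSet(tumor_type, members, n, min_fraction, counts)


def pan_cancer_set(
    common_sets: Mapping[str, CommonHyperSet | Iterable[str]],
    min_type_fraction: float = 0.3,
) -> PanCancerSet:
    """CGIs appearing in >= ceil(min_type_fraction * n_types) common sets."""
    if not common_sets:
        raise ValueError("at least one common set is required")
    n_types = len(common_sets)
    counts: dict[str, int] = {}
    for cs in common_sets.values():
        members = cs.cgis if isinstance(cs, CommonHyperSet) else frozenset(cs)
        for cgi in members:
            counts[cgi] = counts.get(cgi, 0) + 1
    threshold = _inclusive_ceil(min_type_fraction, n_types)
    members = frozenset(c for c, k in counts.items() if k >= threshold)
    return PanCancerSet(members, counts, n_types, threshold)


@dataclass
class RecoveryResult:
    """Cross-control recovery of per-type common hyper sets.

    ``recovered``: fraction of the original (matched-control) set found when
    rebuilding with each other tissue's signature (rows = tumor type, columns
    = control tissue); ``additional``: count of CGIs called beyond the
    original set. The diagonal is exactly 1 / 0 whenever the original set is
    non-empty.
    """

    recovered: pd.DataFrame
    additional: pd.DataFrame
    original_sets: dict[str, CommonHyperSet]
    sets: dict[tuple[str, str], frozenset[str]]  # (tumor type, control) -> common set


def cross_control_recovery(
    tumor_matrices_by_type: Mapping[str, FeatureMethylMatrix],
    signatures_by_type: Mapping[str, HealthySignature],
    min_fraction: float = 0.5,
    **thresholds,
) -> RecoveryResult:
    """Repeat the common-set construction with every control signature.

    For tumor type T and control C, each of T's tumor samples is re-called
    against C's healthy signature and the common set rebuilt; recovery is the
    overlap with T's original (matched-control) set, additions the set
    difference.
    """
    types = list(tumor_matrices_by_type)
    if set(types) - set(signatures_by_type):
        raise ValueError("every tumor type needs a matched signature")
    originals: dict[str, CommonHyperSet] = {}
    sets_tc: dict[tuple[str, str], frozenset[str]] = {}
    for t in types:
        matrix = tumor_matrices_by_type[t]
        for c in types:
            calls = call_cohort_hyper(
                matrix, signatures_by_type[c], matrix.values.columns, **thresholds
            )
            cs = common_hyper_set(calls, min_fraction, tumor_type=t)
            sets_tc[(t, c)] = cs.cgis
            if c == t:
                originals[t] = cs
    recovered = pd.DataFrame(index=types, columns=types, dtype=float)
    additional = pd.DataFrame(index=types, columns=types, dtype=float)
    for t in types:
        orig = originals[t].cgis
        for c in types:
            got = sets_tc[(t, c)]
            if len(orig) == 0:
                recovered.loc[t, c] = np.nan
            else:
                recovered.loc[t, c] = len(got & orig) / len(orig)
            additional.loc[t, c] = len(got - orig)
    return RecoveryResult(recovered, additional, originals, sets_tc)


@dataclass(frozen=True)
class EnrichmentResult:
    """Log2 enrichment of a called set vs uniform random sampling."""

    log2_enrichment: float
    observed_fraction: float
    null_mean_fraction: float
    n_draws: int
    capped: bool = False


def enrichment_vs_random(
    called_set: Iterable[str],
    original_set: Iterable[str],
    eligible_universe: Sequence[str],
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Enrichment of the overlap with ``original_set`` over a random null.

    The null draws ``n_draws`` uniform subsets of ``|called_set|`` CGIs from
    the eligible universe and measures their mean overlap fraction with the
    original set; the statistic is log2(observed / null mean), 0 meaning no
    difference to random sampling. Deterministic under a fixed seed. A zero
    null mean is capped at log2(observed / (1 / (n_draws * |called|))) with
    ``capped=True``.
    """
    if n_draws < 100:
        raise ValueError("need at least 100 null draws")
    called = frozenset(called_set)
    original = frozenset(original_set)
    universe = list(eligible_universe)
    uni = frozenset(universe)
    if not called <= uni or not original <= uni:
        raise ValueError("called and original sets must lie in the eligible universe")
    if not called:
        return EnrichmentResult(float("nan"), float("nan"), float("nan"), n_draws)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = len(called & original) / len(called)
    universe_arr = np.asarray(universe, dtype=object)
    in_original = np.asarray([u in original for u in universe], dtype=bool)
    k = len(called)
    null = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(len(universe_arr), size=k, replace=False)
        null[i] = in_original[draw].mean()
    null_mean = float(null.mean())
    if null_mean == 0.0:
        floor = 1.0 / (n_draws * k)
        value = float(np.log2(observed / floor)) if observed > 0 else 0.0
        return EnrichmentResult(value, observed, 0.0, n_draws, capped=True)
    if observed == 0.0:
        return EnrichmentResult(float("-inf"), observed, null_mean, n_draws)
    return EnrichmentResult(float(np.log2(observed / null_mean)), observed, null_mean, n_draws)
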