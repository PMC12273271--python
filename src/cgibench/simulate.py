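"""Synthetic methylome cohorts with planted ground truth.

The generator emulates the statistical structure of healthy/tumor bisulfite
cohorts: most CGIs (the PRC2-target promoter CGIs among them) are
unmethylated in healthy cells, roughly a third are constitutively methylated
across tissues plus a small tissue-specific complement, tumors gain
methylation at a planted subset of PRC2-target promoter CGIs (each tumor
includes each planted CGI with probability ``p_include``), and the genomic
background splits into highly methylated domains (HMDs) and partially
methylated domains (PMDs) whose methylation erodes with the sample's
proliferative history. Observed values are binomial read draws at
Poisson-distributed coverage (truncated to the assay bounds), or
Gaussian-noised beta values for the array mode.

Every pipeline stage can thus be tested against the planted truth without
any external download; outputs are written in the exact dialects the ingest
module reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (
    ARRAY,
    PROFILES,
    Methylome,
    write_bismark_cov,
)
from .intervals import ChromSizes, complement_intervals, write_bed


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the benchmark's default scenario: 30 healthy and 30 tumor
    WGBS samples, 500 CGIs of 1 kb on two 6-Mb autosomes, half of them
    PRC2-target promoter CGIs, 30% of CGIs constitutively methylated in every
    healthy tissue, a planted tumor set of 200 PRC2-target CGIs included per
    sample with probability 0.8 at a mean gain level of 0.6, and 30% of the
    genome in PMDs losing 0.1 methylation per unit of proliferative history
    (floored at 0.3).
    """

    n_chrom: int = 2
    chrom_length: int = 6_000_000
    cpg_spacing: int = 150
    n_cgis: int = 500
    cgi_length: int = 1000
    cgi_cpg_spacing: int = 15
    min_cgi_gap: int = 10_000
    frac_prc2: float = 0.5
    frac_constitutive_meth: float = 0.30
    tissue_specific_meth_per_tissue: int = 8
    n_healthy: int = 30
    n_tumor: int = 30
    planted_set_size: int = 200
    p_include: float = 0.8
    gain_level: float = 0.6
    pmd_fraction: float = 0.30
    pmd_min_size: int = 300_000
    pmd_max_size: int = 1_000_000
    pmd_gap_min: int = 400_000
    pmd_loss_per_unit_history: float = 0.1
    pmd_floor: float = 0.3
    healthy_history: float = 0.0
    tumor_history: float = 2.0
    hmd_baseline: float = 0.85
    unmeth_mean: float = 0.05
    meth_mean: float = 0.85
    beta_concentration: float = 50.0
    coverage_mean: float = 30.0
    assay: str = "wgbs"
    array_noise_sd: float = 0.05
    solo_isolation_bp: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_prc2", "frac_constitutive_meth", "p_include", "gain_level",
                     "pmd_fraction", "hmd_baseline", "unmeth_mean", "meth_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.planted_set_size > self.n_prc2:
            raise ValueError(
                f"planted_set_size={self.planted_set_size} exceeds the "
                f"{self.n_prc2} PRC2-target CGIs"
            )
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.assay not in PROFILES:
            raise ValueError(f"unknown assay {self.assay!r}")

    @property
    def n_prc2(self) -> int:
        return int(round(self.frac_prc2 * self.n_cgis))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedAnnotation:
    """Genome layout shared by every sample of a cohort."""

    chrom_sizes: ChromSizes
    cgis: pd.DataFrame  # chrom,start,end,name,prc2,promoter
    genes: pd.DataFrame  # chrom,tss,strand,name
    states: pd.DataFrame  # chrom,start,end,name (ChromHMM-style labels)
    pmds: pd.DataFrame  # planted PMD intervals
    cpg_positions: dict[str, np.ndarray]
    solo_sites: pd.DataFrame  # isolated background CpGs inside PMDs


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests."""

    planted: dict[str, frozenset[str]]  # per tumor type
    shared_core: frozenset[str]
    constitutive: frozenset[str]
    tissue_specific: dict[str, frozenset[str]]  # per tumor type / tissue
    included: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    histories: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    annotation: SimulatedAnnotation
    truth: PlantedTruth
    methylomes: list[Methylome]
    samples: pd.DataFrame  # sample_id, assay, condition, group


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _spread(rng: np.random.Generator, seg_start: int, seg_end: int,
            sizes: list[int], gap: int) -> list[int]:
    """Place intervals of the given sizes in [seg_start, seg_end) with at
    least ``gap`` bp between them; returns their start positions."""
    k = len(sizes)
    need = sum(sizes) + gap * (k - 1)
    slack = (seg_end - seg_start) - need
    if slack < 0:
        raise ValueError("infeasible packing")
    w = rng.random(k + 1)
    pre = np.floor(np.cumsum(w / w.sum() * slack)[:-1]).astype(int)
    starts = []
    consumed = 0
    for i, size in enumerate(sizes):
        starts.append(seg_start + int(pre[i]) + consumed + gap * i)
        consumed += size
    return starts


def simulate_annotation(config: SimulationConfig, seed: int | None = None) -> SimulatedAnnotation:
    """Lay out chromosomes, PMDs, CGIs, genes, chromatin states and CpGs.

    PMDs occupy ``pmd_fraction`` of each chromosome in 300 kb - 1 Mb blocks
    separated by at least ``pmd_gap_min``; CGIs (1 kb, >= 10 kb apart) are
    placed only outside PMDs, making PMDs CGI-poor by construction. Every
    PRC2-target CGI carries a TSS so its promoter flag holds; PRC2 CGIs get a
    13_ReprPC chromatin segment, other promoter CGIs 1_TssA, the rest of the
    genome 15_Quies. Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    chrom_sizes = ChromSizes({c: config.chrom_length for c in chroms})

    # PMD layout
    pmd_rows = []
    for chrom in chroms:
        target = config.pmd_fraction * config.chrom_length
        sizes: list[int] = []
        while sum(sizes) < target:
            size = int(rng.integers(config.pmd_min_size, config.pmd_max_size + 1))
            # cap the overshoot so small genomes keep room for CGI placement
            size = max(config.pmd_min_size,
                       min(size, int(target) - sum(sizes) + config.pmd_min_size))
            need = sum(sizes) + size + config.pmd_gap_min * len(sizes)
            if need > config.chrom_length * 0.85:
                break
            sizes.append(size)
        starts = _spread(rng, 0, config.chrom_length, sizes, config.pmd_gap_min)
        for s, size in zip(starts, sizes):
            pmd_rows.append((chrom, s, s + size))
    pmds = pd.DataFrame(pmd_rows, columns=["chrom", "start", "end"])

    # CGI placement outside PMDs
    open_segments = complement_intervals(pmds, chrom_sizes)
    seg_list = list(zip(open_segments["chrom"], open_segments["start"], open_segments["end"]))
    L, g = config.cgi_length, config.min_cgi_gap
    caps = [max(0, (e - s + g) // (L + g)) for _, s, e in seg_list]
    if sum(caps) < config.n_cgis:
        raise ValueError(
            f"infeasible packing: capacity {sum(caps)} < n_cgis {config.n_cgis}"
        )
    # proportional allocation with largest-remainder top-up, capped by capacity
    quota = np.array(caps, dtype=float) / sum(caps) * config.n_cgis
    counts = np.minimum(np.floor(quota).astype(int), caps)
    order = np.argsort(-(quota - counts), kind="stable")
    i = 0
    while counts.sum() < config.n_cgis:
        j = order[i % len(order)]
        if counts[j] < caps[j]:
            counts[j] += 1
        i += 1
    cgi_rows = []
    for (chrom, s, e), k in zip(seg_list, counts):
        if k == 0:
            continue
        for start in _spread(rng, s, e, [L] * int(k), g):
            cgi_rows.append((chrom, start, start + L))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    cgis = cgis.sort_values(["chrom", "start"]).reset_index(drop=True)
    cgis["name"] = [f"CGI_{i:04d}" for i in range(len(cgis))]

    # PRC2 / promoter flags and gene models
    prc2_idx = rng.choice(len(cgis), size=config.n_prc2, replace=False)
    prc2 = np.zeros(len(cgis), dtype=bool)
    prc2[prc2_idx] = True
    promoter = prc2.copy()
    non_prc2 = np.flatnonzero(~prc2)
    extra_prom = rng.choice(non_prc2, size=len(non_prc2) // 2, replace=False)
    promoter[extra_prom] = True
    cgis["prc2"] = prc2
    cgis["promoter"] = promoter
    gene_rows = []
    strands = rng.choice(["+", "-"], size=len(cgis))
    for i in np.flatnonzero(promoter):
        gene_rows.append(
            (cgis.at[i, "chrom"], int(cgis.at[i, "start"]) + 100, strands[i], f"G_{i:04d}")
        )
    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "strand", "name"])

    # ChromHMM-style segmentation: labeled CGI segments over a quiescent genome
    labeled = cgis.copy()
    labeled["state"] = np.where(prc2, "13_ReprPC", np.where(promoter, "1_TssA", "5_TxWk"))
    seg_rows = []
    for chrom in chroms:
        sub = labeled[labeled["chrom"] == chrom]
        prev = 0
        for _, row in sub.iterrows():
            if row["start"] > prev:
                seg_rows.append((chrom, prev, row["start"], "15_Quies"))
            seg_rows.append((chrom, row["start"], row["end"], row["state"]))
            prev = row["end"]
        if prev < config.chrom_length:
            seg_rows.append((chrom, prev, config.chrom_length, "15_Quies"))
    states = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "name"])

    # CpG positions: exponential background spacing + dense CGI grids
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_bg = int(config.chrom_length / config.cpg_spacing * 1.3)
        gaps = np.maximum(rng.exponential(config.cpg_spacing, size=n_bg), 2.0)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < config.chrom_length]
        sub = cgis[cgis["chrom"] == chrom]
        inside = np.zeros(len(pos), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            inside |= (pos >= s - 50) & (pos < e + 50)
        pos = pos[~inside]
        cgi_pos = np.concatenate(
            [np.arange(s + 5, e - 5, config.cgi_cpg_spacing) for s, e in zip(sub["start"], sub["end"])]
        ) if len(sub) else np.empty(0, dtype=np.int64)
        cpg_positions[chrom] = np.unique(np.concatenate([pos, cgi_pos.astype(np.int64)]))

    solo_sites = _solo_sites(cpg_positions, cgis, pmds, config.solo_isolation_bp)
    return SimulatedAnnotation(chrom_sizes, cgis, genes, states, pmds, cpg_positions, solo_sites)


def _solo_sites(cpg_positions, cgis, pmds, isolation_bp) -> pd.DataFrame:
    """Isolated background CpGs (no neighbor within ``isolation_bp``) inside
    planted PMDs — the solo-WCGW site stand-in."""
    rows = []
    for chrom, pos in cpg_positions.items():
        if len(pos) < 3:
            continue
        left = np.diff(pos, prepend=pos[0] - 10**9)
        right = np.diff(pos, append=pos[-1] + 10**9)
        isolated = (left > isolation_bp) & (right > isolation_bp)
        sub = pmds[pmds["chrom"] == chrom]
        in_pmd = np.zeros(len(pos), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            in_pmd |= (pos >= s) & (pos < e)
        for p in pos[isolated & in_pmd]:
            rows.append((chrom, int(p), int(p) + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# truth and methylomes
# ---------------------------------------------------------------------------

def simulate_truth(
    config: SimulationConfig,
    annotation: SimulatedAnnotation,
    rng: np.random.Generator,
    types: list[str] | None = None,
    planted_shared_fraction: float = 0.0,
) -> PlantedTruth:
    """Draw the planted hyper sets and methylated-CGI repertoires.

    With several tumor types, a shared core of ``planted_shared_fraction`` of
    each planted set is common to all types; the remainder is drawn per type
    from the other PRC2-target CGIs. Constitutively methylated CGIs are drawn
    from non-PRC2 CGIs (methylated CGIs sit in gene bodies / intergenic
    space, not at PRC2 promoters); tissue-specific methylated CGIs are drawn
    uniformly from the remaining CGIs and may therefore graze a planted set.
    """
    types = types or ["T1"]
    cgis = annotation.cgis
    names = cgis["name"].to_numpy()
    prc2_names = names[cgis["prc2"].to_numpy()]
    non_prc2_names = names[~cgis["prc2"].to_numpy()]
    n_const = int(round(config.frac_constitutive_meth * len(names)))
    if n_const > len(non_prc2_names):
        raise ValueError("not enough non-PRC2 CGIs for the constitutive set")
    constitutive = frozenset(rng.choice(non_prc2_names, size=n_const, replace=False))

    n_core = int(round(planted_shared_fraction * config.planted_set_size))
    core = frozenset(rng.choice(prc2_names, size=n_core, replace=False)) if n_core else frozenset()
    remaining = np.array(sorted(set(prc2_names) - core))
    planted: dict[str, frozenset[str]] = {}
    for t in types:
        extra = rng.choice(remaining, size=config.planted_set_size - n_core, replace=False)
        planted[t] = core | frozenset(extra)

    eligible_ts = np.array(sorted(set(names) - constitutive))
    tissue_specific = {
        t: frozenset(
            rng.choice(eligible_ts, size=config.tissue_specific_meth_per_tissue, replace=False)
        )
        for t in types
    }
    return PlantedTruth(planted, core, constitutive, tissue_specific)


def _beta(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(mean * conc, (1.0 - mean) * conc)


def simulate_methylome(
    config: SimulationConfig,
    annotation: SimulatedAnnotation,
    truth: PlantedTruth,
    role: str,
    sample_id: str,
    rng: np.random.Generator,
    tumor_type: str = "T1",
    history: float | None = None,
    raw_coverage: bool = False,
) -> Methylome:
    """Simulate one sample.

    Latent per-CpG means: unmethylated CGIs around ``unmeth_mean``,
    methylated (constitutive / tissue-specific / included planted) CGIs
    around their class mean, HMD background around ``hmd_baseline`` and PMD
    background around ``hmd_baseline - loss * history`` (floored), each drawn
    from a Beta with the configured concentration. Observed methylation is a
    binomial draw at truncated-Poisson coverage; ``raw_coverage`` skips the
    truncation to exercise the coverage filter. The planted CGIs included in
    this tumor are recorded in ``truth.included``.
    """
    if role not in ("healthy", "tumor"):
        raise ValueError("role must be 'healthy' or 'tumor'")
    if history is None:
        history = config.tumor_history if role == "tumor" else config.healthy_history
    profile = PROFILES[config.assay]
    cgis = annotation.cgis

    methylated = set(truth.constitutive) | set(truth.tissue_specific.get(tumor_type, frozenset()))
    gained: frozenset[str] = frozenset()
    if role == "tumor":
        planted = np.array(sorted(truth.planted[tumor_type]))
        take = rng.random(len(planted)) < config.p_include
        gained = frozenset(planted[take])
        truth.included[(tumor_type, sample_id)] = gained
    truth.histories[sample_id] = history

    cgi_mean = np.full(len(cgis), config.unmeth_mean)
    names = cgis["name"].to_numpy()
    cgi_mean[np.isin(names, sorted(methylated))] = config.meth_mean
    if gained:
        cgi_mean[np.isin(names, sorted(gained))] = config.gain_level

    pmd_mean = max(config.pmd_floor,
                   config.hmd_baseline - config.pmd_loss_per_unit_history * history)

    frames = []
    for chrom, pos in annotation.cpg_positions.items():
        mu = np.full(len(pos), config.hmd_baseline)
        sub_pmd = annotation.pmds[annotation.pmds["chrom"] == chrom]
        for s, e in zip(sub_pmd["start"], sub_pmd["end"]):
            mu[(pos >= s) & (pos < e)] = pmd_mean
        sub_cgi = cgis[cgis["chrom"] == chrom]
        for s, e, m in zip(sub_cgi["start"], sub_cgi["end"],
                           cgi_mean[sub_cgi.index.to_numpy()]):
            mu[(pos >= s) & (pos < e)] = m
        mu = _beta(rng, mu, config.beta_concentration)
        if config.assay == "array":
            probe_mask = np.zeros(len(pos), dtype=bool)
            for s, e in zip(sub_cgi["start"], sub_cgi["end"]):
                probe_mask |= (pos >= s) & (pos < e)
            probe_mask[::10] = True
            beta = np.clip(mu[probe_mask] + rng.normal(0, config.array_noise_sd,
                                                       size=int(probe_mask.sum())), 0, 1)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos[probe_mask], "meth": beta, "cov": np.nan}))
        else:
            cov = rng.poisson(config.coverage_mean, size=len(pos))
            if not raw_coverage:
                cov = np.clip(cov, profile.min_cov, profile.max_cov)
            cov = np.maximum(cov, 1)
            meth = rng.binomial(cov, mu) / cov
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "meth": meth, "cov": cov.astype(float)}))
    calls = pd.concat(frames, ignore_index=True)
    return Methylome(sample_id, profile, role, tumor_type, calls)


def simulate_cohort(
    config: SimulationConfig,
    n_types: int = 1,
    planted_shared_fraction: float = 0.0,
    histories: dict[str, float] | None = None,
) -> SimulatedCohort:
    """Simulate a full multi-type cohort from one seeded generator hierarchy.

    Per type, ``n_healthy`` healthy and ``n_tumor`` tumor samples are drawn;
    ``histories`` optionally overrides the proliferative history per sample
    id (e.g. to create a history gradient).
    """
    ss = np.random.SeedSequence(config.seed)
    seed_ann, seed_truth, seed_samples = ss.spawn(3)
    annotation = simulate_annotation(config, seed=seed_ann)
    types = [f"T{i + 1}" for i in range(n_types)]
    truth = simulate_truth(
        config, annotation, np.random.default_rng(seed_truth), types, planted_shared_fraction
    )
    methylomes: list[Methylome] = []
    rows = []
    sample_seeds = iter(seed_samples.spawn(n_types * (config.n_healthy + config.n_tumor)))
    for t in types:
        for i in range(config.n_healthy):
            sid = f"{t}_healthy_{i:02d}"
            m = simulate_methylome(
                config, annotation, truth, "healthy", sid,
                np.random.default_rng(next(sample_seeds)), tumor_type=t,
                history=(histories or {}).get(sid),
            )
            methylomes.append(m)
            rows.append((sid, config.assay, "healthy", t))
        for i in range(config.n_tumor):
            sid = f"{t}_tumor_{i:02d}"
            m = simulate_methylome(
                config, annotation, truth, "tumor", sid,
                np.random.default_rng(next(sample_seeds)), tumor_type=t,
                history=(histories or {}).get(sid),
            )
            methylomes.append(m)
            rows.append((sid, config.assay, "tumor", t))
    samples = pd.DataFrame(rows, columns=["sample_id", "assay", "condition", "group"])
    return SimulatedCohort(config, annotation, truth, methylomes, samples)


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write the cohort in the formats the ingest module reads.

    Emits per-sample Bismark-coverage files (or beta tables + manifest for
    arrays), annotation BEDs, the solo-WCGW site BED, the truth tables and a
    sample manifest; re-ingesting reproduces methylation to six decimals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = cohort.annotation
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = out / "chrom.sizes"
    ann.chrom_sizes.to_tsv(paths["chrom_sizes"])
    paths["cgis"] = out / "cgis.bed"
    write_bed(ann.cgis, paths["cgis"], extra_columns=["name"])
    paths["genes"] = out / "genes.tsv"
    ann.genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["states"] = out / "states.bed"
    write_bed(ann.states, paths["states"], extra_columns=["name"])
    paths["pmds_true"] = out / "pmds_true.bed"
    write_bed(ann.pmds, paths["pmds_true"])
    paths["solo_wcgw"] = out / "solo_wcgw.bed"
    write_bed(ann.solo_sites, paths["solo_wcgw"])

    truth = cohort.truth
    paths["planted"] = out / "truth_planted.tsv"
    pd.DataFrame(
        [(t, c) for t, cs in truth.planted.items() for c in sorted(cs)],
        columns=["tumor_type", "cgi"],
    ).to_csv(paths["planted"], sep="\t", index=False)
    paths["constitutive"] = out / "truth_constitutive.tsv"
    pd.DataFrame({"cgi": sorted(truth.constitutive)}).to_csv(
        paths["constitutive"], sep="\t", index=False
    )
    paths["tissue_specific"] = out / "truth_tissue_specific.tsv"
    pd.DataFrame(
        [(t, c) for t, cs in truth.tissue_specific.items() for c in sorted(cs)],
        columns=["tumor_type", "cgi"],
    ).to_csv(paths["tissue_specific"], sep="\t", index=False)
    paths["included"] = out / "truth_included.tsv"
    pd.DataFrame(
        [(t, s, c) for (t, s), cs in truth.included.items() for c in sorted(cs)],
        columns=["tumor_type", "sample_id", "cgi"],
    ).to_csv(paths["included"], sep="\t", index=False)

    sample_rows = []
    manifest_written = False
    for m in cohort.methylomes:
        if m.assay_profile.assay == "array":
            if not manifest_written:
                rows = []
                k = 0
                for chrom, pos in ann.cpg_positions.items():
                    for p in pos:
                        rows.append((f"cg{k:07d}", chrom, int(p)))
                        k += 1
                manifest = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
                paths["manifest"] = out / "manifest.tsv"
                manifest.to_csv(paths["manifest"], sep="\t", index=False)
                probe_of = {(c, p): pid for pid, c, p in manifest.itertuples(index=False)}
                manifest_written = True
            path = out / f"{m.sample_id}.betas.tsv"
            pd.DataFrame(
                {
                    "probe_id": [
                        probe_of[(c, p)] for c, p in zip(m.calls["chrom"], m.calls["pos"])
                    ],
                    "beta": [f"{v:.6f}" for v in m.calls["meth"]],
                }
            ).to_csv(path, sep="\t", index=False)
        else:
            path = out / f"{m.sample_id}.cov"
            write_bismark_cov(m, path)
        # paths relative to the cohort directory keep the sheet portable
        sample_rows.append((m.sample_id, path.name, m.assay_profile.assay, m.condition, m.group))
    paths["samples"] = out / "samples.tsv"
    pd.DataFrame(
        sample_rows, columns=["sample_id", "path", "assay", "condition", "group"]
    ).to_csv(paths["samples"], sep="\t", index=False)
    return paths
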