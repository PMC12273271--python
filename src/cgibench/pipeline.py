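"""End-to-end benchmark orchestration.

`run_benchmark` sequences the full analysis — ingest with coverage/autosome
filters, CGI-level summaries, healthy median signatures, per-sample hyper
calls, per-type common sets, the pan-cancer set, cross-control recovery,
saturation resampling and solo-WCGW scores — and writes every table plus a
machine-readable run log recording all thresholds and seeds. Runs are
deterministic given config + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features, hyper, ingest
from .cohort import saturation_curve
from .intervals import ChromSizes, read_bed


@dataclass
class Thresholds:
    unmeth_max: float = 0.2
    meth_min: float = 0.2
    min_delta: float = 0.1
    min_fraction: float = 0.5
    min_type_fraction: float = 0.3
    min_cpgs: int | None = None  # per-assay default when None
    saturation_min_samples: int = 100
    saturation_n_iter: int = 100
    saturation_n_draw: int = 100


@dataclass
class RunConfig:
    """Inputs and thresholds of one benchmark run.

    The sample sheet (sample_id, path, assay, condition, group) is the single
    source of condition and group labels; nothing is inferred from file
    names.
    """

    sample_sheet: str
    cgis: str
    chrom_sizes: str
    out_dir: str
    solo_sites: str | None = None
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def validate_config(config: RunConfig) -> list[str]:
    """Collect diagnostics (missing files, label problems, threshold ranges)
    without raising; an empty list means the config is clean."""
    diags: list[str] = []
    for attr in ("sample_sheet", "cgis", "chrom_sizes"):
        p = getattr(config, attr)
        if not Path(p).exists():
            diags.append(f"missing file for {attr}: {p}")
    if config.solo_sites and not Path(config.solo_sites).exists():
        diags.append(f"missing file for solo_sites: {config.solo_sites}")
    thr = config.thresholds
    for name in ("unmeth_max", "meth_min", "min_delta", "min_fraction", "min_type_fraction"):
        v = getattr(thr, name)
        if not 0.0 <= v <= 1.0:
            diags.append(f"threshold {name}={v} outside [0, 1]")
    if Path(config.sample_sheet).exists():
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        required = {"sample_id", "path", "assay", "condition", "group"}
        missing_cols = required - set(sheet.columns)
        if missing_cols:
            diags.append(f"sample sheet lacks columns: {sorted(missing_cols)}")
        else:
            for _, row in sheet.iterrows():
                if not _resolve(row["path"], config.sample_sheet).exists():
                    diags.append(f"sample {row['sample_id']}: dangling path {row['path']}")
                if row["condition"] not in ingest.CONDITIONS:
                    diags.append(
                        f"sample {row['sample_id']}: unknown condition {row['condition']}"
                    )
                if row["assay"] not in ingest.PROFILES:
                    diags.append(f"sample {row['sample_id']}: unknown assay {row['assay']}")
            groups = sheet.groupby("group")["condition"].agg(set)
            for group, conds in groups.items():
                if "tumor" in conds and "healthy" not in conds:
                    diags.append(f"tumor type {group} has no healthy samples")
    return diags


def _resolve(path, base) -> Path:
    """Sample-sheet paths may be relative to the sheet's own directory."""
    p = Path(path)
    return p if p.is_absolute() else Path(base).parent / p


def _load_sample(row, chrom_sizes: ChromSizes, sheet_path) -> ingest.Methylome:
    profile = ingest.PROFILES[row["assay"]]
    path = _resolve(row["path"], sheet_path)
    if row["assay"] == "array":
        m = ingest.read_array_betas(
            path, path.parent / "manifest.tsv", sample_id=row["sample_id"],
            condition=row["condition"], group=row["group"],
        )
    else:
        m = ingest.read_cpg_calls(
            path, "bismark_cov", profile, sample_id=row["sample_id"],
            condition=row["condition"], group=row["group"],
        )
    return ingest.restrict_autosomes(ingest.filter_coverage(m), chrom_sizes)


def run_benchmark(config: RunConfig) -> dict[str, Path]:
    """Run the full benchmark and write its report bundle.

    Emits the feature matrix, per-type common hyper sets, the pan-cancer set,
    the cross-control recovery matrix, per-set summaries, saturation curves
    for sufficiently sampled types, optional solo-WCGW scores and a JSON run
    log. Raises when a declared tumor type lacks healthy samples.
    """
    diags = validate_config(config)
    hard = [d for d in diags if "no healthy samples" in d or "missing file" in d]
    if hard:
        raise ValueError("; ".join(hard))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    chrom_sizes = ChromSizes.read_tsv(config.chrom_sizes)
    cgis = read_bed(config.cgis, chrom_sizes)
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    methylomes = {row["sample_id"]: _load_sample(row, chrom_sizes, config.sample_sheet)
                  for _, row in sheet.iterrows()}

    matrix = features.build_matrix(list(methylomes.values()), cgis, thr.min_cpgs)
    paths: dict[str, Path] = {"matrix": out / "cgi_matrix.tsv"}
    matrix.values.to_csv(paths["matrix"], sep="\t", na_rep="NA")

    types = sorted(sheet.loc[sheet["condition"] == "tumor", "group"].unique())
    signatures: dict[str, features.HealthySignature] = {}
    matrices_by_type: dict[str, features.FeatureMethylMatrix] = {}
    common_sets: dict[str, hyper.CommonHyperSet] = {}
    call_sets_by_type: dict[str, dict[str, hyper.HyperCallSet]] = {}
    for t in types:
        healthy_ids = sheet.loc[
            (sheet["group"] == t) & (sheet["condition"] == "healthy"), "sample_id"
        ].tolist()
        tumor_ids = sheet.loc[
            (sheet["group"] == t) & (sheet["condition"] == "tumor"), "sample_id"
        ].tolist()
        signatures[t] = features.healthy_signature(matrix, healthy_ids)
        matrices_by_type[t] = features.FeatureMethylMatrix(
            matrix.values[tumor_ids], matrix.n_cpgs[tumor_ids]
        )
        calls = hyper.call_cohort_hyper(
            matrix, signatures[t], tumor_ids,
            unmeth_max=thr.unmeth_max, meth_min=thr.meth_min, min_delta=thr.min_delta,
        )
        call_sets_by_type[t] = calls
        common_sets[t] = hyper.common_hyper_set(calls, thr.min_fraction, tumor_type=t)
        path = out / f"common_hyper_{t}.bed"
        sub = cgis[cgis["name"].isin(common_sets[t].cgis)].copy()
        sub["count"] = sub["name"].map(common_sets[t].counts)
        sub.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "name", "count"])
        paths[f"common_{t}"] = path

    if types:
        pan = hyper.pan_cancer_set(common_sets, thr.min_type_fraction)
        paths["pan_cancer"] = out / "pan_cancer_hyper.bed"
        sub = cgis[cgis["name"].isin(pan.cgis)].copy()
        sub["count"] = sub["name"].map(pan.counts)
        sub.to_csv(paths["pan_cancer"], sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "name", "count"])

        summaries = []
        for t in types:
            if common_sets[t].cgis:
                s = features.set_summary(matrix.values, sorted(common_sets[t].cgis))
                s.insert(0, "cgi_set", f"common_{t}")
                summaries.append(s.reset_index(names="sample_id"))
        if pan.cgis:
            s = features.set_summary(matrix.values, sorted(pan.cgis))
            s.insert(0, "cgi_set", "pan_cancer")
            summaries.append(s.reset_index(names="sample_id"))
        if summaries:
            paths["summaries"] = out / "set_summaries.tsv"
            pd.concat(summaries).to_csv(paths["summaries"], sep="\t", index=False,
                                        float_format="%.6f")

    if len(types) >= 2:
        recovery = hyper.cross_control_recovery(
            matrices_by_type, signatures,
            min_fraction=thr.min_fraction,
            unmeth_max=thr.unmeth_max, meth_min=thr.meth_min, min_delta=thr.min_delta,
        )
        paths["recovery"] = out / "recovery_matrix.tsv"
        recovery.recovered.to_csv(paths["recovery"], sep="\t", float_format="%.6f")
        paths["recovery_additional"] = out / "recovery_additional.tsv"
        recovery.additional.to_csv(paths["recovery_additional"], sep="\t", float_format="%.0f")

    rng = np.random.default_rng(config.seed)
    curves = []
    skipped = []
    for t in types:
        sets = {s: cs.called for s, cs in call_sets_by_type[t].items()}
        if len(sets) < thr.saturation_min_samples:
            skipped.append(t)
            continue
        curve = saturation_curve(
            sets, thr.saturation_n_iter, thr.saturation_n_draw, rng, tumor_type=t
        )
        curves.append(pd.DataFrame({
            "tumor_type": t,
            "m": np.arange(1, len(curve.mean_curve) + 1),
            "mean_fraction": curve.mean_curve,
        }))
    if curves:
        paths["saturation"] = out / "saturation_curves.tsv"
        pd.concat(curves).to_csv(paths["saturation"], sep="\t", index=False,
                                 float_format="%.6f")

    if config.solo_sites:
        solo = read_bed(config.solo_sites, chrom_sizes)
        rows = []
        for sid, m in methylomes.items():
            score, n_used = features.solo_wcgw_score(m, solo)
            rows.append((sid, score, n_used))
        paths["solo"] = out / "solo_wcgw_scores.tsv"
        pd.DataFrame(rows, columns=["sample_id", "solo_wcgw_mean", "n_sites"]).to_csv(
            paths["solo"], sep="\t", index=False, float_format="%.6f"
        )

    log = {
        "seed": config.seed,
        "thresholds": asdict(thr),
        "n_samples": len(methylomes),
        "tumor_types": types,
        "saturation_skipped": skipped,
        "diagnostics": diags,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["run_log"] = out / "run_log.json"
    with open(paths["run_log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return paths
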