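#!/usr/bin/env python
"""Simulate the default benchmark cohort and write it to disk.

30 healthy and 30 tumor WGBS samples on a two-chromosome 12-Mb genome with
500 CGIs (250 PRC2-target promoter CGIs, 200 of them planted as the tumor
hypermethylation target set), a 30% constitutively methylated CGI fraction
and 30% of the genome in PMDs. The cohort files (Bismark-coverage dialect,
annotation BEDs, truth tables) go to scratch/; a small summary table goes to
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cgibench.simulate import SimulationConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort_default")
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed)
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, args.out)

    ann, truth = cohort.annotation, cohort.truth
    summary = pd.DataFrame(
        [
            ("n_samples", len(cohort.methylomes)),
            ("n_cgis", len(ann.cgis)),
            ("n_prc2_promoter_cgis", int((ann.cgis.prc2 & ann.cgis.promoter).sum())),
            ("n_planted_hyper_cgis", len(truth.planted["T1"])),
            ("n_constitutive_methylated", len(truth.constitutive)),
            ("n_pmds", len(ann.pmds)),
            ("pmd_bp", int((ann.pmds.end - ann.pmds.start).sum())),
            ("n_solo_wcgw_sites", len(ann.solo_sites)),
            ("cpgs_per_sample", cohort.methylomes[0].n_calls),
        ],
        columns=["quantity", "value"],
    )
    out_tsv = ROOT / "results" / "01_cohort_summary.tsv"
    out_tsv.parent.mkdir(exist_ok=True)
    summary.to_csv(out_tsv, sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\ncohort written to {args.out} (sample sheet: {paths['samples']})")


if __name__ == "__main__":
    main()
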