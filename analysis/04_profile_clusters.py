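#!/usr/bin/env python
"""Characterise the phenotype clusters: outcomes and feature profiles.

Writes, per window, a cluster-outcome table (N, deaths, Kaplan-Meier
cumulative mortality with 95% CI, median/IQR days to death, percent share)
and Cohen's-D feature profiles over the top-25 predictors plus the
interpretation add-on variables, under both D conventions.
"""

from pathlib import Path

import pandas as pd

import phenotyper as pt

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort, outcomes, truth = pt.read_cohort(ROOT / "scratch" / "cohort")
    datasets = dict(zip(
        ("admission_30day", "postdischarge_180day"),
        pt.build_analysis_datasets(cohort, outcomes),
    ))
    out = ROOT / "results"
    for name, ds in datasets.items():
        labels = pd.read_csv(
            out / f"clusters_{name}.csv", index_col="child_id"
        )["cluster"]
        summary = pt.summarize_clusters(
            labels, ds.time, ds.event, ds.horizon, denominator=len(cohort.frame)
        )
        summary.to_csv(out / f"cluster_outcomes_{name}.csv")
        print(f"=== {name} ===")
        print(summary.round(3).to_string())

        ranking = pd.read_csv(out / f"importance_{name}.csv")
        top = ranking.loc[ranking["top_k"], "feature"].tolist()
        variables = top + [
            v for v in pt.INTERPRETATION_ADDONS
            if v in cohort.frame.columns and v not in top
        ]
        data = cohort.frame.loc[labels.index, variables]
        for variant, tag in (("complement", "cluster_vs_rest"),
                             ("grand", "cluster_vs_sample")):
            prof = pt.cohens_d_profile(data, labels, variables, variant=variant)
            prof.values.round(3).to_csv(out / f"profile_{tag}_{name}.csv")


if __name__ == "__main__":
    main()
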