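#!/usr/bin/env python
"""Shapley attributions, top-25 rankings, and spectral phenotype clusters.

For each window: exact tree-Shapley attributions averaged over the ten
ensemble members, the top-25 importance ranking, the k = 6 cluster
assignment (labels ordered by Kaplan-Meier mortality), the 4-8 cluster
sensitivity sweep, and the recovery score against the planted phenotypes.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import phenotyper as pt

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main() -> None:
    cohort, outcomes, truth = pt.read_cohort(ROOT / "scratch" / "cohort")
    datasets = dict(zip(
        ("admission_30day", "postdischarge_180day"),
        pt.build_analysis_datasets(cohort, outcomes),
    ))
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    for name, ds in datasets.items():
        ens = pt.EnsembleModel.load(ROOT / "scratch" / "models" / name)
        attr = pt.compute_attributions(ens, ds.features)
        attr.save(ROOT / "scratch" / f"attr_{name}")
        ranking = pt.rank_global_importance(attr, k=25)
        ranking.table.head(50).to_csv(out / f"importance_{name}.csv", index=False)

        cfg = pt.AffinityConfig(seed=SEED)
        outc = (ds.time, ds.event, ds.horizon)
        assignment = pt.spectral_cluster_attributions(attr, 6, cfg, outc)
        assignment.labels.rename("cluster").to_csv(out / f"clusters_{name}.csv")
        sens = pt.sensitivity_over_k(attr, [4, 5, 6, 7, 8], cfg, outc)
        sens.ari_matrix.to_csv(out / f"cluster_sensitivity_ari_{name}.csv")

        k4 = pt.spectral_cluster_attributions(attr, 4, cfg, outc)
        ari = adjusted_rand_score(
            truth.table.loc[ds.features.index, "phenotype"].to_numpy(),
            k4.labels.to_numpy(),
        )
        print(f"{name}: top feature = {ranking.features[0]}; "
              f"k=4 recovery ARI vs planted phenotypes = {ari:.3f}")
        print(f"  top 10: {', '.join(ranking.features[:10])}")


if __name__ == "__main__":
    main()
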