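#!/usr/bin/env python
"""Trace test concordance while recursively eliminating predictors.

Starts from the 50 most influential admission-model predictors and removes
the least informative remaining variable one at a time, refitting the
ensemble at each step (five repeats, fixed boosting budget, split plans
held constant so the curve isolates the effect of feature removal).
"""

from pathlib import Path

import pandas as pd

import phenotyper as pt

ROOT = Path(__file__).resolve().parents[1]
SEED = 11
# the refit loop runs ~50 ensembles, so skip the CV pass and use a fixed
# budget with fewer repeats
BOOST = pt.BoostingConfig(n_rounds=100, early_stopping_rounds=None)
REPEATS = 5


def main() -> None:
    cohort, outcomes, truth = pt.read_cohort(ROOT / "scratch" / "cohort")
    sel = pt.compute_selection_weights(truth.sampled_counts, truth.source_counts)
    weights = sel.assign(cohort.frame["stratum"])
    admission, _ = pt.build_analysis_datasets(cohort, outcomes)

    ens = pt.EnsembleModel.load(ROOT / "scratch" / "models" / "admission_30day")
    attr = pt.compute_attributions(ens, admission.features)
    ranking = pt.rank_global_importance(attr, k=50)

    plans = pt.make_split_plans(admission.n, R=REPEATS, seed=SEED + 1)
    curve = pt.recursive_elimination(
        admission, weights.loc[admission.features.index], plans, BOOST,
        ranking, start_m=50,
    )
    out = ROOT / "results"
    curve.table.to_csv(out / "reduction_curve_admission.csv", index=False)
    summ = curve.summary()
    summ.round(4).to_csv(out / "reduction_summary_admission.csv")
    print(summ.loc[[50, 25, 10, 5, 2, 1]].round(3).to_string())
    print(f"last surviving predictor: {curve.feature_sets[1][0]}")


if __name__ == "__main__":
    main()
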