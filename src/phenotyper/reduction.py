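"""Recursive feature elimination traced by test concordance.

Starting from the most influential ``start_m`` predictors (default 50) of a
full-model importance ranking, the ensemble is refit on the current feature
set, test concordances are recorded, importance is re-estimated *within the
refit model*, and the least informative remaining feature is dropped;
repeat until one feature remains.  Reusing the same split plans at every
step isolates the effect of feature removal from split-to-split noise.

A ``frozen`` mode that eliminates strictly by the initial ranking (never
re-estimating) is provided for comparison, since either reading of
"iteratively removing the least informative remaining variable" is
defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .attribution import ImportanceRanking, compute_attributions, rank_global_importance
from .boosting import BoostingConfig, SplitPlan, fit_survival_ensemble
from .synthetic import AnalysisDataset


@dataclass
class PerformanceCurve:
    """Test concordances at each feature count m, with the feature sets used.

    Feature sets are nested by construction: set(m) is set(m+1) minus its
    least informative member.
    """

    table: pd.DataFrame            # columns: m, repeat, concordance
    feature_sets: Dict[int, List[str]]

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("m")["concordance"]
        out = pd.DataFrame(
            {
                "median": g.median(),
                "q1": g.quantile(0.25),
                "q3": g.quantile(0.75),
            }
        )
        return out.sort_index(ascending=False)


def recursive_elimination(
    dataset: AnalysisDataset,
    weights: Optional[pd.Series],
    plans: Sequence[SplitPlan],
    config: BoostingConfig,
    start_ranking: ImportanceRanking,
    start_m: int = 50,
    mode: Literal["recompute", "frozen"] = "recompute",
) -> PerformanceCurve:
    """Trace test concordance as the predictor set shrinks from start_m to 1."""
    all_ranked = start_ranking.features
    if start_m > len(all_ranked):
        raise ValueError(
            f"start_m={start_m} exceeds the {len(all_ranked)} ranked features"
        )
    if start_m < 1:
        raise ValueError("start_m must be >= 1")
    current = list(all_ranked[:start_m])
    frozen_order = list(all_ranked)  # ascending elimination = reversed ranking

    rows = []
    feature_sets: Dict[int, List[str]] = {}
    for m in range(start_m, 0, -1):
        feature_sets[m] = list(current)
        sub = AnalysisDataset(
            name=f"{dataset.name}_m{m}",
            features=dataset.features[current],
            time=dataset.time,
            event=dataset.event,
            horizon=dataset.horizon,
        )
        drop: Optional[str] = None
        try:
            ensemble = fit_survival_ensemble(sub, weights, plans, config)
            for r, c in zip(plans, ensemble.test_concordances):
                rows.append({"m": m, "repeat": r.repeat_id, "concordance": c})
            if m > 1:
                if mode == "recompute":
                    attr = compute_attributions(ensemble, sub.features)
                    rank = rank_global_importance(attr, k=min(25, m))
                    drop = rank.features[-1]
                else:
                    drop = max(current, key=frozen_order.index)
        except ValueError as exc:  # refit failure: sentinel, keep going
            warnings.warn(f"refit failed at m={m}: {exc}", RuntimeWarning)
            for r in plans:
                rows.append(
                    {"m": m, "repeat": r.repeat_id, "concordance": np.nan}
                )
            if m > 1:
                drop = max(current, key=frozen_order.index)
        if m > 1:
            current.remove(drop)
    return PerformanceCurve(table=pd.DataFrame(rows), feature_sets=feature_sets)
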