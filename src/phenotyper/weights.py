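"""Inverse-probability-of-selection weights for stratified enrolment.

Enrolment oversampled wasted children at a fixed 2:2:1 weekly ratio, so the
sample over-represents the severe strata relative to the admitted source
population.  Weighting each child by (stratum source count) / (stratum
sampled count) restores the source composition; the weights enter the
boosted proportional-hazards loss as per-observation multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd


@dataclass(frozen=True)
class SelectionWeights:
    """Stratum-level inverse selection probabilities.

    Weights are constant within stratum by construction.  ``assign`` expands
    them to a per-child Series given each child's stratum label.
    """

    stratum_weights: Dict[str, float]

    def assign(self, strata: pd.Series) -> pd.Series:
        unknown = set(strata.unique()) - set(self.stratum_weights)
        if unknown:
            raise ValueError(f"strata without weights: {sorted(unknown)}")
        w = strata.map(self.stratum_weights).astype(float)
        w.name = "weight"
        return w


def compute_selection_weights(
    sampled_counts: Mapping[str, int], source_counts: Mapping[str, int]
) -> SelectionWeights:
    """weight(s) = source_counts[s] / sampled_counts[s] for each stratum s.

    The sum of weights over all sampled children then equals the source
    population size, and weighted stratum proportions equal source
    proportions exactly.
    """
    if set(sampled_counts) - set(source_counts):
        raise ValueError("every sampled stratum needs a source count")
    weights: Dict[str, float] = {}
    for s, n_samp in sampled_counts.items():
        n_src = source_counts[s]
        if n_samp <= 0:
            raise ValueError(f"stratum {s!r} has zero sampled count")
        if n_src < n_samp:
            raise ValueError(
                f"stratum {s!r}: sampled count {n_samp} exceeds source count {n_src}"
            )
        weights[s] = n_src / n_samp
    return SelectionWeights(stratum_weights=weights)


def read_weights_csv(path: Path | str) -> pd.Series:
    df = pd.read_csv(path)
    return df.set_index("child_id")["weight"].astype(float)


def write_weights_csv(path: Path | str, strata: pd.Series, weights: SelectionWeights) -> None:
    per_child = weights.assign(strata)
    out = pd.DataFrame({"stratum": strata, "weight": per_child})
    out.index.name = "child_id"
    out.to_csv(path)
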