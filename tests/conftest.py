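"""Shared fixtures: small synthetic cohorts and cached model fits.

Everything is generated programmatically at test time; the heavier
study-scale fits (n = 3000, ten members with CV early stopping) are cached
per seed in a session-scoped factory so several tests can share them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import pytest

import phenotyper as pt


@dataclass
class FittedRun:
    cohort: pt.Cohort
    outcomes: pd.DataFrame
    truth: pt.TruthSidecar
    dataset: pt.AnalysisDataset
    weights: pd.Series
    plans: list
    ensemble: pt.EnsembleModel
    attributions: pt.AttributionMatrix


#: Boosting settings used for the study-scale test fits: the default shallow
#: trees with CV early stopping, capped at 300 rounds.
STUDY_BOOST = pt.BoostingConfig(n_rounds=300, early_stopping_rounds=25)

#: Light settings for small structural fixtures (no CV pass).
LIGHT_BOOST = pt.BoostingConfig(n_rounds=40, early_stopping_rounds=None)


def _fit_default(seed: int) -> FittedRun:
    cfg = pt.GeneratorConfig(n_children=3000, seed=seed)
    cohort, outcomes, truth = pt.generate_cohort(cfg)
    adm, _ = pt.build_analysis_datasets(cohort, outcomes)
    sel = pt.compute_selection_weights(truth.sampled_counts, truth.source_counts)
    w = sel.assign(cohort.frame["stratum"])
    plans = pt.make_split_plans(adm.n, R=10, seed=seed + 100)
    ens = pt.fit_survival_ensemble(adm, w.loc[adm.features.index], plans, STUDY_BOOST)
    attr = pt.compute_attributions(ens, adm.features)
    return FittedRun(cohort, outcomes, truth, adm, w, plans, ens, attr)


@pytest.fixture(scope="session")
def default_run():
    """Factory returning the cached study-scale admission fit for a seed."""
    cache: Dict[int, FittedRun] = {}

    def get(seed: int = 0) -> FittedRun:
        if seed not in cache:
            cache[seed] = _fit_default(seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def small_cohort() -> Tuple[pt.Cohort, pd.DataFrame, pt.TruthSidecar]:
    cfg = pt.small_schema_config(n_children=400, seed=7)
    return pt.generate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_fit() -> FittedRun:
    """Single-signal fixture: one feature carries all hazard signal."""
    cfg = pt.small_schema_config(
        n_children=600, seed=21, target_30day_mortality=0.15
    )
    specs = pt.single_signal_phenotypes()
    cohort, outcomes, truth = pt.generate_cohort(cfg, specs)
    adm, _ = pt.build_analysis_datasets(cohort, outcomes)
    sel = pt.compute_selection_weights(truth.sampled_counts, truth.source_counts)
    w = sel.assign(cohort.frame["stratum"]).loc[adm.features.index]
    plans = pt.make_split_plans(adm.n, R=3, seed=9)
    ens = pt.fit_survival_ensemble(adm, w, plans, LIGHT_BOOST)
    attr = pt.compute_attributions(ens, adm.features)
    return FittedRun(cohort, outcomes, truth, adm, w, plans, ens, attr)
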