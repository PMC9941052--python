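"""End-to-end orchestration of the two mortality analyses.

One config drives the full sequence for each analysis window (30-day
admission; 180-day post-discharge): generate or load the cohort, derive
selection weights, make repeated 90/10 split plans, fit the weighted
boosted-Cox ensemble, compute Shapley attributions and the importance
ranking, spectrally cluster attribution space (with the cluster-number
sensitivity sweep), summarise and profile the clusters, and optionally run
the recursive feature-elimination experiment.  All randomness descends from
one master seed via independent spawned streams, so a fixed config is
end-to-end deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .attribution import (
    AttributionMatrix,
    ImportanceRanking,
    compute_attributions,
    rank_global_importance,
)
from .boosting import BoostingConfig, EnsembleModel, fit_survival_ensemble, make_split_plans
from .clustering import (
    AffinityConfig,
    ClusterAssignment,
    SensitivityResult,
    sensitivity_over_k,
    spectral_cluster_attributions,
)
from .profiles import INTERPRETATION_ADDONS, cohens_d_profile, summarize_clusters
from .reduction import PerformanceCurve, recursive_elimination
from .synthetic import (
    AnalysisDataset,
    Cohort,
    GeneratorConfig,
    PhenotypeSpec,
    TruthSidecar,
    build_analysis_datasets,
    default_phenotypes,
    generate_cohort,
)
from .weights import compute_selection_weights

Window = Literal["admission", "postdischarge"]


class PipelineConfig(BaseModel):
    """Everything needed to reproduce a full run, serialised into the report."""

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    phenotypes: Optional[List[PhenotypeSpec]] = None  # None = default four
    windows: List[Window] = Field(default_factory=lambda: ["admission", "postdischarge"])
    n_repeats: int = Field(default=10, ge=1)
    test_fraction: float = Field(default=0.1, gt=0.0, lt=1.0)
    cv_folds: int = Field(default=10, ge=2)
    boosting: BoostingConfig = Field(default_factory=BoostingConfig)
    affinity: AffinityConfig = Field(default_factory=AffinityConfig)
    k: int = Field(default=6, ge=2)
    sensitivity_ks: List[int] = Field(default_factory=lambda: [4, 5, 6, 7, 8])
    run_sensitivity: bool = True
    top_k_features: int = Field(default=25, ge=1)
    #: None skips the elimination experiment (it refits the ensemble ~50x).
    reduction_start_m: Optional[int] = Field(default=None, ge=1)
    master_seed: int = 0


@dataclass
class WindowResult:
    """All artifacts of one analysis window."""

    name: str
    dataset: AnalysisDataset
    ensemble: EnsembleModel
    attributions: AttributionMatrix
    ranking: ImportanceRanking
    assignment: ClusterAssignment
    sensitivity: Optional[SensitivityResult]
    cluster_summary: pd.DataFrame
    profile_complement: pd.DataFrame
    profile_grand: pd.DataFrame
    reduction_curve: Optional[PerformanceCurve]
    ari_vs_truth: Optional[float]


@dataclass
class ReportBundle:
    config: PipelineConfig
    cohort: Cohort
    outcomes: pd.DataFrame
    truth: TruthSidecar
    strata_counts: Dict[str, int]
    windows: Dict[str, WindowResult]
    manifest: Dict

    def write(self, out_dir: Path | str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        pd.Series(self.strata_counts, name="n").rename_axis("stratum").to_csv(
            out / "strata_counts.csv"
        )
        for wname, res in self.windows.items():
            wdir = out / wname
            wdir.mkdir(exist_ok=True)
            pd.DataFrame(
                {
                    "repeat": [p.repeat_id for p in res.ensemble.plans],
                    "concordance_weighted": res.ensemble.test_concordances,
                    "concordance_unweighted": res.ensemble.test_concordances_unweighted,
                }
            ).to_csv(wdir / "concordances.csv", index=False)
            res.ranking.table.to_csv(wdir / "importance.csv", index=False)
            res.assignment.labels.rename("cluster").to_csv(wdir / "assignment.csv")
            if res.sensitivity is not None:
                for k, a in res.sensitivity.assignments.items():
                    a.labels.rename("cluster").to_csv(wdir / f"assignment_k{k}.csv")
                res.sensitivity.ari_matrix.to_csv(wdir / "sensitivity_ari.csv")
            res.cluster_summary.to_csv(wdir / "cluster_summary.csv")
            res.profile_complement.to_csv(wdir / "profile_cluster_vs_rest.csv")
            res.profile_grand.to_csv(wdir / "profile_cluster_vs_sample.csv")
            # long form (cluster, variable, d) for heatmap-style consumers
            long = (
                res.profile_complement.rename_axis("cluster")
                .reset_index()
                .melt(id_vars="cluster", var_name="variable", value_name="d")
            )
            long.to_csv(wdir / "profile_cluster_vs_rest_long.csv", index=False)
            if res.reduction_curve is not None:
                res.reduction_curve.table.to_csv(wdir / "reduction_curve.csv", index=False)
                res.reduction_curve.summary().to_csv(wdir / "reduction_summary.csv")


def _spawn_seeds(master_seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute generate -> weights -> split -> fit -> attribute -> cluster ->
    profile (-> reduce) for every configured window."""
    seeds = _spawn_seeds(cfg.master_seed, 4 + 2 * len(cfg.windows))
    gen_cfg = cfg.generator.model_copy(update={"seed": seeds[0]})
    specs = cfg.phenotypes if cfg.phenotypes is not None else default_phenotypes()
    cohort, outcomes, truth = generate_cohort(gen_cfg, specs)
    strata_counts = truth.sampled_counts
    sel = compute_selection_weights(truth.sampled_counts, truth.source_counts)
    per_child_w = sel.assign(cohort.frame["stratum"])

    admission, postdischarge = build_analysis_datasets(
        cohort, outcomes,
        admission_horizon=gen_cfg.admission_horizon_days,
        postdischarge_horizon=gen_cfg.postdischarge_horizon_days,
    )
    datasets = {"admission": admission, "postdischarge": postdischarge}
    denominators = {"admission": len(cohort.frame), "postdischarge": len(postdischarge.features)}

    results: Dict[str, WindowResult] = {}
    for wi, window in enumerate(cfg.windows):
        ds = datasets[window]
        split_seed, boost_seed = seeds[4 + 2 * wi], seeds[4 + 2 * wi + 1]
        plans = make_split_plans(
            ds.n, cfg.n_repeats, seed=split_seed,
            test_fraction=cfg.test_fraction, n_folds=cfg.cv_folds,
        )
        boost_cfg = cfg.boosting.model_copy(update={"seed": boost_seed})
        w = per_child_w.loc[ds.features.index]
        ensemble = fit_survival_ensemble(ds, w, plans, boost_cfg)
        attr = compute_attributions(ensemble, ds.features)
        ranking = rank_global_importance(
            attr, k=min(cfg.top_k_features, len(ensemble.feature_names))
        )
        aff_cfg = cfg.affinity.model_copy(update={"seed": seeds[1]})
        outc = (ds.time, ds.event, ds.horizon)
        assignment = spectral_cluster_attributions(attr, cfg.k, aff_cfg, outc)
        sensitivity = (
            sensitivity_over_k(attr, cfg.sensitivity_ks, aff_cfg, outc)
            if cfg.run_sensitivity
            else None
        )
        summary = summarize_clusters(
            assignment.labels, ds.time, ds.event, ds.horizon,
            denominator=denominators[window],
        )
        profile_vars = ranking.top_features() + [
            v
            for v in INTERPRETATION_ADDONS
            if v in cohort.frame.columns and v not in ranking.top_features()
        ]
        profile_data = cohort.frame.loc[ds.features.index, profile_vars]
        prof_c = cohens_d_profile(profile_data, assignment.labels, profile_vars)
        prof_g = cohens_d_profile(
            profile_data, assignment.labels, profile_vars, variant="grand"
        )
        curve = None
        if cfg.reduction_start_m is not None:
            curve = recursive_elimination(
                ds, w, plans, boost_cfg, ranking,
                start_m=min(cfg.reduction_start_m, len(ensemble.feature_names)),
            )
        ari = float(
            adjusted_rand_score(
                truth.table.loc[ds.features.index, "phenotype"].to_numpy(),
                assignment.labels.to_numpy(),
            )
        )
        results[window] = WindowResult(
            name=ds.name,
            dataset=ds,
            ensemble=ensemble,
            attributions=attr,
            ranking=ranking,
            assignment=assignment,
            sensitivity=sensitivity,
            cluster_summary=summary,
            profile_complement=prof_c.values,
            profile_grand=prof_g.values,
            reduction_curve=curve,
            ari_vs_truth=ari,
        )

    import sklearn
    import xgboost
    import lifelines

    manifest = {
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xgboost": xgboost.__version__,
            "scikit-learn": sklearn.__version__,
            "lifelines": lifelines.__version__,
        },
        "master_seed": cfg.master_seed,
        "stage_seeds": seeds,
        "config": json.loads(cfg.model_dump_json()),
        "n_children": int(len(cohort.frame)),
        "windows": {
            w: {
                "n": int(r.dataset.n),
                "events": int(r.dataset.event.sum()),
                "median_concordance_weighted": float(
                    np.median(r.ensemble.test_concordances)
                ),
                "median_concordance_unweighted": float(
                    np.median(r.ensemble.test_concordances_unweighted)
                ),
                "ari_vs_truth": r.ari_vs_truth,
            }
            for w, r in results.items()
        },
    }
    return ReportBundle(
        config=cfg,
        cohort=cohort,
        outcomes=outcomes,
        truth=truth,
        strata_counts=strata_counts,
        windows=results,
        manifest=manifest,
    )
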