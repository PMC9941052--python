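# phenotyper

Explainable survival machine learning for paediatric acute-illness
cohorts: who dies during hospitalisation, who dies after discharge, and
what *kinds* of children are they?

Children admitted to hospital in low-resource settings face high mortality
both in the 30 days after admission and in the six months after discharge.
Risk is usually summarised syndrome by syndrome; this package instead
learns risk from hundreds of admission and discharge variables and then
*explains* it, grouping children into data-driven risk phenotypes.  It is
aimed at biostatisticians and epidemiologists who want a tested, reusable
implementation of this analysis pattern, exercised end to end on a
synthetic cohort generator that emulates the study design (MUAC-stratified
2:2:1 enrolment, ~3101 children, ~7.5% 30-day and ~6% post-discharge
mortality, informative missingness of social variables in early deaths) —
so no data download is required.

## The method

For each analysis window (30-day admission, 180-day post-discharge):

1. **Weighted boosted Cox ensemble.** R = 10 random 90/10 train/test
   splits; per split an XGBoost model with the Cox partial-likelihood
   objective is fit on the training part, weighted by
   inverse-probability-of-selection weights `w_s = N_source(s) / n_sampled(s)`
   that undo the stratified oversampling, with the number of rounds chosen
   by ten-fold cross-validation.  Test discrimination is Harrell's
   C-statistic: the weighted fraction of comparable pairs `(i, j)` with
   `t_i < t_j`, `δ_i = 1` where the earlier death has the higher predicted
   log-hazard margin.
2. **Shapley attributions.** Exact tree-Shapley values per member, so that
   `margin_r(x) = base_r + Σ_k φ_rk(x)`; the ensemble attribution is the
   member mean.  Global importance of feature k is `mean_i |φ_ik|`, and the
   top 25 features are reported.
3. **Spectral phenotype clustering.** Children are clustered on their
   L2-normalised attribution rows (RBF affinity, median-heuristic
   bandwidth, Laplacian eigenvector embedding, k-means), k = 6 by default
   with a 4–8 sensitivity sweep; labels are ordered by cluster mortality.
4. **Cluster profiles.** Per cluster: N, deaths, Kaplan-Meier cumulative
   mortality at the horizon with Greenwood log-log 95% CI, median (IQR)
   days to death, percent share; and Cohen's-D feature profiles
   `D(i, x) = (mean_i x − mean_rest x) / SD_sample(x)` over the top-25
   predictors plus standard interpretation variables.
5. **Recursive feature elimination.** From the top-50 predictors down to
   one, refitting and re-ranking at each step, tracing the C-statistic.

See `docs/methods.md` for assumptions, parameter defaults, and the
synthetic generator's scope.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py    # cohort + outcomes + truth sidecar
python analysis/02_fit_ensembles.py      # both windows, 10 members each
python analysis/03_explain_and_cluster.py
python analysis/04_profile_clusters.py
python analysis/05_reduce_features.py    # optional, ~5 min
```

A ten-line version of the same pipeline through the library:

```python
import numpy as np
import phenotyper as pt

cohort, outcomes, truth = pt.generate_cohort(pt.GeneratorConfig(seed=11))
admission, _ = pt.build_analysis_datasets(cohort, outcomes)
weights = pt.compute_selection_weights(
    truth.sampled_counts, truth.source_counts
).assign(cohort.frame["stratum"])
plans = pt.make_split_plans(admission.n, R=10, seed=11)
ensemble = pt.fit_survival_ensemble(
    admission, weights, plans,
    pt.BoostingConfig(n_rounds=300, early_stopping_rounds=25),
)
print("median test C:", np.median(ensemble.test_concordances))
attr = pt.compute_attributions(ensemble, admission.features)
print("top 5:", pt.rank_global_importance(attr, 25).features[:5])
clusters = pt.spectral_cluster_attributions(
    attr, 6, pt.AffinityConfig(seed=11),
    (admission.time, admission.event, admission.horizon),
)
print(pt.summarize_clusters(
    clusters.labels, admission.time, admission.event, 30.0
).round(3).to_string())
```

On the default cohort (seed 11) this prints a median test C-statistic of
0.785, ranks the planted anthropometric and laboratory features first
(`albumin`, `muac`, `creatinine`, `oedema`, `consciousness_avpu`), and
produces a six-cluster table whose Kaplan-Meier mortality rises
monotonically from 0.1% (n = 759, the well-nourished cluster) to 26%
(n = 435, dominated by the planted oedema and renal phenotypes) — the
synthetic analogue of the low-risk/high-risk phenotype split the method is
designed to expose.  The elimination experiment
(`05_reduce_features.py`) shows the same qualitative shape as the source
design: median C declines only from 0.83 with 50 predictors to 0.79 with
10, then degrades sharply (0.61 with one).  `results/` holds all these
tables for seed 11; any other seed reproduces its own via the scripts
above.

The console entry point mirrors the same stages
(`phenotyper generate | weights | fit | explain | cluster | profile |
reduce | run`); `phenotyper run --out report/` executes both windows from
one config.

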