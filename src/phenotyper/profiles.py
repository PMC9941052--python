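"""Cluster characterisation: Kaplan-Meier mortality, time-to-death, Cohen's D.

Each cluster is summarised the way the study's cluster table is laid out:
number of children, deaths, Kaplan-Meier cumulative mortality at the window
horizon with a Greenwood log-log 95% CI, the median and IQR of days to death
among the deaths, and the cluster's percent share of the analysis
denominator.  Feature profiles are standardised mean differences (Cohen's
D): the cluster-vs-rest mean difference divided by the whole-sample SD.

Two Cohen's-D variants exist because the source describes both: the default
compares cluster i against *all other* clusters; the alternative ("grand")
compares cluster i against the whole sample, under which the exact identity
sum_i N_i * D(i, x) = 0 holds for any fully observed x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

#: The six common clinical variables appended to the influential predictors
#: when profiling clusters, to aid interpretation.
INTERPRETATION_ADDONS = [
    "hiv_status",
    "malaria_rdt",
    "oedema",
    "consciousness_avpu",
    "diarrhoea_reported",
    "sepsis_clinician",
    "left_against_medical_advice",
]


@dataclass(frozen=True)
class KMEstimate:
    cumulative_mortality: float
    ci_low: float
    ci_high: float

    def as_tuple(self) -> tuple:
        return (self.cumulative_mortality, self.ci_low, self.ci_high)


@dataclass(frozen=True)
class MedianDaysToDeath:
    """Median and IQR of event times among deaths; undefined when no deaths."""

    median: float
    q1: float
    q3: float
    n_deaths: int

    @property
    def defined(self) -> bool:
        return self.n_deaths > 0


def km_cumulative_incidence(
    times: Sequence[float], events: Sequence[int], horizon: float, alpha: float = 0.05
) -> KMEstimate:
    """1 - product-limit survival at the horizon, with a Greenwood log-log CI.

    The CI is the exponential-Greenwood (log(-log)) interval, which stays in
    [0, 1]; it is truncated there anyway for safety.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty input: KM estimate undefined")
    if (t < 0).any():
        raise ValueError("negative follow-up times")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)
    s = float(kmf.survival_function_at_times(horizon).iloc[0])
    ci = kmf.confidence_interval_survival_function_
    idx = ci.index.to_numpy(dtype=float)
    at = np.searchsorted(idx, horizon, side="right") - 1
    if at < 0:
        lo_s, hi_s = 1.0, 1.0
    else:
        lo_s, hi_s = float(ci.iloc[at, 0]), float(ci.iloc[at, 1])
    if e.sum() == 0:  # no deaths: mortality 0 with degenerate CI
        return KMEstimate(0.0, 0.0, 0.0)
    est = 1.0 - s
    lo = float(np.clip(1.0 - hi_s, 0.0, 1.0))
    hi = float(np.clip(1.0 - lo_s, 0.0, 1.0))
    return KMEstimate(float(np.clip(est, 0.0, 1.0)), lo, hi)


def median_days_to_death(
    times: Sequence[float], events: Sequence[int]
) -> MedianDaysToDeath:
    """Empirical median and linear-interpolation quartiles of event times,
    restricted to deaths; NaN sentinel values when there are none."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    deaths = t[e == 1]
    if deaths.size == 0:
        return MedianDaysToDeath(np.nan, np.nan, np.nan, 0)
    q1, med, q3 = np.percentile(deaths, [25, 50, 75])
    return MedianDaysToDeath(float(med), float(q1), float(q3), int(deaths.size))


@dataclass
class ProfileMatrix:
    """Cluster x variable Cohen's-D matrix with an undefined-cell mask.

    Cells where the whole-sample SD is zero (or a mean is not computable)
    are NaN and flagged in ``undefined`` rather than silently zeroed.
    """

    values: pd.DataFrame     # index: cluster label, columns: variables
    undefined: pd.DataFrame  # same shape, bool
    variant: str
    sd_mode: str


def cohens_d_profile(
    data: pd.DataFrame,
    labels: pd.Series,
    variables: Optional[Sequence[str]] = None,
    variant: Literal["complement", "grand"] = "complement",
    sd_mode: Literal["sample", "population"] = "sample",
) -> ProfileMatrix:
    """Standardised mean differences of each variable across clusters.

    ``complement``: D(i, x) = (mean of x in cluster i - mean of x in all
    other clusters) / SD of x in the whole sample.  ``grand``: the rest-mean
    is replaced by the whole-sample mean.  Missing values are excluded
    pairwise; binary variables are treated as 0/1 numerics.  ``sd_mode``
    picks the SD denominator convention (n-1 "sample" is the default).
    """
    if variables is None:
        variables = list(data.columns)
    missing_vars = [v for v in variables if v not in data.columns]
    if missing_vars:
        raise ValueError(f"variables not in data: {missing_vars}")
    labels = labels.loc[data.index]
    clusters = sorted(labels.unique())
    ddof = 1 if sd_mode == "sample" else 0

    vals = np.full((len(clusters), len(variables)), np.nan)
    undef = np.zeros((len(clusters), len(variables)), dtype=bool)
    for j, v in enumerate(variables):
        x = data[v].astype(float)
        obs = x.notna()
        n_obs = int(obs.sum())
        sd = float(x[obs].std(ddof=ddof)) if n_obs >= 2 else np.nan
        for i, c in enumerate(clusters):
            in_c = labels == c
            x_in = x[in_c & obs]
            if variant == "complement":
                x_ref = x[~in_c & obs]
            else:
                x_ref = x[obs]
            if (
                n_obs < 2 or not np.isfinite(sd) or sd == 0.0
                or len(x_in) == 0 or len(x_ref) == 0
            ):
                undef[i, j] = True
                continue
            vals[i, j] = (x_in.mean() - x_ref.mean()) / sd
    return ProfileMatrix(
        values=pd.DataFrame(vals, index=clusters, columns=list(variables)),
        undefined=pd.DataFrame(undef, index=clusters, columns=list(variables)),
        variant=variant,
        sd_mode=sd_mode,
    )


def format_share_pct(share: float) -> float:
    """Percent share at the printed precision: one decimal below 10%,
    nearest integer otherwise."""
    return round(share, 1) if share < 10 else float(round(share))


def summarize_clusters(
    labels: pd.Series,
    times: pd.Series,
    events: pd.Series,
    horizon: float,
    denominator: Optional[int] = None,
) -> pd.DataFrame:
    """Per-cluster N, deaths, KM cumulative mortality + CI, median/IQR days
    to death, and percent share of the analysis denominator."""
    idx = labels.index
    times = times.loc[idx]
    events = events.loc[idx]
    if denominator is None:
        denominator = len(idx)
    rows = []
    for c in sorted(labels.unique()):
        in_c = labels == c
        t, e = times[in_c], events[in_c]
        km = km_cumulative_incidence(t, e, horizon)
        md = median_days_to_death(t, e)
        share = 100.0 * int(in_c.sum()) / denominator
        rows.append(
            {
                "cluster": c,
                "n": int(in_c.sum()),
                "deaths": int(e.sum()),
                "km_cumulative_mortality": km.cumulative_mortality,
                "ci_low": km.ci_low,
                "ci_high": km.ci_high,
                "median_days_to_death": md.median,
                "iqr_low": md.q1,
                "iqr_high": md.q3,
                "share_pct": share,
                "share_pct_printed": format_share_pct(share),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
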