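"""Synthetic stratified admission cohorts with planted mortality phenotypes.

The generator emulates the design of a multi-site paediatric acute-illness
cohort: enrolment is stratified on mid-upper-arm circumference (MUAC) at a
2:2:1 weekly ratio (severe wasting/oedema : moderate wasting : no wasting),
children carry four blocks of admission features (demographic, clinical,
laboratory, socioeconomic) plus discharge-phase features, and mortality is
tracked over two windows — 30 days from admission and 180 days from
discharge for children discharged alive.

Latent risk *phenotypes* are planted: each child belongs to one phenotype
that (a) shifts the means of a handful of features and (b) multiplies the
baseline exponential hazard in each window.  A truth sidecar records the
phenotype and true log-hazards so downstream recovery can be scored, and is
kept separate from the feature table so models can never see it.

Missingness mirrors the study's structure: blockwise missing-at-random
rates, plus *informative* missingness — socioeconomic interviews happened
about two days after admission, so every child who died before that day has
the whole social block missing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq

STRATA: Tuple[str, str, str] = (
    "severe_wasting_oedema",
    "moderate_wasting",
    "no_wasting",
)

BLOCKS: Tuple[str, ...] = ("demographic", "clinical", "laboratory", "socioeconomic")
PHASES: Tuple[str, str] = ("admission", "discharge")

#: Named features placed at the head of each block so phenotype shifts and the
#: cluster-profile "interpretation add-ons" can refer to real columns.
NAMED_DEMOGRAPHIC = ["age_months", "sex_female"]
NAMED_CLINICAL = [
    "muac",
    "weight_for_length_z",
    "weight_for_age_z",
    "length_for_age_z",
    "oedema",
    "consciousness_avpu",
    "hiv_status",
    "malaria_rdt",
    "diarrhoea_reported",
    "sepsis_clinician",
    "heart_rate",
    "resp_rate",
    "capillary_refill_s",
    "temperature",
    "unable_to_feed",
    "urine_output_reduced",
    "dehydration_signs",
    "vomiting_reported",
    "skin_turgor_reduced",
]
NAMED_LABORATORY = [
    "urea",
    "creatinine",
    "platelets",
    "albumin",
    "haemoglobin",
    "rbc_count",
    "wbc_count",
    "lymphocytes",
]
NAMED_DISCHARGE_CLINICAL = [
    "length_of_stay_days",
    "left_against_medical_advice",
    "muac_discharge",
    "weight_for_age_z_discharge",
    "weight_for_length_z_discharge",
    "consciousness_avpu_discharge",
]
NAMED_DISCHARGE_LABORATORY = ["urea_discharge", "creatinine_discharge"]

#: Latent-Gaussian features dichotomised at a threshold (prevalence ~ 12%
#: at the default cut of 1.2 population SD; sex at 0 for ~50%).
BINARY_FEATURES = {
    "sex_female": 0.0,
    "oedema": 1.2,
    "hiv_status": 1.8,
    "malaria_rdt": 1.1,
    "diarrhoea_reported": 0.0,
    "sepsis_clinician": 1.3,
    "unable_to_feed": 1.2,
    "consciousness_avpu": 1.5,
    "consciousness_avpu_discharge": 1.8,
    "urine_output_reduced": 1.2,
    "dehydration_signs": 1.0,
    "vomiting_reported": 0.8,
    "skin_turgor_reduced": 1.2,
}


class PhenotypeSpec(BaseModel):
    """A planted latent risk phenotype.

    ``feature_shifts`` are mean shifts, in population-SD units, applied to the
    latent Gaussian of the named features before any dichotomisation.  Hazard
    multipliers scale the calibrated baseline exponential rate of each window.
    """

    name: str
    prevalence: float = Field(gt=0.0, le=1.0)
    feature_shifts: Dict[str, float] = Field(default_factory=dict)
    hazard_multiplier_admission: float = Field(gt=0.0)
    hazard_multiplier_postdischarge: float = Field(gt=0.0)


class MissingnessConfig(BaseModel):
    """Blockwise missing-at-random rates plus the informative social rule."""

    block_rates: Dict[str, float] = Field(
        default_factory=lambda: {
            "demographic": 0.01,
            "clinical": 0.05,
            "laboratory": 0.15,
            "socioeconomic": 0.08,
        }
    )
    #: Children whose admission death precedes this day never had the social
    #: interview: their whole socioeconomic block is set missing.
    social_missing_death_day: float = 2.0

    @field_validator("block_rates")
    @classmethod
    def _rates_valid(cls, v: Dict[str, float]) -> Dict[str, float]:
        for blk, r in v.items():
            if blk not in BLOCKS:
                raise ValueError(f"unknown block {blk!r}")
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {blk!r} must be in [0,1)")
        return v


class GeneratorConfig(BaseModel):
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the source study's design: 3101 children enrolled at a
    2:2:1 MUAC-stratum ratio, ~7.5% 30-day mortality, ~6% mortality in the 180
    days after discharge, 3.7% lost to follow-up, and feature blocks sized so
    the admission analysis sees 207 variables (7 demographic + 184 clinical +
    16 laboratory) and the post-discharge analysis 556.
    """

    n_children: int = Field(default=3101, ge=10)
    strata_ratio: Tuple[int, int, int] = (2, 2, 1)
    target_30day_mortality: float = Field(default=0.075, gt=0.0, lt=1.0)
    target_postdischarge_mortality: float = Field(default=0.06, gt=0.0, lt=1.0)
    feature_block_sizes: Dict[str, int] = Field(
        default_factory=lambda: {
            "demographic": 7,
            "clinical": 184,
            "laboratory": 16,
            "socioeconomic": 186,
        }
    )
    discharge_block_sizes: Dict[str, int] = Field(
        default_factory=lambda: {
            "demographic": 4,
            "clinical": 136,
            "laboratory": 23,
        }
    )
    missingness: MissingnessConfig = Field(default_factory=MissingnessConfig)
    #: Lost-to-follow-up children are censored uniformly on (0, horizon]; the
    #: true loss mechanism of the study is unknown, so uniform is a declared
    #: stand-in rather than a reconstruction.
    ltfu_rate: float = Field(default=0.037, ge=0.0, lt=1.0)
    #: Stratum composition of the notional source population the 2:2:1
    #: enrolment oversamples from; used to derive selection weights.
    source_strata_proportions: Tuple[float, float, float] = (0.15, 0.25, 0.60)
    source_population_multiple: int = Field(default=10, ge=1)
    admission_horizon_days: float = 30.0
    postdischarge_horizon_days: float = 180.0
    block_correlation: float = Field(default=0.1, ge=0.0, lt=1.0)
    los_meanlog: float = 1.6
    los_sdlog: float = 0.6
    lama_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    seed: int = 0

    @field_validator("strata_ratio")
    @classmethod
    def _ratio_valid(cls, v: Tuple[int, int, int]) -> Tuple[int, int, int]:
        if any(x < 0 for x in v) or sum(v) == 0:
            raise ValueError("strata_ratio entries must be nonnegative, not all zero")
        return v

    @field_validator("feature_block_sizes", "discharge_block_sizes")
    @classmethod
    def _blocks_valid(cls, v: Dict[str, int]) -> Dict[str, int]:
        for blk, n in v.items():
            if blk not in BLOCKS:
                raise ValueError(f"unknown block {blk!r}")
            if n < 1:
                raise ValueError(f"block size for {blk!r} must be >= 1")
        return v

    @model_validator(mode="after")
    def _source_props_valid(self) -> "GeneratorConfig":
        if abs(sum(self.source_strata_proportions) - 1.0) > 1e-9:
            raise ValueError("source_strata_proportions must sum to 1")
        return self


@dataclass(frozen=True)
class FeatureSchema:
    """Maps every feature column to its (block, phase)."""

    blocks: Dict[str, str]  # column -> block
    phases: Dict[str, str]  # column -> "admission" | "discharge"

    @property
    def columns(self) -> List[str]:
        return list(self.blocks)

    def select(
        self, blocks: Optional[Sequence[str]] = None, phases: Optional[Sequence[str]] = None
    ) -> List[str]:
        blocks = set(blocks) if blocks is not None else set(BLOCKS)
        phases = set(phases) if phases is not None else set(PHASES)
        return [
            c
            for c in self.blocks
            if self.blocks[c] in blocks and self.phases[c] in phases
        ]

    def to_json(self) -> str:
        return json.dumps({"blocks": self.blocks, "phases": self.phases}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(blocks=d["blocks"], phases=d["phases"])


@dataclass
class Cohort:
    """Per-child feature table (indexed by child_id) with its schema.

    ``frame`` holds stratum, the discharge flags, and one column per feature;
    missing values are encoded as NaN, a single sentinel state the boosted
    learner can branch on natively.
    """

    frame: pd.DataFrame
    schema: FeatureSchema

    @property
    def child_ids(self) -> pd.Index:
        return self.frame.index

    def features(
        self, blocks: Optional[Sequence[str]] = None, phases: Optional[Sequence[str]] = None
    ) -> pd.DataFrame:
        return self.frame[self.schema.select(blocks, phases)]


@dataclass
class TruthSidecar:
    """Ground truth hidden from the models: phenotype and true log-hazards.

    Also carries the generator's stratum source/sampled counts, which are the
    "population truth" the selection weights are derived from in synthetic
    runs.
    """

    table: pd.DataFrame  # index child_id; phenotype, loghaz_admission, loghaz_postdischarge
    source_counts: Dict[str, int]
    sampled_counts: Dict[str, int]


@dataclass
class AnalysisDataset:
    """Features plus (time, event) for one analysis window."""

    name: str
    features: pd.DataFrame
    time: pd.Series
    event: pd.Series
    horizon: float

    @property
    def n(self) -> int:
        return len(self.features)


def default_phenotypes() -> List[PhenotypeSpec]:
    """The default four planted phenotypes.

    They mirror the qualitative cluster structure the study reports: a
    well-nourished low-risk group, a nondescript moderate group, a
    renal-insufficiency group (high urea/creatinine), and a severe
    nutritional-oedema group with depressed platelets and reduced
    consciousness.  Hazard multipliers are spread widely enough that the
    groups occupy clearly different mortality strata.
    """
    return [
        PhenotypeSpec(
            name="thriving",
            prevalence=0.35,
            hazard_multiplier_admission=0.25,
            hazard_multiplier_postdischarge=0.25,
            feature_shifts={
                "muac": 2.4,
                "weight_for_age_z": 2.0,
                "weight_for_length_z": 2.0,
                "length_for_age_z": 1.5,
                "albumin": 1.2,
                "haemoglobin": 0.9,
            },
        ),
        PhenotypeSpec(
            name="moderate_illness",
            prevalence=0.40,
            hazard_multiplier_admission=1.0,
            hazard_multiplier_postdischarge=1.0,
            feature_shifts={
                "muac": -0.8,
                "diarrhoea_reported": 1.2,
                "dehydration_signs": 1.5,
                "skin_turgor_reduced": 1.2,
                "temperature": 0.9,
                "resp_rate": 0.8,
                "wbc_count": 0.8,
            },
        ),
        PhenotypeSpec(
            name="renal",
            prevalence=0.15,
            hazard_multiplier_admission=5.0,
            hazard_multiplier_postdischarge=3.0,
            feature_shifts={
                "urea": 4.0,
                "creatinine": 4.0,
                "urine_output_reduced": 2.5,
                "vomiting_reported": 1.2,
                "heart_rate": -0.9,
                "haemoglobin": -1.2,
            },
        ),
        PhenotypeSpec(
            name="oedema_severe",
            prevalence=0.10,
            hazard_multiplier_admission=12.0,
            hazard_multiplier_postdischarge=6.0,
            feature_shifts={
                "oedema": 3.5,
                "platelets": -2.5,
                "albumin": -2.5,
                "consciousness_avpu": 2.2,
                "unable_to_feed": 1.8,
                "capillary_refill_s": 1.5,
                "muac": -1.5,
                "temperature": -1.2,
            },
        ),
    ]


def single_signal_phenotypes(
    feature: str = "muac",
    shift: float = -3.0,
    hazard_ratio: float = 25.0,
    prevalence_high: float = 0.2,
) -> List[PhenotypeSpec]:
    """Two phenotypes separated by a single strongly shifted feature.

    A fixture where one feature carries all the hazard signal.  The defaults
    (a 20% high-risk group at hazard ratio 25, separated by 3 SD) are
    calibrated so the Bayes-optimal concordance of the true log-hazard
    exceeds 0.8: a rarer high-risk group is essential, since with balanced
    groups the uninformative within-group pairs cap the C-statistic near
    0.75 however large the hazard ratio.
    """
    return [
        PhenotypeSpec(
            name="low_risk",
            prevalence=1.0 - prevalence_high,
            hazard_multiplier_admission=1.0,
            hazard_multiplier_postdischarge=1.0,
        ),
        PhenotypeSpec(
            name="high_risk",
            prevalence=prevalence_high,
            hazard_multiplier_admission=hazard_ratio,
            hazard_multiplier_postdischarge=hazard_ratio,
            feature_shifts={feature: shift},
        ),
    ]


def small_schema_config(**overrides) -> GeneratorConfig:
    """A reduced feature schema for fast experiments and tests."""
    defaults = dict(
        feature_block_sizes={
            "demographic": 3,
            "clinical": 20,
            "laboratory": 8,
            "socioeconomic": 6,
        },
        discharge_block_sizes={"demographic": 1, "clinical": 8, "laboratory": 2},
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def build_schema(config: GeneratorConfig) -> FeatureSchema:
    """Column names and block/phase labels implied by the config."""
    blocks: Dict[str, str] = {}
    phases: Dict[str, str] = {}

    def add(names: List[str], block: str, phase: str) -> None:
        for c in names:
            blocks[c] = block
            phases[c] = phase

    def pad(named: List[str], total: int, stem: str) -> List[str]:
        if total < len(named):
            return named[:total]
        fill = [f"{stem}_{i:03d}" for i in range(1, total - len(named) + 1)]
        return named + fill

    fbs = config.feature_block_sizes
    add(pad(NAMED_DEMOGRAPHIC, fbs["demographic"], "demo_adm"), "demographic", "admission")
    add(pad(NAMED_CLINICAL, fbs["clinical"], "clin_adm"), "clinical", "admission")
    add(pad(NAMED_LABORATORY, fbs["laboratory"], "lab_adm"), "laboratory", "admission")
    add(pad([], fbs.get("socioeconomic", 0), "soc"), "socioeconomic", "admission")

    dbs = config.discharge_block_sizes
    add(pad([], dbs.get("demographic", 0), "demo_dis"), "demographic", "discharge")
    add(
        pad(NAMED_DISCHARGE_CLINICAL, dbs.get("clinical", 0), "clin_dis"),
        "clinical",
        "discharge",
    )
    add(
        pad(NAMED_DISCHARGE_LABORATORY, dbs.get("laboratory", 0), "lab_dis"),
        "laboratory",
        "discharge",
    )
    return FeatureSchema(blocks=blocks, phases=phases)


def _validate_specs(specs: Sequence[PhenotypeSpec], schema: FeatureSchema) -> None:
    total = sum(s.prevalence for s in specs)
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"phenotype prevalences must sum to 1, got {total:.6f}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("phenotype names must be unique")
    known = set(schema.columns)
    for s in specs:
        unknown = set(s.feature_shifts) - known
        if unknown:
            raise ValueError(
                f"phenotype {s.name!r} shifts unknown features: {sorted(unknown)}"
            )


def _observed_event_prob(rate: np.ndarray, horizon: float, ltfu_rate: float) -> np.ndarray:
    """P(death observed before horizon) under exponential hazard + uniform LTFU.

    A lost-to-follow-up child is censored at C ~ U(0, horizon]; the death is
    observed only if T <= C, which for T ~ Exp(rate) gives
    1 - (1 - exp(-r*H)) / (r*H).
    """
    rh = rate * horizon
    f = -np.expm1(-rh)  # P(T <= H)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ltfu = np.where(rh > 0, 1.0 - f / np.where(rh > 0, rh, 1.0), 0.0)
    return (1.0 - ltfu_rate) * f + ltfu_rate * p_ltfu


def _calibrate_base_rate(
    multipliers: np.ndarray, horizon: float, target: float, ltfu_rate: float
) -> float:
    """Root-find the baseline exponential rate so the cohort's expected
    observed-death fraction at the horizon equals ``target``."""

    def gap(lam: float) -> float:
        return float(
            np.mean(_observed_event_prob(lam * multipliers, horizon, ltfu_rate)) - target
        )

    return float(brentq(gap, 1e-12, 50.0, xtol=1e-14, rtol=1e-12))


def generate_cohort(
    config: GeneratorConfig, specs: Optional[Sequence[PhenotypeSpec]] = None
) -> Tuple[Cohort, pd.DataFrame, TruthSidecar]:
    """Generate a stratified cohort with planted phenotypes and two outcome
    windows.

    Returns ``(cohort, outcomes, truth)`` where ``outcomes`` has one row per
    child with columns ``admission_time_days``, ``admission_event``,
    ``postdischarge_time_days`` and ``postdischarge_event`` (the last two NaN
    for children not discharged alive), and ``truth`` is the hidden sidecar.
    """
    if specs is None:
        specs = default_phenotypes()
    schema = build_schema(config)
    _validate_specs(specs, schema)
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    child_ids = pd.Index([f"C{i:06d}" for i in range(1, n + 1)], name="child_id")

    # --- enrolment strata at the configured weekly ratio -------------------
    ratio = np.asarray(config.strata_ratio, dtype=float)
    strata = rng.choice(len(STRATA), size=n, p=ratio / ratio.sum())
    stratum_labels = np.asarray(STRATA)[strata]

    # --- phenotype assignment ---------------------------------------------
    prev = np.array([s.prevalence for s in specs])
    prev = prev / prev.sum()
    ph_idx = rng.choice(len(specs), size=n, p=prev)
    ph_names = np.asarray([s.name for s in specs])[ph_idx]

    # --- latent block-structured Gaussian features -------------------------
    cols = schema.columns
    p = len(cols)
    rho = config.block_correlation
    block_of = np.asarray([f"{schema.blocks[c]}|{schema.phases[c]}" for c in cols])
    latent = np.sqrt(1.0 - rho) * rng.standard_normal((n, p))
    for blk in np.unique(block_of):
        mask = block_of == blk
        latent[:, mask] += np.sqrt(rho) * rng.standard_normal((n, 1))
    col_pos = {c: j for j, c in enumerate(cols)}
    shift_mat = np.zeros((len(specs), p))
    for si, s in enumerate(specs):
        for c, delta in s.feature_shifts.items():
            shift_mat[si, col_pos[c]] = delta
    latent += shift_mat[ph_idx]

    feat = latent.copy()
    for c, thr in BINARY_FEATURES.items():
        if c in col_pos:
            feat[:, col_pos[c]] = (latent[:, col_pos[c]] > thr).astype(float)

    frame = pd.DataFrame(feat, index=child_ids, columns=cols)

    # length of stay is a real generated quantity, not a latent Gaussian
    los = np.minimum(
        rng.lognormal(config.los_meanlog, config.los_sdlog, size=n),
        config.admission_horizon_days,
    )
    if "length_of_stay_days" in frame.columns:
        frame["length_of_stay_days"] = los

    # --- admission-window survival -----------------------------------------
    h_adm = config.admission_horizon_days
    mult_adm = np.array([s.hazard_multiplier_admission for s in specs])[ph_idx]
    lam = _calibrate_base_rate(
        mult_adm, h_adm, config.target_30day_mortality, config.ltfu_rate
    )
    t_death_adm = rng.exponential(1.0 / (lam * mult_adm))
    ltfu_adm = rng.random(n) < config.ltfu_rate
    c_adm = np.where(ltfu_adm, rng.uniform(0.0, h_adm, size=n), h_adm)
    adm_time = np.minimum(t_death_adm, c_adm)
    adm_event = (t_death_adm <= c_adm).astype(int)

    died_in_hospital = (adm_event == 1) & (t_death_adm <= los)
    discharged = ~died_in_hospital
    lama = discharged & (rng.random(n) < config.lama_rate)
    if "left_against_medical_advice" in frame.columns:
        frame["left_against_medical_advice"] = lama.astype(float)

    # --- post-discharge window (discharged children only) -------------------
    h_pd = config.postdischarge_horizon_days
    mult_pd = np.array([s.hazard_multiplier_postdischarge for s in specs])[ph_idx]
    mu = _calibrate_base_rate(
        mult_pd[discharged], h_pd, config.target_postdischarge_mortality, config.ltfu_rate
    )
    t_death_pd = rng.exponential(1.0 / (mu * mult_pd))
    ltfu_pd = rng.random(n) < config.ltfu_rate
    c_pd = np.where(ltfu_pd, rng.uniform(0.0, h_pd, size=n), h_pd)
    pd_time = np.minimum(t_death_pd, c_pd)
    pd_event = (t_death_pd <= c_pd).astype(float)
    pd_time = np.where(discharged, pd_time, np.nan)
    pd_event = np.where(discharged, pd_event, np.nan)

    # --- missingness ---------------------------------------------------------
    protected = {"length_of_stay_days", "left_against_medical_advice"}
    for blk, rate in config.missingness.block_rates.items():
        if rate <= 0:
            continue
        cset = [
            c
            for c in schema.columns
            if schema.blocks[c] == blk and c not in protected
        ]
        if not cset:
            continue
        mask = rng.random((n, len(cset))) < rate
        vals = frame[cset].to_numpy()
        vals[mask] = np.nan
        frame[cset] = vals
    social_cols = [c for c in schema.columns if schema.blocks[c] == "socioeconomic"]
    early_death = (adm_event == 1) & (
        adm_time < config.missingness.social_missing_death_day
    )
    if social_cols and early_death.any():
        frame.loc[early_death, social_cols] = np.nan

    meta = pd.DataFrame(
        {
            "stratum": stratum_labels,
            "discharged_alive": discharged,
            "left_against_medical_advice_flag": lama,
        },
        index=child_ids,
    )
    frame = pd.concat([meta, frame], axis=1)

    outcomes = pd.DataFrame(
        {
            "admission_time_days": adm_time,
            "admission_event": adm_event,
            "postdischarge_time_days": pd_time,
            "postdischarge_event": pd_event,
        },
        index=child_ids,
    )

    # --- truth sidecar -------------------------------------------------------
    truth_table = pd.DataFrame(
        {
            "phenotype": ph_names,
            "loghaz_admission": np.log(lam * mult_adm),
            "loghaz_postdischarge": np.log(mu * mult_pd),
        },
        index=child_ids,
    )
    sampled_counts = {
        s: int((stratum_labels == s).sum()) for s in STRATA
    }
    n_source = config.source_population_multiple * n
    raw = [p_ * n_source for p_ in config.source_strata_proportions]
    source_counts = {
        s: max(int(round(r)), sampled_counts[s]) for s, r in zip(STRATA, raw)
    }
    truth = TruthSidecar(
        table=truth_table, source_counts=source_counts, sampled_counts=sampled_counts
    )
    return Cohort(frame=frame, schema=schema), outcomes, truth


def build_analysis_datasets(
    cohort: Cohort, outcomes: pd.DataFrame,
    admission_horizon: float = 30.0, postdischarge_horizon: float = 180.0,
) -> Tuple[AnalysisDataset, AnalysisDataset]:
    """Project the cohort into the two analysis datasets.

    The admission dataset keeps every child and only admission-phase
    demographic, clinical and laboratory features — the socioeconomic block is
    excluded because social interviews were missing for early deaths and the
    learner treats missingness as signal.  The post-discharge dataset keeps
    only children discharged alive and all feature blocks including
    discharge-phase and socioeconomic features.
    """
    missing = cohort.child_ids.difference(outcomes.index)
    if len(missing):
        raise ValueError(f"outcomes missing for {len(missing)} children")
    outcomes = outcomes.loc[cohort.child_ids]

    adm_cols = cohort.schema.select(
        blocks=["demographic", "clinical", "laboratory"], phases=["admission"]
    )
    admission = AnalysisDataset(
        name="admission_30day",
        features=cohort.frame[adm_cols].copy(),
        time=outcomes["admission_time_days"].copy(),
        event=outcomes["admission_event"].astype(int).copy(),
        horizon=admission_horizon,
    )

    disc = cohort.frame["discharged_alive"].astype(bool)
    pd_cols = cohort.schema.select()  # all blocks, both phases
    feats = cohort.frame.loc[disc, pd_cols].copy()
    postdischarge = AnalysisDataset(
        name="postdischarge_180day",
        features=feats,
        time=outcomes.loc[disc, "postdischarge_time_days"].copy(),
        event=outcomes.loc[disc, "postdischarge_event"].astype(int).copy(),
        horizon=postdischarge_horizon,
    )
    return admission, postdischarge


def schema_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


def write_cohort(
    out_dir: Path | str, cohort: Cohort, outcomes: pd.DataFrame, truth: TruthSidecar
) -> None:
    """Write cohort + outcomes as CSV and Parquet with a JSON schema sidecar;
    the truth sidecar goes to its own JSON so models cannot see it by accident."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.frame.to_csv(out / "cohort.csv")
    cohort.frame.to_parquet(out / "cohort.parquet")
    outcomes.to_csv(out / "outcomes.csv")
    (out / "schema.json").write_text(cohort.schema.to_json())
    truth_payload = {
        "source_counts": truth.source_counts,
        "sampled_counts": truth.sampled_counts,
        "children": truth.table.reset_index().to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))


def read_cohort(in_dir: Path | str) -> Tuple[Cohort, pd.DataFrame, TruthSidecar]:
    inp = Path(in_dir)
    schema = FeatureSchema.from_json((inp / "schema.json").read_text())
    frame = pd.read_parquet(inp / "cohort.parquet")
    outcomes = pd.read_csv(inp / "outcomes.csv", index_col="child_id")
    d = json.loads((inp / "truth.json").read_text())
    table = pd.DataFrame(d["children"]).set_index("child_id")
    truth = TruthSidecar(
        table=table,
        source_counts=d["source_counts"],
        sampled_counts=d["sampled_counts"],
    )
    return Cohort(frame=frame, schema=schema), outcomes, truth
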