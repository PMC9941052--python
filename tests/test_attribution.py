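"""Shapley attribution axioms and global importance rankings."""

import re

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

import phenotyper as pt
from phenotyper.attribution import AttributionMatrix


def test_additivity_base_plus_rowsum_equals_margin(signal_fit):
    attr = signal_fit.attributions
    scores = pt.predict_risk(signal_fit.ensemble, signal_fit.dataset.features)
    recon = attr.member_margins()          # (R, n)
    direct = scores.per_member.T           # (R, n)
    assert np.abs(recon - direct).max() < 1e-5


def test_constant_feature_gets_zero_attribution():
    """Dummy-player axiom: a feature constant across all children can never
    split a tree, so its attribution column is identically zero."""
    rng = np.random.default_rng(0)
    n = 120
    feats = pd.DataFrame(
        {
            "signal": rng.normal(size=n),
            "constant": np.full(n, 3.7),
            "noise": rng.normal(size=n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    t = np.exp(-feats["signal"]) * rng.exponential(5, n) + 0.1
    ds = pt.AnalysisDataset(
        name="const", features=feats,
        time=pd.Series(t, index=feats.index),
        event=pd.Series(np.ones(n, dtype=int), index=feats.index),
        horizon=30,
    )
    plans = pt.make_split_plans(n, R=2, seed=1)
    ens = pt.fit_survival_ensemble(
        ds, None, plans, pt.BoostingConfig(n_rounds=20, early_stopping_rounds=None)
    )
    attr = pt.compute_attributions(ens, feats)
    j = attr.feature_names.index("constant")
    assert np.abs(attr.values[:, :, j]).max() == 0.0


def _parse_stump(booster: xgb.Booster):
    """Extract (split_feature_idx, threshold, left_value, right_value,
    left_cover, right_cover) from a depth-1 single-tree dump."""
    dump = booster.get_dump(with_stats=True)[0]
    thr = float(re.search(r"\[f(\d+)<([-\d.e+]+)\]", dump).group(2))
    feat = int(re.search(r"\[f(\d+)<", dump).group(1))
    leaves = re.findall(r"leaf=([-\d.e+]+),cover=([-\d.e+]+)", dump)
    (v_yes, c_yes), (v_no, c_no) = [(float(a), float(b)) for a, b in leaves]
    return feat, thr, v_yes, c_yes, v_no, c_no


def test_stump_shapley_matches_closed_form():
    """For a single depth-1 tree the path-dependent tree-Shapley value of the
    split feature is leaf_value - cover-weighted mean leaf value, and the
    base value is that mean; every other feature gets zero."""
    rng = np.random.default_rng(5)
    n = 200
    x = rng.normal(size=n)
    feats = pd.DataFrame({"x": x, "other": rng.normal(size=n)})
    t = np.where(x > 0, rng.exponential(2, n), rng.exponential(20, n)) + 0.1
    y = t  # all events
    dtrain = xgb.DMatrix(feats.to_numpy(), label=y)  # default f0/f1 names for the dump
    params = {
        "objective": "survival:cox", "max_depth": 1, "eta": 1.0,
        "lambda": 0.0, "tree_method": "hist", "nthread": 1, "seed": 0,
    }
    booster = xgb.train(params, dtrain, num_boost_round=1)
    feat, thr, v_yes, c_yes, v_no, c_no = _parse_stump(booster)
    base = (v_yes * c_yes + v_no * c_no) / (c_yes + c_no)
    contribs = booster.predict(dtrain, pred_contribs=True)
    # DMatrix stores float32: compare on the same precision as the tree does
    x_col = feats.to_numpy()[:, feat].astype(np.float32)
    expected_split = np.where(x_col < np.float32(thr), v_yes, v_no) - base
    assert np.allclose(contribs[:, feat], expected_split, atol=1e-5)
    other = 1 - feat
    assert np.abs(contribs[:, other]).max() < 1e-7
    assert np.allclose(contribs[:, 2], base, atol=1e-5)


class TestImportanceRanking:
    def _matrix(self, values: np.ndarray, names) -> AttributionMatrix:
        n = values.shape[0]
        return AttributionMatrix(
            child_ids=pd.Index([f"c{i}" for i in range(n)]),
            feature_names=list(names),
            values=values[None, :, :],
            base_values=np.zeros((1, n)),
            missing_mask=np.zeros_like(values, dtype=bool),
        )

    def test_hand_computed_importance(self):
        vals = np.array([[1.0, 0.1], [-1.0, 0.0], [2.0, -0.1]])
        attr = self._matrix(vals, ["f1", "f2"])
        rank = pt.rank_global_importance(attr, k=1)
        assert rank.features == ["f1", "f2"]
        row = rank.table.set_index("feature")
        assert row.loc["f1", "importance"] == pytest.approx(4 / 3)
        assert row.loc["f2", "importance"] == pytest.approx(0.2 / 3)
        assert rank.top_features() == ["f1"]

    def test_all_zero_ties_break_lexicographically(self):
        attr = self._matrix(np.zeros((4, 3)), ["zeta", "alpha", "mid"])
        rank = pt.rank_global_importance(attr, k=2)
        assert rank.features == ["alpha", "mid", "zeta"]
        assert (rank.table["importance"] == 0).all()

    def test_top_25_flagged_on_admission_model(self, default_run):
        run = default_run(0)
        assert len(run.ensemble.feature_names) == 207
        rank = pt.rank_global_importance(run.attributions, k=25)
        assert int(rank.table["top_k"].sum()) == 25
        assert (rank.table["importance"].diff().dropna() <= 1e-12).all()

    def test_invariance_to_child_and_feature_permutation(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(30, 5))
        names = ["a", "b", "c", "d", "e"]
        base = pt.rank_global_importance(self._matrix(vals, names), k=2)
        perm_children = rng.permutation(30)
        r1 = pt.rank_global_importance(self._matrix(vals[perm_children], names), k=2)
        assert r1.features == base.features
        perm_feats = rng.permutation(5)
        r2 = pt.rank_global_importance(
            self._matrix(vals[:, perm_feats], [names[j] for j in perm_feats]), k=2
        )
        assert r2.features == base.features

    def test_k_validation(self):
        attr = self._matrix(np.ones((3, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            pt.rank_global_importance(attr, k=0)
        with pytest.raises(ValueError):
            pt.rank_global_importance(attr, k=5)


def test_planted_features_rank_highly():
    """Recovery property: with a small set of planted hazard-carrying
    features, all of them appear within the top 2 x (number planted) ranks.

    Uses a dedicated two-phenotype fixture whose high-risk group shifts four
    features; redundant multi-feature signatures (as in the default cohort)
    deliberately dilute individual attributions, so the axiom-level check
    lives here, on a fixture where each feature carries real signal.
    """
    cfg = pt.small_schema_config(n_children=800, seed=31, target_30day_mortality=0.2)
    shifts = {"muac": -2.0, "urea": 2.5, "platelets": -2.0, "albumin": -2.0}
    specs = [
        pt.PhenotypeSpec(
            name="low", prevalence=0.7,
            hazard_multiplier_admission=1.0, hazard_multiplier_postdischarge=1.0,
        ),
        pt.PhenotypeSpec(
            name="high", prevalence=0.3,
            hazard_multiplier_admission=10.0, hazard_multiplier_postdischarge=10.0,
            feature_shifts=shifts,
        ),
    ]
    cohort, outcomes, _ = pt.generate_cohort(cfg, specs)
    adm, _ = pt.build_analysis_datasets(cohort, outcomes)
    plans = pt.make_split_plans(adm.n, R=3, seed=32)
    ens = pt.fit_survival_ensemble(
        adm, None, plans, pt.BoostingConfig(n_rounds=60, early_stopping_rounds=None)
    )
    attr = pt.compute_attributions(ens, adm.features)
    rank = pt.rank_global_importance(attr, k=len(shifts))
    positions = {f: i + 1 for i, f in enumerate(rank.features)}
    cutoff = 2 * len(shifts)
    outside = [f for f in shifts if positions[f] > cutoff]
    assert not outside, f"planted features outside top {cutoff}: {outside}"


def test_every_phenotype_signature_reaches_top25(default_run):
    """On the default cohort each planted phenotype must place at least one
    of its signature features among the top-25 predictors."""
    run = default_run(0)
    rank = pt.rank_global_importance(run.attributions, k=25)
    top = set(rank.top_features())
    for spec in pt.default_phenotypes():
        if spec.feature_shifts:
            assert top & set(spec.feature_shifts), spec.name


def test_schema_mismatch_rejected(signal_fit):
    feats = signal_fit.dataset.features.iloc[:, ::-1]
    with pytest.raises(ValueError, match="schema"):
        pt.compute_attributions(signal_fit.ensemble, feats)


def test_attribution_roundtrip_save(signal_fit, tmp_path):
    attr = signal_fit.attributions
    attr.save(tmp_path)
    long = pd.read_parquet(tmp_path / "attributions.parquet")
    R, n, p = attr.values.shape
    assert len(long) == R * n * p
    member0 = long[long["member"] == 0].pivot(
        index="child_id", columns="feature", values="value"
    )
    member0 = member0.loc[attr.child_ids, attr.feature_names]
    assert np.allclose(member0.to_numpy(), attr.values[0])
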