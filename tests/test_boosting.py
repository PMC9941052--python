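"""Split plans, the weighted C-statistic, and the boosted-Cox ensemble."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.utils import concordance_index as lifelines_cindex

import phenotyper as pt
from phenotyper.boosting import _cox_labels

from .oracles import concordance_bruteforce


class TestSplitPlans:
    def test_sizes_and_partition(self):
        plans = pt.make_split_plans(100, R=10, seed=0)
        assert len(plans) == 10
        for p in plans:
            assert len(p.test_idx) == 10
            assert len(p.train_idx) == 90
            assert not set(p.train_idx) & set(p.test_idx)
            # folds partition the training part into 10 nonempty folds
            assert sorted(np.unique(p.folds)) == list(range(10))
            assert len(p.folds) == len(p.train_idx)

    def test_determinism(self):
        a = pt.make_split_plans(173, R=4, seed=9)
        b = pt.make_split_plans(173, R=4, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.train_idx, y.train_idx)
            assert np.array_equal(x.test_idx, y.test_idx)
            assert np.array_equal(x.folds, y.folds)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            pt.make_split_plans(10, R=2)
        with pytest.raises(ValueError, match="too small"):
            pt.make_split_plans(21, R=1, n_folds=20)

    def test_test_set_coverage_fraction(self):
        """Across R=10 independent 90/10 splits each child lands in >=1 test
        set with probability 1 - 0.9^10 ~ 0.651; the realized fraction at
        n = 3101 must be close."""
        plans = pt.make_split_plans(3101, R=10, seed=3)
        covered = np.zeros(3101, dtype=bool)
        for p in plans:
            covered[p.test_idx] = True
        assert covered.mean() == pytest.approx(1 - 0.9**10, abs=0.03)


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.array([1.0, 2, 3, 4])
        assert pt.concordance_index(-t, t, np.ones(4, int)) == 1.0

    def test_all_tied_scores(self):
        t = np.array([1.0, 2, 3, 4])
        assert pt.concordance_index(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_five_point_censored_fixture(self):
        times = np.array([2.0, 4, 4, 6, 8])
        events = np.array([1, 1, 0, 1, 1])
        scores = np.array([5.0, 4, 3, 2, 1])
        expected = concordance_bruteforce(scores, times, events)
        got = pt.concordance_index(scores, times, events)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == 1.0  # scores decrease with time; all comparable pairs correct

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(5, 60))
    def test_matches_bruteforce_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        t = rng.exponential(5, n).round(1) + 0.1
        e = rng.integers(0, 2, n)
        s = rng.normal(size=n).round(2)  # rounding forces some score ties
        w = rng.uniform(0.5, 3.0, n)
        expected = concordance_bruteforce(s, t, e, w)
        got = pt.concordance_index(s, t, e, weights=w)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 80)
        e = rng.integers(0, 2, 80)
        s = rng.normal(size=80)
        base = pt.concordance_index(s, t, e)
        assert pt.concordance_index(np.exp(s), t, e) == pytest.approx(base)
        assert pt.concordance_index(3 * s + 7, t, e) == pytest.approx(base)

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        s = rng.normal(size=60)
        assert pt.concordance_index(s, t, e, weights=np.full(60, 2.5)) == (
            pt.concordance_index(s, t, e)
        )

    def test_agrees_with_lifelines_on_unique_times(self):
        rng = np.random.default_rng(3)
        t = rng.permutation(np.arange(1.0, 101.0))  # unique times
        e = rng.integers(0, 2, 100)
        s = rng.normal(size=100)
        ours = pt.concordance_index(s, t, e)
        theirs = lifelines_cindex(t, -s, e)  # lifelines expects survival scores
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_warns_nan(self):
        with pytest.warns(RuntimeWarning, match="no comparable pairs"):
            v = pt.concordance_index(
                np.array([1.0, 2.0]), np.array([5.0, 5.0]), np.array([0, 0])
            )
        assert np.isnan(v)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            pt.concordance_index(np.ones(3), np.ones(2), np.ones(2, int))
        with pytest.raises(ValueError, match="binary"):
            pt.concordance_index(np.ones(2), np.ones(2), np.array([0, 2]))


class TestEnsemble:
    def test_one_member_and_concordance_per_plan(self, signal_fit):
        ens = signal_fit.ensemble
        assert ens.n_members == len(signal_fit.plans)
        assert len(ens.test_concordances) == ens.n_members
        assert len(ens.test_concordances_unweighted) == ens.n_members
        assert all(0 <= c <= 1 for c in ens.test_concordances)

    def test_ten_repeats_give_ten_concordances(self, signal_fit):
        ds, w = signal_fit.dataset, signal_fit.weights
        plans = pt.make_split_plans(ds.n, R=10, seed=4)
        cfg = pt.BoostingConfig(n_rounds=10, early_stopping_rounds=None)
        ens = pt.fit_survival_ensemble(ds, w, plans, cfg)
        assert len(ens.test_concordances) == 10

    def test_all_censored_training_split_refused(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        ds = pt.AnalysisDataset(
            name="censored",
            features=feats,
            time=pd.Series(rng.uniform(1, 10, 40), index=feats.index),
            event=pd.Series(np.zeros(40, dtype=int), index=feats.index),
            horizon=30,
        )
        plans = pt.make_split_plans(40, R=1, seed=0, n_folds=2)
        with pytest.raises(ValueError, match="no events"):
            pt.fit_survival_ensemble(
                ds, None, plans, pt.BoostingConfig(n_rounds=5, early_stopping_rounds=None)
            )

    def test_infinite_features_rejected(self, signal_fit):
        feats = signal_fit.dataset.features.copy()
        feats.iloc[0, 0] = np.inf
        ds = pt.AnalysisDataset(
            name="inf", features=feats, time=signal_fit.dataset.time,
            event=signal_fit.dataset.event, horizon=30,
        )
        with pytest.raises(ValueError, match="non-finite"):
            pt.fit_survival_ensemble(
                ds, None, signal_fit.plans, pt.BoostingConfig(n_rounds=5, early_stopping_rounds=None)
            )

    def test_predict_risk_mean_is_member_mean(self, signal_fit):
        scores = pt.predict_risk(signal_fit.ensemble, signal_fit.dataset.features)
        assert np.allclose(
            scores.ensemble_mean.to_numpy(), scores.per_member.mean(axis=1)
        )

    def test_predict_schema_mismatch(self, signal_fit):
        feats = signal_fit.dataset.features.iloc[:, ::-1]
        with pytest.raises(ValueError, match="schema"):
            pt.predict_risk(signal_fit.ensemble, feats)

    def test_monotone_constraint_respected(self):
        """With a monotone-increasing constraint on the planted hazard
        feature, raising it along a grid never lowers the margin."""
        cfg = pt.small_schema_config(n_children=400, seed=2, target_30day_mortality=0.2)
        specs = pt.single_signal_phenotypes(feature="muac", shift=3.0)
        cohort, outcomes, _ = pt.generate_cohort(cfg, specs)
        adm, _ = pt.build_analysis_datasets(cohort, outcomes)
        plans = pt.make_split_plans(adm.n, R=1, seed=1)
        boost = pt.BoostingConfig(
            n_rounds=30, early_stopping_rounds=None,
            monotone_constraints={"muac": 1},
        )
        ens = pt.fit_survival_ensemble(adm, None, plans, boost)
        grid = adm.features.iloc[[0] * 25].reset_index(drop=True)
        grid.index = [f"g{i}" for i in range(25)]
        grid["muac"] = np.linspace(-4, 4, 25)
        margins = pt.predict_risk(ens, grid).ensemble_mean.to_numpy()
        assert (np.diff(margins) >= -1e-9).all()

    def test_serialization_roundtrip(self, signal_fit, tmp_path):
        signal_fit.ensemble.save(tmp_path / "model")
        loaded = pt.EnsembleModel.load(tmp_path / "model")
        assert loaded.n_members == signal_fit.ensemble.n_members
        assert loaded.feature_names == signal_fit.ensemble.feature_names
        a = pt.predict_risk(loaded, signal_fit.dataset.features).ensemble_mean
        b = pt.predict_risk(signal_fit.ensemble, signal_fit.dataset.features).ensemble_mean
        assert np.allclose(a, b)


def test_margin_tracks_true_loghazard(default_run):
    """On the default planted cohort the ensemble-mean margin must rank
    children consistently with the true log-hazard (Spearman > 0.5)."""
    from scipy.stats import spearmanr

    run = default_run(0)
    scores = pt.predict_risk(run.ensemble, run.dataset.features)
    rho = spearmanr(
        scores.ensemble_mean.to_numpy(),
        run.truth.table.loc[run.dataset.features.index, "loghaz_admission"].to_numpy(),
    ).statistic
    assert rho > 0.5


def test_cox_label_encoding():
    t = np.array([3.0, 5.0])
    e = np.array([1, 0])
    assert np.array_equal(_cox_labels(t, e), np.array([3.0, -5.0]))
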