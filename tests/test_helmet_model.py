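import math

import numpy as np
import pytest
import xgboost as xgb
from hypothesis import given, strategies as st

from helmet.helmet_model import (
    HelmetHyperparams,
    ModelBundle,
    check_patient_disjoint,
    make_splits,
    make_weighted_objective,
    predict_proba,
    train_helmet,
    tune_w_and_params,
    weighted_xent,
)
from helmet.observation_builder import ImputerStats


def _onehot(y, k=4):
    return np.eye(k)[np.asarray(y, dtype=int)]


class TestWeightedXent:
    def test_w1_reduces_to_plain_cross_entropy(self, rng):
        p = rng.dirichlet(np.ones(4), 50)
        y = rng.integers(0, 4, 50)
        filt = rng.random(50) < 0.3
        loss, _, _ = weighted_xent(p, _onehot(y), filt, w=1.0)
        plain = -np.log(p[np.arange(50), y]).sum()
        assert loss == pytest.approx(plain)

    def test_perfect_prediction_has_zero_loss(self):
        y = np.array([0, 2, 3])
        loss, grad, _ = weighted_xent(_onehot(y), _onehot(y), np.ones(3, bool), w=0.5)
        assert loss == pytest.approx(0.0)
        assert np.allclose(grad, 0.0)

    def test_two_observation_half_weight_closed_form(self):
        # one filtered + one non-filtered observation, both with p_true = 0.5,
        # w = 0.5: L = ln2 + 0.5 ln2 = 1.5 ln2
        p = np.array([[0.5, 0.5, 0.0, 0.0], [0.5, 0.5, 0.0, 0.0]])
        y = _onehot([0, 0])
        loss, _, _ = weighted_xent(p, y, np.array([True, False]), w=0.5)
        assert loss == pytest.approx(1.5 * math.log(2))

    @given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_loss_is_affine_in_w(self, w1, w2):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), 30)
        y = rng.integers(0, 4, 30)
        filt = rng.random(30) < 0.4
        L = lambda w: weighted_xent(p, _onehot(y), filt, w)[0]
        # slope = cross-entropy of the non-filtered subset, independent of w
        slope_expected = -np.log(p[np.arange(30), y])[~filt].sum()
        if abs(w1 - w2) > 1e-9:
            slope = (L(w1) - L(w2)) / (w1 - w2)
            assert slope == pytest.approx(slope_expected, rel=1e-9)

    def test_all_filtered_equals_none_filtered_at_w1(self, rng):
        p = rng.dirichlet(np.ones(4), 20)
        y = _onehot(rng.integers(0, 4, 20))
        all_f = weighted_xent(p, y, np.ones(20, bool), 1.0)[0]
        none_f = weighted_xent(p, y, np.zeros(20, bool), 1.0)[0]
        assert all_f == pytest.approx(none_f)

    def test_zero_probability_at_truth_is_clipped(self):
        p = np.array([[0.0, 1.0, 0.0, 0.0]])
        loss, _, _ = weighted_xent(p, _onehot([0]), np.array([True]), 0.5)
        assert np.isfinite(loss)

    def test_invalid_w_rejected(self, rng):
        p = rng.dirichlet(np.ones(4), 3)
        with pytest.raises(ValueError):
            weighted_xent(p, _onehot([0, 1, 2]), np.zeros(3, bool), w=0.0)


class TestSplits:
    def test_100_patients_give_20_test(self):
        plan = make_splits([f"p{i}" for i in range(100)], seed=0)
        assert len(plan) == 5
        for train, test in plan:
            assert len(test) == 20 and len(train) == 80

    def test_same_seed_same_plan(self):
        ids = [f"p{i}" for i in range(37)]
        assert make_splits(ids, seed=5).splits == make_splits(ids, seed=5).splits

    def test_patient_disjointness(self):
        plan = make_splits([f"p{i}" for i in range(50)], seed=1)
        check_patient_disjoint(plan)  # must not raise
        for train, test in plan:
            assert not set(train) & set(test)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b"], seed=0)


def _toy_training_data(rng, n=400):
    """Feature 0 encodes the class; the rest is noise."""
    y = rng.integers(0, 4, n)
    X = rng.normal(size=(n, 5))
    X[:, 0] = y + rng.normal(0, 0.3, n)
    filt = rng.random(n) < 0.35
    return X, y, filt


class TestTraining:
    def test_w1_training_equals_builtin_softprob(self, rng):
        """Dual-route check: at w = 1 the custom objective must reproduce the
        library's standard multiclass log-loss training exactly."""
        X, y, filt = _toy_training_data(rng)
        hp = HelmetHyperparams(w=1.0, n_rounds=30, seed=7)
        booster = train_helmet(X, y, filt, hp)
        p_custom = predict_proba(booster, X)

        dtrain = xgb.DMatrix(X, label=y.astype(float), nthread=1)
        builtin = xgb.train(
            {"objective": "multi:softprob", "num_class": 4, "tree_method": "hist",
             "max_depth": hp.max_depth, "eta": hp.learning_rate,
             "subsample": hp.subsample, "colsample_bytree": hp.colsample_bytree,
             "lambda": hp.reg_lambda, "seed": hp.seed, "nthread": 1, "base_score": 0.5},
            dtrain, num_boost_round=hp.n_rounds,
        )
        assert np.allclose(p_custom, builtin.predict(dtrain), atol=1e-5)

    def test_weighted_training_equals_builtin_with_sample_weights(self, rng):
        """The transition-weighted objective is softprob with weights u_i."""
        X, y, filt = _toy_training_data(rng)
        w = 0.4
        hp = HelmetHyperparams(w=w, n_rounds=25, seed=3)
        p_custom = predict_proba(train_helmet(X, y, filt, hp), X)

        u = np.where(filt, 1.0, w)
        dtrain = xgb.DMatrix(X, label=y.astype(float), weight=u, nthread=1)
        builtin = xgb.train(
            {"objective": "multi:softprob", "num_class": 4, "tree_method": "hist",
             "max_depth": hp.max_depth, "eta": hp.learning_rate,
             "subsample": hp.subsample, "colsample_bytree": hp.colsample_bytree,
             "lambda": hp.reg_lambda, "seed": hp.seed, "nthread": 1, "base_score": 0.5},
            dtrain, num_boost_round=hp.n_rounds,
        )
        assert np.allclose(p_custom, builtin.predict(dtrain), atol=1e-5)

    def test_training_loss_decreases_with_rounds(self, rng):
        X, y, filt = _toy_training_data(rng)
        losses = []
        for rounds in (5, 40):
            hp = HelmetHyperparams(w=0.5, n_rounds=rounds, seed=0, subsample=1.0)
            p = predict_proba(train_helmet(X, y, filt, hp), X)
            losses.append(weighted_xent(p, np.eye(4)[y], filt, 0.5)[0])
        assert losses[1] < losses[0]

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        with pytest.raises(ValueError):
            train_helmet(X, np.ones(30, int), np.zeros(30, bool), HelmetHyperparams())

    def test_predictions_on_simplex_and_deterministic(self, rng):
        X, y, filt = _toy_training_data(rng)
        hp = HelmetHyperparams(n_rounds=20, seed=1)
        b1 = train_helmet(X, y, filt, hp)
        b2 = train_helmet(X, y, filt, hp)
        p1, p2 = predict_proba(b1, X), predict_proba(b2, X)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(p1, p2)
        # identical observations -> identical rows
        X2 = np.vstack([X[0], X[0]])
        assert np.array_equal(*predict_proba(b1, X2))

    def test_decreasing_w_shifts_loss_mass_to_transitions(self, rng):
        X, y, filt = _toy_training_data(rng)
        shares = []
        for w in (1.0, 0.2):
            hp = HelmetHyperparams(w=w, n_rounds=40, seed=0)
            p = predict_proba(train_helmet(X, y, filt, hp), X)
            ce = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, 1))
            total = ce[filt].sum() + w * ce[~filt].sum()
            shares.append(ce[filt].sum() / total)
        assert shares[1] >= shares[0]


class TestBundle:
    def test_save_load_round_trip(self, rng, tmp_path):
        X, y, filt = _toy_training_data(rng, n=200)
        hp = HelmetHyperparams(n_rounds=10, seed=0)
        names = [f"f{i}" for i in range(5)]
        booster = train_helmet(X, y, filt, hp, feature_names=names)
        bundle = ModelBundle(
            booster=booster, feature_names=names,
            categories={n: "static" for n in names},
            imputer=ImputerStats(means={n: 0.0 for n in names}),
            hyperparams=hp,
        )
        bundle.save(tmp_path / "m")
        loaded = ModelBundle.load(tmp_path / "m")
        assert loaded.feature_names == names
        assert loaded.hyperparams == hp
        assert np.allclose(predict_proba(loaded, X), predict_proba(bundle, X))

    def test_schema_mismatch_rejected(self, rng, tmp_path):
        X, y, filt = _toy_training_data(rng, n=100)
        hp = HelmetHyperparams(n_rounds=5, seed=0)
        names = [f"f{i}" for i in range(5)]
        bundle = ModelBundle(
            booster=train_helmet(X, y, filt, hp, feature_names=names),
            feature_names=names, categories={}, imputer=ImputerStats(means={}),
            hyperparams=hp,
        )
        with pytest.raises(ValueError):
            predict_proba(bundle, X[:, :3])


class TestTuning:
    def test_budget_one_returns_single_candidate(self, rng):
        X, y, filt = _toy_training_data(rng, n=200)
        pids = [f"p{i % 20}" for i in range(200)]
        space = {"n_rounds": (5, 10), "max_depth": (2, 3)}
        hp, trace = tune_w_and_params(X, y, filt, pids, budget=1, seed=0, space=space)
        assert len(trace) == 1
        assert trace["objective"].iloc[0] == trace["objective"].max()

    def test_returns_objective_maximizer_and_is_deterministic(self, rng):
        X, y, filt = _toy_training_data(rng, n=200)
        pids = [f"p{i % 20}" for i in range(200)]
        space = {"n_rounds": (5, 15), "max_depth": (2, 4)}
        hp1, tr1 = tune_w_and_params(X, y, filt, pids, budget=3, seed=4, space=space)
        hp2, tr2 = tune_w_and_params(X, y, filt, pids, budget=3, seed=4, space=space)
        assert hp1 == hp2
        assert np.allclose(tr1["objective"], tr2["objective"])
        best_row = tr1.loc[tr1["objective"].idxmax()]
        assert hp1.n_rounds == int(best_row["n_rounds"])
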