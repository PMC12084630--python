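"""Transition-weighted gradient-boosted multiclass MLS prediction.

The training loss is a weighted categorical cross-entropy

.. math::

    L(y, p) = -\\sum_{i \\in F} \\sum_c y_{ic} \\log p_{ic}
              - w \\sum_{i \\in NF} \\sum_c y_{ic} \\log p_{ic},

where :math:`F` is the set of *filtered* observations (target class differs
from the current class), :math:`NF` its complement, and :math:`w \\in (0, 1]`
down-weights non-transitions.  Equivalently each observation carries weight
``u_i = 1`` if filtered else ``w``, so the objective plugs into gradient
boosting as a weighted softmax: gradient ``u_i (p_ic − y_ic)`` and diagonal
curvature ``u_i · max(2 p_ic (1 − p_ic), ε)`` on the class margins (the
boosted-softmax convention; at ``w = 1`` training is exactly standard
multiclass log-loss).

Splits are always at the patient level: all of a patient's observations land
on one side, so no information leaks between train and test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .data_model import N_CLASSES
from .observation_builder import FeatureSchema, ImputerStats
from .evaluation import weighted_ovr_curves

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-12  # floor inside log terms; the loss is never -inf
HESS_EPS = 1e-16


@dataclass
class HelmetHyperparams:
    """Boosting and loss hyperparameters.

    ``w`` is the non-transition loss weight (1 = plain cross-entropy);
    the default 0.5 is a neutral pre-tuning choice, replaced by
    :func:`tune_w_and_params` in tuned runs.
    """

    w: float = 0.5
    n_rounds: int = 150
    max_depth: int = 4
    learning_rate: float = 0.1
    subsample: float = 0.9
    colsample_bytree: float = 0.9
    reg_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.w <= 1):
            raise ValueError("w must lie in (0, 1]")
        if self.n_rounds <= 0 or self.max_depth <= 0:
            raise ValueError("boosting counts must be positive")


def _softmax(margins: np.ndarray) -> np.ndarray:
    z = margins - margins.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_xent(
    p: np.ndarray,
    y_onehot: np.ndarray,
    filtered: np.ndarray,
    w: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Transition-weighted cross-entropy value, gradient and curvature.

    Returns ``(loss, grad, hess)`` where gradient/curvature are with respect
    to softmax class margins: ``grad = u (p − y)`` and
    ``hess = u · max(2 p (1 − p), ε)`` with ``u_i = 1`` if filtered else
    ``w``.  Probabilities are clipped at 1e-12 inside the log.
    """
    if not (0 < w <= 1):
        raise ValueError("w must lie in (0, 1]")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y_onehot, dtype=float)
    u = np.where(np.asarray(filtered, dtype=bool), 1.0, w)
    logp = np.log(np.clip(p, PROB_CLIP, 1.0))
    loss = float(-(u[:, None] * y * logp).sum())
    grad = u[:, None] * (p - y)
    hess = u[:, None] * np.maximum(2.0 * p * (1.0 - p), HESS_EPS)
    return loss, grad, hess


def make_weighted_objective(filtered: np.ndarray, w: float):
    """XGBoost custom objective closure implementing the weighted softmax."""
    filtered = np.asarray(filtered, dtype=bool)

    def objective(preds: np.ndarray, dtrain: xgb.DMatrix):
        labels = dtrain.get_label().astype(int)
        margins = preds.reshape(labels.size, N_CLASSES)
        p = _softmax(margins)
        y = np.eye(N_CLASSES)[labels]
        _, grad, hess = weighted_xent(p, y, filtered, w)
        return grad, hess

    return objective


@dataclass
class SplitPlan:
    """Five independent seeded 80/20 patient-level partitions."""

    splits: list[tuple[list[str], list[str]]]
    seed: int

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def make_splits(
    patient_ids: Sequence[str],
    seed: int,
    n_splits: int = 5,
    test_size: float = 0.2,
    bootstrap: bool = False,
) -> SplitPlan:
    """Patient-level train/test partitions (80/20 by default).

    With ``bootstrap=True`` the training side is additionally resampled with
    replacement (off by default; partitions stay disjoint either way in terms
    of the patients evaluated).
    """
    ids = [str(p) for p in patient_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < n_splits:
        raise ValueError(f"need at least {n_splits} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_size * len(ids))))
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(len(ids))
        test = [ids[i] for i in perm[:n_test]]
        train = [ids[i] for i in perm[n_test:]]
        if bootstrap:
            train = [train[i] for i in rng.integers(0, len(train), len(train))]
        splits.append((train, test))
    return SplitPlan(splits=splits, seed=seed)


@dataclass
class ModelBundle:
    """A trained model plus everything needed to apply it to new records."""

    booster: xgb.Booster
    feature_names: list[str]
    categories: dict[str, str]
    imputer: ImputerStats
    hyperparams: HelmetHyperparams
    split_id: int = 0
    model_type: str = "helmet"

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(directory / "model.json"))
        meta = {
            "model_type": self.model_type,
            "split_id": self.split_id,
            "feature_names": self.feature_names,
            "categories": self.categories,
            "imputer_means": self.imputer.means,
            "hyperparams": asdict(self.hyperparams),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(directory / "model.json"))
        return cls(
            booster=booster,
            feature_names=meta["feature_names"],
            categories=meta["categories"],
            imputer=ImputerStats(means=meta["imputer_means"]),
            hyperparams=HelmetHyperparams(**meta["hyperparams"]),
            split_id=meta["split_id"],
            model_type=meta["model_type"],
        )


def _xgb_params(hp: HelmetHyperparams) -> dict:
    return {
        "objective": "multi:softprob",  # declares output shape; custom obj overrides training
        "num_class": N_CLASSES,
        "tree_method": "hist",
        "max_depth": hp.max_depth,
        "eta": hp.learning_rate,
        "subsample": hp.subsample,
        "colsample_bytree": hp.colsample_bytree,
        "lambda": hp.reg_lambda,
        "seed": hp.seed,
        "nthread": 1,  # single-threaded histograms for reproducibility
        "base_score": 0.5,
        "disable_default_eval_metric": 1,
    }


def train_helmet(
    X: np.ndarray,
    y: np.ndarray,
    filtered: np.ndarray,
    hp: HelmetHyperparams,
    feature_names: Sequence[str] | None = None,
) -> xgb.Booster:
    """Fit the boosted ensemble under the transition-weighted objective."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two target classes")
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise ValueError("feature matrix width does not match the schema")
    # observation weights also steer the weighted quantile sketch, keeping
    # histogram bins consistent with the loss weighting
    u = np.where(np.asarray(filtered, dtype=bool), 1.0, hp.w)
    dtrain = xgb.DMatrix(
        np.asarray(X, dtype=float),
        label=y.astype(float),
        weight=u,
        feature_names=list(feature_names) if feature_names is not None else None,
        nthread=1,
    )
    booster = xgb.train(
        _xgb_params(hp),
        dtrain,
        num_boost_round=hp.n_rounds,
        obj=make_weighted_objective(filtered, hp.w),
    )
    return booster


def predict_proba(
    booster_or_bundle: xgb.Booster | ModelBundle, X: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Class-probability matrix (rows on the simplex; argmax ties break low)."""
    if isinstance(booster_or_bundle, ModelBundle):
        bundle = booster_or_bundle
        booster = bundle.booster
        feature_names = bundle.feature_names
        if X.shape[1] != len(feature_names):
            raise ValueError("feature matrix width does not match the bundle schema")
    else:
        booster = booster_or_bundle
    dmat = xgb.DMatrix(
        np.asarray(X, dtype=float),
        feature_names=list(feature_names) if feature_names is not None else None,
        nthread=1,
    )
    margins = booster.predict(dmat, output_margin=True)
    return _softmax(margins.reshape(-1, N_CLASSES))


def tune_w_and_params(
    X: np.ndarray,
    y: np.ndarray,
    filtered: np.ndarray,
    patient_of_obs: Sequence[str],
    budget: int = 10,
    seed: int = 0,
    space: dict | None = None,
) -> tuple[HelmetHyperparams, pd.DataFrame]:
    """Seeded random search maximizing inner-validation *filtered* AUROC.

    A patient-level 80/20 inner split is carved out of the supplied training
    data; each sampled candidate is trained on the inner-train side and
    scored on the inner-validation transition subset.  Falls back to overall
    AUROC (with a warning) if that subset has fewer than two classes.
    Returns the winning hyperparameters and the full search trace.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    pids = np.asarray([str(p) for p in patient_of_obs])
    unique = np.unique(pids)
    perm = rng.permutation(unique.size)
    n_val = max(1, int(round(0.2 * unique.size)))
    val_ids = set(unique[perm[:n_val]])
    val_mask = np.isin(pids, list(val_ids))

    default_space = {
        "w": (0.05, 1.0),
        "max_depth": (3, 7),
        "learning_rate": (0.03, 0.3),
        "n_rounds": (60, 250),
        "subsample": (0.6, 1.0),
        "colsample_bytree": (0.6, 1.0),
    }
    space = {**default_space, **(space or {})}

    trace_rows = []
    best: tuple[float, HelmetHyperparams] | None = None
    for k in range(budget):
        hp = HelmetHyperparams(
            w=float(rng.uniform(*space["w"])),
            max_depth=int(rng.integers(space["max_depth"][0], space["max_depth"][1] + 1)),
            learning_rate=float(rng.uniform(*space["learning_rate"])),
            n_rounds=int(rng.integers(space["n_rounds"][0], space["n_rounds"][1] + 1)),
            subsample=float(rng.uniform(*space["subsample"])),
            colsample_bytree=float(rng.uniform(*space["colsample_bytree"])),
            seed=seed,
        )
        booster = train_helmet(X[~val_mask], y[~val_mask], filtered[~val_mask], hp)
        p_val = predict_proba(booster, X[val_mask])
        f_mask = np.asarray(filtered, dtype=bool)[val_mask]
        score_set = "filtered"
        try:
            score = weighted_ovr_curves(p_val[f_mask], y[val_mask][f_mask]).auroc
        except ValueError:
            logger.warning("inner filtered set degenerate; falling back to overall AUROC")
            score_set = "overall"
            score = weighted_ovr_curves(p_val, y[val_mask]).auroc
        trace_rows.append({**asdict(hp), "objective": score, "objective_set": score_set})
        if best is None or score > best[0]:
            best = (score, hp)
    trace = pd.DataFrame(trace_rows)
    assert best is not None
    return best[1], trace


def check_patient_disjoint(plan: SplitPlan) -> None:
    """Raise if any split shares a patient between train and test sides."""
    for i, (train, test) in enumerate(plan):
        overlap = set(train) & set(test)
        if overlap:
            raise ValueError(f"split {i}: patients on both sides: {sorted(overlap)[:5]}")
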