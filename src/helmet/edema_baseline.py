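"""EDEMA-style multinomial-regression comparator.

A retrained multinomial logistic model on the classic malignant-edema risk
inputs — not the published score's original coefficients.  Exactly eight
features per observation:

static: admission blood glucose, admission HbA1c, history of previous
stroke, mechanical thrombectomy at any point, thrombolysis (tPA) at any
point (the "any point" flags are deliberately static: the event anywhere in
the stay sets the flag for every hour);

dynamic (forward-filled): most recent blood glucose, basal cistern
effacement on the most recent scan, MLS on the most recent scan.

The baseline is always trained and evaluated on the same patient-level
splits as the boosted model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_model import PatientRecord, TimedValue
from .observation_builder import FFILL_SUFFIX, forward_fill

EDEMA_STATIC = ["admission_glucose", "admission_hba1c", "prior_stroke"]
EDEMA_TREATMENT = ["thrombectomy_any", "thrombolysis_any"]
EDEMA_DYNAMIC = [
    "glucose" + FFILL_SUFFIX,
    "basal_cistern_effacement" + FFILL_SUFFIX,
    "mls_mm" + FFILL_SUFFIX,
]
EDEMA_FEATURES = EDEMA_STATIC + EDEMA_TREATMENT + EDEMA_DYNAMIC


def treatment_flags(record: PatientRecord) -> dict[str, float]:
    kinds = {t.kind for t in record.treatments}
    return {
        "thrombectomy_any": float("thrombectomy" in kinds),
        "thrombolysis_any": float("thrombolysis_tpa" in kinds),
    }


def build_edema_features(
    record: PatientRecord, hour: int, static_means: Mapping[str, float] | None = None
) -> np.ndarray:
    """The 8-feature vector for one patient-hour (NaN-imputed from means)."""
    feats: dict[str, float] = {}
    for name in EDEMA_STATIC:
        val = record.static.features.get(name)
        feats[name] = np.nan if val is None else float(val)
    feats.update(treatment_flags(record))

    glu = [tv for tv in record.series if tv.variable == "glucose"]
    feats["glucose" + FFILL_SUFFIX] = float(forward_fill(glu, [hour])[0])
    cist = [
        TimedValue("basal_cistern_effacement", sc.hour, float(sc.basal_cistern_effacement))
        for sc in record.scans
        if sc.basal_cistern_effacement is not None
    ]
    feats["basal_cistern_effacement" + FFILL_SUFFIX] = float(forward_fill(cist, [hour])[0])
    mls = [TimedValue("mls_mm", sc.hour, sc.mls_mm) for sc in record.scans]
    feats["mls_mm" + FFILL_SUFFIX] = float(forward_fill(mls, [hour])[0])

    vec = np.array([feats[name] for name in EDEMA_FEATURES], dtype=float)
    if static_means is not None:
        for i, name in enumerate(EDEMA_FEATURES):
            if np.isnan(vec[i]) and name in static_means:
                vec[i] = static_means[name]
    return vec


def edema_feature_frame(
    observations: pd.DataFrame, records: Sequence[PatientRecord] | Mapping[str, PatientRecord]
) -> pd.DataFrame:
    """Vectorized EDEMA features for every row of an observation table.

    Expects the observation table to already carry the forward-filled
    ``glucose__last`` / ``basal_cistern_effacement__last`` / ``mls_mm__last``
    columns and the three static inputs (imputed upstream); only the two
    "any point" treatment flags are added here.
    """
    if not isinstance(records, Mapping):
        records = {r.patient_id: r for r in records}
    needed = EDEMA_STATIC + EDEMA_DYNAMIC
    missing = [c for c in needed if c not in observations.columns]
    if missing:
        raise KeyError(f"observation table lacks EDEMA inputs: {missing}")
    out = observations[["patient_id", "hour"]].copy()
    for c in needed:
        out[c] = observations[c].to_numpy()
    flags = {pid: treatment_flags(rec) for pid, rec in records.items()}
    pid_arr = observations["patient_id"].astype(str)
    out["thrombectomy_any"] = pid_arr.map(lambda p: flags[p]["thrombectomy_any"]).to_numpy()
    out["thrombolysis_any"] = pid_arr.map(lambda p: flags[p]["thrombolysis_any"]).to_numpy()
    return out[["patient_id", "hour", *EDEMA_FEATURES]]


@dataclass
class EdemaModel:
    """Ridge-regularized multinomial logistic baseline (4-class, simplex output).

    Inputs are mean-imputed and standardized with training-split statistics
    before the linear model.
    """

    model: LogisticRegression
    feature_names: list[str]
    means: dict[str, float]
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(np.asarray(X, dtype=float))
        raw = self.model.predict_proba(X)
        out = np.zeros((X.shape[0], 4))
        for j, c in enumerate(self.model.classes_):
            out[:, int(c)] = raw[:, j]
        return out

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        for i, name in enumerate(self.feature_names):
            col = X[:, i]
            col[np.isnan(col)] = self.means[name]
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_sd
        return X


def train_edema(X: np.ndarray, y: np.ndarray, seed: int = 0, C: float = 1.0) -> EdemaModel:
    """Fit the multinomial baseline (deterministic: lbfgs, fixed seed)."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("baseline training needs at least two target classes")
    X = np.asarray(X, dtype=float)
    means = {
        name: float(np.nanmean(X[:, i])) for i, name in enumerate(EDEMA_FEATURES)
    }
    model = EdemaModel(
        model=LogisticRegression(
            C=C, max_iter=2000, solver="lbfgs", random_state=seed
        ),
        feature_names=list(EDEMA_FEATURES),
        means=means,
    )
    Xi = model._prepare(X)
    model.scale_mean = Xi.mean(axis=0)
    model.scale_sd = np.where(Xi.std(axis=0) > 0, Xi.std(axis=0), 1.0)
    model.model.fit(model._prepare(X), y)
    return model
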