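"""Shapley feature attribution and category composition of the top features.

Attributions come from exact tree-path-dependent TreeSHAP on the boosted
ensemble, per observation, per feature, per class, on the margin scale;
local accuracy holds: bias + sum of attributions = class margin.

For reporting, per-class values are aggregated as the mean absolute
attribution over observations summed over the four classes.  The top-k
features (k = 20) are then decomposed into the share contributed by each
feature category — report-text probabilities, human-extracted radiographic
features, dynamic medical-record variables, static characteristics —
stratified by the patient's current (most recent prior) MLS class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xgboost as xgb

from .data_model import CATEGORIES, N_CLASSES
from .helmet_model import ModelBundle


def shapley_values(bundle: ModelBundle, X: np.ndarray) -> np.ndarray:
    """Exact TreeSHAP attributions, shape ``(n_obs, n_class, n_feat + 1)``.

    The trailing column is the per-class bias (expected margin); rows satisfy
    ``margin[i, c] = contribs[i, c].sum()``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(bundle.feature_names):
        raise ValueError("feature matrix width does not match the bundle schema")
    dmat = xgb.DMatrix(X, feature_names=bundle.feature_names, nthread=1)
    contribs = bundle.booster.predict(dmat, pred_contribs=True)
    return contribs.reshape(X.shape[0], N_CLASSES, X.shape[1] + 1)


def aggregate_importance(contribs: np.ndarray, feature_names: list[str]) -> pd.Series:
    """Mean |attribution| over observations, summed over classes, per feature."""
    per_feat = np.abs(contribs[:, :, :-1]).mean(axis=0).sum(axis=0)
    return pd.Series(per_feat, index=feature_names).sort_values(ascending=False)


def rank_and_compose(
    contribs: np.ndarray,
    feature_names: list[str],
    categories: dict[str, str],
    current_class: np.ndarray | None = None,
    top_k: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked feature list and per-stratum category composition of the top-k.

    Returns ``(ranking, composition)``: the ranking has one row per feature
    and stratum (score = mean |SHAP| summed over classes within the stratum);
    the composition gives, per stratum, the share of top-k importance mass in
    each category (shares sum to 1).
    """
    missing = [f for f in feature_names if f not in categories]
    if missing:
        raise KeyError(f"features without a category tag: {missing[:5]}")
    n = contribs.shape[0]
    if top_k > len(feature_names):
        import warnings

        warnings.warn("top_k exceeds feature count; using all features")
        top_k = len(feature_names)
    if current_class is None:
        strata = {"all": np.ones(n, dtype=bool)}
    else:
        cur = np.asarray(current_class, dtype=int)
        strata = {f"class{c}": cur == c for c in np.unique(cur)}

    rank_rows, comp_rows = [], []
    for stratum, mask in strata.items():
        if not mask.any():
            continue
        scores = aggregate_importance(contribs[mask], feature_names)
        for r, (feat, score) in enumerate(scores.items(), start=1):
            rank_rows.append(
                dict(stratum=stratum, feature=feat, category=categories[feat],
                     score=float(score), rank=r)
            )
        top = scores.iloc[:top_k]
        total = float(top.sum())
        for cat in CATEGORIES:
            mass = float(sum(s for f, s in top.items() if categories[f] == cat))
            comp_rows.append(
                dict(stratum=stratum, category=cat,
                     proportion=mass / total if total > 0 else 0.0)
            )
    return pd.DataFrame(rank_rows), pd.DataFrame(comp_rows)


def plot_composition(composition: pd.DataFrame, path: str) -> None:
    """Stacked bar chart: top-feature category share per current-class stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = composition.pivot(index="stratum", columns="category", values="proportion")
    pivot = pivot.reindex(columns=list(CATEGORIES))
    ax = pivot.plot(kind="bar", stacked=True, figsize=(6, 4), width=0.7)
    ax.set_ylabel("share of top-feature importance")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
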