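"""End-to-end pipeline: simulate → observations → targets → models → metrics.

Every run is driven by one declarative config dict (YAML on disk via the
CLI) and a single integer seed; artifacts land in a directory tree whose
``run.json`` records the config hash, so re-running with a changed config
refuses to overwrite without ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation, importance
from .data_model import PatientRecord, read_cohort, validate_patient, write_cohort
from .edema_baseline import EDEMA_FEATURES, edema_feature_frame, train_edema
from .helmet_model import (
    HelmetHyperparams,
    ModelBundle,
    check_patient_disjoint,
    make_splits,
    predict_proba,
    train_helmet,
    tune_w_and_params,
)
from .observation_builder import (
    FeatureSchema,
    ImputerStats,
    build_observation_table,
)
from .synthetic_cohort import SimConfig, simulate_cohort
from .target_builder import add_targets, binarize_5mm

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "task": 24,                 # prediction horizon in hours (8 or 24)
    "n_patients": 100,
    "profile": "derivation",
    "sim": {},                  # SimConfig overrides
    "hyperparams": {},          # HelmetHyperparams overrides
    "tune": False,
    "tune_budget": 8,
    "n_splits": 5,
    "modes": ["overall", "filtered"],
    "binary_5mm": False,
    "top_k": 20,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _merge_config(config: Mapping | None) -> dict:
    merged = {**DEFAULT_CONFIG, **(config or {})}
    if merged["task"] not in (8, 24):
        raise ValueError(f"task horizon must be 8 or 24, got {merged['task']}")
    return merged


def prepare_data(
    config: dict, seed: int, records: Sequence[PatientRecord] | None = None
) -> tuple[list[PatientRecord], pd.DataFrame, FeatureSchema]:
    """Cohort plus un-imputed observation table with targets attached."""
    schema = FeatureSchema()
    if records is None:
        sim = SimConfig.for_profile(
            config["profile"],
            n_patients=config["n_patients"],
            seed=seed,
            **config["sim"],
        )
        records = simulate_cohort(sim)
    bad = {r.patient_id: v for r in records if (v := validate_patient(r))}
    if bad:
        raise ValueError(f"invalid records: {bad}")
    obs = build_observation_table(records, schema)
    obs = add_targets(obs, records, config["task"])
    return list(records), obs, schema


def fit_and_eval_split(
    records: Sequence[PatientRecord],
    obs: pd.DataFrame,
    schema: FeatureSchema,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    config: dict,
    seed: int,
    split_id: int,
) -> dict:
    """Train HELMET and the EDEMA baseline on one split; evaluate both."""
    features = schema.feature_names()
    valid = obs[obs["valid"]].reset_index(drop=True)
    train = valid[valid["patient_id"].isin(set(train_ids))]
    test = valid[valid["patient_id"].isin(set(test_ids))]

    imputer = ImputerStats.fit(obs, schema, train_ids)
    train_i, test_i = imputer.transform(train), imputer.transform(test)

    hp_kwargs = {**config["hyperparams"], "seed": seed}
    X_tr = train_i[features].to_numpy(dtype=float)
    y_tr = train_i["target_class"].to_numpy(dtype=int)
    f_tr = train_i["filtered"].to_numpy(dtype=bool)
    if config["tune"]:
        hp, _ = tune_w_and_params(
            X_tr, y_tr, f_tr,
            train_i["patient_id"].tolist(),
            budget=config["tune_budget"], seed=seed,
        )
        hp.seed = seed
    else:
        hp = HelmetHyperparams(**hp_kwargs)
    booster = train_helmet(X_tr, y_tr, f_tr, hp, feature_names=features)
    bundle = ModelBundle(
        booster=booster,
        feature_names=features,
        categories=schema.categories(),
        imputer=imputer,
        hyperparams=hp,
        split_id=split_id,
    )

    X_te = test_i[features].to_numpy(dtype=float)
    y_te = test_i["target_class"].to_numpy(dtype=int)
    cur_te = test_i["current_class"].to_numpy(dtype=int)
    p_helmet = predict_proba(bundle, X_te)

    recmap = {r.patient_id: r for r in records}
    ed_tr = edema_feature_frame(train_i, recmap)[EDEMA_FEATURES].to_numpy(dtype=float)
    ed_te = edema_feature_frame(test_i, recmap)[EDEMA_FEATURES].to_numpy(dtype=float)
    edema = train_edema(ed_tr, y_tr, seed=seed)
    p_edema = edema.predict_proba(ed_te)

    out = {"bundle": bundle, "test": test_i, "edema": edema}
    for model, p in (("helmet", p_helmet), ("edema", p_edema)):
        for mode in config["modes"]:
            out[(model, mode)] = evaluation.evaluate(p, y_te, cur_te, mode=mode)
    if config["binary_5mm"]:
        out.update(_binary_5mm_split(train_i, test_i, features, hp, config))
    return out


def _binary_5mm_split(train_i, test_i, features, hp, config) -> dict:
    """Sensitivity analysis: retrain on the binary >5 mm window-max target."""
    yb_tr = binarize_5mm(train_i["target_mls_mm"].to_numpy())
    yb_te = binarize_5mm(test_i["target_mls_mm"].to_numpy())
    cur_tr = (train_i["mls_mm__last"].to_numpy(dtype=float) > 5.0).astype(int)
    cur_te = (test_i["mls_mm__last"].to_numpy(dtype=float) > 5.0).astype(int)
    if np.unique(yb_tr).size < 2:
        logger.warning("binary 5 mm target degenerate on this split; skipped")
        return {}
    booster = train_helmet(
        train_i[features].to_numpy(dtype=float), yb_tr,
        (yb_tr != cur_tr), hp, feature_names=features,
    )
    p = predict_proba(booster, test_i[features].to_numpy(dtype=float), feature_names=features)
    res = {}
    for mode in config["modes"]:
        res[("helmet_binary5mm", mode)] = evaluation.evaluate(
            p, yb_te, cur_te, mode=mode
        )
    return res


def run_pipeline(
    config: Mapping | None,
    seed: int,
    outdir: str | Path,
    records: Sequence[PatientRecord] | None = None,
    force: bool = False,
) -> pd.DataFrame:
    """Run the full pipeline; return the metrics summary table.

    Artifacts written under ``outdir``: cohort CSVs, the observation table,
    per-split models, ``metrics.csv``, ``importance.csv`` (+ composition
    plot) and ``run.json`` with the config hash and seed.
    """
    config = _merge_config(config)
    outdir = Path(outdir)
    chash = config_hash({**config, "seed": seed})
    run_file = outdir / "run.json"
    if run_file.exists():
        prev = json.loads(run_file.read_text())
        if prev.get("config_hash") != chash and not force:
            raise FileExistsError(
                f"{outdir} holds artifacts from a different config "
                f"({prev.get('config_hash')} != {chash}); pass force=True to overwrite"
            )
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - halt with stage name and cause
            raise PipelineError(name, exc) from exc

    records, obs, schema = stage("prepare-data", prepare_data, config, seed, records)
    stage("write-cohort", write_cohort, records, outdir / "cohort")
    obs.to_csv(outdir / "observations.csv", index=False)
    (outdir / "observations.meta.json").write_text(
        json.dumps({"categories": schema.categories(), "task": config["task"]}, indent=1)
    )

    plan = stage(
        "make-splits", make_splits,
        [r.patient_id for r in records], seed, n_splits=config["n_splits"],
    )
    check_patient_disjoint(plan)

    models = ["helmet", "edema"] + (["helmet_binary5mm"] if config["binary_5mm"] else [])
    per_model: dict[str, dict[str, list]] = {
        m: {mode: [] for mode in config["modes"]} for m in models
    }
    last = None
    for k, (train_ids, test_ids) in enumerate(plan):
        res = stage(
            f"split-{k}", fit_and_eval_split,
            records, obs, schema, train_ids, test_ids, config, seed, k,
        )
        for m in models:
            for mode in config["modes"]:
                if (m, mode) in res:
                    per_model[m][mode].append(res[(m, mode)])
        res["bundle"].save(outdir / "models" / f"helmet_split{k}")
        last = res

    tables = []
    for m in models:
        filled = {mode: v for mode, v in per_model[m].items() if v}
        if not filled:
            continue
        report = evaluation.summarize_splits(filled)
        tables.append(evaluation.metrics_table(report, model=m, task=config["task"]))
    metrics = pd.concat(tables, ignore_index=True)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "metrics.meta.json").write_text(
        json.dumps({"config_hash": chash, "columns": list(metrics.columns)}, indent=1)
    )

    # feature attributions from the last split's model on its test set
    assert last is not None
    test_i = last["test"]
    X_te = test_i[schema.feature_names()].to_numpy(dtype=float)
    n_sample = min(len(test_i), 500)
    contribs = stage(
        "explain", importance.shapley_values, last["bundle"], X_te[:n_sample]
    )
    ranking, composition = importance.rank_and_compose(
        contribs,
        schema.feature_names(),
        schema.categories(),
        current_class=test_i["current_class"].to_numpy()[:n_sample],
        top_k=config["top_k"],
    )
    ranking.to_csv(outdir / "importance.csv", index=False)
    composition.to_csv(outdir / "importance_composition.csv", index=False)
    try:
        importance.plot_composition(composition, str(outdir / "importance_composition.png"))
        summary = metrics.drop_duplicates(["model", "mode", "metric"])
        evaluation.plot_metrics_radar(summary, str(outdir / "metrics_radar.png"))
    except Exception as exc:  # plotting is best-effort
        logger.warning("plot rendering failed: %s", exc)

    run_file.write_text(
        json.dumps({"config_hash": chash, "seed": seed, "config": config}, indent=1, default=str)
    )
    return metrics
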