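"""Hourly observation construction: grids, forward-fill, rolling max, imputation.

Each patient-hour on the grid becomes one observation row.  Every dynamic EHR
and radiographic variable contributes two derived features — the most recent
value (``__last``, forward-fill) and the maximum over the previous 24 h
(``__max24``) — plus one extra forward-filled feature carrying the MLS value
from the scan *before* the most recent one (patient trajectory).  With text
features enabled, 12 forward-filled report-probability columns are appended.

Feature-count identity (reference schema):
``33 static + 2*16 dynamic + 2*36 radiographic + 1 prior-MLS + 12 text = 150``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    PatientRecord,
    ReportProbabilities,
    TimedValue,
    mls_to_class,
)

logger = logging.getLogger(__name__)

FFILL_SUFFIX = "__last"
RMAX_SUFFIX = "__max24"
PRIOR_MLS_FEATURE = "prior_mls_mm" + FFILL_SUFFIX

#: Columns of the observation table that are bookkeeping, never model inputs.
META_COLUMNS = ("patient_id", "hour", "current_class")

TRUNCATION_H = 168  # seven days, measured from admission on the LSW axis
ROLLING_WINDOW_H = 24


class SchemaError(ValueError):
    """Feature schema and observation table disagree."""


# --------------------------------------------------------------------------
# Reference variable lists.  The exact clinical variable sets are
# site-configurable; these defaults carry the reference cardinalities
# (33 static, 16 dynamic EHR, 36 human-extracted radiographic).
# --------------------------------------------------------------------------

DEFAULT_STATIC = [
    "age", "sex_female", "nihss_admission", "aspects_admission",
    "prior_stroke", "atrial_fibrillation", "hypertension", "diabetes",
    "anticoagulant_use", "antiplatelet_use", "current_smoker",
    "admission_sbp", "admission_dbp", "admission_map", "admission_heart_rate",
    "admission_temperature", "admission_respiratory_rate", "admission_spo2",
    "admission_wbc", "admission_glucose", "admission_hba1c",
    "admission_sodium", "admission_potassium", "admission_creatinine",
    "admission_bun", "admission_osmolality", "admission_hemoglobin",
    "admission_platelets", "admission_inr", "left_hemisphere",
    "aca_involvement", "vessel_occlusion_grade", "admission_hour_of_day",
]

DEFAULT_DYNAMIC = [
    "heart_rate", "sbp", "dbp", "map", "temperature", "respiratory_rate",
    "spo2", "gcs", "wbc", "sodium", "glucose", "creatinine", "bun",
    "osmolality", "mannitol_dose", "hypertonic_saline_dose",
]

DEFAULT_RADIOGRAPHIC = [
    "mls_mm", "pineal_shift_mm", "basal_cistern_effacement",
    "sulcal_effacement", "ventricular_compression", "petechial_hemorrhage",
    "parenchymal_hemorrhage", "hemorrhagic_transformation",
    "infarct_volume_ml", "aspects_followup", "collateral_score",
    "cerebral_atrophy", "hydrocephalus", "uncal_herniation",
    "subfalcine_herniation", "mls_over_3mm", "mls_over_5mm", "mls_over_8mm",
    "hours_since_mls_over_3mm", "hours_since_mls_over_8mm", "pineal_over_2mm",
    "edema_extent_score", "gray_white_differentiation_loss",
    "insular_ribbon_loss", "hyperdense_mca_sign", "hemorrhage_volume_ml",
    "ventricle_ratio", "csf_volume_ml", "third_ventricle_shift_mm",
    "shift_ratio", "temporal_horn_dilation", "basal_ganglia_involvement",
    "cortical_involvement", "m1_territory_involvement",
    "m2_territory_involvement", "scan_quality_score",
]


@dataclass
class FeatureSchema:
    """Names of static, dynamic-EHR and radiographic variables plus the
    derived-feature naming rule and per-feature category tags."""

    static: list[str] = field(default_factory=lambda: list(DEFAULT_STATIC))
    dynamic: list[str] = field(default_factory=lambda: list(DEFAULT_DYNAMIC))
    radiographic: list[str] = field(default_factory=lambda: list(DEFAULT_RADIOGRAPHIC))
    include_text: bool = True

    def __post_init__(self) -> None:
        for group in (self.static, self.dynamic, self.radiographic):
            if len(set(group)) != len(group):
                raise SchemaError("duplicate variable names within a schema group")

    @staticmethod
    def derived(name: str) -> tuple[str, str]:
        return name + FFILL_SUFFIX, name + RMAX_SUFFIX

    def dynamic_features(self) -> list[str]:
        return [d for v in self.dynamic for d in self.derived(v)]

    def radiographic_features(self) -> list[str]:
        return [d for v in self.radiographic for d in self.derived(v)] + [PRIOR_MLS_FEATURE]

    def text_features(self) -> list[str]:
        return ReportProbabilities.feature_names() if self.include_text else []

    def feature_names(self) -> list[str]:
        return (
            list(self.static)
            + self.dynamic_features()
            + self.radiographic_features()
            + self.text_features()
        )

    def categories(self) -> dict[str, str]:
        cats = {f: "static" for f in self.static}
        cats.update({f: "dynamic_ehr" for f in self.dynamic_features()})
        cats.update({f: "human_radiographic" for f in self.radiographic_features()})
        cats.update({f: "llm_text" for f in self.text_features()})
        return cats


def build_hourly_grid(record: PatientRecord) -> list[int]:
    """Integer observation hours for one patient.

    Runs from ``ceil(admission_hour)`` to ``min(end_hour, admission + 168 h)``,
    stopping strictly before any decompressive hemicraniectomy (data after
    surgical decompression are omitted).
    """
    adm = record.static.admission_hour
    start = int(math.ceil(adm))
    last = min(math.floor(record.end_hour), math.floor(adm + TRUNCATION_H))
    dhc = record.hemicraniectomy_hour()
    if dhc is not None:
        last = min(last, int(math.ceil(dhc)) - 1)
    if last < start:
        return []
    return list(range(start, last + 1))


def forward_fill(series: Sequence[TimedValue], grid: Sequence[int]) -> np.ndarray:
    """Most recent raw value at or before each grid hour; NaN when none exists."""
    return _sweep(series, grid, mode="last")


def rolling_max_24h(series: Sequence[TimedValue], grid: Sequence[int]) -> np.ndarray:
    """Max raw value with event hour in ``(h − 24, h]``; NaN when the window is empty."""
    return _sweep(series, grid, mode="max24")


def _sweep(series: Sequence[TimedValue], grid: Sequence[int], mode: str) -> np.ndarray:
    hours = np.array([tv.hour for tv in series], dtype=float)
    values = np.array([tv.value for tv in series], dtype=float)
    if hours.size and np.any(np.diff(hours) < 0):
        order = np.argsort(hours, kind="stable")
        hours, values = hours[order], values[order]
    g = np.asarray(grid, dtype=float)
    out = np.full(g.shape, np.nan)
    if hours.size == 0:
        return out
    hi = np.searchsorted(hours, g, side="right")
    if mode == "last":
        mask = hi > 0
        out[mask] = values[hi[mask] - 1]
    else:
        lo = np.searchsorted(hours, g - ROLLING_WINDOW_H, side="right")
        for i, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                out[i] = values[a:b].max()
    return out


def _scan_series(record: PatientRecord, variable: str) -> list[TimedValue]:
    """Radiographic variables viewed as a timed series over scans."""
    out = []
    for sc in record.scans:
        if variable == "mls_mm":
            val: float | None = sc.mls_mm
        elif variable == "pineal_shift_mm":
            val = sc.pineal_shift_mm
        elif variable == "basal_cistern_effacement":
            val = sc.basal_cistern_effacement
        else:
            val = sc.radiographic.get(variable)
        if val is not None and not (isinstance(val, float) and math.isnan(val)):
            out.append(TimedValue(variable, sc.hour, float(val)))
    return out


def build_observations(
    record: PatientRecord,
    schema: FeatureSchema,
    report_probs: Mapping[float, ReportProbabilities] | None = None,
) -> pd.DataFrame:
    """One (un-imputed) observation row per grid hour with >= 1 prior scan.

    ``report_probs`` maps scan hour -> :class:`ReportProbabilities`; when
    omitted and the schema enables text features, probabilities attached to
    the scans themselves are used.
    """
    grid = build_hourly_grid(record)
    scan_hours = record.scan_hours()
    if not grid or scan_hours.size == 0:
        return pd.DataFrame(columns=[*META_COLUMNS, *schema.feature_names()])

    g = np.asarray(grid, dtype=float)
    n_prior = np.searchsorted(scan_hours, g, side="right")
    keep = n_prior > 0  # current MLS class must exist
    grid = [h for h, k in zip(grid, keep) if k]
    if not grid:
        return pd.DataFrame(columns=[*META_COLUMNS, *schema.feature_names()])
    n_prior = n_prior[keep]

    mls = record.scan_mls()
    current_class = np.array([mls_to_class(mls[i - 1]) for i in n_prior])

    data: dict[str, np.ndarray] = {
        "patient_id": np.repeat(record.patient_id, len(grid)),
        "hour": np.asarray(grid, dtype=int),
        "current_class": current_class,
    }
    for name in schema.static:
        val = record.static.features.get(name)
        data[name] = np.full(len(grid), np.nan if val is None else float(val))

    by_var: dict[str, list[TimedValue]] = {v: [] for v in schema.dynamic}
    for tv in record.series:
        if tv.variable in by_var:
            by_var[tv.variable].append(tv)
    for name in schema.dynamic:
        f_name, m_name = schema.derived(name)
        data[f_name] = forward_fill(by_var[name], grid)
        data[m_name] = rolling_max_24h(by_var[name], grid)

    for name in schema.radiographic:
        f_name, m_name = schema.derived(name)
        series = _scan_series(record, name)
        data[f_name] = forward_fill(series, grid)
        data[m_name] = rolling_max_24h(series, grid)

    # MLS from the scan before the most recent one, forward-filled
    prior = np.full(len(grid), np.nan)
    two_plus = n_prior >= 2
    prior[two_plus] = mls[n_prior[two_plus] - 2]
    data[PRIOR_MLS_FEATURE] = prior

    if schema.include_text:
        if report_probs is None:
            report_probs = {
                sc.hour: sc.report_probs
                for sc in record.scans
                if sc.report_probs is not None
            }
        prob_series = sorted(report_probs.items())
        p_hours = np.array([h for h, _ in prob_series], dtype=float)
        p_mat = (
            np.vstack([rp.flatten() for _, rp in prob_series])
            if prob_series
            else np.empty((0, 12))
        )
        idx = np.searchsorted(p_hours, np.asarray(grid, dtype=float), side="right")
        for j, col in enumerate(ReportProbabilities.feature_names()):
            vals = np.full(len(grid), np.nan)
            mask = idx > 0
            if p_hours.size:
                vals[mask] = p_mat[idx[mask] - 1, j]
            data[col] = vals

    frame = pd.DataFrame(data)
    expected = [*META_COLUMNS, *schema.feature_names()]
    if list(frame.columns) != expected:
        raise SchemaError("observation columns do not match the schema")
    return frame


def build_observation_table(
    records: Sequence[PatientRecord], schema: FeatureSchema
) -> pd.DataFrame:
    """Concatenated un-imputed observation rows for a whole cohort."""
    frames = [build_observations(r, schema) for r in records]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=[*META_COLUMNS, *schema.feature_names()])
    return pd.concat(frames, ignore_index=True)


@dataclass
class ImputerStats:
    """Training-split mean-imputation statistics.

    Static-feature means are computed over one row per training patient;
    means for derived (forward-fill / rolling-max / text) columns — a
    deliberate extension of mean imputation beyond statics — are computed
    over training observations and logged as such.
    """

    means: dict[str, float]

    @classmethod
    def fit(
        cls,
        observations: pd.DataFrame,
        schema: FeatureSchema,
        train_patients: Sequence[str] | None = None,
    ) -> "ImputerStats":
        obs = observations
        if train_patients is not None:
            obs = obs[obs["patient_id"].isin(set(map(str, train_patients)))]
        if not len(obs):
            raise ValueError("no training observations to fit the imputer on")
        means: dict[str, float] = {}
        per_patient = obs.groupby("patient_id", sort=False).first()
        for name in schema.static:
            means[name] = float(per_patient[name].mean())
        derived = [c for c in schema.feature_names() if c not in schema.static]
        logger.info("mean imputation extended to %d derived columns", len(derived))
        for name in derived:
            means[name] = float(obs[name].mean())
        missing = [n for n, m in means.items() if math.isnan(m)]
        if missing:
            raise ValueError(
                "features entirely missing in the training split: " + ", ".join(missing)
            )
        return cls(means=means)

    def transform(self, observations: pd.DataFrame) -> pd.DataFrame:
        out = observations.copy()
        for name, mean in self.means.items():
            if name in out.columns:
                out[name] = out[name].fillna(mean)
        return out


def fit_imputer(
    observations: pd.DataFrame,
    schema: FeatureSchema,
    train_patients: Sequence[str] | None = None,
) -> ImputerStats:
    """Convenience wrapper over :meth:`ImputerStats.fit` (training split only)."""
    return ImputerStats.fit(observations, schema, train_patients)
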