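"""Domain types for hourly midline-shift (MLS) severity prediction.

All times are real hours measured from the moment the patient was last seen
well (LSW); observation grids use integer hours on the same axis.  MLS in mm
is discretized into four ordinal severity classes::

    class 0  "0mm"    MLS == 0
    class 1  "0-3mm"  0 < MLS <= 3
    class 2  "3-8mm"  3 < MLS <= 8
    class 3  ">8mm"   MLS > 8

Boundary values belong to the lower class; the convention is recorded in
:data:`CLASS_EDGES_MM` so downstream code never hard-codes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Upper edges (inclusive) of classes 0..2; class 3 is unbounded above.
CLASS_EDGES_MM: tuple[float, float, float] = (0.0, 3.0, 8.0)

CLASS_LABELS: tuple[str, ...] = ("0mm", "0-3mm", "3-8mm", ">8mm")
N_CLASSES: int = 4

#: Horizons (hours) for which prediction targets may be built.  8 h and 24 h
#: are the clinical tasks; 36 h exists only to train report-text classifiers.
VALID_HORIZONS: tuple[int, ...] = (8, 24, 36)

#: Feature-category tags used for importance aggregation.
CATEGORIES: tuple[str, ...] = ("llm_text", "human_radiographic", "dynamic_ehr", "static")

#: Treatment vocabulary.  Hemicraniectomy censors all later data.
TREATMENT_KINDS: tuple[str, ...] = (
    "osmotic",
    "thrombolysis_tpa",
    "thrombectomy",
    "hemicraniectomy",
)

SIMPLEX_ATOL = 1e-9


class ValidationError(ValueError):
    """Raised for inputs that violate a domain-type invariant."""


def mls_to_class(mls_mm: float) -> int:
    """Map a midline-shift measurement in mm to its ordinal severity class.

    Parameters
    ----------
    mls_mm : float
        Non-negative, finite midline shift in millimetres.

    Returns
    -------
    int
        Class code in ``{0, 1, 2, 3}``; exact boundary values (3 mm, 8 mm)
        fall in the lower class.
    """
    if not math.isfinite(mls_mm) or mls_mm < 0:
        raise ValidationError(f"mls_mm must be finite and >= 0, got {mls_mm!r}")
    if mls_mm == 0:
        return 0
    if mls_mm <= CLASS_EDGES_MM[1]:
        return 1
    if mls_mm <= CLASS_EDGES_MM[2]:
        return 2
    return 3


def mls_to_class_array(mls_mm: np.ndarray) -> np.ndarray:
    """Vectorized :func:`mls_to_class`."""
    arr = np.asarray(mls_mm, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValidationError("mls_mm values must be finite and >= 0")
    out = np.ones(arr.shape, dtype=int)
    out[arr == 0] = 0
    out[arr > CLASS_EDGES_MM[1]] = 2
    out[arr > CLASS_EDGES_MM[2]] = 3
    return out


@dataclass(frozen=True)
class ReportProbabilities:
    """Per-scan class-probability features from a radiology report.

    One probability 4-vector per horizon (8 h, 24 h, 36 h); flattened feature
    length is 12.
    """

    p8: tuple[float, float, float, float]
    p24: tuple[float, float, float, float]
    p36: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name, vec in (("p8", self.p8), ("p24", self.p24), ("p36", self.p36)):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (4,):
                raise ValidationError(f"{name} must have 4 entries")
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > SIMPLEX_ATOL:
                raise ValidationError(
                    f"{name} must be a probability vector summing to 1, got {vec}"
                )

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.p8, self.p24, self.p36])

    @staticmethod
    def feature_names() -> list[str]:
        return [f"p{w}_class{c}" for w in VALID_HORIZONS for c in range(4)]


@dataclass
class StaticProfile:
    """Time-invariant patient features plus the admission hour (post-LSW)."""

    patient_id: str
    admission_hour: float
    features: dict[str, float] = field(default_factory=dict)


@dataclass
class TimedValue:
    """A single timed measurement of a dynamic EHR variable."""

    variable: str
    hour: float
    value: float


@dataclass
class ScanRecord:
    """One radiographic scan: MLS plus other human-extracted image features.

    ``radiographic`` holds any extra per-scan variables beyond the three named
    fields; ``report_text`` / ``report_probs`` carry the radiology-report
    channel when text features are enabled.
    """

    hour: float
    mls_mm: float
    pineal_shift_mm: float | None = None
    basal_cistern_effacement: float | None = None
    radiographic: dict[str, float] = field(default_factory=dict)
    report_text: str | None = None
    report_probs: ReportProbabilities | None = None


@dataclass
class TreatmentEvent:
    hour: float
    kind: str


@dataclass
class PatientRecord:
    """One hospitalization: static profile, timed series, scans, treatments."""

    static: StaticProfile
    series: list[TimedValue] = field(default_factory=list)
    scans: list[ScanRecord] = field(default_factory=list)
    treatments: list[TreatmentEvent] = field(default_factory=list)
    end_hour: float = 0.0

    @property
    def patient_id(self) -> str:
        return self.static.patient_id

    def hemicraniectomy_hour(self) -> float | None:
        hours = [t.hour for t in self.treatments if t.kind == "hemicraniectomy"]
        return min(hours) if hours else None

    def scan_hours(self) -> np.ndarray:
        return np.array([s.hour for s in self.scans], dtype=float)

    def scan_mls(self) -> np.ndarray:
        return np.array([s.mls_mm for s in self.scans], dtype=float)


@dataclass
class TargetLabel:
    """Window-max MLS class target for one observation hour."""

    horizon_h: int
    valid: bool
    target_class: int | None = None
    filtered: bool | None = None
    target_mls_mm: float | None = None


def validate_patient(record: PatientRecord) -> list[str]:
    """Check every domain-type invariant; return human-readable violations.

    Violations are returned, never raised, so callers can audit whole cohorts.
    An empty list means the record is fully conformant.
    """
    v: list[str] = []
    s = record.static
    if not (0 <= s.admission_hour <= 24):
        v.append(
            "static.admission_hour: admission within 24 h of last-seen-well "
            f"required, got {s.admission_hour}"
        )
    if len(set(s.features)) != len(s.features):
        v.append("static.features: duplicate feature names")
    for bad in ("race", "ethnicity"):
        if any(bad in name.lower() for name in s.features):
            v.append(f"static.features: {bad} must not be a model feature")

    hours = [sc.hour for sc in record.scans]
    if any(b <= a for a, b in zip(hours, hours[1:])):
        v.append("scans: scan ordering — hours must be strictly increasing")
    for i, sc in enumerate(record.scans):
        if sc.hour < 0:
            v.append(f"scans[{i}].hour: must be >= 0")
        if not math.isfinite(sc.mls_mm) or sc.mls_mm < 0:
            v.append(f"scans[{i}].mls_mm: must be finite and >= 0")
        if sc.pineal_shift_mm is not None and sc.pineal_shift_mm < 0:
            v.append(f"scans[{i}].pineal_shift_mm: must be >= 0 or missing")

    for i, tv in enumerate(record.series):
        if tv.hour < 0:
            v.append(f"series[{i}].hour: must be >= 0")
    for i, tr in enumerate(record.treatments):
        if tr.hour < 0:
            v.append(f"treatments[{i}].hour: must be >= 0")
        if tr.kind not in TREATMENT_KINDS:
            v.append(f"treatments[{i}].kind: unknown treatment {tr.kind!r}")

    event_hours = (
        [tv.hour for tv in record.series]
        + [sc.hour for sc in record.scans]
        + [tr.hour for tr in record.treatments]
    )
    if event_hours and record.end_hour < max(event_hours):
        v.append("end_hour: must be >= the last event hour")
    return v


# ---------------------------------------------------------------------------
# File formats: four delimited-text tables (UTF-8, header row, empty = missing)
# ---------------------------------------------------------------------------

STATICS_FILE = "statics.csv"
EVENTS_FILE = "events.csv"
SCANS_FILE = "scans.csv"
TREATMENTS_FILE = "treatments.csv"

_SCAN_NAMED = ("mls_mm", "pineal_shift_mm", "basal_cistern_effacement")


def write_cohort(records: Sequence[PatientRecord], directory: str | Path) -> None:
    """Write a cohort to ``statics/events/scans/treatments.csv`` in *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    static_rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "admission_hour": r.static.admission_hour,
            "end_hour": r.end_hour,
        }
        row.update(r.static.features)
        static_rows.append(row)
    pd.DataFrame(static_rows).to_csv(directory / STATICS_FILE, index=False)

    ev = [
        {"patient_id": r.patient_id, "variable": tv.variable, "hour": tv.hour, "value": tv.value}
        for r in records
        for tv in r.series
    ]
    pd.DataFrame(ev, columns=["patient_id", "variable", "hour", "value"]).to_csv(
        directory / EVENTS_FILE, index=False
    )

    prob_names = ReportProbabilities.feature_names()
    extra_names: list[str] = []
    for r in records:
        for sc in r.scans:
            for name in sc.radiographic:
                if name not in extra_names:
                    extra_names.append(name)
    scan_rows = []
    for r in records:
        for sc in r.scans:
            row = {
                "patient_id": r.patient_id,
                "hour": sc.hour,
                "mls_mm": sc.mls_mm,
                "pineal_shift_mm": sc.pineal_shift_mm,
                "basal_cistern_effacement": sc.basal_cistern_effacement,
            }
            for name in extra_names:
                row[name] = sc.radiographic.get(name)
            row["report_text"] = sc.report_text
            if sc.report_probs is not None:
                row.update(dict(zip(prob_names, sc.report_probs.flatten())))
            scan_rows.append(row)
    cols = ["patient_id", "hour", *_SCAN_NAMED, *extra_names, "report_text", *prob_names]
    pd.DataFrame(scan_rows, columns=cols).to_csv(directory / SCANS_FILE, index=False)

    tr = [
        {"patient_id": r.patient_id, "hour": t.hour, "kind": t.kind}
        for r in records
        for t in r.treatments
    ]
    pd.DataFrame(tr, columns=["patient_id", "hour", "kind"]).to_csv(
        directory / TREATMENTS_FILE, index=False
    )


def _opt(x) -> float | None:
    return None if pd.isna(x) else float(x)


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read a cohort previously written by :func:`write_cohort`.

    Round-trips: ``read_cohort(write_cohort(records)) == records`` up to float
    representation (exact, since pandas writes shortest-repr floats).
    """
    directory = Path(directory)
    rt = dict(float_precision="round_trip")
    statics = pd.read_csv(directory / STATICS_FILE, **rt)
    events = pd.read_csv(directory / EVENTS_FILE, **rt)
    scans = pd.read_csv(directory / SCANS_FILE, **rt)
    treatments = pd.read_csv(directory / TREATMENTS_FILE, **rt)

    prob_names = ReportProbabilities.feature_names()
    reserved = {"patient_id", "hour", *_SCAN_NAMED, "report_text", *prob_names}
    extra_names = [c for c in scans.columns if c not in reserved]
    meta_cols = {"patient_id", "admission_hour", "end_hour"}
    feat_cols = [c for c in statics.columns if c not in meta_cols]

    records = []
    for _, srow in statics.iterrows():
        pid = str(srow["patient_id"])
        prof = StaticProfile(
            patient_id=pid,
            admission_hour=float(srow["admission_hour"]),
            features={c: _opt(srow[c]) for c in feat_cols},
        )
        pev = events[events["patient_id"].astype(str) == pid]
        series = [
            TimedValue(str(e.variable), float(e.hour), float(e.value))
            for e in pev.itertuples()
        ]

        psc = scans[scans["patient_id"].astype(str) == pid].sort_values("hour")
        scan_list = []
        for _, row in psc.iterrows():
            probs = None
            if prob_names[0] in psc.columns and not pd.isna(row[prob_names[0]]):
                flat = [float(row[c]) for c in prob_names]
                probs = ReportProbabilities(tuple(flat[0:4]), tuple(flat[4:8]), tuple(flat[8:12]))
            text = row.get("report_text")
            scan_list.append(
                ScanRecord(
                    hour=float(row["hour"]),
                    mls_mm=float(row["mls_mm"]),
                    pineal_shift_mm=_opt(row["pineal_shift_mm"]),
                    basal_cistern_effacement=_opt(row["basal_cistern_effacement"]),
                    radiographic={
                        n: _opt(row[n]) for n in extra_names if not pd.isna(row[n])
                    },
                    report_text=None if pd.isna(text) else str(text),
                    report_probs=probs,
                )
            )
        ptr = treatments[treatments["patient_id"].astype(str) == pid]
        tr_list = [TreatmentEvent(float(t.hour), str(t.kind)) for t in ptr.itertuples()]
        records.append(
            PatientRecord(
                static=prof,
                series=series,
                scans=scan_list,
                treatments=tr_list,
                end_hour=float(srow["end_hour"]),
            )
        )
    return records
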