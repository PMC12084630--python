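"""Synthetic hospitalization generator for large-MCA-stroke edema trajectories.

The real cohorts behind this problem are protected health information, so the
package ships a simulator that emulates the statistical structure the
pipeline assumes rather than any real patient:

* admission within 24 h of last-seen-well; hours indexed from LSW;
* CT scans at gamma-distributed intervals (derivation-like mean 11.3 h,
  validation-like mean 18.8 h);
* midline shift rising log-linearly to a peak 2–5 days post-ictus and
  decaying afterwards, with Gaussian measurement noise;
* pre-worsening drift in white-cell count, temperature and sodium whose
  amplitude is ``signal_strength``;
* treatments correlated with severity; decompressive hemicraniectomy censors
  all later data;
* per-scan report class-probability features concentrated on the true future
  class as ``text_informativeness`` grows (a stand-in for report-text models);
* missing-completely-at-random gaps per variable family.

All randomness flows from a single seed through named ``SeedSequence``
substreams, so identical configs reproduce byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_model import (
    PatientRecord,
    ReportProbabilities,
    ScanRecord,
    StaticProfile,
    TimedValue,
    TreatmentEvent,
    mls_to_class,
)
from .observation_builder import DEFAULT_DYNAMIC, DEFAULT_RADIOGRAPHIC, DEFAULT_STATIC


class ConfigError(ValueError):
    """Degenerate or inconsistent simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulator configuration.

    Defaults follow the derivation-cohort regime: mean inter-scan interval
    11.3 h, MLS peaking 48–120 h post-ictus, a severity mix weighted toward
    moderate/severe shift (cohort mean maximum MLS ≈ 6.6 mm).
    """

    n_patients: int = 100
    seed: int = 0
    scan_interval_mean_h: float = 11.3
    scan_interval_shape: float = 1.6
    peak_window_h: tuple[float, float] = (48.0, 120.0)
    class_mix: tuple[float, float, float, float] = (0.15, 0.25, 0.35, 0.25)
    signal_strength: float = 1.0
    text_informativeness: float = 6.0
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"static": 0.05, "dynamic": 0.10, "radiographic": 0.08}
    )
    mls_noise_sd: float = 0.25
    drift_lead_h: float = 24.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.scan_interval_mean_h <= 0 or self.scan_interval_shape <= 0:
            raise ConfigError("scan interval parameters must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.class_mix):
            raise ConfigError("class_mix must be a probability 4-vector")
        if self.peak_window_h[0] >= self.peak_window_h[1] or self.peak_window_h[0] <= 0:
            raise ConfigError("peak_window_h must be an increasing positive pair")
        for fam, rate in self.missingness.items():
            if not (0 <= rate <= 1):
                raise ConfigError(f"missingness[{fam}] must lie in [0, 1]")
        if self.signal_strength < 0 or self.text_informativeness < 0:
            raise ConfigError("signal knobs must be non-negative")

    @classmethod
    def for_profile(cls, profile: str, **kwargs) -> "SimConfig":
        """``derivation`` (scans every ~11.3 h) or ``validation`` (~18.8 h)."""
        if profile == "derivation":
            return cls(**kwargs)
        if profile == "validation":
            kwargs.setdefault("scan_interval_mean_h", 18.8)
            kwargs.setdefault("scan_interval_shape", 0.9)
            return cls(**kwargs)
        raise ConfigError(f"unknown profile {profile!r}")


@dataclass(frozen=True)
class TrajectoryParams:
    """Piecewise log-linear MLS trajectory: exponential rise to ``peak_mm`` at
    ``peak_hour``, exponential decay afterwards, Gaussian noise on top."""

    peak_mm: float
    peak_hour: float
    onset_mm: float = 0.05
    decay_tau_h: float = 60.0
    noise_sd: float = 0.25


def simulate_mls_trajectory(
    params: TrajectoryParams, seed: int | np.random.SeedSequence
) -> Callable[[float], float]:
    """Frozen-noise trajectory function ``hour -> mls_mm`` (vectorizable).

    A zero peak yields the identically-zero trajectory (no noise): such
    patients never develop midline shift.
    """
    if params.peak_mm < 0 or params.peak_hour <= 0:
        raise ConfigError("peak magnitude must be >= 0 and peak hour positive")
    if params.peak_mm == 0:
        return lambda hour: np.zeros_like(np.asarray(hour, dtype=float)) + 0.0

    rise_tau = params.peak_hour / math.log(params.peak_mm / params.onset_mm)
    rng = np.random.default_rng(seed)
    noise_grid = np.arange(0.0, 501.0)
    noise = rng.normal(0.0, params.noise_sd, noise_grid.size)

    def base(t: np.ndarray) -> np.ndarray:
        rising = params.peak_mm * np.exp(-(params.peak_hour - t) / rise_tau)
        falling = params.peak_mm * np.exp(-(t - params.peak_hour) / params.decay_tau_h)
        return np.where(t <= params.peak_hour, rising, falling)

    def trajectory(hour):
        t = np.asarray(hour, dtype=float)
        eps = np.interp(t, noise_grid, noise)
        return np.maximum(base(t) + eps, 0.0)

    trajectory.base = base  # noise-free curve, used for crossing times
    trajectory.params = params
    return trajectory


def _upward_crossings(params: TrajectoryParams) -> list[float]:
    """Hours at which the noise-free curve first exceeds the 3/8 mm edges."""
    if params.peak_mm <= 0:
        return []
    rise_tau = params.peak_hour / math.log(params.peak_mm / params.onset_mm)
    out = []
    for edge in (3.0, 8.0):
        if params.peak_mm > edge:
            out.append(params.peak_hour - rise_tau * math.log(params.peak_mm / edge))
    return out


def simulate_report_probs(
    true_classes: Sequence[int],
    text_informativeness: float,
    rng: np.random.Generator,
) -> ReportProbabilities:
    """Draw per-horizon report class probabilities around the true classes.

    Each horizon's 4-vector is Dirichlet(1 + s·e_true): uniform-mean at
    s = 0, concentrating on the true future class as s grows.
    """
    if text_informativeness < 0:
        raise ConfigError("text_informativeness must be >= 0")
    if len(true_classes) != 3:
        raise ValueError("one true class per horizon (8, 24, 36 h) required")
    vecs = []
    for c in true_classes:
        alpha = np.ones(4)
        alpha[int(c)] += text_informativeness
        draw = rng.dirichlet(alpha)
        vecs.append(tuple(draw / draw.sum()))
    return ReportProbabilities(*vecs)


# -- per-variable generation tables ----------------------------------------

_VITALS = {
    "heart_rate": (82.0, 10.0, 2.0),
    "sbp": (150.0, 15.0, 2.0),
    "dbp": (80.0, 10.0, 2.0),
    "map": (103.0, 11.0, 2.0),
    "temperature": (97.7, 0.5, 2.0),
    "respiratory_rate": (18.0, 3.0, 2.0),
    "spo2": (97.0, 1.5, 2.0),
    "gcs": (12.0, 2.0, 4.0),
}
_LABS = {
    "wbc": (11.5, 2.5, 12.0),
    "sodium": (138.0, 2.5, 12.0),
    "glucose": (150.0, 35.0, 12.0),
    "creatinine": (1.1, 0.4, 12.0),
    "bun": (20.0, 7.0, 12.0),
    "osmolality": (299.0, 8.0, 12.0),
}
#: additive pre-transition drift amplitudes at signal_strength = 1
_DRIFT_AMPLITUDE = {"wbc": 3.0, "temperature": 1.2, "sodium": 2.0}

_PEAK_RANGE_BY_CLASS = {0: (0.0, 0.0), 1: (0.8, 2.9), 2: (3.3, 7.8), 3: (8.4, 13.0)}


def _drift(t: np.ndarray, crossings: Sequence[float], lead: float) -> np.ndarray:
    """Unit-amplitude ramp rising over ``lead`` hours before each class
    transition, holding 12 h, then relaxing over 24 h."""
    total = np.zeros_like(t, dtype=float)
    for tc in crossings:
        up = np.clip((t - (tc - lead)) / lead, 0.0, 1.0)
        down = np.clip(((tc + 12.0 + 24.0) - t) / 24.0, 0.0, 1.0)
        total += np.minimum(up, down)
    return np.clip(total, 0.0, 1.5)


def _simulate_statics(rng: np.random.Generator, max_class: int) -> dict[str, float]:
    sev = max_class / 3.0
    f: dict[str, float] = {}
    f["age"] = float(np.clip(rng.normal(68, 15), 22, 98))
    f["sex_female"] = float(rng.random() < 0.5)
    f["nihss_admission"] = float(np.clip(rng.normal(15 + 5 * sev, 4), 2, 42))
    f["aspects_admission"] = float(np.clip(rng.normal(6.5 - 2.5 * sev, 1.6), 0, 10))
    for name, p in [
        ("prior_stroke", 0.11), ("atrial_fibrillation", 0.46),
        ("hypertension", 0.71), ("diabetes", 0.25),
        ("anticoagulant_use", 0.2), ("antiplatelet_use", 0.3),
        ("current_smoker", 0.2), ("left_hemisphere", 0.48),
        ("aca_involvement", 0.07),
    ]:
        f[name] = float(rng.random() < p)
    f["admission_sbp"] = float(rng.normal(150, 28))
    f["admission_dbp"] = float(rng.normal(80, 15))
    f["admission_map"] = (f["admission_sbp"] + 2 * f["admission_dbp"]) / 3.0
    f["admission_heart_rate"] = float(rng.normal(82, 19))
    f["admission_temperature"] = float(rng.normal(97.7, 1.0))
    f["admission_respiratory_rate"] = float(rng.normal(18, 4))
    f["admission_spo2"] = float(np.clip(rng.normal(97, 2), 80, 100))
    f["admission_wbc"] = float(np.clip(rng.normal(11.5, 4), 2, 40))
    f["admission_glucose"] = float(np.clip(rng.normal(150, 60), 50, 500))
    f["admission_hba1c"] = float(np.clip(rng.normal(6.2, 1.3), 4, 14))
    f["admission_sodium"] = float(rng.normal(137.8, 3.5))
    f["admission_potassium"] = float(rng.normal(4.0, 0.5))
    f["admission_creatinine"] = float(np.clip(rng.normal(1.1, 0.6), 0.3, 8))
    f["admission_bun"] = float(np.clip(rng.normal(20, 10), 4, 90))
    f["admission_osmolality"] = float(rng.normal(299, 12))
    f["admission_hemoglobin"] = float(rng.normal(13.5, 2.0))
    f["admission_platelets"] = float(np.clip(rng.normal(230, 70), 30, 700))
    f["admission_inr"] = float(np.clip(rng.normal(1.15, 0.3), 0.8, 6))
    f["vessel_occlusion_grade"] = float(rng.integers(0, 4))
    f["admission_hour_of_day"] = float(rng.integers(0, 24))
    assert set(f) == set(DEFAULT_STATIC)
    return f


def _scan_extras(
    rng: np.random.Generator,
    hour: float,
    mls: float,
    first_over3: float | None,
    first_over8: float | None,
) -> dict[str, float]:
    """The 33 radiographic variables beyond MLS / pineal shift / cisterns."""
    sig = lambda x: 1.0 / (1.0 + math.exp(-x))
    e: dict[str, float] = {}
    e["sulcal_effacement"] = float(rng.random() < sig((mls - 2) / 1.5))
    e["ventricular_compression"] = float(rng.random() < sig((mls - 4) / 1.5))
    e["petechial_hemorrhage"] = float(rng.random() < 0.45)
    e["parenchymal_hemorrhage"] = float(rng.random() < 0.12)
    e["hemorrhagic_transformation"] = float(rng.random() < 0.2)
    e["infarct_volume_ml"] = float(max(0, rng.normal(60 + 14 * mls, 25)))
    e["aspects_followup"] = float(np.clip(rng.normal(6 - 0.35 * mls, 1.5), 0, 10))
    e["collateral_score"] = float(rng.integers(0, 4))
    e["cerebral_atrophy"] = float(rng.random() < 0.44)
    e["hydrocephalus"] = float(rng.random() < sig((mls - 7) / 2))
    e["uncal_herniation"] = float(rng.random() < sig((mls - 9) / 1.5))
    e["subfalcine_herniation"] = float(rng.random() < sig((mls - 5) / 1.5))
    e["mls_over_3mm"] = float(mls > 3)
    e["mls_over_5mm"] = float(mls > 5)
    e["mls_over_8mm"] = float(mls > 8)
    if first_over3 is not None:
        e["hours_since_mls_over_3mm"] = max(0.0, hour - first_over3)
    if first_over8 is not None:
        e["hours_since_mls_over_8mm"] = max(0.0, hour - first_over8)
    e["pineal_over_2mm"] = float(0.45 * mls > 2)
    e["edema_extent_score"] = float(np.clip(rng.normal(0.8 + 0.25 * mls, 0.7), 0, 5))
    e["gray_white_differentiation_loss"] = float(rng.random() < sig((mls - 1) / 2))
    e["insular_ribbon_loss"] = float(rng.random() < 0.5)
    e["hyperdense_mca_sign"] = float(rng.random() < 0.35)
    e["hemorrhage_volume_ml"] = float(max(0, rng.normal(2 + mls, 6)))
    e["ventricle_ratio"] = float(np.clip(rng.normal(0.32 - 0.01 * mls, 0.05), 0.05, 0.6))
    e["csf_volume_ml"] = float(max(5, rng.normal(140 - 4 * mls, 20)))
    e["third_ventricle_shift_mm"] = float(max(0, rng.normal(0.7 * mls, 0.6)))
    e["shift_ratio"] = float(max(0, rng.normal(0.45, 0.1)))
    e["temporal_horn_dilation"] = float(rng.random() < sig((mls - 6) / 2))
    e["basal_ganglia_involvement"] = float(rng.random() < 0.4)
    e["cortical_involvement"] = float(rng.random() < 0.6)
    e["m1_territory_involvement"] = float(rng.random() < 0.5)
    e["m2_territory_involvement"] = float(rng.random() < 0.5)
    e["scan_quality_score"] = float(rng.integers(1, 6))
    return e


def _simulate_patient(index: int, config: SimConfig, ss: np.random.SeedSequence) -> PatientRecord:
    streams = ss.spawn(6)
    rng_core, rng_traj_seed, rng_dyn, rng_scan, rng_text, rng_miss = (
        np.random.default_rng(s) for s in streams
    )
    pid = f"P{index:04d}"

    max_class = int(rng_core.choice(4, p=np.asarray(config.class_mix)))
    lo, hi = _PEAK_RANGE_BY_CLASS[max_class]
    peak_mm = float(rng_core.uniform(lo, hi)) if hi > 0 else 0.0
    peak_hour = float(rng_core.uniform(*config.peak_window_h))
    params = TrajectoryParams(peak_mm=peak_mm, peak_hour=peak_hour, noise_sd=config.mls_noise_sd)
    trajectory = simulate_mls_trajectory(params, streams[1])
    crossings = _upward_crossings(params)

    admission = float(rng_core.uniform(2.0, 20.0))
    end_hour = admission + float(rng_core.uniform(96.0, 200.0))

    statics = _simulate_statics(rng_core, max_class)
    statics["nihss_admission"] = float(
        np.clip(statics["nihss_admission"] + 2.0 * (peak_mm > 8), 2, 42)
    )

    # ---- scans -----------------------------------------------------------
    scan_hours: list[float] = []
    t = admission + float(rng_scan.uniform(0.0, 2.0))
    while t < end_hour:
        scan_hours.append(round(t, 3))
        step = rng_scan.gamma(
            config.scan_interval_shape,
            config.scan_interval_mean_h / config.scan_interval_shape,
        )
        t += max(0.5, float(step))
    scan_mls = np.round(np.asarray(trajectory(np.array(scan_hours))), 3) if scan_hours else np.array([])

    first_over3 = next((h for h, m in zip(scan_hours, scan_mls) if m > 3), None)
    first_over8 = next((h for h, m in zip(scan_hours, scan_mls) if m > 8), None)

    # ---- treatments ------------------------------------------------------
    treatments: list[TreatmentEvent] = []
    if rng_core.random() < 0.45:
        treatments.append(TreatmentEvent(round(admission + rng_core.uniform(0.5, 2.0), 3), "thrombolysis_tpa"))
    if rng_core.random() < 0.25 + 0.1 * (max_class >= 2):
        treatments.append(TreatmentEvent(round(admission + rng_core.uniform(1.0, 6.0), 3), "thrombectomy"))
    osmotic_start: float | None = None
    p_osm = 0.7 if max_class >= 2 else (0.15 if max_class == 1 else 0.03)
    if rng_core.random() < p_osm:
        anchor = crossings[0] if crossings else peak_hour
        osmotic_start = float(np.clip(anchor + rng_core.uniform(-6, 6), admission + 1, end_hour - 1))
        treatments.append(TreatmentEvent(round(osmotic_start, 3), "osmotic"))
    dhc_hour: float | None = None
    if max_class == 3 and rng_core.random() < 0.35:
        dhc_hour = float(np.clip(peak_hour - rng_core.uniform(0, 12), admission + 12, end_hour - 1))
        treatments.append(TreatmentEvent(round(dhc_hour, 3), "hemicraniectomy"))

    # ---- dynamic series --------------------------------------------------
    miss_dyn = float(config.missingness.get("dynamic", 0.0))
    series: list[TimedValue] = []
    drift_amp = {
        k: config.signal_strength * v for k, v in _DRIFT_AMPLITUDE.items()
    }
    for name in DEFAULT_DYNAMIC:
        if name in ("mannitol_dose", "hypertonic_saline_dose"):
            if osmotic_start is None:
                continue
            times = np.arange(osmotic_start, end_hour, 6.0)
            base = 50.0 if name == "mannitol_dose" else 150.0
            vals = base + rng_dyn.normal(0, 0.1 * base, times.size)
        else:
            mu, sd, cadence = (_VITALS | _LABS)[name]
            times = admission + np.sort(
                rng_dyn.uniform(0, end_hour - admission, max(1, int((end_hour - admission) / cadence)))
            )
            n = times.size
            vals = np.empty(n)
            level = rng_dyn.normal(mu, sd)
            for k in range(n):
                level = mu + 0.8 * (level - mu) + 0.6 * sd * rng_dyn.normal()
                vals[k] = level
            if name in drift_amp and crossings:
                vals = vals + drift_amp[name] * _drift(times, crossings, config.drift_lead_h)
        keep = rng_dyn.random(times.size) >= miss_dyn
        for h, v in zip(times[keep], vals[keep]):
            series.append(TimedValue(name, round(float(h), 3), round(float(v), 3)))
    series.sort(key=lambda tv: (tv.hour, tv.variable))

    # ---- scan records with report probabilities --------------------------
    miss_rad = float(config.missingness.get("radiographic", 0.0))
    sh_arr = np.asarray(scan_hours)
    scans: list[ScanRecord] = []
    for i, (h, m) in enumerate(zip(scan_hours, scan_mls)):
        future: list[int] = []
        for w in (8, 24, 36):
            inside = (sh_arr > h) & (sh_arr <= h + w)
            future.append(
                mls_to_class(float(scan_mls[inside].max())) if inside.any() else mls_to_class(float(m))
            )
        probs = simulate_report_probs(future, config.text_informativeness, rng_text)
        pineal = max(0.0, 0.45 * m + rng_scan.normal(0, 0.3))
        cistern = float(rng_scan.random() < 1.0 / (1.0 + math.exp(-(m - 6) / 1.5)))
        extras = _scan_extras(rng_scan, h, float(m), first_over3, first_over8)
        extras = {
            k: round(v, 3)
            for k, v in extras.items()
            if rng_miss.random() >= miss_rad
        }
        scans.append(
            ScanRecord(
                hour=h,
                mls_mm=float(m),
                pineal_shift_mm=None if rng_miss.random() < miss_rad else round(pineal, 3),
                basal_cistern_effacement=None if rng_miss.random() < miss_rad else cistern,
                radiographic=extras,
                report_probs=probs,
            )
        )

    # ---- static missingness ---------------------------------------------
    miss_stat = float(config.missingness.get("static", 0.0))
    feats: dict[str, float | None] = {
        k: (None if rng_miss.random() < miss_stat else round(v, 3))
        for k, v in statics.items()
    }

    record = PatientRecord(
        static=StaticProfile(patient_id=pid, admission_hour=round(admission, 3), features=feats),
        series=series,
        scans=scans,
        treatments=sorted(treatments, key=lambda tr: tr.hour),
        end_hour=round(end_hour, 3),
    )
    if dhc_hour is not None:
        record = _censor_after(record, dhc_hour)
    return record


def _censor_after(record: PatientRecord, hour: float) -> PatientRecord:
    """Drop all data strictly after a hemicraniectomy; end follow-up there."""
    return PatientRecord(
        static=record.static,
        series=[tv for tv in record.series if tv.hour <= hour],
        scans=[sc for sc in record.scans if sc.hour <= hour],
        treatments=[tr for tr in record.treatments if tr.hour <= hour],
        end_hour=round(hour, 3),
    )


def simulate_cohort(config: SimConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` validated synthetic hospitalizations."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    return [_simulate_patient(i, config, child) for i, child in enumerate(children)]
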