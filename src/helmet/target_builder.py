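"""Window-max MLS prediction targets and transition ("filtered") flags.

For an observation at integer hour ``h`` and horizon ``W`` the target is the
severity class of the maximum MLS over all scans with hour in the half-open
window ``(h, h + W]``.  Hours whose window contains no scan are invalid: with
consecutive scans 40 h apart and W = 24, the first 16 post-scan hours are
excluded and the remaining 24 hours all target the later scan — i.e. each
scan yields up to W valid observations.

An observation is *filtered* (a transition) when its target class differs
from the patient's current class at that hour.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    VALID_HORIZONS,
    PatientRecord,
    TargetLabel,
    mls_to_class,
    mls_to_class_array,
)


class HorizonError(ValueError):
    """Prediction horizon not in the supported set."""


def _check_horizon(horizon_h: int) -> None:
    if horizon_h not in VALID_HORIZONS:
        raise HorizonError(
            f"horizon must be one of {VALID_HORIZONS}, got {horizon_h}"
        )


def assign_target(record: PatientRecord, hour: int, horizon_h: int) -> TargetLabel:
    """Target label for one patient-hour.

    Requires at least one scan at or before ``hour`` (the current class must
    exist).  A scan exactly at ``hour`` does not satisfy its own window.
    """
    _check_horizon(horizon_h)
    scan_hours = record.scan_hours()
    mls = record.scan_mls()
    n_prior = int(np.searchsorted(scan_hours, hour, side="right"))
    if n_prior == 0:
        raise ValueError(f"no scan at or before hour {hour}; current class undefined")
    lo = n_prior  # first scan strictly after `hour`
    hi = int(np.searchsorted(scan_hours, hour + horizon_h, side="right"))
    if hi <= lo:
        return TargetLabel(horizon_h=horizon_h, valid=False)
    window_max = float(mls[lo:hi].max())
    target_class = mls_to_class(window_max)
    current_class = mls_to_class(float(mls[n_prior - 1]))
    return TargetLabel(
        horizon_h=horizon_h,
        valid=True,
        target_class=target_class,
        filtered=target_class != current_class,
        target_mls_mm=window_max,
    )


def add_targets(
    observations: pd.DataFrame,
    records: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    horizon_h: int,
) -> pd.DataFrame:
    """Append ``valid``, ``target_class``, ``filtered``, ``target_mls_mm``
    columns to an observation table (vectorized per patient)."""
    _check_horizon(horizon_h)
    if not isinstance(records, Mapping):
        records = {r.patient_id: r for r in records}

    out = observations.copy()
    n = len(out)
    valid = np.zeros(n, dtype=bool)
    target_class = np.full(n, -1, dtype=int)
    target_mm = np.full(n, np.nan)

    for pid, idx in out.groupby("patient_id", sort=False).indices.items():
        rec = records[str(pid)]
        scan_hours = rec.scan_hours()
        mls = rec.scan_mls()
        hours = out["hour"].to_numpy()[idx].astype(float)
        lo = np.searchsorted(scan_hours, hours, side="right")
        hi = np.searchsorted(scan_hours, hours + horizon_h, side="right")
        ok = hi > lo
        # suffix max of scan MLS makes window maxima O(1) per observation:
        # max(mls[lo:hi]) for contiguous scans; windows always end at hi
        if scan_hours.size:
            wmax = np.array(
                [mls[a:b].max() if b > a else np.nan for a, b in zip(lo, hi)]
            )
        else:
            wmax = np.full(len(idx), np.nan)
        valid[idx] = ok
        target_mm[idx[ok]] = wmax[ok]
        if ok.any():
            target_class[idx[ok]] = mls_to_class_array(wmax[ok])

    out["valid"] = valid
    out["target_class"] = np.where(valid, target_class, -1)
    out["target_mls_mm"] = target_mm
    filt = np.zeros(n, dtype=bool)
    filt[valid] = out["target_class"].to_numpy()[valid] != out["current_class"].to_numpy()[valid]
    out["filtered"] = filt
    return out


def binarize_5mm(target_mls_mm: np.ndarray) -> np.ndarray:
    """Binary sensitivity-analysis target: window-max MLS > 5 mm vs <= 5 mm.

    Boundary 5 mm goes to the lower (<=) class, matching the class-edge
    convention.  Input rows must come from valid observations.
    """
    arr = np.asarray(target_mls_mm, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("binarize_5mm requires valid (non-NaN) window maxima")
    return (arr > 5.0).astype(int)
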