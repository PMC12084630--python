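"""Radiology-report class-probability features.

Reports are cropped to their "Findings" and "Impression" sections and fed to
one probabilistic 4-class classifier per horizon (8 / 24 / 36 h); the twelve
resulting probabilities become forward-filled observation features.

The bundled classifier is a regularized multinomial logistic regression on
token counts: desk-scale, deterministic, and swappable for any adapter that
honors the same per-scan 12-probability interface (e.g. a fine-tuned
clinical transformer; a reference adapter configuration — six epochs at an
initial learning rate of 2e-5 — is documented in docs/methods.md).
Precomputed probabilities pass through unchanged, so fully synthetic runs
can skip text entirely.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .data_model import (
    SIMPLEX_ATOL,
    ReportProbabilities,
    ScanRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SECTION_HEADERS = (
    "findings", "impression", "technique", "comparison", "indication",
    "history", "clinical information", "exam", "procedure",
)
_HEADER_RE = re.compile(
    r"^\s*(" + "|".join(_SECTION_HEADERS) + r")\s*:", re.IGNORECASE | re.MULTILINE
)


def extract_sections(report_text: str) -> str:
    """Concatenated "Findings" and "Impression" sections of a report.

    Header matching is case-insensitive and order-independent.  If neither
    header is present the whole text is returned and a warning logged.
    """
    if not report_text or not report_text.strip():
        raise ValidationError("report text is empty")
    matches = list(_HEADER_RE.finditer(report_text))
    pieces = []
    for i, m in enumerate(matches):
        name = m.group(1).lower()
        if name in ("findings", "impression"):
            end = matches[i + 1].start() if i + 1 < len(matches) else len(report_text)
            pieces.append(report_text[m.start():end].strip())
    if not pieces:
        logger.warning("no Findings/Impression headers found; using full text")
        return report_text
    return "\n".join(pieces)


@dataclass
class StandinReportClassifier:
    """Token-count multinomial logistic classifier for one horizon."""

    vectorizer: CountVectorizer
    model: LogisticRegression
    horizon_h: int

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        X = self.vectorizer.transform([extract_sections(t) for t in texts])
        raw = self.model.predict_proba(X)
        out = np.zeros((len(texts), 4))
        for j, c in enumerate(self.model.classes_):
            out[:, int(c)] = raw[:, j]
        return out


def fit_standin_classifier(
    texts: Sequence[str],
    targets_by_horizon: Mapping[int, Sequence[int]],
    patient_ids: Sequence[str],
    seed: int = 0,
) -> dict[int, StandinReportClassifier]:
    """One probabilistic classifier per horizon, patient-level 80/20 split.

    Texts from 80% of patients are used for fitting; the 20% holdout accuracy
    is logged per horizon.  Raises if a horizon's training targets collapse
    to a single class.
    """
    if set(targets_by_horizon) != {8, 24, 36}:
        raise ValueError("targets required for horizons 8, 24 and 36 h")
    pids = np.asarray([str(p) for p in patient_ids])
    unique = np.unique(pids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique.size)
    n_test = max(1, int(round(0.2 * unique.size)))
    test_ids = set(unique[perm[:n_test]])
    test_mask = np.isin(pids, list(test_ids))

    cropped = [extract_sections(t) for t in texts]
    out: dict[int, StandinReportClassifier] = {}
    for horizon, targets in targets_by_horizon.items():
        y = np.asarray(targets, dtype=int)
        y_train = y[~test_mask]
        if np.unique(y_train).size < 2:
            raise ValueError(f"horizon {horizon}: single-class training targets")
        vec = CountVectorizer(token_pattern=r"[A-Za-z][A-Za-z_]+")
        X_train = vec.fit_transform([c for c, m in zip(cropped, test_mask) if not m])
        model = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
        model.fit(X_train, y_train)
        clf = StandinReportClassifier(vectorizer=vec, model=model, horizon_h=horizon)
        if test_mask.any():
            X_test = vec.transform([c for c, m in zip(cropped, test_mask) if m])
            acc = float(np.mean(model.predict(X_test) == y[test_mask]))
            logger.info("horizon %d h stand-in holdout accuracy: %.3f", horizon, acc)
        out[horizon] = clf
    return out


def report_probability_features(
    scans: Sequence[ScanRecord],
    classifiers: Mapping[int, StandinReportClassifier] | None = None,
) -> list[ReportProbabilities]:
    """Per-scan 12-probability features (3 horizons x 4 classes).

    Precomputed probabilities attached to a scan pass through unchanged
    (after simplex validation); otherwise the scan's report text is
    classified.  A scan with neither channel is a data error.
    """
    out = []
    for i, sc in enumerate(scans):
        if sc.report_probs is not None:
            vecs = (sc.report_probs.p8, sc.report_probs.p24, sc.report_probs.p36)
            for v in vecs:
                if abs(sum(v) - 1.0) > SIMPLEX_ATOL or any(x < 0 for x in v):
                    raise ValidationError(
                        f"scan {i}: precomputed probabilities off the simplex"
                    )
            out.append(sc.report_probs)
        elif sc.report_text is not None and classifiers is not None:
            probs = {
                w: clf.predict_proba([sc.report_text])[0]
                for w, clf in classifiers.items()
            }
            out.append(
                ReportProbabilities(
                    tuple(probs[8]), tuple(probs[24]), tuple(probs[36])
                )
            )
        else:
            raise ValidationError(
                f"scan {i}: neither report probabilities nor classifiable text"
            )
    return out
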