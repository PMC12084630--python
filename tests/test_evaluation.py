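import numpy as np
import pytest

from helmet.evaluation import (
    accuracy_argmax,
    evaluate,
    summarize_splits,
    summarize_values,
    weighted_ovr_curves,
    worsening_metrics,
)


def brute_force_ovr_areas(p: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Independent oracle: explicit per-cutoff confusion counts at every
    unique score, weighted class averaging, trapezoidal areas."""
    classes, counts = np.unique(y, return_counts=True)
    weights = dict(zip(classes.tolist(), (counts / counts.sum()).tolist()))
    cutoffs = np.unique(np.concatenate([p.ravel(), [0.0, 1.0]]))
    points = []
    for t in cutoffs:
        tpr_avg = fpr_avg = prec_avg = 0.0
        for c in classes:
            pos = y == c
            pred = p[:, c] >= t
            tp = int(np.sum(pred & pos))
            fp = int(np.sum(pred & ~pos))
            fn = int(np.sum(~pred & pos))
            tn = int(np.sum(~pred & ~pos))
            tpr = tp / (tp + fn)
            fpr = fp / (fp + tn) if (fp + tn) else 0.0
            prec = tp / (tp + fp) if (tp + fp) else 1.0
            w = weights[int(c)]
            tpr_avg += w * tpr
            fpr_avg += w * fpr
            prec_avg += w * prec
        points.append((t, fpr_avg, tpr_avg, prec_avg))
    points.sort(key=lambda q: -q[0])
    fpr = np.array([q[1] for q in points])
    tpr = np.array([q[2] for q in points])
    prec = np.array([q[3] for q in points])
    auroc = float(np.trapezoid(tpr, fpr))
    auprc = float(np.trapezoid(prec, tpr))
    return auroc, auprc


class TestCurves:
    def test_perfect_separation_gives_auroc_one(self):
        y = np.array([0, 1, 2, 3] * 10)
        p = np.eye(4)[y] * 0.97 + 0.01
        curves = weighted_ovr_curves(p, y)
        assert curves.auroc == pytest.approx(1.0, abs=1e-6)

    def test_threshold_sweep_matches_brute_force_oracle(self, rng):
        for trial in range(3):
            n = 200
            y = rng.integers(0, 4, n)
            p = rng.dirichlet(np.ones(4) * (trial + 0.5), n)
            curves = weighted_ovr_curves(p, y)
            auroc_bf, auprc_bf = brute_force_ovr_areas(p, y)
            assert curves.auroc == pytest.approx(auroc_bf, abs=1e-6)
            assert curves.auprc == pytest.approx(auprc_bf, abs=1e-6)

    def test_single_class_targets_rejected(self, rng):
        p = rng.dirichlet(np.ones(4), 10)
        with pytest.raises(ValueError):
            weighted_ovr_curves(p, np.zeros(10, int))

    def test_complement_symmetry(self, rng):
        """Reversing all scores mirrors the ROC curve: AUROCs sum to 1."""
        n = 120
        y = rng.integers(0, 2, n)  # two-class instance for a clean mirror
        q = rng.random(n)
        p = np.zeros((n, 4))
        p[:, 1], p[:, 0] = q, 1 - q
        a = weighted_ovr_curves(p, y).auroc
        b = weighted_ovr_curves(p[:, [1, 0, 2, 3]], y).auroc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_weighted_curve_lies_between_class_extremes(self, rng):
        n = 300
        y = rng.integers(0, 4, n)
        p = rng.dirichlet(np.ones(4), n)
        curves = weighted_ovr_curves(p, y)
        per_class = []
        for c in range(4):
            pos = y == c
            thr = curves.thresholds
            s_pos, s_neg = np.sort(p[pos, c]), np.sort(p[~pos, c])
            tpr = (pos.sum() - np.searchsorted(s_pos, thr, side="left")) / pos.sum()
            per_class.append(tpr)
        per_class = np.vstack(per_class)
        assert np.all(curves.tpr <= per_class.max(axis=0) + 1e-12)
        assert np.all(curves.tpr >= per_class.min(axis=0) - 1e-12)


class TestAccuracy:
    def test_perfect_argmax(self):
        y = np.array([0, 1, 2, 3])
        assert accuracy_argmax(np.eye(4)[y], y) == 1.0

    def test_ties_break_to_lowest_class(self):
        p = np.full((1, 4), 0.25)
        assert accuracy_argmax(p, np.array([0])) == 1.0
        assert accuracy_argmax(p, np.array([1])) == 0.0

    def test_empty_input_is_undefined(self):
        assert np.isnan(accuracy_argmax(np.empty((0, 4)), np.empty(0, int)))


class TestWorsening:
    def test_true_and_predicted_worsening_counts_as_hit(self):
        p = np.zeros((1, 4)); p[0, 3] = 1.0      # predicts class 3
        sens, spec = worsening_metrics(p, np.array([2]), np.array([1]))
        assert sens == 1.0 and np.isnan(spec)    # no negatives in this set

    def test_top_class_can_never_worsen(self):
        p = np.zeros((2, 4)); p[:, 3] = 1.0
        sens, spec = worsening_metrics(p, np.array([3, 3]), np.array([3, 3]))
        assert np.isnan(sens)                    # no positive truth exists
        assert spec == 1.0                       # argmax == current, never "worse"

    def test_persistence_predictor_has_zero_sensitivity(self, rng):
        n = 50
        cur = rng.integers(0, 4, n)
        y = np.clip(cur + rng.integers(0, 2, n), 0, 3)
        p = np.eye(4)[cur]                       # always predicts the current class
        sens, spec = worsening_metrics(p, y, cur)
        if (y > cur).any():
            assert sens == 0.0
        assert spec == 1.0


class TestEvaluate:
    def test_filtered_mode_selects_exact_transition_subset(self, rng):
        n = 200
        y = rng.integers(0, 4, n)
        cur = rng.integers(0, 4, n)
        p = rng.dirichlet(np.ones(4), n)
        res_f = evaluate(p, y, cur, mode="filtered")
        keep = y != cur
        res_manual = evaluate(p[keep], y[keep], cur[keep], mode="overall")
        for m in ("auroc", "auprc", "accuracy"):
            assert res_f[m] == pytest.approx(res_manual[m])

    def test_order_invariance(self, rng):
        n = 100
        y = rng.integers(0, 4, n)
        cur = rng.integers(0, 4, n)
        p = rng.dirichlet(np.ones(4), n)
        perm = rng.permutation(n)
        a = evaluate(p, y, cur)
        b = evaluate(p[perm], y[perm], cur[perm])
        for m in a:
            assert a[m] == pytest.approx(b[m], nan_ok=True)

    def test_no_transitions_leaves_filtered_undefined(self, rng):
        y = np.array([1, 1, 2, 2])
        p = rng.dirichlet(np.ones(4), 4)
        res = evaluate(p, y, y.copy(), mode="filtered")
        assert all(np.isnan(v) for v in res.values())


class TestSummaries:
    def test_identical_split_values_collapse_ci(self):
        mean, lo, hi, n = summarize_values([0.9] * 5)
        assert (mean, lo, hi, n) == (0.9, 0.9, 0.9, 5)

    def test_t_interval_matches_closed_form(self):
        # sd = sqrt(0.00625) = 0.0790569, t_{0.975,4} = 2.7764451
        # half-width = 2.7764451 * 0.0790569 / sqrt(5) = 0.0981622
        mean, lo, hi, _ = summarize_values([0.8, 0.85, 0.9, 0.95, 1.0])
        assert mean == pytest.approx(0.9)
        assert lo == pytest.approx(0.9 - 0.0981622, abs=1e-6)
        assert hi == pytest.approx(0.9 + 0.0981622, abs=1e-6)

    def test_undefined_values_reduce_n(self):
        mean, lo, hi, n = summarize_values([0.8, np.nan, 0.9, np.nan, 1.0])
        assert n == 3 and mean == pytest.approx(0.9)

    def test_report_summary_table_shape(self):
        reports = {"overall": [dict(auroc=0.9, auprc=0.8, accuracy=0.7,
                                    sensitivity=0.6, specificity=0.95)] * 5}
        df = summarize_splits(reports).summary()
        assert len(df) == 5 * 5
        assert set(df.columns) >= {"mode", "metric", "split", "value", "mean", "ci_lo", "ci_hi"}
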