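"""ROC construction, DeLong inference, grading and cut-point selection."""

import numpy as np
import pandas as pd
import pytest

from accelcal.calibration import (alt_select_spec_priority, auc_ci,
                                  compare_auc, dichotomize, grade_auc,
                                  roc_curve, select_cutpoint)


def brute_force_auc(pos, neg, direction):
    """Pairwise concordance with ties counted 1/2 (independent oracle)."""
    sgn = -1.0 if direction == "below" else 1.0
    p, n = sgn * np.asarray(pos)[:, None], sgn * np.asarray(neg)[None, :]
    return float(((p > n).sum() + 0.5 * (p == n).sum()) / p.size / n.shape[1])


def brute_force_best_corner(values, labels, direction):
    """Exhaustive scan of every candidate threshold for the corner distance."""
    pos, neg = values[labels], values[~labels]
    uniq = np.unique(values)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in cands:
        if direction == "below":
            sens, spec = np.mean(pos < t), np.mean(neg >= t)
        else:
            sens, spec = np.mean(pos >= t), np.mean(neg < t)
        d = (1 - sens) ** 2 + (1 - spec) ** 2
        if best is None or d < best:
            best = d
    return best


def epochs_frame(values, classes):
    return pd.DataFrame({"site": "hip", "enmo_mg": values,
                         "intensity_class": classes})


class TestDichotomize:
    CLASSES = ["ST"] * 10 + ["light"] * 5 + ["MVPA"] * 5

    def test_st_boundary_counts(self):
        _, y = dichotomize(epochs_frame(np.arange(20.0), self.CLASSES), "st")
        assert y.sum() == 10 and (~y).sum() == 10

    def test_mvpa_boundary_counts(self):
        _, y = dichotomize(epochs_frame(np.arange(20.0), self.CLASSES), "mvpa")
        assert y.sum() == 5 and (~y).sum() == 15

    def test_absent_class_errors_by_name(self):
        frame = epochs_frame(np.arange(4.0), ["ST"] * 4)
        with pytest.raises(ValueError, match="MVPA"):
            dichotomize(frame, "mvpa")


class TestROCCurve:
    def test_perfect_separation_auc_one(self):
        vals = np.r_[np.arange(10.0), np.arange(50.0, 60.0)]
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]  # ST below
        assert roc_curve(vals, y, "below").auc == pytest.approx(1.0)

    def test_shuffled_labels_auc_near_half(self, rng):
        vals = rng.normal(size=500)
        y = rng.random(500) < 0.5
        assert roc_curve(vals, y, "above").auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_all_identical_flagged(self):
        curve = roc_curve(np.ones(10), np.r_[np.ones(5, bool), np.zeros(5, bool)],
                          "above")
        assert curve.degenerate and curve.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("direction", ["below", "above"])
    def test_trapezoid_equals_concordance_oracle(self, direction):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(4, 50)
            vals = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            curve = roc_curve(vals, y, direction)
            oracle = brute_force_auc(vals[y], vals[~y], direction)
            assert curve.auc == pytest.approx(oracle, abs=1e-12)

    def test_monotone_sweep(self, rng):
        vals = rng.normal(size=200)
        y = rng.random(200) < 0.4
        curve = roc_curve(vals, y, "above")
        assert np.all(np.diff(curve.sensitivities) <= 1e-12)
        assert np.all(np.diff(1 - curve.specificities) <= 1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        vals = np.abs(rng.normal(size=100)) + 0.1
        y = rng.random(100) < 0.5
        a = roc_curve(vals, y, "above").auc
        b = roc_curve(np.log(vals), y, "above").auc
        assert a == pytest.approx(b, abs=1e-12)


class TestDeLong:
    def binormal(self, rng, auc=0.8, m=100, n=100):
        from scipy.stats import norm
        mu = np.sqrt(2) * norm.ppf(auc)
        vals = np.r_[rng.normal(mu, 1, m), rng.normal(0, 1, n)]
        y = np.r_[np.ones(m, bool), np.zeros(n, bool)]
        return vals, y

    def test_perfect_auc_ci_clipped_at_one(self):
        vals = np.r_[np.arange(10.0) + 100, np.arange(10.0)]
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        lo, hi = auc_ci(roc_curve(vals, y, "above"))
        assert hi == 1.0

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (50, 100, 200, 400):
            rng = np.random.default_rng(5)
            vals, y = self.binormal(rng, m=n, n=n)
            lo, hi = auc_ci(roc_curve(vals, y, "above"))
            widths.append(hi - lo)
        assert np.all(np.diff(widths) < 0)

    def test_agreement_with_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        vals, y = self.binormal(rng)
        curve = roc_curve(vals, y, "above")
        assert curve.auc == pytest.approx(roc_auc_score(y, vals), abs=1e-12)

    def test_curve_vs_itself_paired_p_one(self, rng):
        vals, y = self.binormal(rng)
        curve = roc_curve(vals, y, "above")
        res = compare_auc(curve, curve, paired=True)
        assert res.p_value == 1.0 and res.delta == 0.0

    def test_mismatched_pairing_errors(self, rng):
        va, ya = self.binormal(rng, m=50, n=50)
        vb, yb = self.binormal(rng, m=60, n=60)
        with pytest.raises(ValueError):
            compare_auc(roc_curve(va, ya, "above"), roc_curve(vb, yb, "above"),
                        paired=True)

    def test_power_for_separated_aucs(self):
        """AUC 0.9 vs 0.6 at n=100/100 per arm: unpaired DeLong p < 0.01
        nearly always."""
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            va, ya = self.binormal(rng, auc=0.9)
            vb, yb = self.binormal(rng, auc=0.6)
            res = compare_auc(roc_curve(va, ya, "above"),
                              roc_curve(vb, yb, "above"), paired=False)
            hits += res.p_value < 0.01
        assert hits / n_sim >= 0.95


class TestGrading:
    @pytest.mark.parametrize("auc,grade", [
        (0.62, "poor"), (0.699, "poor"), (0.70, "fair"), (0.74, "fair"),
        (0.79, "fair"), (0.80, "good"), (0.85, "good"), (0.89, "good"),
        (0.90, "excellent"), (1.0, "excellent"),
    ])
    def test_bands(self, auc, grade):
        assert grade_auc(auc) == grade

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            grade_auc(1.2)


class TestSelectCutpoint:
    def test_corner_distance_picks_smallest(self):
        """The (1-sens)^2 + (1-spec)^2 minimum beats every other candidate."""
        vals = np.r_[np.full(8, 1.0), np.full(2, 3.0),    # positives (ST, below)
                     np.full(1, 1.5), np.full(9, 3.5)]
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        cp = select_cutpoint(roc_curve(vals, y, "below"))
        assert cp.distance == pytest.approx(
            brute_force_best_corner(vals, y, "below"), abs=1e-12)
        assert cp.distance <= 0.05 + 1e-12

    def test_perfect_separation_distance_zero(self):
        vals = np.r_[np.full(5, 10.0), np.full(5, 100.0)]
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        cp = select_cutpoint(roc_curve(vals, y, "below"))
        assert cp.distance == 0.0
        assert 10 < cp.threshold_raw < 100

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(6, 50)
            vals = np.round(rng.normal(size=n) * 3, 1)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            for direction in ("below", "above"):
                cp = select_cutpoint(roc_curve(vals, y, direction))
                oracle = brute_force_best_corner(vals, y, direction)
                assert cp.distance == pytest.approx(oracle, abs=1e-12)

    def test_reported_threshold_is_integer(self, rng):
        vals = rng.uniform(0, 200, 100)
        y = vals + rng.normal(0, 30, 100) > 100
        cp = select_cutpoint(roc_curve(vals, y, "above"))
        assert isinstance(cp.threshold, int)


class TestAltSelect:
    def test_sensitivity_floor_respected(self, rng):
        vals = np.r_[rng.normal(2, 1, 100), rng.normal(0, 1, 100)]
        y = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        cp = alt_select_spec_priority(roc_curve(vals, y, "above"), min_sens=0.6)
        assert cp.sensitivity >= 0.6

    def test_zero_floor_maximizes_specificity(self, rng):
        vals = np.r_[rng.normal(6, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        cp = alt_select_spec_priority(roc_curve(vals, y, "above"), min_sens=0.0)
        assert cp.specificity == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = rng.integers(8, 50)
            vals = np.round(rng.normal(size=n) * 2, 1)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            curve = roc_curve(vals, y, "above")
            cp = alt_select_spec_priority(curve, min_sens=0.5)
            idx = np.isfinite(curve.thresholds)
            sens, spec = curve.sensitivities[idx], curve.specificities[idx]
            best_spec = spec[sens >= 0.5].max()
            assert cp.specificity == pytest.approx(best_spec, abs=1e-12)

    def test_unreachable_floor_errors(self, rng):
        vals = np.r_[np.zeros(5), np.ones(5)]
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        curve = roc_curve(vals, y, "above")  # positives all BELOW negatives
        with pytest.raises(ValueError):
            alt_select_spec_priority(curve, min_sens=0.9)
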