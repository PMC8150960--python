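"""ROC cut-point calibration with DeLong inference.

Labelled 5 s epochs (acceleration metric value + MET-derived intensity
class) are dichotomized per boundary — sedentary (ST) versus everything
else, or MVPA versus everything else — and swept over candidate thresholds
(midpoints between consecutive distinct metric values, plus infinite ends).

Classification direction: an epoch is called ST when its value falls
*below* the ST threshold, and MVPA when its value is *at or above* the
MVPA threshold, so published-style thresholds read as an upper bound for
ST and a lower bound for MVPA.

The area under the curve is the trapezoidal area, identical to the
Mann-Whitney concordance probability with ties counted 1/2. Confidence
intervals and AUC comparisons use DeLong's structural-components variance
with a normal approximation. The operating point minimizes the squared
distance to the perfect corner,

    (1 - sensitivity)^2 + (1 - specificity)^2,

with ties broken toward higher specificity, then the smaller threshold.
An alternative specificity-first selector (maximal specificity subject to
a sensitivity floor) is provided for MVPA thresholds whose corner-distance
choice proves too permissive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .calorimetry import LIGHT, MVPA, ST

ST_BOUNDARY = "st"
MVPA_BOUNDARY = "mvpa"

#: Accuracy grades by AUC band (lower edges inclusive).
GRADE_BANDS = ((0.90, "excellent"), (0.80, "good"), (0.70, "fair"))


def grade_auc(auc: float) -> str:
    """Grade an AUC: >=0.90 excellent, 0.80-0.89 good, 0.70-0.79 fair, <0.70 poor."""
    if not (0.0 <= auc <= 1.0):
        raise ValueError("auc must lie in [0, 1]")
    for edge, name in GRADE_BANDS:
        if auc >= edge:
            return name
    return "poor"


def direction_for_boundary(boundary: str) -> str:
    b = boundary.lower()
    if b == ST_BOUNDARY:
        return "below"
    if b == MVPA_BOUNDARY:
        return "above"
    raise ValueError(f"unknown boundary {boundary!r}")


def dichotomize(epochs: pd.DataFrame, boundary: str,
                metric: str = "enmo_mg") -> Tuple[np.ndarray, np.ndarray]:
    """Metric values and binary labels for one boundary.

    ST boundary: positives are ST epochs, negatives light + MVPA.
    MVPA boundary: positives are MVPA epochs, negatives ST + light.
    Raises if either side is empty (the ROC is undefined).
    """
    cls = epochs["intensity_class"]
    target = ST if boundary.lower() == ST_BOUNDARY else MVPA
    if boundary.lower() not in (ST_BOUNDARY, MVPA_BOUNDARY):
        raise ValueError(f"unknown boundary {boundary!r}")
    y = (cls == target).to_numpy()
    if not y.any():
        raise ValueError(f"no {target} epochs; ROC undefined for {boundary} boundary")
    if y.all():
        raise ValueError(
            f"only {target} epochs present; no negative class for {boundary} boundary")
    return epochs[metric].to_numpy(dtype=float), y


@dataclass
class ROCCurve:
    """Threshold sweep for one (boundary, site, metric) combination."""

    boundary: str
    site: str
    metric: str
    direction: str                 # 'below' (ST) or 'above' (MVPA)
    thresholds: np.ndarray         # increasing; first/last are -inf/+inf
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    pos_values: np.ndarray = field(repr=False)
    neg_values: np.ndarray = field(repr=False)
    degenerate: bool = False

    def scores(self) -> Tuple[np.ndarray, np.ndarray]:
        """Orientation-corrected scores (higher = more positive)."""
        sgn = -1.0 if self.direction == "below" else 1.0
        return sgn * self.pos_values, sgn * self.neg_values


def roc_curve(values: np.ndarray, labels: np.ndarray, direction: str,
              boundary: str = "", site: str = "", metric: str = "") -> ROCCurve:
    """Build a ROC curve from labelled values.

    ``direction='below'`` predicts positive when value < threshold (ST
    convention); ``'above'`` predicts positive when value >= threshold
    (MVPA convention). Candidate thresholds are midpoints between
    consecutive distinct values plus the two infinite ends. A degenerate
    input (all values identical) yields AUC 0.5 and is flagged.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    pos = values[labels]
    neg = values[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative")
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    frac_pos_below = np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    frac_neg_below = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    if direction == "below":
        sens = frac_pos_below
        spec = 1.0 - frac_neg_below
    else:
        sens = 1.0 - frac_pos_below
        spec = frac_neg_below
    # integrate in threshold order (reversed for 'above') so fpr is
    # non-decreasing and tie-group diagonals stay adjacent
    fpr = 1.0 - spec
    order = slice(None) if direction == "below" else slice(None, None, -1)
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCCurve(boundary=boundary, site=site, metric=metric,
                    direction=direction, thresholds=thresholds,
                    sensitivities=sens, specificities=spec, auc=auc,
                    n_pos=int(pos.size), n_neg=int(neg.size),
                    pos_values=pos, neg_values=neg,
                    degenerate=bool(uniq.size == 1))


def _delong_components(pos_scores: np.ndarray,
                       neg_scores: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components (V10 per positive, V01 per negative)."""
    m, n = pos_scores.size, neg_scores.size
    both = np.concatenate([pos_scores, neg_scores])
    r_all = rankdata(both)
    r_pos = rankdata(pos_scores)
    r_neg = rankdata(neg_scores)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float((r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v10, v01


def delong_variance(curve: ROCCurve) -> float:
    pos, neg = curve.scores()
    _, v10, v01 = _delong_components(pos, neg)
    return float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)


def auc_ci(curve: ROCCurve, alpha: float = 0.05) -> Tuple[float, float]:
    """DeLong normal-approximation CI for the AUC, clipped to [0, 1].

    A zero variance (perfect or degenerate separation without ties across
    classes) collapses to the point interval (auc, auc).
    """
    if curve.n_pos < 2 or curve.n_neg < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    var = delong_variance(curve)
    if var <= 0.0:
        return (curve.auc, curve.auc)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return (float(max(curve.auc - half, 0.0)), float(min(curve.auc + half, 1.0)))


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float
    paired: bool


def compare_auc(curve_a: ROCCurve, curve_b: ROCCurve,
                paired: bool = True) -> AUCComparison:
    """DeLong test for a difference between two AUCs (two-sided).

    Paired comparison requires both curves to be built from the same
    epochs in the same order (e.g., two metrics of the same epoch table);
    the correlation of the structural components is then accounted for.
    """
    pa, na = curve_a.scores()
    pb, nb = curve_b.scores()
    auc_a, v10a, v01a = _delong_components(pa, na)
    auc_b, v10b, v01b = _delong_components(pb, nb)
    if paired:
        if pa.size != pb.size or na.size != nb.size:
            raise ValueError("paired comparison requires identical epoch counts")
        var = (np.var(v10a - v10b, ddof=1) / pa.size
               + np.var(v01a - v01b, ddof=1) / na.size)
    else:
        var = (np.var(v10a, ddof=1) / pa.size + np.var(v01a, ddof=1) / na.size
               + np.var(v10b, ddof=1) / pb.size + np.var(v01b, ddof=1) / nb.size)
    delta = auc_a - auc_b
    if var <= 0.0:
        z = 0.0 if delta == 0.0 else np.inf * np.sign(delta)
        p = 1.0 if delta == 0.0 else 0.0
    else:
        z = float(delta / np.sqrt(var))
        p = float(2.0 * norm.sf(abs(z)))
    return AUCComparison(auc_a, auc_b, float(delta), z, p, paired)


@dataclass
class CutPoint:
    """A calibrated threshold for one (boundary, site, metric)."""

    boundary: str
    site: str
    metric: str
    threshold: int                # reported, rounded to native integer units
    threshold_raw: float
    sensitivity: float
    specificity: float
    auc: float
    auc_ci95: Tuple[float, float]
    grade: str
    direction: str
    distance: float               # (1-sens)^2 + (1-spec)^2 at the threshold

    def as_dict(self) -> Dict:
        d = {k: getattr(self, k) for k in (
            "boundary", "site", "metric", "threshold", "threshold_raw",
            "sensitivity", "specificity", "auc", "grade", "direction")}
        d["auc_ci95_lo"], d["auc_ci95_hi"] = self.auc_ci95
        return d


def _finite_candidates(curve: ROCCurve) -> np.ndarray:
    return np.flatnonzero(np.isfinite(curve.thresholds))


def select_cutpoint(curve: ROCCurve, ci: Optional[Tuple[float, float]] = None) -> CutPoint:
    """Threshold minimizing the squared distance to perfect sensitivity and
    specificity; ties go to the higher specificity, then the smaller
    threshold."""
    idx = _finite_candidates(curve)
    if idx.size == 0:
        # all values identical: the lone value is the only usable threshold
        t = float(curve.pos_values[0])
        sens = spec = 0.5  # nominal; the curve is flagged degenerate
        d = (1 - sens) ** 2 + (1 - spec) ** 2
        return _mk_cutpoint(curve, t, sens, spec, d, ci)
    sens = curve.sensitivities[idx]
    spec = curve.specificities[idx]
    t = curve.thresholds[idx]
    d = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    d_round = np.round(d, 12)
    order = np.lexsort((t, -spec, d_round))
    best = order[0]
    return _mk_cutpoint(curve, float(t[best]), float(sens[best]),
                        float(spec[best]), float(d[best]), ci)


def alt_select_spec_priority(curve: ROCCurve, min_sens: float = 0.6,
                             ci: Optional[Tuple[float, float]] = None) -> CutPoint:
    """Maximize specificity subject to sensitivity >= ``min_sens``.

    Used when the corner-distance choice misclassifies too much light
    activity as the behaviour of interest; keeping a sensitivity floor
    while pushing specificity up trades detections for fewer false calls.
    """
    idx = _finite_candidates(curve)
    if idx.size == 0:
        raise ValueError("degenerate curve: no finite thresholds")
    sens = curve.sensitivities[idx]
    spec = curve.specificities[idx]
    t = curve.thresholds[idx]
    ok = sens >= min_sens
    if not ok.any():
        raise ValueError(f"no threshold reaches sensitivity >= {min_sens}")
    sens, spec, t = sens[ok], spec[ok], t[ok]
    order = np.lexsort((t, -sens, -np.round(spec, 12)))
    best = order[0]
    d = (1 - sens[best]) ** 2 + (1 - spec[best]) ** 2
    return _mk_cutpoint(curve, float(t[best]), float(sens[best]),
                        float(spec[best]), float(d), ci)


def _mk_cutpoint(curve: ROCCurve, t_raw: float, sens: float, spec: float,
                 d: float, ci: Optional[Tuple[float, float]]) -> CutPoint:
    if ci is None:
        ci = auc_ci(curve) if (curve.n_pos >= 2 and curve.n_neg >= 2) \
            else (curve.auc, curve.auc)
    return CutPoint(boundary=curve.boundary, site=curve.site,
                    metric=curve.metric,
                    threshold=int(round(t_raw)), threshold_raw=t_raw,
                    sensitivity=sens, specificity=spec, auc=curve.auc,
                    auc_ci95=ci, grade=grade_auc(curve.auc),
                    direction=curve.direction, distance=d)


DEFAULT_METRICS = ("enmo_mg", "counts_per_epoch")
DEFAULT_BOUNDARIES = (ST_BOUNDARY, MVPA_BOUNDARY)


def calibrate_cutpoints(
    epochs: pd.DataFrame,
    sites: Optional[Sequence[str]] = None,
    metrics: Sequence[str] = DEFAULT_METRICS,
    boundaries: Sequence[str] = DEFAULT_BOUNDARIES,
    epoch_s: int = 5,
) -> Tuple[pd.DataFrame, Dict, Dict[Tuple[str, str, str], ROCCurve]]:
    """Full calibration sweep over site x metric x boundary.

    Epochs are pooled across participants into one ROC per combination.
    Returns a report table (one row per combination), a JSON-serializable
    cut-point bundle for cross-validation, and the underlying curves.
    """
    if sites is None:
        sites = list(pd.unique(epochs["site"]))
    report_rows: List[Dict] = []
    bundle: Dict = {"epoch_s": int(epoch_s), "cutpoints": []}
    curves: Dict[Tuple[str, str, str], ROCCurve] = {}
    for site in sites:
        sub = epochs[epochs["site"] == site]
        for boundary in boundaries:
            for metric in metrics:
                values, y = dichotomize(sub, boundary, metric)
                curve = roc_curve(values, y, direction_for_boundary(boundary),
                                  boundary=boundary, site=site, metric=metric)
                cp = select_cutpoint(curve)
                curves[(site, metric, boundary)] = curve
                row = cp.as_dict()
                row.update(n_pos=curve.n_pos, n_neg=curve.n_neg)
                report_rows.append(row)
                bundle["cutpoints"].append(cp.as_dict())
    report = pd.DataFrame(report_rows)
    return report, bundle, curves


__all__ = [
    "ST_BOUNDARY", "MVPA_BOUNDARY", "GRADE_BANDS",
    "grade_auc", "direction_for_boundary", "dichotomize",
    "ROCCurve", "roc_curve", "delong_variance", "auc_ci",
    "AUCComparison", "compare_auc",
    "CutPoint", "select_cutpoint", "alt_select_spec_priority",
    "calibrate_cutpoints", "DEFAULT_METRICS", "DEFAULT_BOUNDARIES",
]
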