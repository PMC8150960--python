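"""External cross-validation of fixed cut-points, and epoch-scale conversion.

Calibrated thresholds are applied unchanged to an independent labelled
epoch table (no re-calibration): each epoch is classified by the fixed
threshold using the calibration direction convention (ST when value is
below the ST threshold, MVPA when at or above the MVPA threshold) and
tabulated against its MET-derived class. Sensitivity and specificity per
(boundary, site, metric) summarize the transfer.

Count thresholds scale linearly with the epoch length (counts are sums);
ENMO thresholds do not (ENMO is an average, invariant to epoch length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass
class CrossValResult:
    """Sensitivity/specificity of one fixed threshold on an external sample."""

    boundary: str
    site: str
    metric: str
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def as_dict(self) -> Dict:
        return {k: getattr(self, k) for k in (
            "boundary", "site", "metric", "threshold",
            "sensitivity", "specificity", "tp", "fp", "tn", "fn")}


def apply_single_cutpoint(values: np.ndarray, labels: np.ndarray,
                          threshold: float, direction: str) -> Tuple[int, int, int, int]:
    """Confusion counts (tp, fp, tn, fn) for one threshold.

    ``direction='below'``: predicted positive when value < threshold (so a
    value exactly at an ST threshold is *not* ST). ``'above'``: predicted
    positive when value >= threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if direction == "below":
        pred = values < threshold
    elif direction == "above":
        pred = values >= threshold
    else:
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return tp, fp, tn, fn


def apply_cutpoints(epochs: pd.DataFrame, bundle: Dict,
                    epoch_s: Optional[int] = None,
                    use_raw_threshold: bool = True) -> pd.DataFrame:
    """Evaluate every cut-point of a calibration bundle on labelled epochs.

    ``bundle`` is the JSON object written by the calibration stage. Its
    epoch length must match the table's (pass ``epoch_s``); a mismatch is
    an error directing to :func:`scale_cutpoint`. By default the raw
    (unrounded) thresholds are applied, which reproduces the calibration
    sample's recorded sensitivity/specificity exactly when applied back to
    it; set ``use_raw_threshold=False`` to apply the reported integers.
    """
    from .calibration import dichotomize  # local import avoids a cycle

    if epoch_s is not None and int(bundle.get("epoch_s", epoch_s)) != int(epoch_s):
        raise ValueError(
            f"bundle thresholds are per {bundle['epoch_s']} s epochs but the table "
            f"uses {epoch_s} s epochs; convert count thresholds with scale_cutpoint()")
    rows = []
    for cp in bundle["cutpoints"]:
        site = cp["site"]
        sub = epochs[epochs["site"] == site]
        if sub.empty:
            continue
        values, y = dichotomize(sub, cp["boundary"], cp["metric"])
        t = cp["threshold_raw"] if use_raw_threshold else cp["threshold"]
        tp, fp, tn, fn = apply_single_cutpoint(values, y, t, cp["direction"])
        res = CrossValResult(
            boundary=cp["boundary"], site=site, metric=cp["metric"],
            threshold=t,
            sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
            specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
            tp=tp, fp=fp, tn=tn, fn=fn)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def scale_cutpoint(threshold: float, epoch_a_s: float, epoch_b_s: float,
                   metric: str = "counts_per_epoch") -> float:
    """Convert a count threshold between epoch lengths (e.g. /5 s to /min).

    Counts are sums over the epoch, so the threshold scales by the length
    ratio and is rounded to the nearest integer. ENMO thresholds must not
    be scaled: ENMO is a time average and is invariant to epoch length.
    """
    if "enmo" in metric.lower():
        raise ValueError(
            "ENMO is an epoch average and is invariant to epoch length; "
            "only count thresholds scale")
    if epoch_a_s <= 0 or epoch_b_s <= 0:
        raise ValueError("epoch lengths must be > 0")
    if epoch_a_s == epoch_b_s:
        return threshold
    return float(np.rint(threshold * epoch_b_s / epoch_a_s))


def bmi(body_mass_kg: float, height_cm: float) -> float:
    """Body mass index: mass (kg) divided by squared height (m^2)."""
    if body_mass_kg <= 0 or height_cm <= 0:
        raise ValueError("mass and height must be > 0")
    h_m = height_cm / 100.0
    return body_mass_kg / (h_m * h_m)


__all__ = ["CrossValResult", "apply_single_cutpoint", "apply_cutpoints",
           "scale_cutpoint", "bmi"]
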