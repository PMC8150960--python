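"""Breath-by-breath gas exchange to steady-state METs and intensity classes.

The metabolic intensity of each laboratory bout is computed from portable
indirect calorimetry: breath-level VO2 (mL/min) is matched to the
accelerometer's second-by-second grid, artifact peaks deviating more than
2 SD from the window mean are removed, and the steady-state VO2 over the
last two minutes of the bout is divided by body mass and by the 1-MET
constant. For adults over 70 the 1-MET oxygen uptake is taken as
2.8 mL/kg/min rather than the usual adult 3.5 mL/kg/min.

Intensity classes use the energy-expenditure criterion only: sedentary
(ST) at <= 1.5 METs, moderate-to-vigorous (MVPA) at >= 3 METs, light in
between. Classification is at the activity level; every epoch of a bout
inherits the bout's class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

#: 1 MET expressed as oxygen uptake for adults over 70 (mL O2/kg/min).
MET_CONSTANT_OLDER_ADULTS = 2.8
#: The conventional adult value, available by configuration.
MET_CONSTANT_ADULTS = 3.5

ST_MAX_MET = 1.5
MVPA_MIN_MET = 3.0

ST = "ST"
LIGHT = "light"
MVPA = "MVPA"


def classify_intensity(met: float, st_max: float = ST_MAX_MET,
                       mvpa_min: float = MVPA_MIN_MET) -> str:
    """ST if met <= 1.5, MVPA if met >= 3, light otherwise (both inclusive)."""
    if met <= 0:
        raise ValueError("met must be > 0")
    if met <= st_max:
        return ST
    if met >= mvpa_min:
        return MVPA
    return LIGHT


def match_breaths_to_seconds(
    breaths: pd.DataFrame,
    origin: Optional[pd.Timestamp] = None,
    end: Optional[pd.Timestamp] = None,
    max_gap_s: int = 10,
    column: str = "vo2_mlmin",
) -> pd.Series:
    """Assign breath values to a one-second grid.

    Each breath lands in its floor second; seconds holding several breaths
    take their mean, and empty seconds carry the most recent value forward
    for at most ``max_gap_s`` seconds (longer gaps stay missing). The
    returned series is indexed by the second's start timestamp.
    """
    if breaths.empty:
        raise ValueError("breath series is empty")
    t = pd.to_datetime(breaths["time"])
    if origin is None:
        origin = t.iloc[0].floor("s")
    if end is None:
        end = t.iloc[-1]
    sec = ((t - origin).dt.total_seconds() // 1.0).astype(int)
    per_sec = breaths.groupby(sec.values)[column].mean()
    n_sec = int(np.floor((end - origin).total_seconds())) + 1
    grid = per_sec.reindex(range(n_sec))
    grid = grid.ffill(limit=max_gap_s)
    grid.index = origin + pd.to_timedelta(grid.index, unit="s")
    return grid


def remove_peaks(values: np.ndarray, sd_mult: float = 2.0,
                 two_sided: bool = True, iterate: bool = False) -> np.ndarray:
    """Drop artifact peaks deviating more than ``sd_mult`` SD from the mean.

    Whole-window mean/SD, single pass by default (``iterate=True`` repeats
    until no value is dropped). The test is two-sided by default since
    dropout artifacts are as unphysiological as spikes; ``two_sided=False``
    drops high outliers only. Fewer than three values are returned
    unchanged with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        warnings.warn("fewer than 3 values; peak removal skipped")
        return values
    while True:
        mean, sd = values.mean(), values.std()
        dev = values - mean
        bad = (np.abs(dev) if two_sided else dev) > sd_mult * sd
        if not bad.any():
            return values
        values = values[~bad]
        if not iterate:
            return values


@dataclass
class ActivityMET:
    """Steady-state metabolic intensity of one bout."""

    participant: str
    activity: str
    met: float
    vo2_mlkgmin: float
    n_seconds_used: int
    window: Tuple[pd.Timestamp, pd.Timestamp]
    usable: bool

    @property
    def intensity_class(self) -> Optional[str]:
        return classify_intensity(self.met) if self.usable else None


def steady_state_met(
    vo2_per_second: pd.Series,
    window: Tuple[pd.Timestamp, pd.Timestamp],
    body_mass_kg: float,
    met_constant: float = MET_CONSTANT_OLDER_ADULTS,
    sd_mult: float = 2.0,
    min_usable_s: int = 30,
    participant: str = "",
    activity: str = "",
) -> ActivityMET:
    """MET over a steady-state window: mean cleaned VO2 / mass / constant.

    Bouts with fewer than ``min_usable_s`` usable seconds in the window are
    flagged unusable (too short to determine METs reliably).
    """
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    w0, w1 = window
    vals = vo2_per_second.loc[(vo2_per_second.index >= w0)
                              & (vo2_per_second.index < w1)].to_numpy()
    vals = vals[~np.isnan(vals)]
    if vals.size >= 3:
        vals = remove_peaks(vals, sd_mult=sd_mult)
    usable = vals.size >= min_usable_s
    if usable:
        vo2_kg = float(vals.mean()) / body_mass_kg
        met = vo2_kg / met_constant
    else:
        vo2_kg = met = float("nan")
    return ActivityMET(participant, activity, met, vo2_kg,
                       int(vals.size), window, usable)


def resting_rate(
    vo2_per_second: pd.Series,
    lying_window: Tuple[pd.Timestamp, pd.Timestamp],
    body_mass_kg: float,
    sd_mult: float = 2.0,
    window_s: int = 300,
) -> float:
    """Resting oxygen uptake (mL/kg/min): mean cleaned VO2 over the last 5 min
    of the lying-still bout, divided by body mass."""
    w0, w1 = lying_window
    if (w1 - w0).total_seconds() < window_s:
        raise ValueError(f"lying bout shorter than {window_s} s")
    tail = (w1 - pd.to_timedelta(window_s, unit="s"), w1)
    vals = vo2_per_second.loc[(vo2_per_second.index >= tail[0])
                              & (vo2_per_second.index < tail[1])].to_numpy()
    vals = remove_peaks(vals[~np.isnan(vals)], sd_mult=sd_mult)
    if vals.size == 0:
        raise ValueError("no usable seconds in the resting window")
    return float(vals.mean()) / body_mass_kg


def activity_mets(
    breaths: pd.DataFrame,
    annotation: pd.DataFrame,
    body_mass_kg: float,
    met_constant: float = MET_CONSTANT_OLDER_ADULTS,
    sd_mult: float = 2.0,
    met_window_s: float = 120.0,
) -> pd.DataFrame:
    """Per-bout METs for one participant: last ``met_window_s`` of each bout.

    Returns one row per annotated bout with ``met``, ``vo2_mlkgmin``,
    ``intensity_class`` (None when unusable) and the usable flag.
    """
    origin = annotation["start"].min()
    end = annotation["end"].max()
    vo2 = match_breaths_to_seconds(breaths, origin=origin, end=end)
    rows = []
    for _, bout in annotation.iterrows():
        w1 = bout["end"]
        w0 = max(bout["start"], w1 - pd.to_timedelta(met_window_s, unit="s"))
        res = steady_state_met(vo2, (w0, w1), body_mass_kg,
                               met_constant=met_constant, sd_mult=sd_mult,
                               participant=bout["participant"],
                               activity=bout["activity"])
        rows.append({
            "participant": res.participant,
            "activity": res.activity,
            "met": res.met,
            "vo2_mlkgmin": res.vo2_mlkgmin,
            "n_seconds_used": res.n_seconds_used,
            "usable": res.usable,
            "intensity_class": res.intensity_class,
        })
    return pd.DataFrame(rows)


__all__ = [
    "MET_CONSTANT_OLDER_ADULTS", "MET_CONSTANT_ADULTS",
    "ST", "LIGHT", "MVPA", "ST_MAX_MET", "MVPA_MIN_MET",
    "classify_intensity", "match_breaths_to_seconds", "remove_peaks",
    "steady_state_met", "resting_rate", "activity_mets", "ActivityMET",
]
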