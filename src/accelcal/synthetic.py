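"""Synthetic raw-acceleration and breath-by-breath calorimetry generator.

The study data this pipeline was designed for are not public, so this module
fabricates datasets with the same statistical shape and a known ground
truth:

* **Raw acceleration** per participant x wear site: within each bout the
  signal is a fixed, randomly oriented unit gravity vector plus a sinusoid
  at the activity's dominant movement frequency plus white jitter. The
  sinusoid amplitude is calibrated numerically so the bout's mean ENMO hits
  the activity's per-site target.
* **Breath-by-breath gas exchange**: irregular breath timestamps
  (exponential inter-breath gaps clipped to 1.5–6 s, ~12–30 breaths/min);
  VO2 follows the bout's steady state ``MET x 2.8 mL/kg/min x mass`` through
  a first-order exponential on-transient, with multiplicative Gaussian noise
  and an optional fraction of artifact spikes deviating well over 2 SD.
* **Annotations** carrying bout boundaries plus the generating (true) MET
  and intensity class, enabling parameter-recovery tests.

Between-participant variability enters by *personalizing* the protocol:
each participant draws their own bout MET and per-site ENMO targets from
the template means/SDs (truncated at physiological floors). Identical
seeds produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calorimetry import MET_CONSTANT_OLDER_ADULTS, classify_intensity
from .metrics import RawSignal, enmo_per_sample
from .protocols import (ActivityTemplate, ProtocolSpec, SyntheticParticipant,
                        WEAR_SITES)

DEFAULT_START = pd.Timestamp("2021-05-11 08:00:00")
DEFAULT_JITTER_G = 0.002  # white sensor/posture jitter per axis, in g
DEFAULT_DEMO_SEED = 42    # fixed seed of the packaged demo dataset

_ENMO_FLOOR_MG = 0.5
_MET_FLOOR = 0.7


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _simulated_mean_enmo_mg(amplitude_g: float, freq_hz: float,
                            sample_rate_hz: float, gravity: np.ndarray,
                            direction: np.ndarray, jitter: np.ndarray,
                            t: np.ndarray) -> float:
    s = gravity + amplitude_g * np.sin(2 * np.pi * freq_hz * t)[:, None] * direction
    return float(enmo_per_sample(s + jitter).mean() * 1000.0)


def calibrate_amplitude(
    target_enmo_mg: float,
    freq_hz: float,
    sample_rate_hz: float,
    gravity: Optional[np.ndarray] = None,
    direction: Optional[np.ndarray] = None,
    jitter_g: float = 0.0,
    sim_s: float = 8.0,
    rel_tol: float = 0.02,
    max_amplitude_g: float = 4.0,
) -> float:
    """Sinusoid amplitude (g) whose gravity+sinusoid signal has the target mean ENMO.

    Mean ENMO is a monotone function of the amplitude for a fixed geometry,
    so a bisection on a short simulated signal (with a frozen jitter
    realization when ``jitter_g > 0``) converges quickly. Targets at or
    below the jitter floor return 0; targets beyond ``max_amplitude_g``
    raise ``ValueError``.
    """
    if target_enmo_mg < 0:
        raise ValueError("target_enmo_mg must be >= 0")
    gravity = np.array([0.0, 0.0, 1.0]) if gravity is None else np.asarray(gravity, float)
    direction = np.array([1.0, 0.0, 0.0]) if direction is None else np.asarray(direction, float)
    # simulate whole oscillation cycles so partial-cycle bias cannot skew the mean
    n_cycles = max(2.0, np.ceil(sim_s * freq_hz))
    sim_s = n_cycles / freq_hz
    n = int(round(sim_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    jitter = (np.random.default_rng(0).normal(0.0, jitter_g, size=(n, 3))
              if jitter_g > 0 else np.zeros((n, 3)))

    def f(a: float) -> float:
        return _simulated_mean_enmo_mg(a, freq_hz, sample_rate_hz,
                                       gravity, direction, jitter, t)

    if target_enmo_mg <= max(f(0.0), 1e-12):
        return 0.0
    lo, hi = 0.0, max_amplitude_g
    if f(hi) < target_enmo_mg:
        raise ValueError(
            f"target {target_enmo_mg} mg unreachable with amplitude <= {max_amplitude_g} g")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - target_enmo_mg) <= rel_tol * target_enmo_mg:
            return mid
        if val < target_enmo_mg:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_raw_signal(
    participant: SyntheticParticipant,
    protocol: ProtocolSpec,
    site: str,
    rng: Optional[np.random.Generator] = None,
    jitter_g: float = DEFAULT_JITTER_G,
    start_time: pd.Timestamp = DEFAULT_START,
) -> Tuple[RawSignal, pd.DataFrame]:
    """Raw tri-axial signal plus bout annotation for one participant x site.

    Each bout gets its own fixed random orientation (gravity direction) and
    movement direction; the sinusoid amplitude is calibrated so the bout's
    mean ENMO approximates the template's per-site target.
    """
    if site not in protocol.wear_sites:
        raise ValueError(
            f"unknown wear site {site!r}; protocol defines {list(protocol.wear_sites)}")
    if rng is None:
        rng = np.random.default_rng(participant.seed)
    fs = protocol.sample_rate_hz
    chunks: List[np.ndarray] = []
    ann_rows = []
    t_cursor = start_time
    for act in protocol.activities:
        n = int(round(act.duration_s * fs))
        gravity = _unit_vector(rng)
        direction = _unit_vector(rng)
        phase = rng.uniform(0.0, 2 * np.pi)
        target = float(act.enmo_target_mg[site])
        amp = calibrate_amplitude(target, act.movement_freq_hz, fs,
                                  gravity=gravity, direction=direction,
                                  jitter_g=jitter_g)
        t = np.arange(n) / fs
        bout = (gravity
                + amp * np.sin(2 * np.pi * act.movement_freq_hz * t + phase)[:, None]
                * direction
                + rng.normal(0.0, jitter_g, size=(n, 3)))
        chunks.append(bout)
        end = t_cursor + pd.to_timedelta(act.duration_s, unit="s")
        ann_rows.append({
            "participant": participant.id,
            "activity": act.label,
            "start": t_cursor,
            "end": end,
            "true_met": act.met_mean,
            "true_class": classify_intensity(act.met_mean),
        })
        t_cursor = end
    samples = np.vstack(chunks)
    return RawSignal(start_time, fs, samples), pd.DataFrame(ann_rows)


def generate_breath_series(
    participant: SyntheticParticipant,
    protocol: ProtocolSpec,
    artifact_rate: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    noise_frac: float = 0.04,
    tau_s: float = 30.0,
    mean_ibi_s: float = 3.5,
    start_time: pd.Timestamp = DEFAULT_START,
) -> pd.DataFrame:
    """Breath-by-breath VO2/VCO2 for one participant over the whole protocol.

    Breath times are irregular (exponential gaps clipped to [1.5 s, 6 s]).
    VO2 tracks each bout's steady state ``met x 2.8 x mass`` (mL/min)
    through a first-order on-transient of time constant ``tau_s``, with
    Gaussian noise of SD ``noise_frac x steady state``. A fraction
    ``artifact_rate`` of breaths is replaced by spikes deviating more than
    2 SD above the local level.
    """
    if not (0.0 <= artifact_rate < 0.2):
        raise ValueError("artifact_rate must lie in [0, 0.2)")
    if rng is None:
        rng = np.random.default_rng(participant.seed + 1)
    mass = participant.body_mass_kg
    total = protocol.total_duration_s

    gaps = np.clip(rng.exponential(mean_ibi_s, size=int(total / 1.2) + 8), 1.5, 6.0)
    times = np.cumsum(gaps)
    times = times[times < total]

    # Steady-state VO2 profile over bouts, then the exponential on-transient.
    bout_edges = np.cumsum([0.0] + [a.duration_s for a in protocol.activities])
    ss_levels = np.array([a.met_mean * MET_CONSTANT_OLDER_ADULTS * mass
                          for a in protocol.activities])
    vo2 = np.empty_like(times)
    level_prev = participant.resting_vo2_mlkgmin * mass  # pre-protocol resting
    for i, act in enumerate(protocol.activities):
        m = (times >= bout_edges[i]) & (times < bout_edges[i + 1])
        dt = times[m] - bout_edges[i]
        ss = ss_levels[i]
        vo2[m] = level_prev + (ss - level_prev) * (1.0 - np.exp(-dt / tau_s))
        level_prev = level_prev + (ss - level_prev) * (
            1.0 - np.exp(-(bout_edges[i + 1] - bout_edges[i]) / tau_s))
    bout_idx = np.clip(np.searchsorted(bout_edges, times, side="right") - 1,
                       0, len(ss_levels) - 1)
    noise_sd = noise_frac * ss_levels[bout_idx]
    if noise_frac > 0:
        vo2 = vo2 + rng.normal(0.0, 1.0, size=times.shape) * noise_sd

    if artifact_rate > 0:
        spike = rng.random(times.shape) < artifact_rate
        vo2[spike] += (4.0 + rng.exponential(2.0, size=int(spike.sum()))) * noise_sd[spike]

    vo2 = np.maximum(vo2, 0.0)
    vco2 = vo2 * 0.88
    if noise_frac > 0:
        vco2 = np.maximum(vco2 * (1.0 + rng.normal(0.0, 0.02, size=times.shape)), 0.0)
    return pd.DataFrame({
        "time": start_time + pd.to_timedelta(times, unit="s"),
        "vo2_mlmin": vo2,
        "vco2_mlmin": vco2,
    })


def generate_participants(
    n: int,
    seed: int,
    prefix: str = "P",
    mass_mean: float = 73.3, mass_sd: float = 12.4,
    height_mean: float = 166.0, height_sd: float = 8.5,
    resting_mean: float = 3.0, resting_sd: float = 0.7,
) -> List[SyntheticParticipant]:
    """Draw plausible older-adult participants (defaults mirror a 70+ cohort)."""
    rng = np.random.default_rng(seed)
    parts = []
    for i in range(n):
        mass = float(np.clip(rng.normal(mass_mean, mass_sd), 45.0, 115.0))
        height = float(np.clip(rng.normal(height_mean, height_sd), 140.0, 195.0))
        resting = float(np.clip(rng.normal(resting_mean, resting_sd), 1.9, 4.1))
        parts.append(SyntheticParticipant(
            id=f"{prefix}{i + 1:03d}",
            body_mass_kg=round(mass, 1),
            height_cm=round(height, 1),
            resting_vo2_mlkgmin=round(resting, 2),
            seed=int((seed * 1_000_003 + 7919 * (i + 1)) % 2**31),
        ))
    return parts


def personalize_protocol(
    protocol: ProtocolSpec,
    participant: SyntheticParticipant,
    rng: np.random.Generator,
    enmo_noise_scale: float = 1.0,
    met_noise_scale: float = 1.0,
) -> ProtocolSpec:
    """Participant-level protocol: bout METs and ENMO targets drawn per template.

    Draws come from truncated normals around the template means; the resting
    bout's MET is tied to the participant's own resting oxygen uptake so
    that the resting-rate analysis recovers it. Noise scales of 0 collapse
    the draws onto the template means (used by convergence tests).
    """
    acts = []
    for act in protocol.activities:
        if act.resting:
            met = participant.resting_vo2_mlkgmin / MET_CONSTANT_OLDER_ADULTS
        else:
            met = max(rng.normal(act.met_mean, act.met_sd * met_noise_scale), _MET_FLOOR)
        targets = {}
        for s in act.enmo_target_mg:
            draw = rng.normal(act.enmo_target_mg[s],
                              act.enmo_sd_mg[s] * enmo_noise_scale)
            targets[s] = max(draw, _ENMO_FLOOR_MG)
        acts.append(dataclasses.replace(
            act, met_mean=float(met), met_sd=0.0,
            enmo_target_mg=targets, enmo_sd_mg={s: 0.0 for s in targets}))
    return dataclasses.replace(protocol, activities=acts)


@dataclass
class ParticipantData:
    """All simulated records for one participant."""

    participant: SyntheticParticipant
    protocol: ProtocolSpec            # personalized copy
    signals: Dict[str, RawSignal]     # site -> raw signal
    breaths: pd.DataFrame
    annotation: pd.DataFrame


def iter_participant_data(
    protocol: ProtocolSpec,
    participants: Sequence[SyntheticParticipant],
    artifact_rate: float = 0.05,
    jitter_g: float = DEFAULT_JITTER_G,
    enmo_noise_scale: float = 1.0,
    met_noise_scale: float = 1.0,
    sites: Optional[Sequence[str]] = None,
) -> Iterator[ParticipantData]:
    """Stream per-participant synthetic data (memory stays per-participant).

    Randomness is fully determined by each participant's own seed, so the
    stream is reproducible regardless of consumption order.
    """
    sites = list(protocol.wear_sites if sites is None else sites)
    for p in participants:
        rng = np.random.default_rng(p.seed)
        personal = personalize_protocol(protocol, p, rng,
                                        enmo_noise_scale=enmo_noise_scale,
                                        met_noise_scale=met_noise_scale)
        signals = {}
        annotation = None
        for site in sites:
            signals[site], annotation = generate_raw_signal(
                p, personal, site, rng=rng, jitter_g=jitter_g)
        breaths = generate_breath_series(p, personal, artifact_rate, rng=rng)
        yield ParticipantData(p, personal, signals, breaths, annotation)


@dataclass
class SyntheticDataset:
    """A fully materialized study arm (all participants)."""

    protocol: ProtocolSpec
    participants: List[SyntheticParticipant]
    data: List[ParticipantData]

    @property
    def annotations(self) -> pd.DataFrame:
        return pd.concat([d.annotation for d in self.data], ignore_index=True)

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(p) for p in self.participants])


def generate_dataset(
    protocol: ProtocolSpec,
    participants: Sequence[SyntheticParticipant],
    **kwargs,
) -> SyntheticDataset:
    """Materialize :func:`iter_participant_data` for every participant."""
    data = list(iter_participant_data(protocol, participants, **kwargs))
    return SyntheticDataset(protocol, list(participants), data)


def _iso(ts: pd.Series) -> pd.Series:
    return ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f")


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write a dataset as plain CSV/YAML files.

    Layout: ``raw_<participant>_<site>.csv`` (timestamp_iso, x_g, y_g, z_g),
    ``breath_<participant>.csv`` (timestamp_iso, vo2_mlmin, vco2_mlmin),
    ``annotation.csv``, ``participants.csv``, ``protocol.yaml``.
    """
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.protocol.to_yaml(out / "protocol.yaml")
    dataset.participants_frame().to_csv(out / "participants.csv", index=False)
    ann = dataset.annotations.copy()
    ann["start"] = _iso(ann["start"])
    ann["end"] = _iso(ann["end"])
    ann.to_csv(out / "annotation.csv", index=False)
    for d in dataset.data:
        pid = d.participant.id
        for site, sig_ in d.signals.items():
            ts = sig_.start_time + pd.to_timedelta(
                np.arange(sig_.n_samples) / sig_.sample_rate_hz, unit="s")
            pd.DataFrame({
                "timestamp_iso": _iso(pd.Series(ts)),
                "x_g": np.round(sig_.samples[:, 0], 6),
                "y_g": np.round(sig_.samples[:, 1], 6),
                "z_g": np.round(sig_.samples[:, 2], 6),
            }).to_csv(out / f"raw_{pid}_{site}.csv", index=False)
        br = d.breaths.copy()
        br.insert(0, "timestamp_iso", _iso(br.pop("time")))
        br.round(3).to_csv(out / f"breath_{pid}.csv", index=False)


def read_raw_csv(path, sample_rate_hz: float) -> RawSignal:
    """Read a raw-signal CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    start = pd.Timestamp(df["timestamp_iso"].iloc[0])
    return RawSignal(start, sample_rate_hz, df[["x_g", "y_g", "z_g"]].to_numpy())


def read_breath_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["time"] = pd.to_datetime(df.pop("timestamp_iso"))
    return df[["time", "vo2_mlmin", "vco2_mlmin"]]


def read_annotation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


__all__ = [
    "calibrate_amplitude", "generate_raw_signal", "generate_breath_series",
    "generate_participants", "personalize_protocol",
    "iter_participant_data", "generate_dataset", "write_dataset",
    "read_raw_csv", "read_breath_csv", "read_annotation_csv",
    "ParticipantData", "SyntheticDataset",
    "DEFAULT_START", "DEFAULT_JITTER_G", "DEFAULT_DEMO_SEED",
]
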