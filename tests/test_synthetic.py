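"""Synthetic generator: amplitude calibration, signal targets, breath series."""

import numpy as np
import pandas as pd
import pytest

from accelcal.calorimetry import activity_mets
from accelcal.metrics import enmo_per_second
from accelcal.protocols import (HIP, area_like_protocol,
                                mobement_like_protocol)
from accelcal.synthetic import (calibrate_amplitude, generate_breath_series,
                                generate_dataset, generate_participants,
                                generate_raw_signal, personalize_protocol,
                                write_dataset)


def simulated_mean_enmo(amplitude, freq, fs, seconds=10):
    n = int(seconds * fs)
    t = np.arange(n) / fs
    s = np.tile([0.0, 0.0, 1.0], (n, 1))
    s[:, 0] += amplitude * np.sin(2 * np.pi * freq * t)
    norm = np.linalg.norm(s, axis=1)
    return np.maximum(norm - 1, 0).mean() * 1000


class TestCalibrateAmplitude:
    def test_zero_target_gives_zero_amplitude(self):
        assert calibrate_amplitude(0.0, 1.0, 80.0) == 0.0

    def test_target_50mg_round_trips(self):
        amp = calibrate_amplitude(50.0, 1.0, 80.0)
        assert 47.5 <= simulated_mean_enmo(amp, 1.0, 80.0) <= 52.5

    def test_monotone_in_target(self):
        amps = [calibrate_amplitude(t, 1.0, 80.0) for t in (10, 50, 150)]
        assert amps[0] < amps[1] < amps[2]

    def test_unreachable_target_errors(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_amplitude(5e6, 1.0, 80.0)


@pytest.fixture(scope="module")
def participant():
    return generate_participants(1, seed=5)[0]


@pytest.fixture(scope="module")
def protocol():
    return area_like_protocol(bout_s=90, lying_s=90)


class TestRawSignal:
    def bout_enmo(self, sig, ann, label):
        e = enmo_per_second(sig)
        row = ann[ann["activity"] == label].iloc[0]
        i0 = int((row["start"] - sig.start_time).total_seconds())
        i1 = int((row["end"] - sig.start_time).total_seconds())
        return e[i0 + 5:i1 - 5].mean()

    def test_unknown_site_errors(self, participant, protocol):
        with pytest.raises(ValueError, match="ankle"):
            generate_raw_signal(participant, protocol, "ankle")

    def test_zero_target_bout_is_pure_gravity(self, participant):
        import dataclasses
        proto = area_like_protocol(bout_s=60, lying_s=60)
        act0 = dataclasses.replace(proto.activities[0],
                                   enmo_target_mg={s: 0.0 for s in proto.wear_sites})
        proto = dataclasses.replace(proto, activities=[act0])
        sig, ann = generate_raw_signal(participant, proto, HIP, jitter_g=0.0)
        assert self.bout_enmo(sig, ann, act0.label) == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("label,target", [
        ("lying_still", 3.4), ("brisk_walk", 137.2),
    ])
    def test_bout_mean_enmo_hits_target(self, participant, protocol, label, target):
        sig, ann = generate_raw_signal(participant, protocol, HIP)
        assert self.bout_enmo(sig, ann, label) == pytest.approx(target, rel=0.20)

    def test_annotation_carries_ground_truth_class(self, participant, protocol):
        _, ann = generate_raw_signal(participant, protocol, HIP)
        assert {"true_met", "true_class"} <= set(ann.columns)
        walks = ann[ann["activity"] == "brisk_walk"]
        assert (walks["true_class"] == "MVPA").all()


class TestBreathSeries:
    def test_noise_free_steady_state_matches_met_definition(self):
        from accelcal.protocols import SyntheticParticipant
        p = SyntheticParticipant("X", 100.0, 170.0, 2.8, seed=9)
        proto = area_like_protocol(bout_s=300, lying_s=300)
        br = generate_breath_series(p, proto, artifact_rate=0.0, noise_frac=0.0)
        # lying bout (resting template): met tied to 1.0 here since resting = 2.8
        t_end = proto.activities[0].duration_s
        sel = br[(br["time"] - br["time"].iloc[0]).dt.total_seconds().between(t_end - 60, t_end)]
        assert sel["vo2_mlmin"].mean() == pytest.approx(280.0, rel=0.01)

    def test_breath_rate_physiological(self):
        p = generate_participants(1, seed=2)[0]
        br = generate_breath_series(p, area_like_protocol(bout_s=60, lying_s=60), 0.0)
        gaps = np.diff(br["time"]).astype("timedelta64[ns]").astype(float) / 1e9
        rate_per_min = 60.0 / gaps.mean()
        assert 10 <= rate_per_min <= 40
        assert gaps.min() >= 1.5 - 1e-6 and gaps.max() <= 6.0 + 1e-6

    def test_no_artifacts_means_no_gross_outliers(self):
        p = generate_participants(1, seed=7)[0]
        proto = area_like_protocol(bout_s=300, lying_s=300)
        br = generate_breath_series(p, proto, artifact_rate=0.0)
        t = (br["time"] - br["time"].iloc[0]).dt.total_seconds()
        for i, act in enumerate(proto.activities[:4]):
            lo, hi = i * 300 + 120, (i + 1) * 300
            vals = br.loc[t.between(lo, hi), "vo2_mlmin"].to_numpy()
            dev = np.abs(vals - vals.mean()) / vals.std()
            assert dev.max() <= 4.0

    def test_invalid_artifact_rate_errors(self):
        p = generate_participants(1, seed=2)[0]
        with pytest.raises(ValueError):
            generate_breath_series(p, area_like_protocol(), artifact_rate=0.5)

    def test_met_recovery_with_artifacts(self):
        """Calorimetry round-trip: recovered MET within 0.15 of the generating MET."""
        p = generate_participants(1, seed=11)[0]
        proto = area_like_protocol(bout_s=240, lying_s=390)
        rng = np.random.default_rng(p.seed)
        personal = personalize_protocol(proto, p, rng, enmo_noise_scale=0.0)
        _, ann = generate_raw_signal(p, personal, HIP, rng=rng)
        br = generate_breath_series(p, personal, artifact_rate=0.05, rng=rng)
        mets = activity_mets(br, ann, p.body_mass_kg)
        merged = mets.merge(ann[["activity", "true_met"]], on="activity")
        usable = merged[merged["usable"]]
        assert len(usable) == len(proto.activities)
        assert np.max(np.abs(usable["met"] - usable["true_met"])) <= 0.15


class TestDatasetDeterminism:
    def test_identical_seed_byte_identical_files(self, tmp_path):
        proto = mobement_like_protocol(bout_s=40, walk_s=40)
        for d in ("a", "b"):
            parts = generate_participants(2, seed=99)
            ds = generate_dataset(proto, parts)
            write_dataset(ds, tmp_path / d)
        for fa in sorted((tmp_path / "a").iterdir()):
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_default_protocol_covers_all_intensity_classes(self):
        for proto in (area_like_protocol(), mobement_like_protocol()):
            classes = {"ST": 0, "light": 0, "MVPA": 0}
            for a in proto.activities:
                if a.met_mean <= 1.5:
                    classes["ST"] += 1
                elif a.met_mean >= 3.0:
                    classes["MVPA"] += 1
                else:
                    classes["light"] += 1
            assert min(classes.values()) >= 2, (proto.name, classes)
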