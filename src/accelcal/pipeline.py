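"""End-to-end orchestration: simulate -> metrics -> METs -> calibrate -> cross-validate.

Two entry styles are provided:

* :func:`run_demo` — the packaged in-memory demonstration: a fixed-seed
  calibration-style arm (three sites, 80 Hz) is simulated, labelled and
  calibrated, and the resulting cut-point bundle is cross-validated on an
  independently simulated arm (two sites, 60 Hz, different activities).
  Raw signals are processed per participant and discarded, so memory stays
  flat.
* file-based ``stage_*`` functions — the CLI's building blocks, reading and
  writing the CSV/YAML/JSON artifacts documented in ``docs/methods.md``.

Every file-writing run leaves a ``run_manifest.json`` with the seed, the
configuration hash and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import calibration, calorimetry, crossval, metrics, synthetic
from .protocols import ProtocolSpec, SyntheticParticipant, area_like_protocol, \
    mobement_like_protocol
from .synthetic import DEFAULT_DEMO_SEED

EPOCH_COLUMNS = ["participant", "site", "activity", "epoch_start",
                 "enmo_mg", "counts_per_epoch", "met", "intensity_class"]


def label_participant_epochs(
    pdata: synthetic.ParticipantData,
    epoch_s: int = 5,
    trim_s: float = 15.0,
    target_s: float = 180.0,
    met_constant: float = calorimetry.MET_CONSTANT_OLDER_ADULTS,
    sd_mult: float = 2.0,
    met_window_s: float = 120.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Epoch table for one participant with MET labels joined in.

    Computes per-epoch ENMO/counts for every wear site, the per-bout
    steady-state MET from the breath series, and joins the bout's
    intensity class onto its epochs. Bouts flagged unusable (too few
    usable seconds of gas exchange) are dropped.
    """
    mets = calorimetry.activity_mets(
        pdata.breaths, pdata.annotation, pdata.participant.body_mass_kg,
        met_constant=met_constant, sd_mult=sd_mult, met_window_s=met_window_s)
    tables = []
    for site, sig in pdata.signals.items():
        tables.append(metrics.epoch_table_for_signal(
            sig, pdata.annotation, pdata.participant.id, site,
            epoch_s=epoch_s, trim_s=trim_s, target_s=target_s))
    epochs = pd.concat(tables, ignore_index=True)
    epochs = epochs.merge(
        mets[["participant", "activity", "met", "intensity_class", "usable"]],
        on=["participant", "activity"], how="left")
    epochs = epochs[epochs["usable"].fillna(False)].drop(columns="usable")
    return epochs.reset_index(drop=True), mets


def build_labelled_epochs(
    protocol: ProtocolSpec,
    participants: Sequence[SyntheticParticipant],
    artifact_rate: float = 0.05,
    enmo_noise_scale: float = 1.0,
    met_noise_scale: float = 1.0,
    **label_kwargs,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an arm and return (epochs, per-bout METs, annotations)."""
    epoch_parts, met_parts, ann_parts = [], [], []
    for pdata in synthetic.iter_participant_data(
            protocol, participants, artifact_rate=artifact_rate,
            enmo_noise_scale=enmo_noise_scale,
            met_noise_scale=met_noise_scale):
        ep, mets = label_participant_epochs(pdata, epoch_s=protocol.epoch_s,
                                            **label_kwargs)
        epoch_parts.append(ep)
        met_parts.append(mets)
        ann_parts.append(pdata.annotation)
    return (pd.concat(epoch_parts, ignore_index=True),
            pd.concat(met_parts, ignore_index=True),
            pd.concat(ann_parts, ignore_index=True))


@dataclass
class DemoResult:
    """Everything the packaged demonstration run produces."""

    seed: int
    calibration_epochs: pd.DataFrame
    calibration_mets: pd.DataFrame
    cutpoint_report: pd.DataFrame
    bundle: Dict
    curves: Dict
    crossval_epochs: pd.DataFrame
    crossval_results: pd.DataFrame
    auc_comparisons: pd.DataFrame


def compare_metric_aucs(curves: Dict) -> pd.DataFrame:
    """Paired DeLong tests: ENMO vs counts per (site, boundary)."""
    rows = []
    keys = {(site, boundary) for (site, _m, boundary) in curves}
    for site, boundary in sorted(keys):
        a = curves.get((site, "enmo_mg", boundary))
        b = curves.get((site, "counts_per_epoch", boundary))
        if a is None or b is None:
            continue
        cmp_ = calibration.compare_auc(a, b, paired=True)
        rows.append({"site": site, "boundary": boundary,
                     "auc_enmo": cmp_.auc_a, "auc_counts": cmp_.auc_b,
                     "delta": cmp_.delta, "z": cmp_.z, "p_value": cmp_.p_value})
    return pd.DataFrame(rows)


def run_demo(
    seed: int = DEFAULT_DEMO_SEED,
    n_calibration: int = 24,
    n_crossval: int = 12,
    artifact_rate: float = 0.05,
    outdir: Optional[str] = None,
) -> DemoResult:
    """Fixed-seed calibration + external cross-validation demonstration.

    Problem sizes default to a desk-scale study: 24 calibration and 12
    cross-validation participants with 3.5 min bouts (see docs/methods.md).
    """
    cal_protocol = area_like_protocol()
    cv_protocol = mobement_like_protocol()
    parts_cal = synthetic.generate_participants(n_calibration, seed=seed, prefix="A")
    parts_cv = synthetic.generate_participants(n_crossval, seed=seed + 500_017, prefix="M")

    cal_epochs, cal_mets, _ = build_labelled_epochs(
        cal_protocol, parts_cal, artifact_rate=artifact_rate)
    report, bundle, curves = calibration.calibrate_cutpoints(
        cal_epochs, sites=list(cal_protocol.wear_sites),
        epoch_s=cal_protocol.epoch_s)

    cv_epochs, _cv_mets, _ = build_labelled_epochs(
        cv_protocol, parts_cv, artifact_rate=artifact_rate)
    cv_bundle = {"epoch_s": bundle["epoch_s"],
                 "cutpoints": [cp for cp in bundle["cutpoints"]
                               if cp["site"] in cv_protocol.wear_sites]}
    cv_results = crossval.apply_cutpoints(cv_epochs, cv_bundle,
                                          epoch_s=cv_protocol.epoch_s)
    comparisons = compare_metric_aucs(curves)

    result = DemoResult(seed, cal_epochs, cal_mets, report, bundle, curves,
                        cv_epochs, cv_results, comparisons)
    if outdir is not None:
        _write_demo(result, outdir)
    return result


def _config_hash(config: Dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_demo(result: DemoResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.calibration_epochs.to_csv(out / "calibration_epochs.csv", index=False)
    result.crossval_epochs.to_csv(out / "crossval_epochs.csv", index=False)
    result.cutpoint_report.to_csv(out / "cutpoints.csv", index=False)
    result.crossval_results.to_csv(out / "crossval_results.csv", index=False)
    result.auc_comparisons.to_csv(out / "auc_comparisons.csv", index=False)
    with open(out / "cutpoint_bundle.json", "w") as fh:
        json.dump(result.bundle, fh, indent=2)
    config = {"seed": result.seed,
              "n_calibration_epochs": len(result.calibration_epochs),
              "n_crossval_epochs": len(result.crossval_epochs)}
    manifest = {"config": config, "config_hash": _config_hash(config),
                "rows": {"cutpoints": len(result.cutpoint_report),
                         "crossval_results": len(result.crossval_results)}}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# File-based stages (the CLI's backend)

PROTOCOLS = {"area": area_like_protocol, "mobement": mobement_like_protocol}


def stage_simulate(protocol_name: str, n_participants: int, seed: int,
                   outdir, artifact_rate: float = 0.05) -> None:
    """Simulate an arm and write raw/breath/annotation CSVs plus protocol YAML."""
    if protocol_name not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol_name!r}; "
                         f"choose from {sorted(PROTOCOLS)}")
    protocol = PROTOCOLS[protocol_name]()
    parts = synthetic.generate_participants(n_participants, seed=seed)
    dataset = synthetic.generate_dataset(protocol, parts,
                                         artifact_rate=artifact_rate)
    synthetic.write_dataset(dataset, outdir)


def stage_metrics(data_dir, out_csv, epoch_s: int = 5, trim_s: float = 15.0,
                  target_s: float = 180.0) -> pd.DataFrame:
    """Raw CSVs + annotation -> per-epoch metric table CSV."""
    data = Path(data_dir)
    protocol = ProtocolSpec.from_yaml(data / "protocol.yaml")
    ann = synthetic.read_annotation_csv(data / "annotation.csv")
    tables = []
    for raw in sorted(data.glob("raw_*.csv")):
        stem = raw.stem[len("raw_"):]
        pid, site = stem.rsplit("_", 1) if stem.count("_") == 1 else \
            (stem.split("_")[0], "_".join(stem.split("_")[1:]))
        sig = synthetic.read_raw_csv(raw, protocol.sample_rate_hz)
        tables.append(metrics.epoch_table_for_signal(
            sig, ann[ann["participant"] == pid], pid, site,
            epoch_s=epoch_s, trim_s=trim_s, target_s=target_s))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out_csv, index=False)
    return table


def stage_mets(data_dir, epochs_csv, out_epochs_csv, out_mets_csv,
               met_constant: float = calorimetry.MET_CONSTANT_OLDER_ADULTS,
               sd_mult: float = 2.0, window_s: float = 120.0) -> pd.DataFrame:
    """Breath CSVs -> per-bout METs; intensity classes joined into the epoch CSV."""
    data = Path(data_dir)
    ann = synthetic.read_annotation_csv(data / "annotation.csv")
    participants = pd.read_csv(data / "participants.csv").set_index("id")
    epochs = pd.read_csv(epochs_csv, parse_dates=["epoch_start"])
    met_parts = []
    for pid, sub_ann in ann.groupby("participant"):
        breaths = synthetic.read_breath_csv(data / f"breath_{pid}.csv")
        met_parts.append(calorimetry.activity_mets(
            breaths, sub_ann, participants.loc[pid, "body_mass_kg"],
            met_constant=met_constant, sd_mult=sd_mult, met_window_s=window_s))
    mets = pd.concat(met_parts, ignore_index=True)
    mets.to_csv(out_mets_csv, index=False)
    labelled = epochs.merge(
        mets[["participant", "activity", "met", "intensity_class", "usable"]],
        on=["participant", "activity"], how="left")
    labelled = labelled[labelled["usable"].fillna(False)].drop(columns="usable")
    labelled.to_csv(out_epochs_csv, index=False)
    return labelled


def stage_calibrate(epochs_csv, out_report_csv, out_bundle_json,
                    epoch_s: int = 5) -> pd.DataFrame:
    epochs = pd.read_csv(epochs_csv)
    report, bundle, _ = calibration.calibrate_cutpoints(epochs, epoch_s=epoch_s)
    report.to_csv(out_report_csv, index=False)
    with open(out_bundle_json, "w") as fh:
        json.dump(bundle, fh, indent=2)
    return report


def stage_crossval(epochs_csv, bundle_json, out_csv,
                   epoch_s: int = 5) -> pd.DataFrame:
    bundle_path = Path(bundle_json)
    if not bundle_path.exists():
        raise FileNotFoundError(
            f"cut-point bundle {bundle_json} not found; run the 'calibrate' "
            "stage first")
    with open(bundle_path) as fh:
        bundle = json.load(fh)
    epochs = pd.read_csv(epochs_csv)
    sites = set(epochs["site"].unique())
    bundle = {"epoch_s": bundle["epoch_s"],
              "cutpoints": [cp for cp in bundle["cutpoints"]
                            if cp["site"] in sites]}
    results = crossval.apply_cutpoints(epochs, bundle, epoch_s=epoch_s)
    results.to_csv(out_csv, index=False)
    return results


__all__ = [
    "label_participant_epochs", "build_labelled_epochs", "run_demo",
    "DemoResult", "compare_metric_aucs",
    "stage_simulate", "stage_metrics", "stage_mets",
    "stage_calibrate", "stage_crossval", "PROTOCOLS", "EPOCH_COLUMNS",
]
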