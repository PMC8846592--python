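"""HDF5 / CSV persistence for synthetic sessions.

Layout of one session file:

    /lfp             trials x channels x time, mV
    /extracortical   trials x time
    /meta            depths_mm, sample_rate, array_onset_index (+ provenance)
    /trials          columns of the behavioural table
    /truth           latent component templates, per-trial gains, boundary,
                     column color preference, noiseless extracortical trace

Datasets are written with ``track_times=False`` so a fixed generator seed
yields a byte-identical file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .session import GroundTruth, SessionRecording, TRIAL_COLUMNS, validate_trial_table


def _write_ds(group: h5py.Group, name: str, data) -> None:
    group.create_dataset(name, data=data, track_times=False)


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_session(
    path,
    recording: SessionRecording,
    trials: pd.DataFrame,
    truth: Optional[GroundTruth] = None,
    config_dict: Optional[dict] = None,
) -> None:
    trials = validate_trial_table(trials, recording.n_trials)
    with h5py.File(path, "w", libver="earliest", track_order=False) as f:
        _write_ds(f, "lfp", recording.lfp)
        _write_ds(f, "extracortical", recording.extracortical)
        meta = f.create_group("meta")
        _write_ds(meta, "depths_mm", recording.depths)
        _write_ds(meta, "sample_rate", recording.sample_rate)
        _write_ds(meta, "array_onset_index", recording.array_onset_index)
        if config_dict is not None:
            blob = json.dumps(config_dict, sort_keys=True)
            _write_ds(meta, "config_json", np.bytes_(blob.encode()))
            _write_ds(meta, "config_hash", np.bytes_(config_hash(config_dict).encode()))
        tg = f.create_group("trials")
        _write_ds(tg, "trial_id", trials["trial_id"].to_numpy(np.int64))
        _write_ds(tg, "target_in_rf", trials["target_in_rf"].to_numpy(np.int8))
        _write_ds(
            tg,
            "target_hemifield",
            trials["target_hemifield"].to_numpy(dtype="S6"),
        )
        _write_ds(tg, "rf_color", trials["rf_color"].to_numpy(dtype="S6"))
        _write_ds(tg, "saccade_time_ms", trials["saccade_time_ms"].to_numpy(float))
        _write_ds(tg, "correct", trials["correct"].to_numpy(np.int8))
        if truth is not None:
            gt = f.create_group("truth")
            comps = gt.create_group("component_maps")
            for name, arr in truth.component_maps.items():
                _write_ds(comps, name, arr)
            if truth.component_gains is not None:
                gains = gt.create_group("component_gains")
                for col in truth.component_gains.columns:
                    _write_ds(gains, col, truth.component_gains[col].to_numpy(float))
            _write_ds(gt, "boundary_channel", truth.boundary_channel)
            _write_ds(gt, "column_color_pref", np.bytes_(truth.column_color_pref.encode()))
            if truth.attention_gain_applied is not None:
                _write_ds(gt, "attention_gain_applied", truth.attention_gain_applied)
            if truth.clean_extracortical is not None:
                _write_ds(gt, "clean_extracortical", truth.clean_extracortical)


def read_session(path) -> tuple[SessionRecording, pd.DataFrame, Optional[GroundTruth]]:
    with h5py.File(path, "r") as f:
        recording = SessionRecording(
            lfp=f["lfp"][()],
            extracortical=f["extracortical"][()],
            depths=f["meta/depths_mm"][()],
            sample_rate=float(f["meta/sample_rate"][()]),
            array_onset_index=int(f["meta/array_onset_index"][()]),
        )
        tg = f["trials"]
        trials = pd.DataFrame(
            {
                "trial_id": tg["trial_id"][()],
                "target_in_rf": tg["target_in_rf"][()].astype(bool),
                "target_hemifield": [s.decode() for s in tg["target_hemifield"][()]],
                "rf_color": [s.decode() for s in tg["rf_color"][()]],
                "saccade_time_ms": tg["saccade_time_ms"][()],
                "correct": tg["correct"][()].astype(bool),
            }
        )
        truth = None
        if "truth" in f:
            gt = f["truth"]
            gains = None
            if "component_gains" in gt:
                gains = pd.DataFrame(
                    {k: gt["component_gains"][k][()] for k in gt["component_gains"]}
                )
            truth = GroundTruth(
                component_maps={k: gt["component_maps"][k][()] for k in gt["component_maps"]},
                component_gains=gains,
                boundary_channel=int(gt["boundary_channel"][()]),
                column_color_pref=gt["column_color_pref"][()].tobytes().decode(),
                attention_gain_applied=(
                    gt["attention_gain_applied"][()] if "attention_gain_applied" in gt else None
                ),
                clean_extracortical=(
                    gt["clean_extracortical"][()] if "clean_extracortical" in gt else None
                ),
            )
    return recording, trials, truth


def export_trials_csv(path, trials: pd.DataFrame) -> None:
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(Path(path), index=False)
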