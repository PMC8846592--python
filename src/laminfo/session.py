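"""In-memory containers for a laminar recording session.

A session couples a trial-structured laminar LFP (trials x channels x time),
one extracortical potential channel (trials x time), the probe geometry, and
a per-trial behavioural table.  Synthetic sessions additionally carry the
generator's ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

def _as_float(x: np.ndarray) -> np.ndarray:
    """View as a floating array without upcasting float32 signals."""
    arr = np.asarray(x)
    return arr if np.issubdtype(arr.dtype, np.floating) else arr.astype(float)


TRIAL_COLUMNS = [
    "trial_id",
    "target_in_rf",
    "target_hemifield",
    "rf_color",
    "saccade_time_ms",
    "correct",
]


@dataclass
class SessionRecording:
    """Trial-structured laminar LFP plus one extracortical channel."""

    lfp: np.ndarray              # (n_trials, n_channels, n_time), mV
    extracortical: np.ndarray    # (n_trials, n_time)
    depths: np.ndarray           # (n_channels,) mm, ordered, uniform spacing
    sample_rate: float           # Hz
    array_onset_index: int       # sample index of t = 0

    def __post_init__(self) -> None:
        # float32 signal arrays are kept as-is (large sessions)
        self.lfp = _as_float(self.lfp)
        self.extracortical = _as_float(self.extracortical)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be (trials, channels, time)")
        if self.extracortical.shape != (self.lfp.shape[0], self.lfp.shape[2]):
            raise ValueError("extracortical must be (trials, time) matching lfp")
        if self.depths.shape != (self.lfp.shape[1],):
            raise ValueError("one depth per channel required")
        steps = np.diff(self.depths)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("channel spacing must be uniform")
        if self.array_onset_index * 1000.0 / self.sample_rate < 300.0 - 1e-9:
            raise ValueError("recording must cover >=300 ms before array onset")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[2]

    @property
    def spacing(self) -> float:
        return float(self.depths[1] - self.depths[0])

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sample_rate
        return (np.arange(self.n_samples) - self.array_onset_index) * dt

    def time_index(self, t_ms: float) -> int:
        """Nearest sample index to a time in ms relative to array onset."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


def validate_trial_table(trials: pd.DataFrame, n_trials: Optional[int] = None) -> pd.DataFrame:
    """Check the behavioural table and return it with canonical dtypes."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    out = trials.copy()
    out["target_in_rf"] = out["target_in_rf"].astype(bool)
    out["correct"] = out["correct"].astype(bool)
    bad = set(out["rf_color"]) - {"red", "green"}
    if bad:
        raise ValueError(f"unknown rf_color labels: {sorted(bad)}")
    bad = set(out["target_hemifield"]) - {"contra", "ipsi"}
    if bad:
        raise ValueError(f"unknown target_hemifield labels: {sorted(bad)}")
    if (out["saccade_time_ms"] <= 0).any():
        raise ValueError("saccade times must be positive (ms after array onset)")
    if n_trials is not None and len(out) != n_trials:
        raise ValueError("trial table length does not match recording")
    return out


@dataclass
class GroundTruth:
    """Latent structure of a synthetic session.

    ``component_maps`` holds the two zero-sum sink/source pair templates
    (interior depths x time); per-trial latent CSD is their gain-weighted sum,
    reconstructable via :meth:`latent_csd`.
    """

    component_maps: dict[str, np.ndarray] = field(default_factory=dict)
    component_gains: Optional[pd.DataFrame] = None   # per trial, one col per map
    component_info: Optional[pd.DataFrame] = None    # centers, widths, onsets
    boundary_channel: int = 0                        # deepest L4 channel (full probe)
    column_color_pref: str = "none"
    attention_gain_applied: Optional[np.ndarray] = None  # per-trial extragranular factor
    clean_extracortical: Optional[np.ndarray] = None     # (n_trials, n_time), noiseless

    def latent_csd(self, trial: int) -> np.ndarray:
        """Reconstruct one trial's latent CSD (interior depths x time)."""
        if self.component_gains is None:
            raise ValueError("ground truth carries no per-trial gains")
        total = None
        for name, tpl in self.component_maps.items():
            g = float(self.component_gains[name].iloc[trial])
            total = g * tpl if total is None else total + g * tpl
        return total
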