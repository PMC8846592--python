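"""Configuration objects for the synthetic-session generator and the pipeline.

Units follow the recording conventions throughout the package: depth in mm
(increasing into cortex), time in ms relative to search-array onset, voltages
in mV, conductivity in S/m.  The extracortical forward model omits its global
scale factor, so extracortical amplitudes share the (arbitrary but internally
consistent) units of the forward sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

VALID_COLORS = ("red", "green")
VALID_PREFS = ("red", "green", "none")


@dataclass
class SynthConfig:
    """Parameters of one synthetic laminar recording session.

    The defaults emulate a V4 column recorded with a 32-channel laminar probe
    (0.1 mm spacing, 1 kHz analysis rate): an early granular (L4) input sink
    ~50 ms after array onset, a gradually rising, sustained supragranular
    (L2/3) sink from ~100 ms paired with an infragranular (L5/6) return
    source, attention (target-in-receptive-field) modulation confined to that
    extragranular sink/source pair, columnar color-selective gamma power, and
    an extracortical channel driven by the column's currents through a
    distance-weighted forward sum plus independent background and noise.
    """

    n_trials_per_condition: int = 150
    n_channels: int = 32
    spacing: float = 0.1                  # mm between adjacent contacts
    sample_rate: float = 1000.0           # Hz
    time_range: tuple[float, float] = (-300.0, 400.0)   # ms re array onset
    conductivity: float = 0.4             # S/m

    # True laminar geometry (full-probe channel indices, 0 = shallowest).
    # boundary_channel is the deepest channel of L4 (the L4/5 boundary).
    boundary_channel: int = 16

    # Granular (L4) component: brief feedforward input sink.
    l4_sink_onset: float = 50.0           # ms
    l4_time_constant: float = 20.0        # ms, alpha-function rise/decay
    l4_amplitude: float = 0.6             # CSD units (sigma * mV / mm^2)
    l4_depth_sigma: float = 0.15          # mm

    # Extragranular component: sustained L2/3 sink + L5/6 source.
    l23_sink_onset: float = 120.0         # ms
    l23_rise: float = 70.0                # ms, linear ramp to plateau
    l23_amplitude: float = 0.5
    l23_depth_sigma: float = 0.18         # mm

    # Attention and color coupling.
    attention_gain: float = 0.8
    coupling_gain_preferred: float = 0.5
    column_color_pref: str = "red"
    gamma_power_ratio: float = 2.0        # preferred/non-preferred band power
    gamma_amplitude: float = 0.05         # mV, non-preferred-color RMS scale
    gamma_band: tuple[float, float] = (30.0, 150.0)   # Hz
    gamma_window: tuple[float, float] = (50.0, 250.0)  # ms, active span

    # Trial-to-trial variability and noise.
    amplitude_jitter_extragranular: float = 0.15
    amplitude_jitter_granular: float = 0.05
    noise_sd_lfp: float = 0.007           # mV per channel
    noise_sd_extracortical: float = 0.05  # forward units
    noise_band_hz: float = 100.0          # recording bandwidth of the noise
    background_amplitude: float = 0.10    # forward units, <=30 Hz drift

    # Behaviour.
    saccade_median: float = 225.0         # ms
    saccade_sd: float = 50.0              # ms
    saccade_min: float = 100.0            # ms, truncation floor
    correct_rate: float = 0.9

    # Extracortical electrode position: this far above the shallowest contact.
    extracortical_offset: float = 0.3     # mm

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 17:
            raise ValueError("need at least 17 channels for laminar coverage")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not self.l4_sink_onset < self.l23_sink_onset:
            raise ValueError("granular sink must precede the extragranular sink")
        t0, t1 = self.time_range
        if not (t0 <= -300.0 and t1 > self.l23_sink_onset):
            raise ValueError("time_range must cover a >=300 ms baseline and the response")
        if not (t0 < self.l4_sink_onset < t1):
            raise ValueError("component onsets must lie inside time_range")
        if self.attention_gain < 0:
            raise ValueError("attention_gain must be non-negative")
        if self.column_color_pref not in VALID_PREFS:
            raise ValueError(f"column_color_pref must be one of {VALID_PREFS}")
        if self.gamma_power_ratio < 1:
            raise ValueError("gamma_power_ratio must be >= 1")
        if not 0 < self.gamma_band[0] < self.gamma_band[1] < self.sample_rate / 2:
            raise ValueError("gamma band must lie inside (0, Nyquist)")
        lo, hi = 1, self.n_channels - 2
        if not (lo + 9 <= self.boundary_channel and self.boundary_channel + 5 <= hi):
            raise ValueError("boundary_channel leaves no room for 15 interior depths")
        if not 0 < self.correct_rate <= 1:
            raise ValueError("correct_rate must be in (0, 1]")

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sample_rate
        return np.arange(self.time_range[0], self.time_range[1] + 0.5 * dt, dt)

    @property
    def n_samples(self) -> int:
        return self.times_ms.size

    @property
    def array_onset_index(self) -> int:
        return int(np.argmin(np.abs(self.times_ms)))

    @property
    def depths_mm(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.spacing

    def to_dict(self) -> dict:
        d = asdict(self)
        d["time_range"] = list(self.time_range)
        return d


@dataclass
class PipelineConfig:
    """Parameters steering the end-to-end multi-session pipeline."""

    n_sessions: int = 5
    synth: SynthConfig = field(default_factory=SynthConfig)

    # Analysis parameters (shared across sessions).
    n_bins: int = 5
    lag_ms: float = 10.0
    n_shuffle: int = 5000
    alpha: float = 0.05
    persistence_ms: float = 10.0
    consensus_fraction: float = 0.75
    n2pc_window: tuple[float, float] = (150.0, 190.0)
    info_window: tuple[float, float] = (100.0, 250.0)
    baseline_window: tuple[float, float] = (-300.0, 0.0)
    clip_margin_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.lag_ms <= 0:
            raise ValueError("lag must be positive")
        if self.n_shuffle < 100:
            raise ValueError("need at least 100 shuffles")
        if not 0 < self.consensus_fraction < 1:
            raise ValueError("consensus_fraction must be in (0, 1)")
        if self.n_sessions < 1:
            raise ValueError("need at least one session")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth_raw = raw.pop("synth", {})
        if "time_range" in synth_raw:
            synth_raw["time_range"] = tuple(synth_raw["time_range"])
        for key in ("n2pc_window", "info_window", "baseline_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=SynthConfig(**synth_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = self.synth.to_dict()
        for key in ("n2pc_window", "info_window", "baseline_window"):
            d[key] = list(d[key])
        return d
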