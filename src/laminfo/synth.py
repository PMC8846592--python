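"""Synthetic laminar sessions with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a 32-channel laminar LFP at 0.1 mm spacing and 1 kHz with a >=300 ms
pre-array baseline, an early granular (L4) input sink ~50 ms after array
onset, a gradually rising, sustained supragranular (L2/3) sink from ~100 ms
paired with an infragranular (L5/6) source, attention modulation confined to
that extragranular pair, columnar color-selective gamma power, and one
extracortical channel built from the column's currents by the same
distance-weighted forward sum the analysis uses, plus independent background
and white noise.

Latent CSD components are spatiotemporal Gaussians grouped into zero-sum
sink/source pairs, so the depth integral of the latent CSD vanishes at every
timepoint (dipole closure) and the laminar LFP follows by exact double
integration of the second-difference operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .config import SynthConfig, VALID_COLORS
from .forward import ForwardGeometry, erp_from_csd
from .session import GroundTruth, SessionRecording


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the 2x2 design: attention x color in the receptive field."""

    target_in_rf: bool
    rf_color: str

    def __post_init__(self) -> None:
        if self.rf_color not in VALID_COLORS:
            raise ValueError(f"unknown color label: {self.rf_color!r}")


def _alpha_envelope(times_ms: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Synaptic-style alpha function, peak 1 at onset + tau, zero before onset."""
    u = (times_ms - onset) / tau
    env = np.where(u > 0, u * np.exp(1.0 - u), 0.0)
    return env


def _ramp_envelope(times_ms: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """Linear ramp from onset to plateau (gradually arising, sustained)."""
    return np.clip((times_ms - onset) / rise, 0.0, 1.0)


def _pair_profile(
    interior_channels: np.ndarray,
    sink_center: float,
    source_center: float,
    sink_sigma_ch: float,
    source_sigma_ch: float,
) -> np.ndarray:
    """Zero-sum sink/source depth profile with unit-peak sink.

    The source Gaussian is rescaled so its depth sum matches the sink's,
    enforcing dipole closure exactly.
    """
    gs = np.exp(-0.5 * ((interior_channels - sink_center) / sink_sigma_ch) ** 2)
    gr = np.exp(-0.5 * ((interior_channels - source_center) / source_sigma_ch) ** 2)
    gr = gr * (gs.sum() / gr.sum())
    return -gs + gr


def component_maps(config: SynthConfig) -> dict[str, np.ndarray]:
    """The two latent sink/source pair templates (interior depths x time).

    ``granular``: brief L4 input sink with a deep return source.
    ``extragranular``: sustained L2/3 sink paired with an L5/6 source; this
    is the pair that attention modulates.
    """
    times = config.times_ms
    interior = np.arange(1, config.n_channels - 1, dtype=float)
    b = config.boundary_channel
    sig_ch = config.l4_depth_sigma / config.spacing
    sig_eg = config.l23_depth_sigma / config.spacing

    gran_depth = _pair_profile(interior, b - 2, b + 2, sig_ch, sig_ch * 1.3)
    gran = config.l4_amplitude * np.outer(
        gran_depth, _alpha_envelope(times, config.l4_sink_onset, config.l4_time_constant)
    )

    eg_depth = _pair_profile(interior, b - 7, b + 3, sig_eg, sig_eg * 1.2)
    eg = config.l23_amplitude * np.outer(
        eg_depth, _ramp_envelope(times, config.l23_sink_onset, config.l23_rise)
    )
    return {"granular": gran, "extragranular": eg}


def attention_factor(condition: TrialCondition, config: SynthConfig) -> float:
    """Multiplicative gain on the extragranular pair for this condition.

    Distractor-in-RF trials keep the base amplitude.  Target-in-RF trials
    scale the pair by (1 + attention_gain * c) where the color-coupling
    factor c is 1, or (1 + coupling_gain_preferred) when the RF color
    matches the column's preference.
    """
    if not condition.target_in_rf:
        return 1.0
    coupled = (
        config.column_color_pref != "none"
        and condition.rf_color == config.column_color_pref
    )
    c = (1.0 + config.coupling_gain_preferred) if coupled else 1.0
    return 1.0 + config.attention_gain * c


def build_csd_truth(condition: TrialCondition, config: SynthConfig) -> np.ndarray:
    """Latent CSD (interior depths x time) for one trial condition.

    Contains the granular sink from ``l4_sink_onset`` and the extragranular
    sink/source pair from ``l23_sink_onset``; only the latter carries the
    attention gain.  Depth-integral is zero at every timepoint.
    """
    maps = component_maps(config)
    return maps["granular"] + attention_factor(condition, config) * maps["extragranular"]


def csd_to_lfp(latent_csd: np.ndarray, spacing: float, conductivity: float) -> np.ndarray:
    """Laminar LFP whose second spatial derivative reproduces the CSD.

    Inverts CSD = -sigma * D2[x] / z^2 by double cumulative summation with
    both integration constants set to zero, so the two shallowest channels
    carry the (zero) affine extension.  Input has interior depths on axis
    -2; output gains two boundary channels.
    """
    latent_csd = np.asarray(latent_csd, dtype=float)
    n_int = latent_csd.shape[-2]
    if n_int < 1:
        raise ValueError("need at least one interior depth (3 channels)")
    g = -latent_csd * spacing**2 / conductivity       # second differences
    c2 = np.cumsum(np.cumsum(g, axis=-2), axis=-2)
    shape = list(latent_csd.shape)
    shape[-2] = n_int + 2
    lfp = np.zeros(shape, dtype=float)
    lfp[..., 2:, :] = c2
    return lfp


def _lowpass_background(
    white: np.ndarray, sample_rate: float, amplitude: float, corner_hz: float = 30.0
) -> np.ndarray:
    """Slow (<= corner) background drift scaled to a target RMS amplitude."""
    sos = sps.butter(4, corner_hz, btype="lowpass", fs=sample_rate, output="sos")
    slow = sps.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(slow**2))
    if rms == 0:
        return slow
    return slow * (amplitude / rms)


def _band_limited_noise(
    shape: tuple[int, ...],
    rng: np.random.Generator,
    sample_rate: float,
    sd: float,
    corner_hz: float,
    dtype=np.float64,
) -> np.ndarray:
    """Recording noise band-limited to the acquisition bandwidth.

    White noise low-passed at ``corner_hz`` (the 1-100 Hz hardware filter of
    the emulated system) and rescaled so the per-sample SD equals ``sd``.
    """
    white = rng.standard_normal(shape, dtype=np.float32)
    if corner_hz >= sample_rate / 2:
        out = white
    else:
        sos = sps.butter(4, corner_hz, btype="lowpass", fs=sample_rate, output="sos")
        out = sps.sosfiltfilt(sos, white, axis=-1).astype(np.float32)
        out /= np.float32(out.std())
    out *= np.float32(sd)
    return out.astype(dtype, copy=False)


def forward_extracortical(
    latent_csd: np.ndarray,
    geometry: ForwardGeometry,
    background_amplitude: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Extracortical trace: forward sum + independent background + white noise.

    With ``background_amplitude`` and ``noise_sd`` both zero the output is
    exactly the forward model's trace; the background component is
    statistically independent of the local column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = erp_from_csd(latent_csd, geometry)
    out = clean.copy()
    if background_amplitude > 0:
        out = out + _lowpass_background(
            rng.standard_normal(clean.shape), sample_rate, background_amplitude
        )
    if noise_sd > 0:
        out = out + noise_sd * rng.standard_normal(clean.shape)
    return out


def gamma_component(
    rf_colors: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial color-selective gamma-band trace, shared across channels.

    Band-limited (30-150 Hz) noise, tapered to the response span, normalized
    trial-wise so that mean band power over 75-200 ms equals
    gamma_amplitude^2 / 2 for the non-preferred color and gamma_power_ratio
    times that for the preferred color.  Because the same trace is added to
    every channel, its second spatial derivative — hence its CSD footprint —
    is exactly zero.
    """
    lo, hi = config.gamma_band
    if hi >= config.sample_rate / 2:
        raise ValueError("gamma band outside Nyquist")
    times = config.times_ms
    n_trials = len(rf_colors)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=config.sample_rate, output="sos")
    raw = sps.sosfiltfilt(sos, rng.standard_normal((n_trials, times.size)), axis=-1)
    taper = np.zeros(times.size)
    w0, w1 = config.gamma_window
    active = (times >= w0) & (times <= w1)
    n_active = int(active.sum())
    if n_active > 8:
        taper[active] = sps.windows.tukey(n_active, alpha=0.5)
    raw = raw * taper[None, :]
    # trial-wise RMS normalization inside the response window used for CSI
    resp = (times >= 75.0) & (times <= 200.0)
    rms = np.sqrt(np.mean(raw[:, resp] ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    unit = raw / rms
    amp = np.full(n_trials, config.gamma_amplitude)
    if config.column_color_pref != "none":
        preferred = np.asarray(rf_colors) == config.column_color_pref
        amp = np.where(preferred, amp * np.sqrt(config.gamma_power_ratio), amp)
    return unit * amp[:, None]


def add_gamma_selectivity(
    lfp: np.ndarray,
    rf_colors: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add the column's color-selective gamma component to a laminar LFP."""
    gamma = gamma_component(rf_colors, config, rng)
    return lfp + gamma[:, None, :]


def default_geometry(config: SynthConfig) -> ForwardGeometry:
    return ForwardGeometry.for_interior_channels(
        config.depths_mm, offset_above=config.extracortical_offset
    )


def generate_session(
    config: SynthConfig,
) -> tuple[SessionRecording, pd.DataFrame, GroundTruth]:
    """One synthetic session: recording, trial table, and ground truth.

    The design is balanced: target-in-RF / distractor-in-RF crossed with
    red / green in the RF, ``n_trials_per_condition`` each, interleaved in
    random order.  Saccade times are truncated-normal (median ~
    ``saccade_median``, floor ``saccade_min``).  Deterministic under a fixed
    seed.
    """
    if config.n_trials_per_condition < 10:
        warnings.warn(
            "fewer than 10 trials per condition: information estimates unreliable",
            UserWarning,
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # --- trial table -------------------------------------------------------
    cells = [
        TrialCondition(tin, col)
        for tin in (True, False)
        for col in VALID_COLORS
    ]
    conditions = [c for c in cells for _ in range(config.n_trials_per_condition)]
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]
    n_trials = len(conditions)

    a = (config.saccade_min - config.saccade_median) / config.saccade_sd
    saccades = stats.truncnorm.rvs(
        a, np.inf, loc=config.saccade_median, scale=config.saccade_sd,
        size=n_trials, random_state=rng,
    )
    correct = rng.random(n_trials) < config.correct_rate

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "target_in_rf": [c.target_in_rf for c in conditions],
            "target_hemifield": [
                "contra" if c.target_in_rf else "ipsi" for c in conditions
            ],
            "rf_color": [c.rf_color for c in conditions],
            "saccade_time_ms": saccades,
            "correct": correct,
        }
    )

    # --- latent CSD and laminar LFP ---------------------------------------
    maps = component_maps(config)
    att = np.array([attention_factor(c, config) for c in conditions])
    jitter_g = np.clip(
        1.0 + config.amplitude_jitter_granular * rng.standard_normal(n_trials), 0.1, None
    )
    jitter_e = np.clip(
        1.0 + config.amplitude_jitter_extragranular * rng.standard_normal(n_trials), 0.1, None
    )
    gains = pd.DataFrame({"granular": jitter_g, "extragranular": att * jitter_e})

    lfp_templates = {
        name: csd_to_lfp(m, config.spacing, config.conductivity)
        for name, m in maps.items()
    }
    # float32 signal arrays and in-place accumulation: sessions are large
    lfp = np.einsum(
        "i,ct->ict",
        gains["granular"].to_numpy(np.float32),
        lfp_templates["granular"].astype(np.float32),
    )
    lfp += np.einsum(
        "i,ct->ict",
        gains["extragranular"].to_numpy(np.float32),
        lfp_templates["extragranular"].astype(np.float32),
    )
    gamma = gamma_component(trials["rf_color"].to_numpy(), config, rng).astype(np.float32)
    lfp += gamma[:, None, :]
    if config.noise_sd_lfp > 0:
        lfp += _band_limited_noise(
            lfp.shape, rng, config.sample_rate, config.noise_sd_lfp,
            config.noise_band_hz, dtype=np.float32,
        )

    # --- extracortical channel --------------------------------------------
    geometry = default_geometry(config)
    fwd_templates = {name: erp_from_csd(m, geometry) for name, m in maps.items()}
    clean = (
        gains["granular"].to_numpy()[:, None] * fwd_templates["granular"][None]
        + gains["extragranular"].to_numpy()[:, None] * fwd_templates["extragranular"][None]
    )
    extracortical = clean.copy()
    if config.background_amplitude > 0:
        extracortical = extracortical + _lowpass_background(
            rng.standard_normal(clean.shape), config.sample_rate, config.background_amplitude
        )
    if config.noise_sd_extracortical > 0:
        extracortical = extracortical + _band_limited_noise(
            clean.shape, rng, config.sample_rate, config.noise_sd_extracortical,
            config.noise_band_hz,
        )

    recording = SessionRecording(
        lfp=lfp,
        extracortical=extracortical,
        depths=config.depths_mm,
        sample_rate=config.sample_rate,
        array_onset_index=config.array_onset_index,
    )
    truth = GroundTruth(
        component_maps=maps,
        component_gains=gains,
        component_info=pd.DataFrame(
            {
                "component": ["granular", "extragranular"],
                "sink_center_channel": [
                    config.boundary_channel - 2,
                    config.boundary_channel - 7,
                ],
                "source_center_channel": [
                    config.boundary_channel + 2,
                    config.boundary_channel + 3,
                ],
                "onset_ms": [config.l4_sink_onset, config.l23_sink_onset],
                "amplitude": [config.l4_amplitude, config.l23_amplitude],
                "attention_modulated": [False, True],
            }
        ),
        boundary_channel=config.boundary_channel,
        column_color_pref=config.column_color_pref,
        attention_gain_applied=att,
        clean_extracortical=clean,
    )
    return recording, trials, truth


def synthetic_broadband(
    duration_ms: float = 500.0,
    sample_rate: float = 24000.0,
    burst_window_ms: tuple[float, float] = (100.0, 200.0),
    burst_band_hz: tuple[float, float] = (400.0, 2000.0),
    burst_amplitude: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """High-rate broadband trace with an embedded spiking-band burst.

    Returns (times_ms, trace).  This exists to exercise the MUA derivation
    chain, which needs a sample rate of at least 6 kHz.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * sample_rate / 1000.0))
    times = np.arange(n) * 1000.0 / sample_rate
    trace = noise_sd * rng.standard_normal(n)
    sos = sps.butter(4, burst_band_hz, btype="bandpass", fs=sample_rate, output="sos")
    burst = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(burst**2))
    if rms > 0:
        burst = burst * (burst_amplitude / rms)
    active = (times >= burst_window_ms[0]) & (times <= burst_window_ms[1])
    trace[active] += burst[active]
    return times, trace
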