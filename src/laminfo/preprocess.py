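"""Trial-level signal conditioning shared by all downstream stages.

Conventions: traces are (..., n_time) arrays at a uniform sample rate; times
are ms relative to array onset; missing (clipped) samples are NaN and every
averaging step counts available trials per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


def baseline_correct(
    traces: np.ndarray, times_ms: np.ndarray, window: tuple[float, float] = (-300.0, 0.0)
) -> np.ndarray:
    """Subtract each trace's mean over the pre-array window.

    The default window is the 300 ms preceding array onset; a shorter window
    (e.g. [-50, 0] ms) can be passed for scalp-style traces.  Idempotent and
    invariant to constant offsets.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    traces = np.asarray(traces)
    if not np.issubdtype(traces.dtype, np.floating):
        traces = traces.astype(float)
    if window[0] < times_ms[0] - 1e-9 or window[1] > times_ms[-1] + 1e-9:
        raise ValueError("baseline window outside the recorded span")
    sel = (times_ms >= window[0]) & (times_ms < window[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    return traces - np.nanmean(traces[..., sel], axis=-1, keepdims=True)


@dataclass
class ClippedTraces:
    """Traces with post-saccade samples marked missing (NaN)."""

    traces: np.ndarray
    n_available: np.ndarray       # per-timepoint available-trial counts
    fully_clipped: np.ndarray     # trials with no post-onset samples left


def clip_at_saccade(
    traces: np.ndarray,
    saccade_times_ms: np.ndarray,
    times_ms: np.ndarray,
    margin_ms: float = 10.0,
) -> ClippedTraces:
    """Mark samples from ``saccade - margin`` onward as missing, per trial.

    Retained samples are never altered.  Trials clipped back to (or before)
    array onset are flagged rather than dropped.
    """
    if margin_ms < 0:
        raise ValueError("margin must be non-negative")
    traces = np.array(traces, copy=True)
    if not np.issubdtype(traces.dtype, np.floating):
        traces = traces.astype(float)
    times_ms = np.asarray(times_ms, dtype=float)
    sacc = np.asarray(saccade_times_ms, dtype=float)
    if sacc.shape[0] != traces.shape[0]:
        raise ValueError("one saccade time per trial required")
    cutoff = sacc - margin_ms
    missing = times_ms[None, :] >= cutoff[:, None]       # (n_trials, n_time)
    mask = missing.reshape(missing.shape[0], *([1] * (traces.ndim - 2)), missing.shape[1])
    traces[np.broadcast_to(mask, traces.shape)] = np.nan
    post = times_ms >= 0
    fully = (missing[:, post]).all(axis=1) if post.any() else np.zeros(len(sacc), bool)
    return ClippedTraces(
        traces=traces,
        n_available=(~missing).sum(axis=0),
        fully_clipped=fully,
    )


def _bandpass_sos(band: tuple[float, float], sample_rate: float, order: int = 4):
    lo, hi = band
    nyq = sample_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def bandpass(traces: np.ndarray, band: tuple[float, float], sample_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    sos = _bandpass_sos(band, sample_rate, order)
    return signal.sosfiltfilt(sos, np.asarray(traces, dtype=float), axis=-1)


def gamma_power(
    traces: np.ndarray,
    times_ms: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (30.0, 150.0),
    window: tuple[float, float] = (75.0, 200.0),
) -> np.ndarray:
    """Mean band-limited power over a response window.

    The trace is band-passed with a zero-phase 4th-order Butterworth filter,
    the analytic-signal envelope is squared and halved (so a pure in-band
    sinusoid of amplitude a yields a^2/2), and the result is averaged over
    the window.  Windows whose samples are entirely missing yield NaN.
    NaN samples (clipped tails) are zero-filled before filtering and their
    envelope samples excluded from the average.
    """
    traces = np.asarray(traces)
    if not np.issubdtype(traces.dtype, np.floating):
        traces = traces.astype(float)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= window[0]) & (times_ms <= window[1])
    if not sel.any():
        raise ValueError("response window contains no samples")
    nan_mask = np.isnan(traces)
    filled = np.where(nan_mask, 0.0, traces)
    filtered = bandpass(filled, band, sample_rate)
    env = np.abs(signal.hilbert(filtered, axis=-1))
    inst_power = 0.5 * env**2
    inst_power[nan_mask] = np.nan
    win_power = inst_power[..., sel]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # fully clipped windows
        out = np.nanmean(win_power, axis=-1)
    return out


def derive_mua(broadband: np.ndarray, sample_rate: float) -> np.ndarray:
    """Multiunit activity from a broadband trace.

    Four stages in order: low-pass at 3 kHz, high-pass at 300 Hz, full-wave
    rectification, low-pass at 150 Hz.  Requires a sample rate of at least
    6 kHz so the 3 kHz corner is below Nyquist.  Positively homogeneous:
    scaling the input by a > 0 scales the output by a.
    """
    if sample_rate < 6000.0:
        raise ValueError("MUA derivation requires a sample rate >= 6 kHz")
    x = np.asarray(broadband, dtype=float)
    sos_lp3k = signal.butter(4, 3000.0, btype="lowpass", fs=sample_rate, output="sos")
    sos_hp = signal.butter(4, 300.0, btype="highpass", fs=sample_rate, output="sos")
    sos_lp150 = signal.butter(4, 150.0, btype="lowpass", fs=sample_rate, output="sos")
    x = signal.sosfiltfilt(sos_lp3k, x, axis=-1)
    x = signal.sosfiltfilt(sos_hp, x, axis=-1)
    x = np.abs(x)
    return signal.sosfiltfilt(sos_lp150, x, axis=-1)


@dataclass
class TrialAverage:
    mean: np.ndarray
    ci_halfwidth: np.ndarray     # 95% normal-approximation halfwidth
    n_available: np.ndarray


def trial_average(traces: np.ndarray, selector: np.ndarray | None = None) -> TrialAverage:
    """Per-timepoint mean and 95% CI over available (unclipped) trials."""
    traces = np.asarray(traces, dtype=float)
    if selector is not None:
        sel = np.asarray(selector, dtype=bool)
        if sel.sum() == 0:
            raise ValueError("empty trial selection")
        traces = traces[sel]
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 trials to average")
    n = np.sum(~np.isnan(traces), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(traces, axis=0)
        sd = np.nanstd(traces, axis=0, ddof=1)
    ci = 1.96 * sd / np.sqrt(np.maximum(n, 1))
    ci = np.where(n >= 2, ci, np.nan)
    return TrialAverage(mean=mean, ci_halfwidth=ci, n_available=n)
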