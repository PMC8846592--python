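"""Current source density estimation and laminar compartment handling.

CSD is the discrete second spatial derivative of the laminar LFP,

    CSD(t, d) = -sigma * (x(t, d - z) + x(t, d + z) - 2 x(t, d)) / z**2

with x the extracellular voltage (mV), z the electrode spacing (mm) and
sigma the tissue conductivity (S/m).  Negative values are current sinks.
The estimate exists only on interior channels; the outermost channel at each
end is dropped (no padding by default).

Sessions are aligned across recordings by the granular (L4) input sink: the
earliest post-stimulus sink identifies L4, and depths are expressed relative
to the L4/5 boundary.  Each laminar compartment (L2/3, L4, L5/6) is the mean
of five contiguous sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

COMPARTMENTS = ("L2/3", "L4", "L5/6")
SITES_PER_COMPARTMENT = 5


@dataclass
class CSDStack:
    """Per-trial CSD over interior depths.

    ``csd`` has shape (n_trials, n_interior, n_time) in units of
    sigma * mV / mm^2.  Interior row ``k`` corresponds to full-probe channel
    ``k + 1``.
    """

    csd: np.ndarray
    spacing: float            # mm
    conductivity: float       # S/m
    sample_rate: float        # Hz
    array_onset_index: int
    boundary_channel: int | None = None   # full-probe index of deepest L4 site

    @property
    def n_interior(self) -> int:
        return self.csd.shape[-2]

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sample_rate
        return (np.arange(self.csd.shape[-1]) - self.array_onset_index) * dt

    def interior_row(self, channel: int) -> int:
        """Map a full-probe channel index to a CSD row."""
        row = channel - 1
        if not 0 <= row < self.n_interior:
            raise IndexError(f"channel {channel} is not an interior channel")
        return row


def compute_csd(lfp: np.ndarray, spacing: float, conductivity: float) -> np.ndarray:
    """Second-spatial-derivative CSD on interior channels.

    Parameters
    ----------
    lfp : ndarray
        (..., n_channels, n_time) laminar LFP in mV on uniformly spaced
        channels.
    spacing : float
        Interelectrode distance z in mm.
    conductivity : float
        Conductivity sigma in S/m.

    Returns
    -------
    ndarray with shape (..., n_channels - 2, n_time).
    """
    lfp = np.asarray(lfp)
    if not np.issubdtype(lfp.dtype, np.floating):
        lfp = lfp.astype(float)
    if lfp.shape[-2] < 3:
        raise ValueError("CSD needs at least 3 channels")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    upper = lfp[..., :-2, :]
    lower = lfp[..., 2:, :]
    mid = lfp[..., 1:-1, :]
    return -conductivity * (upper + lower - 2.0 * mid) / spacing**2


def csd_stack_from_lfp(
    lfp: np.ndarray,
    spacing: float,
    conductivity: float,
    sample_rate: float,
    array_onset_index: int,
) -> CSDStack:
    return CSDStack(
        csd=compute_csd(lfp, spacing, conductivity),
        spacing=spacing,
        conductivity=conductivity,
        sample_rate=sample_rate,
        array_onset_index=array_onset_index,
    )


def align_to_granular_sink(
    trial_averaged_csd: np.ndarray,
    times_ms: np.ndarray,
    *,
    threshold_sd: float = 4.0,
    search_window: tuple[float, float] = (25.0, 100.0),
    baseline_window: tuple[float, float] = (-300.0, 0.0),
    min_sink_duration_ms: float = 5.0,
) -> int:
    """Locate the L4/5 boundary from the earliest granular input sink.

    The earliest post-stimulus sink marks the granular input layer.  A
    channel "crosses" when its trial-averaged CSD drops below
    ``-threshold_sd`` times its own pre-array baseline SD (default 4: the
    search spans many correlated samples per channel, so a lower threshold
    admits frequent spurious crossings) inside the search
    window; the excursion must persist for ``min_sink_duration_ms`` (an
    input sink is sustained, a noise spike is not).  Among the channels
    crossing earliest (several can cross within the same sample), the one
    with the strongest sink at the crossing time — ties: the deeper
    channel — is taken as the centre of the 5-site L4 span, so the returned
    boundary, the deepest L4 channel, is that channel + 2.

    Parameters are in ms relative to array onset.  Returns the boundary as a
    full-probe channel index (interior row + 1).

    Raises
    ------
    RuntimeError if no channel crosses inside the window.
    """
    csd = np.asarray(trial_averaged_csd, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    if csd.ndim != 2 or csd.shape[1] != times.size:
        raise ValueError("expected (n_interior, n_time) trial-averaged CSD")
    base = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not base.any():
        raise ValueError("no baseline samples available for noise estimation")
    sd = np.nanstd(csd[:, base], axis=1)
    sd = np.where(sd > 0, sd, np.inf)
    win = (times >= search_window[0]) & (times <= search_window[1])
    win_idx = np.flatnonzero(win)
    below = csd[:, win_idx] < (-threshold_sd * sd[:, None])
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    need = max(1, int(round(min_sink_duration_ms / dt)))
    if need > 1 and below.shape[1] >= need:
        # a crossing counts only if sustained for `need` consecutive samples
        sustained = below[:, : below.shape[1] - need + 1].copy()
        for k in range(1, need):
            sustained &= below[:, k : below.shape[1] - need + 1 + k]
        below = sustained
    crossing_channels = np.flatnonzero(below.any(axis=1))
    if crossing_channels.size == 0:
        raise RuntimeError("no granular sink detected in the search window")
    first_cross = np.array([below[c].argmax() for c in crossing_channels])
    earliest = first_cross.min()
    candidates = crossing_channels[first_cross == earliest]
    amp = csd[candidates, win_idx[earliest]]
    strongest = amp == amp.min()                # most negative = strongest sink
    centre_row = int(candidates[strongest].max())   # then the deeper channel
    boundary_row = centre_row + SITES_PER_COMPARTMENT // 2
    return boundary_row + 1                     # full-probe channel index


def compartment_rows(boundary_channel: int, n_interior: int) -> dict[str, np.ndarray]:
    """Interior-row index sets for L2/3, L4, L5/6 given the L4/5 boundary.

    L4 is the boundary channel and the 4 channels above it; L2/3 the next 5
    above; L5/6 the 5 below.  Raises if the 15-site span leaves the interior.
    """
    b = boundary_channel - 1    # interior row of the boundary channel
    spans = {
        "L2/3": np.arange(b - 9, b - 4),
        "L4": np.arange(b - 4, b + 1),
        "L5/6": np.arange(b + 1, b + 6),
    }
    for name, rows in spans.items():
        if rows[0] < 0 or rows[-1] >= n_interior:
            raise ValueError(
                f"compartment {name} needs interior rows {rows[0]}..{rows[-1]} "
                f"but only 0..{n_interior - 1} exist"
            )
    return spans


def compartment_series(stack: CSDStack, boundary_channel: int | None = None) -> dict[str, np.ndarray]:
    """Per-trial compartment series: 5-site mean CSD for L2/3, L4, L5/6.

    Missing (clipped) samples propagate as NaN.  Returns a dict of
    (n_trials, n_time) arrays.
    """
    if boundary_channel is None:
        boundary_channel = stack.boundary_channel
    if boundary_channel is None:
        raise ValueError("stack is not aligned: no boundary channel")
    spans = compartment_rows(boundary_channel, stack.n_interior)
    return {name: stack.csd[:, rows, :].mean(axis=1) for name, rows in spans.items()}


@dataclass
class AttentionCSDDifference:
    """Target-minus-distractor CSD difference with a per-cell t-test mask."""

    difference: np.ndarray    # (n_interior, n_time)
    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray   # boolean, p < alpha (uncorrected)
    alpha: float


def attention_csd_difference(
    stack: CSDStack, target_in_rf: np.ndarray, alpha: float = 0.05
) -> AttentionCSDDifference:
    """Mean CSD difference (target-in-RF minus distractor-in-RF) per cell.

    Each (depth, time) cell gets a two-sample t-test across trials at
    ``alpha`` (uncorrected), matching the per-cell masking used for laminar
    difference maps.  Clipped samples are omitted per cell.
    """
    sel = np.asarray(target_in_rf, dtype=bool)
    if sel.all() or (~sel).all():
        raise ValueError("both target-in-RF and distractor-in-RF trials are required")
    a = stack.csd[sel]
    b = stack.csd[~sel]
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("need >=2 trials per condition")
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-clipped cells
        diff = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
        t, p = stats.ttest_ind(a, b, axis=0, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = np.where(np.isnan(p), False, p < alpha)
    return AttentionCSDDifference(diff, t, p, sig, alpha)
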