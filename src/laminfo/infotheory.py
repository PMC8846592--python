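"""Discrete information statistics with Monte-Carlo shuffle significance.

All statistics are plug-in estimates on discretized signals, in bits:

* entropy               H(S)   = sum_s p(s) log2 1/p(s)
* mutual information    I(X;Y) = sum_ij p(x_i, y_j) log2 p(x_i,y_j)/(p(x_i)p(y_j))
* specific information  I(X=x;S) = sum_s p(s|x) [log2 1/p(x) - log2 1/p(x|s)]
* minimum information   I_min(X;S1,S2) = sum_x p(x) min{I(X=x;S1), I(X=x;S2)}
* information transmission
    I_T(X; Y_past -> Z_future)
        = I_min(X; Z_future, {Z_past, Y_past}) - I_min(X; Z_future, Z_past)

Continuous signals are discretized with uniform-count (quantile) bins,
independently at each timepoint across trials; the attention variable X is
kept in its native binary states.  The joint state {Z_past, Y_past} is the
Cartesian pair of the two label vectors (up to B^2 states).

Significance is assessed by Monte-Carlo shuffling: the trial assignment of X
(or of one signal, for signal-signal mutual information) is permuted, and
the one-sided p-value uses the add-one permutation formula
p = (1 + #{null >= observed}) / (1 + n_shuffle).  Each timepoint draws its
permutations from its own counter-keyed substream of the master seed, so
per-timepoint results do not depend on evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


class DegenerateBinningWarning(UserWarning):
    """All samples identical: uniform-count binning collapses to one bin."""


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _quantile_labels(samples: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniform-count labels 0..B-1 via average ranks (tied values share a bin)."""
    n = samples.size
    _, inverse, counts = np.unique(samples, return_inverse=True, return_counts=True)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    avg_rank = starts + (counts - 1) / 2.0        # 0-based mean rank per value
    ranks = avg_rank[inverse]
    return np.floor(ranks * n_bins / n).astype(np.int64)


def discretize_uniform_count(samples: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-count (quantile) binning into labels 0..n_bins-1.

    Invariant to strictly monotone transforms of the samples.  Bin
    occupancies differ by at most one up to ties; tied values always share
    a bin.  If every sample is identical a single-bin labelling is returned
    and a :class:`DegenerateBinningWarning` is issued.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < n_bins:
        raise ValueError("need at least n_bins samples")
    if np.isnan(samples).any():
        raise ValueError("samples contain NaN; drop missing trials first")
    if np.all(samples == samples[0]):
        warnings.warn("all samples identical; single-bin labels", DegenerateBinningWarning)
        return np.zeros(samples.size, dtype=np.int64)
    return _quantile_labels(samples, n_bins)


# ---------------------------------------------------------------------------
# Plug-in statistics from label vectors
# ---------------------------------------------------------------------------

def _as_labels(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary hashable-ish labels to dense ints."""
    arr = np.asarray(labels)
    uniq, dense = np.unique(arr, return_inverse=True)
    return dense.astype(np.int64), uniq.size


def _joint_counts(x: np.ndarray, y: np.ndarray, nx: int, ny: int) -> np.ndarray:
    return np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny).astype(float)


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plug-in MI in bits from (..., nx, ny) contingency tables."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    pj = counts / n
    px = pj.sum(axis=-1, keepdims=True)
    py = pj.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pj * np.log2(pj / (px * py))
    term = np.where(counts > 0, term, 0.0)
    return term.sum(axis=(-2, -1))


def _specific_info_from_counts(counts: np.ndarray) -> np.ndarray:
    """Specific information I(X=x;S) per x from (..., nx, ns) tables."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    pj = counts / n
    px = pj.sum(axis=-1, keepdims=True)
    ps = pj.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(pj / (px * ps))       # log2 p(x|s)/p(x)
        p_s_given_x = pj / px
        contrib = np.where(counts > 0, p_s_given_x * log_ratio, 0.0)
    return contrib.sum(axis=-1)                    # (..., nx)


def _imin_from_counts(counts1: np.ndarray, counts2: np.ndarray) -> np.ndarray:
    """I_min from two (..., nx, *) tables sharing the X margin."""
    si1 = _specific_info_from_counts(counts1)
    si2 = _specific_info_from_counts(counts2)
    n = counts1.sum(axis=(-2, -1), keepdims=True)
    px = (counts1.sum(axis=-1) / n[..., 0])        # (..., nx)
    return (px * np.minimum(si1, si2)).sum(axis=-1)


def entropy(labels: np.ndarray) -> float:
    """Plug-in entropy in bits (base-2, 0*log(1/0) = 0)."""
    dense, k = _as_labels(labels)
    if dense.size == 0:
        raise ValueError("empty label vector")
    p = np.bincount(dense, minlength=k) / dense.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(x_labels: np.ndarray, y_labels: np.ndarray) -> float:
    """Plug-in mutual information I(X;Y) in bits; symmetric and >= 0."""
    x, nx = _as_labels(x_labels)
    y, ny = _as_labels(y_labels)
    if x.size != y.size:
        raise ValueError("label vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired samples")
    return float(_mi_from_counts(_joint_counts(x, y, nx, ny)))


def specific_information(x_value, s_labels: np.ndarray, x_labels: np.ndarray) -> float:
    """Information that S carries about the particular outcome X = x.

    Uses the specific-information (DeWeese-Meister) form, whose p(x)-weighted
    sum over x recovers I(X;S) exactly.
    """
    x_arr = np.asarray(x_labels)
    uniq = np.unique(x_arr)
    where = np.flatnonzero(uniq == x_value)
    if where.size == 0:
        raise ValueError(f"x_value {x_value!r} not observed in x_labels")
    x, nx = _as_labels(x_arr)
    s, ns = _as_labels(s_labels)
    if x.size != s.size:
        raise ValueError("label vectors must have equal length")
    si = _specific_info_from_counts(_joint_counts(x, s, nx, ns))
    return float(si[int(where[0])])


def minimum_information(
    x_labels: np.ndarray, s1_labels: np.ndarray, s2_labels: np.ndarray
) -> float:
    """I_min(X; S1, S2) = sum_x p(x) min{I(X=x;S1), I(X=x;S2)}."""
    x, nx = _as_labels(x_labels)
    s1, n1 = _as_labels(s1_labels)
    s2, n2 = _as_labels(s2_labels)
    if not (x.size == s1.size == s2.size):
        raise ValueError("label vectors must have equal length")
    c1 = _joint_counts(x, s1, nx, n1)
    c2 = _joint_counts(x, s2, nx, n2)
    return float(_imin_from_counts(c1, c2))


# ---------------------------------------------------------------------------
# Information transmission
# ---------------------------------------------------------------------------

@dataclass
class TransmissionSpec:
    """Inputs for lagged information transmission I_T(X; Y_past -> Z_future).

    ``x`` is the per-trial attention variable (binary); ``y`` and ``z`` are
    per-trial time series (n_trials, n_time); ``lag_samples`` the past-future
    offset (10 ms at 1 kHz by default); ``n_bins`` the uniform-count bin
    count.  Missing samples are NaN and exclude the trial at the affected
    timepoints only.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    lag_samples: int = 10
    n_bins: int = 5

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.lag_samples <= 0:
            raise ValueError("lag must be a positive number of samples")
        if self.y.shape != self.z.shape or self.y.shape[0] != self.x.shape[0]:
            raise ValueError("x, y, z trial dimensions must agree")


def _transmission_labels(spec: TransmissionSpec, t_index: int):
    """Usable-trial labels (x, zf, zp, yp, joint) at one timepoint, or None."""
    if t_index - spec.lag_samples < 0 or t_index >= spec.z.shape[1]:
        raise IndexError("t - lag outside the series")
    zf_raw = spec.z[:, t_index]
    zp_raw = spec.z[:, t_index - spec.lag_samples]
    yp_raw = spec.y[:, t_index - spec.lag_samples]
    usable = np.isfinite(zf_raw) & np.isfinite(zp_raw) & np.isfinite(yp_raw)
    if usable.sum() < max(2, spec.n_bins):
        return None
    x, nx = _as_labels(spec.x[usable])
    if nx < 2:
        return None
    B = spec.n_bins
    zf = _quantile_labels(zf_raw[usable], B)
    zp = _quantile_labels(zp_raw[usable], B)
    yp = _quantile_labels(yp_raw[usable], B)
    joint = zp * B + yp
    return x, nx, zf, zp, joint, B


def information_transmission(spec: TransmissionSpec, t_index: int) -> float:
    """I_T about X from Y_past to Z_future at one timepoint, in bits.

    Z_future is Z at t, Z_past and Y_past are at t - lag; trials with a
    missing sample at either timepoint are excluded for this t only.
    Returns NaN when fewer than two usable trials (or one X state) remain.
    """
    lab = _transmission_labels(spec, t_index)
    if lab is None:
        return float("nan")
    x, nx, zf, zp, joint, B = lab
    c_zf = _joint_counts(x, zf, nx, B)
    c_joint = _joint_counts(x, joint, nx, B * B)
    c_zp = _joint_counts(x, zp, nx, B)
    return float(_imin_from_counts(c_zf, c_joint) - _imin_from_counts(c_zf, c_zp))


# ---------------------------------------------------------------------------
# Monte-Carlo shuffle significance
# ---------------------------------------------------------------------------

@dataclass
class McResult:
    observed: float
    p: float
    null_mean: float
    null_quantile: float
    alpha: float
    n_shuffle: int

    @property
    def significant(self) -> bool:
        return np.isfinite(self.observed) and self.p <= self.alpha


def mc_significance(
    stat_fn: Callable[..., float],
    x_labels: np.ndarray,
    *signals: np.ndarray,
    n_shuffle: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> McResult:
    """Permutation test: shuffle the trial assignment of ``x_labels``.

    ``stat_fn(x, *signals)`` must return a nonnegative information statistic;
    the test is one-sided.  A NaN observed statistic propagates (p = NaN).
    """
    if n_shuffle < 100:
        raise ValueError("need at least 100 shuffles")
    rng = np.random.default_rng(seed)
    x = np.asarray(x_labels)
    observed = float(stat_fn(x, *signals))
    if not np.isfinite(observed):
        return McResult(observed, float("nan"), float("nan"), float("nan"), alpha, n_shuffle)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        null[k] = stat_fn(rng.permutation(x), *signals)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffle)
    return McResult(
        observed=observed,
        p=float(p),
        null_mean=float(null.mean()),
        null_quantile=float(np.quantile(null, 1.0 - alpha)),
        alpha=alpha,
        n_shuffle=n_shuffle,
    )


def _permuted_rows(x: np.ndarray, n_shuffle: int, rng: np.random.Generator) -> np.ndarray:
    """(n_shuffle, n) array of independent permutations of x."""
    tiled = np.tile(x, (n_shuffle, 1))
    return rng.permuted(tiled, axis=1)


def _perm_counts(
    xperm: np.ndarray, s: np.ndarray, nx: int, ns: int
) -> np.ndarray:
    """Contingency tables (n_shuffle, nx, ns) for permuted x vs fixed s."""
    K, n = xperm.shape
    flat = (xperm * ns + s[None, :]) + (np.arange(K)[:, None] * (nx * ns))
    counts = np.bincount(flat.ravel(), minlength=K * nx * ns)
    return counts.reshape(K, nx, ns).astype(float)


def _perm_counts_fixed_x(
    x: np.ndarray, sperm: np.ndarray, nx: int, ns: int
) -> np.ndarray:
    """Contingency tables (n_shuffle, nx, ns) for fixed x vs permuted s."""
    K, n = sperm.shape
    flat = (x[None, :] * ns + sperm) + (np.arange(K)[:, None] * (nx * ns))
    counts = np.bincount(flat.ravel(), minlength=K * nx * ns)
    return counts.reshape(K, nx, ns).astype(float)


def _substream(master_seed: int, stream_id: int, t_index: int) -> np.random.Generator:
    """Counter-keyed substream: per-timepoint results are order-independent."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream_id, t_index))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Persistence filtering and consensus
# ---------------------------------------------------------------------------

def persistent_intervals(
    p_series: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
    min_duration_ms: float = 10.0,
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive significant timepoints lasting long enough.

    A run of k consecutive significant samples at interval dt counts as
    k * dt ms; runs shorter than ``min_duration_ms`` are discarded.  Returns
    (start_ms, end_ms) pairs where end is the last significant sample.
    """
    p = np.asarray(p_series, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    if p.shape != times.shape:
        raise ValueError("p series and time base must align")
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    sig = np.isfinite(p) & (p <= alpha)
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(np.append(sig, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            length = (i - start) * dt
            if length >= min_duration_ms - 1e-9:
                intervals.append((float(times[start]), float(times[i - 1])))
            start = None
    return intervals


def sessionwise_consensus(
    per_session_significance: np.ndarray, fraction: float = 0.75
) -> np.ndarray:
    """Timepoints significant in strictly more than ``fraction`` of sessions.

    Input is a boolean (n_sessions, n_time) matrix; returns a boolean mask.
    """
    sig = np.asarray(per_session_significance, dtype=bool)
    if sig.ndim != 2 or sig.shape[0] < 1:
        raise ValueError("expected a non-empty (n_sessions, n_time) matrix")
    return sig.mean(axis=0) > fraction


# ---------------------------------------------------------------------------
# Time-resolved drivers (vectorized Monte-Carlo nulls)
# ---------------------------------------------------------------------------

@dataclass
class InfoTimeSeries:
    """Per-millisecond information statistic with its Monte-Carlo null."""

    name: str
    times_ms: np.ndarray
    statistic: np.ndarray        # bits
    p: np.ndarray
    null_mean: np.ndarray
    null_quantile: np.ndarray    # (1 - alpha) null quantile
    n_used: np.ndarray           # usable trials per timepoint
    alpha: float
    min_duration_ms: float
    intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return np.isfinite(self.p) & (self.p <= self.alpha)

    def significant_in_window(self, window: tuple[float, float]) -> bool:
        """True if any persistent interval overlaps the window."""
        lo, hi = window
        return any(e >= lo and s <= hi for s, e in self.intervals)

    def finalize(self) -> "InfoTimeSeries":
        self.intervals = persistent_intervals(
            self.p, self.times_ms, self.alpha, self.min_duration_ms
        )
        return self


def _finish_series(name, times, stat, p, nmean, nq, nused, alpha, min_dur):
    return InfoTimeSeries(
        name=name,
        times_ms=np.asarray(times, dtype=float),
        statistic=stat,
        p=p,
        null_mean=nmean,
        null_quantile=nq,
        n_used=nused,
        alpha=alpha,
        min_duration_ms=min_dur,
    ).finalize()


def condition_mi_series(
    x: np.ndarray,
    z: np.ndarray,
    times_ms: np.ndarray,
    t_indices: np.ndarray,
    *,
    n_bins: int = 5,
    n_shuffle: int = 5000,
    alpha: float = 0.05,
    min_duration_ms: float = 10.0,
    seed: int = 0,
    stream_id: int = 0,
    name: str = "MI(condition; signal)",
) -> InfoTimeSeries:
    """MI between a per-trial condition and a signal, per timepoint.

    The null permutes the trial assignment of the condition variable using a
    counter-keyed substream per timepoint.
    """
    x = np.asarray(x)
    z = np.asarray(z, dtype=float)
    t_indices = np.asarray(t_indices)
    T = t_indices.size
    stat = np.full(T, np.nan)
    p = np.full(T, np.nan)
    nmean = np.full(T, np.nan)
    nq = np.full(T, np.nan)
    nused = np.zeros(T, dtype=int)
    for i, t in enumerate(t_indices):
        usable = np.isfinite(z[:, t])
        nused[i] = int(usable.sum())
        if nused[i] < max(2, n_bins):
            continue
        xx, nx = _as_labels(x[usable])
        if nx < 2:
            continue
        s = _quantile_labels(z[usable, t], n_bins)
        obs = float(_mi_from_counts(_joint_counts(xx, s, nx, n_bins)))
        rng = _substream(seed, stream_id, int(t))
        xperm = _permuted_rows(xx, n_shuffle, rng)
        null = _mi_from_counts(_perm_counts(xperm, s, nx, n_bins))
        stat[i] = obs
        p[i] = (1.0 + np.sum(null >= obs)) / (1.0 + n_shuffle)
        nmean[i] = null.mean()
        nq[i] = np.quantile(null, 1.0 - alpha)
    return _finish_series(name, times_ms[t_indices], stat, p, nmean, nq, nused, alpha, min_duration_ms)


def signal_mi_series(
    y: np.ndarray,
    z: np.ndarray,
    times_ms: np.ndarray,
    t_indices: np.ndarray,
    *,
    n_bins: int = 5,
    n_shuffle: int = 5000,
    alpha: float = 0.05,
    min_duration_ms: float = 10.0,
    seed: int = 0,
    stream_id: int = 1,
    name: str = "MI(signal; signal)",
) -> InfoTimeSeries:
    """Simultaneous MI between two signals per timepoint.

    The null permutes one signal's trial assignment.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    t_indices = np.asarray(t_indices)
    T = t_indices.size
    stat = np.full(T, np.nan)
    p = np.full(T, np.nan)
    nmean = np.full(T, np.nan)
    nq = np.full(T, np.nan)
    nused = np.zeros(T, dtype=int)
    for i, t in enumerate(t_indices):
        usable = np.isfinite(y[:, t]) & np.isfinite(z[:, t])
        nused[i] = int(usable.sum())
        if nused[i] < max(2, n_bins):
            continue
        sy = _quantile_labels(y[usable, t], n_bins)
        sz = _quantile_labels(z[usable, t], n_bins)
        obs = float(_mi_from_counts(_joint_counts(sy, sz, n_bins, n_bins)))
        rng = _substream(seed, stream_id, int(t))
        yperm = _permuted_rows(sy, n_shuffle, rng)
        null = _mi_from_counts(_perm_counts(yperm, sz, n_bins, n_bins))
        stat[i] = obs
        p[i] = (1.0 + np.sum(null >= obs)) / (1.0 + n_shuffle)
        nmean[i] = null.mean()
        nq[i] = np.quantile(null, 1.0 - alpha)
    return _finish_series(name, times_ms[t_indices], stat, p, nmean, nq, nused, alpha, min_duration_ms)


def transmission_series(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    times_ms: np.ndarray,
    t_indices: np.ndarray,
    *,
    lag_samples: int = 10,
    n_bins: int = 5,
    n_shuffle: int = 5000,
    alpha: float = 0.05,
    min_duration_ms: float = 10.0,
    seed: int = 0,
    stream_id: int = 2,
    name: str = "I_T(X; Y_past -> Z_future)",
) -> InfoTimeSeries:
    """Information transmission per timepoint with a shuffled-source null.

    The null permutes the trial assignment of the source signal Y_past while
    keeping X and Z fixed.  This tests the hypothesis that Y transmits
    nothing, and — unlike shuffling X — it preserves the X-Z dependence and
    the finite-sample bias of the 25-state joint term {Z_past, Y_past} in
    the null, so a compartment that merely sits next to an informative
    extracortical signal is not flagged.
    """
    spec = TransmissionSpec(x=x, y=y, z=z, lag_samples=lag_samples, n_bins=n_bins)
    t_indices = np.asarray(t_indices)
    T = t_indices.size
    stat = np.full(T, np.nan)
    p = np.full(T, np.nan)
    nmean = np.full(T, np.nan)
    nq = np.full(T, np.nan)
    nused = np.zeros(T, dtype=int)
    B = n_bins
    for i, t in enumerate(t_indices):
        lab = _transmission_labels(spec, int(t))
        if lab is None:
            continue
        xx, nx, zf, zp, joint, _ = lab
        nused[i] = xx.size
        c_zf = _joint_counts(xx, zf, nx, B)
        c_joint = _joint_counts(xx, joint, nx, B * B)
        c_zp = _joint_counts(xx, zp, nx, B)
        term2 = float(_imin_from_counts(c_zf, c_zp))
        obs = float(_imin_from_counts(c_zf, c_joint)) - term2
        rng = _substream(seed, stream_id, int(t))
        yperm = _permuted_rows(joint % B, n_shuffle, rng)   # permute Y_past labels
        joint_perm = (joint // B)[None, :] * B + yperm
        pc_joint = _perm_counts_fixed_x(xx, joint_perm, nx, B * B)
        null = _imin_from_counts(np.broadcast_to(c_zf, (n_shuffle, nx, B)), pc_joint) - term2
        stat[i] = obs
        p[i] = (1.0 + np.sum(null >= obs)) / (1.0 + n_shuffle)
        nmean[i] = null.mean()
        nq[i] = np.quantile(null, 1.0 - alpha)
    return _finish_series(name, times_ms[t_indices], stat, p, nmean, nq, nused, alpha, min_duration_ms)
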