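"""Forward reconstruction of the extracortical potential from laminar CSD.

The calculated event-related potential at an extracortical point d_i is the
distance-weighted sum of the column's currents,

    ERP_cal(d_i, t) = sum_j CSD(d_j, t) / sqrt(h^2 + (d_j - d_i)^2),

with h the lateral offset (0 by default: the electrode sits in the column's
vertical plane).  The global scale factor is omitted because the absolute
magnitude of a 1-D CSD-derived potential is not identifiable, so only
waveform shape and between-condition differences are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ForwardGeometry:
    """Geometry of the forward sum: source depths and evaluation point (mm)."""

    source_depths: np.ndarray      # (n_sources,) mm
    eval_depth: float              # mm, above the shallowest source
    lateral_offset: float = 0.0    # h, mm

    def __post_init__(self) -> None:
        self.source_depths = np.asarray(self.source_depths, dtype=float)
        if self.distances().min() <= 0:
            raise ValueError("evaluation point coincides with a source (zero distance)")

    def distances(self) -> np.ndarray:
        return np.sqrt(
            self.lateral_offset**2 + (self.source_depths - self.eval_depth) ** 2
        )

    @classmethod
    def for_interior_channels(
        cls,
        depths_mm: np.ndarray,
        offset_above: float = 0.3,
        lateral_offset: float = 0.0,
        skip_top: int = 0,
    ) -> "ForwardGeometry":
        """Geometry for CSD on the interior channels of a laminar probe.

        The evaluation point sits ``offset_above`` mm above the shallowest
        full-probe contact (default 0.3 mm, i.e. just outside cortex).
        ``skip_top`` drops that many of the shallowest interior rows from
        the source sum — probes are inserted with a subset of superficial
        contacts left outside cortex, which carry no cortical current but
        the largest 1/r weights.
        """
        depths_mm = np.asarray(depths_mm, dtype=float)
        return cls(
            source_depths=depths_mm[1 + skip_top : -1],
            eval_depth=float(depths_mm[0]) - offset_above,
            lateral_offset=lateral_offset,
        )


def erp_from_csd(csd: np.ndarray, geometry: ForwardGeometry) -> np.ndarray:
    """Distance-weighted forward sum of CSD; linear in its input.

    Parameters
    ----------
    csd : ndarray
        (..., n_sources, n_time) current source density.
    geometry : ForwardGeometry
        Source depths and evaluation point; all distances must be positive.

    Returns
    -------
    ndarray with shape (..., n_time); NaN propagates from clipped samples.
    """
    csd = np.asarray(csd, dtype=float)
    w = 1.0 / geometry.distances()
    if csd.shape[-2] != w.size:
        raise ValueError("csd depth axis does not match geometry")
    return np.einsum("...dt,d->...t", csd, w)


@dataclass
class ErpComparison:
    """Calculated-vs-observed comparison of condition difference waveforms."""

    times_ms: np.ndarray
    diff_cal: np.ndarray          # target - distractor, calculated ERP
    diff_obs: np.ndarray          # target - distractor, observed ERP
    sign_agreement: bool          # same polarity of the window-mean difference
    difference_correlation: float
    divergence_time_cal_ms: float   # NaN when never diverging
    divergence_time_obs_ms: float
    window: tuple[float, float]


def _first_divergence(
    diff: np.ndarray,
    ci_halfwidth: np.ndarray,
    times_ms: np.ndarray,
    min_duration_ms: float,
    dt_ms: float,
) -> float:
    """First post-onset time where |diff| exceeds its 95% CI for a sustained run."""
    valid = times_ms >= 0
    exceed = np.abs(diff) > ci_halfwidth
    exceed &= valid
    need = max(1, int(round(min_duration_ms / dt_ms)))
    run = 0
    for i, flag in enumerate(exceed):
        run = run + 1 if flag else 0
        if run >= need:
            return float(times_ms[i - need + 1])
    return float("nan")


def compare_calculated_observed(
    erp_cal: np.ndarray,
    erp_obs: np.ndarray,
    target_in_rf: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float] = (150.0, 190.0),
    min_divergence_ms: float = 20.0,
) -> ErpComparison:
    """Compare the condition difference of ERP_cal and the observed ERP.

    Both inputs are per-trial traces (n_trials, n_time) on a common time
    base; the condition difference is target-in-RF minus opposite.  Reports
    (a) whether the window-mean differences share a sign, (b) the Pearson
    correlation of the two post-onset difference waveforms, and (c) each
    waveform's first divergence time: the first post-onset sample where the
    difference exceeds its 95% confidence halfwidth for a sustained run
    (default 20 ms: a genuine condition difference persists, while
    band-limited noise rarely clears a pointwise interval that long).
    """
    sel = np.asarray(target_in_rf, dtype=bool)
    if sel.all() or (~sel).all():
        raise ValueError("both conditions are required")
    times_ms = np.asarray(times_ms, dtype=float)
    dt = float(times_ms[1] - times_ms[0])

    def cond_diff(x):
        import warnings as _warnings

        a, b = x[sel], x[~sel]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-clipped columns
            d = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
            na = np.sum(~np.isnan(a), axis=0).clip(min=1)
            nb = np.sum(~np.isnan(b), axis=0).clip(min=1)
            var = np.nanvar(a, axis=0, ddof=1) / na + np.nanvar(b, axis=0, ddof=1) / nb
        return d, 1.96 * np.sqrt(var)

    d_cal, ci_cal = cond_diff(np.asarray(erp_cal, dtype=float))
    d_obs, ci_obs = cond_diff(np.asarray(erp_obs, dtype=float))

    in_win = (times_ms >= window[0]) & (times_ms <= window[1])
    if not in_win.any():
        raise ValueError("comparison window outside the time base")
    m_cal = np.nanmean(d_cal[in_win])
    m_obs = np.nanmean(d_obs[in_win])

    post = times_ms >= 0
    ok = post & np.isfinite(d_cal) & np.isfinite(d_obs)
    if ok.sum() >= 3 and np.nanstd(d_cal[ok]) > 0 and np.nanstd(d_obs[ok]) > 0:
        corr = float(np.corrcoef(d_cal[ok], d_obs[ok])[0, 1])
    else:
        corr = float("nan")

    return ErpComparison(
        times_ms=times_ms,
        diff_cal=d_cal,
        diff_obs=d_obs,
        sign_agreement=bool(np.sign(m_cal) == np.sign(m_obs)),
        difference_correlation=corr,
        divergence_time_cal_ms=_first_divergence(d_cal, ci_cal, times_ms, min_divergence_ms, dt),
        divergence_time_obs_ms=_first_divergence(d_obs, ci_obs, times_ms, min_divergence_ms, dt),
        window=window,
    )
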