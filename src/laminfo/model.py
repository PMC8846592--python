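"""Session-level model tying laminar currents to the extracortical field.

:class:`LaminarAttentionModel` is built from a :class:`SessionRecording` and
its trial table; :meth:`fit` runs the four-step information analysis —

1. MI(extracortical; target position),
2. MI(laminar CSD compartment; target position),
3. MI(laminar CSD compartment; extracortical signal),
4. I_T(target position; CSD compartment -> extracortical),

each per millisecond with a Monte-Carlo shuffle null and persistence
filtering — and returns a :class:`LaminarAttentionResults` carrying the
estimates, their nulls, the aligned CSD stack, and diagnostic comparisons
(attention CSD difference map, forward-modelled ERP, columnar selectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import csd as csd_mod
from . import forward as forward_mod
from . import infotheory as it
from . import preprocess as pp
from .config import SynthConfig
from .selectivity import SelectivityProfile, bootstrap_null, test_selectivity
from .session import SessionRecording, validate_trial_table

STEP_NAMES = {
    1: "MI(extracortical; target)",
    2: "MI(CSD; target)",
    3: "MI(CSD; extracortical)",
    4: "I_T(target; CSD -> extracortical)",
}


class LaminarAttentionModel:
    """Four-step information analysis of one laminar session.

    Parameters
    ----------
    recording : SessionRecording
    trials : DataFrame
        Behavioural table; only correct trials enter information analyses.
    n_bins, lag_ms, n_shuffle, alpha, persistence_ms :
        Information-analysis parameters (uniform-count bins, past-future
        lag, Monte-Carlo shuffles, significance level, persistence minimum).
    info_window : (ms, ms)
        Interval over which the per-millisecond statistics are evaluated.
    n2pc_window : (ms, ms)
        Attention-component interval annotated in reports.
    boundary_channel : int, optional
        Skip sink-based alignment and use this L4/5 boundary.
    sigma : float
        Conductivity (S/m) for the CSD scale.
    seed : int
        Master seed for all shuffle substreams.
    """

    def __init__(
        self,
        recording: SessionRecording,
        trials: pd.DataFrame,
        *,
        n_bins: int = 5,
        lag_ms: float = 10.0,
        n_shuffle: int = 5000,
        alpha: float = 0.05,
        persistence_ms: float = 10.0,
        info_window: tuple[float, float] = (100.0, 250.0),
        n2pc_window: tuple[float, float] = (150.0, 190.0),
        baseline_window: tuple[float, float] = (-300.0, 0.0),
        clip_margin_ms: float = 10.0,
        sigma: float = 0.4,
        boundary_channel: Optional[int] = None,
        seed: int = 0,
    ) -> None:
        self.recording = recording
        self.trials = validate_trial_table(trials, recording.n_trials)
        self.n_bins = n_bins
        self.lag_ms = lag_ms
        self.n_shuffle = n_shuffle
        self.alpha = alpha
        self.persistence_ms = persistence_ms
        self.info_window = info_window
        self.n2pc_window = n2pc_window
        self.baseline_window = baseline_window
        self.clip_margin_ms = clip_margin_ms
        self.sigma = sigma
        self.boundary_channel = boundary_channel
        self.seed = seed
        lag = lag_ms * recording.sample_rate / 1000.0
        if abs(lag - round(lag)) > 1e-9 or round(lag) < 1:
            raise ValueError("lag must be a positive multiple of the sample interval")
        self.lag_samples = int(round(lag))

    @classmethod
    def from_hdf5(cls, path, **kwargs) -> "LaminarAttentionModel":
        from .sessionio import read_session

        recording, trials, _ = read_session(path)
        return cls(recording, trials, **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: Optional[SynthConfig] = None, **kwargs
    ) -> "LaminarAttentionModel":
        from .synth import generate_session

        config = config or SynthConfig()
        recording, trials, truth = generate_session(config)
        model = cls(recording, trials, **kwargs)
        model.ground_truth = truth
        return model

    # -- preprocessing ------------------------------------------------------

    def _prepare(self):
        rec = self.recording
        times = rec.times_ms
        sacc = self.trials["saccade_time_ms"].to_numpy(float)

        lfp = pp.baseline_correct(rec.lfp, times, self.baseline_window)
        extr = pp.baseline_correct(rec.extracortical, times, self.baseline_window)
        extr = pp.clip_at_saccade(extr, sacc, times, self.clip_margin_ms).traces

        raw_csd = csd_mod.compute_csd(lfp, rec.spacing, self.sigma)
        clipped = pp.clip_at_saccade(raw_csd, sacc, times, self.clip_margin_ms)
        stack = csd_mod.CSDStack(
            csd=clipped.traces,
            spacing=rec.spacing,
            conductivity=self.sigma,
            sample_rate=rec.sample_rate,
            array_onset_index=rec.array_onset_index,
        )
        return lfp, extr, stack

    def _align(self, stack: csd_mod.CSDStack, correct: np.ndarray) -> int:
        if self.boundary_channel is not None:
            return int(self.boundary_channel)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-clipped cells
            avg = np.nanmean(stack.csd[correct], axis=0)
        return csd_mod.align_to_granular_sink(
            avg, stack.times_ms, baseline_window=self.baseline_window
        )

    # -- estimation ---------------------------------------------------------

    def fit(self, steps: tuple[int, ...] = (1, 2, 3, 4)) -> "LaminarAttentionResults":
        rec = self.recording
        times = rec.times_ms
        correct = self.trials["correct"].to_numpy(bool)
        if correct.sum() < 4:
            raise ValueError("too few correct trials")

        lfp, extr, stack = self._prepare()
        boundary = self._align(stack, correct)
        stack.boundary_channel = boundary
        compartments = csd_mod.compartment_series(stack, boundary)

        t0 = rec.time_index(self.info_window[0])
        t1 = rec.time_index(self.info_window[1])
        t_indices = np.arange(max(t0, self.lag_samples), t1 + 1)

        x_hemi = self.trials["target_hemifield"].to_numpy()[correct]
        x_rf = self.trials["target_in_rf"].to_numpy()[correct].astype(int)
        extr_c = extr[correct]
        comp_c = {k: v[correct] for k, v in compartments.items()}

        common = dict(
            n_bins=self.n_bins,
            n_shuffle=self.n_shuffle,
            alpha=self.alpha,
            min_duration_ms=self.persistence_ms,
            seed=self.seed,
        )
        results: dict[int, dict[str, it.InfoTimeSeries]] = {}
        if 1 in steps:
            results[1] = {
                "extracortical": it.condition_mi_series(
                    x_hemi, extr_c, times, t_indices,
                    stream_id=10, name=STEP_NAMES[1], **common,
                )
            }
        if 2 in steps:
            results[2] = {
                name: it.condition_mi_series(
                    x_rf, series, times, t_indices,
                    stream_id=20 + i, name=f"{STEP_NAMES[2]} [{name}]", **common,
                )
                for i, (name, series) in enumerate(comp_c.items())
            }
        if 3 in steps:
            results[3] = {
                name: it.signal_mi_series(
                    series, extr_c, times, t_indices,
                    stream_id=30 + i, name=f"{STEP_NAMES[3]} [{name}]", **common,
                )
                for i, (name, series) in enumerate(comp_c.items())
            }
        if 4 in steps:
            results[4] = {
                name: it.transmission_series(
                    x_rf, series, extr_c, times, t_indices,
                    lag_samples=self.lag_samples,
                    stream_id=40 + i, name=f"{STEP_NAMES[4]} [{name}]", **common,
                )
                for i, (name, series) in enumerate(comp_c.items())
            }

        return LaminarAttentionResults(
            model=self,
            boundary_channel=boundary,
            csd_stack=stack,
            compartments=compartments,
            extracortical=extr,
            lfp_preprocessed=lfp,
            steps=results,
            t_indices=t_indices,
        )


@dataclass
class LaminarAttentionResults:
    """Estimates and diagnostics from a fitted session."""

    model: LaminarAttentionModel
    boundary_channel: int
    csd_stack: csd_mod.CSDStack
    compartments: dict[str, np.ndarray]
    extracortical: np.ndarray
    lfp_preprocessed: np.ndarray
    steps: dict[int, dict[str, it.InfoTimeSeries]]
    t_indices: np.ndarray
    _attention_diff: Optional[csd_mod.AttentionCSDDifference] = field(
        default=None, repr=False
    )

    # -- convenience --------------------------------------------------------

    @property
    def n2pc_window(self) -> tuple[float, float]:
        return self.model.n2pc_window

    def series(self, step: int, key: str | None = None) -> it.InfoTimeSeries:
        group = self.steps[step]
        if key is None:
            key = next(iter(group))
        return group[key]

    def significant_in_n2pc(self, step: int, key: str) -> bool:
        """Persistent significance overlapping the attention window."""
        return self.series(step, key).significant_in_window(self.n2pc_window)

    def attention_csd_difference(self) -> csd_mod.AttentionCSDDifference:
        if self._attention_diff is None:
            correct = self.model.trials["correct"].to_numpy(bool)
            sub = csd_mod.CSDStack(
                csd=self.csd_stack.csd[correct],
                spacing=self.csd_stack.spacing,
                conductivity=self.csd_stack.conductivity,
                sample_rate=self.csd_stack.sample_rate,
                array_onset_index=self.csd_stack.array_onset_index,
                boundary_channel=self.boundary_channel,
            )
            self._attention_diff = csd_mod.attention_csd_difference(
                sub,
                self.model.trials["target_in_rf"].to_numpy(bool)[correct],
                alpha=self.model.alpha,
            )
        return self._attention_diff

    def erp_cal(
        self, geometry: Optional[forward_mod.ForwardGeometry] = None
    ) -> np.ndarray:
        """Per-trial forward-modelled extracortical potential (ERP_cal).

        The default geometry sums the cortical currents only: interior rows
        more than two channels above the aligned column's L2/3 span are
        treated as extracortical contacts (probes leave superficial contacts
        outside cortex) and excluded.
        """
        rec = self.model.recording
        if geometry is None:
            skip = max(0, self.boundary_channel - 11 - 1)
            geometry = forward_mod.ForwardGeometry.for_interior_channels(
                rec.depths, skip_top=skip
            )
        n_src = geometry.source_depths.size
        return forward_mod.erp_from_csd(self.csd_stack.csd[:, -n_src:, :], geometry)

    def erp_comparison(
        self,
        geometry: Optional[forward_mod.ForwardGeometry] = None,
        window: Optional[tuple[float, float]] = None,
    ) -> forward_mod.ErpComparison:
        """Forward-modelled ERP_cal vs the observed extracortical ERP.

        ERP_cal is computed per trial from the (clipped) CSD stack so trial
        attrition is handled identically for both signals.
        """
        rec = self.model.recording
        erp_cal = self.erp_cal(geometry)
        correct = self.model.trials["correct"].to_numpy(bool)
        return forward_mod.compare_calculated_observed(
            erp_cal[correct],
            self.extracortical[correct],
            self.model.trials["target_in_rf"].to_numpy(bool)[correct],
            rec.times_ms,
            window=window or self.n2pc_window,
        )

    def gamma_site_csis(
        self,
        band: tuple[float, float] = (30.0, 150.0),
        window: tuple[float, float] = (75.0, 200.0),
    ) -> np.ndarray:
        """Per-site CSI over the 15 aligned depths, from distractor trials.

        Gamma power is taken per LFP site on correct distractor-in-RF trials
        with a red vs green stimulus in the receptive field.
        """
        rec = self.model.recording
        trials = self.model.trials
        sel = (~trials["target_in_rf"].to_numpy(bool)) & trials["correct"].to_numpy(bool)
        colors = trials["rf_color"].to_numpy()
        channels = np.arange(self.boundary_channel - 9, self.boundary_channel + 6)
        power = pp.gamma_power(
            self.lfp_preprocessed[:, channels, :], rec.times_ms, rec.sample_rate,
            band=band, window=window,
        )
        red = np.nanmean(power[sel & (colors == "red")], axis=0)
        green = np.nanmean(power[sel & (colors == "green")], axis=0)
        from .selectivity import csi as _csi

        return _csi(red, green)

    def selectivity_profile(
        self,
        pool: np.ndarray,
        n_boot: int = 1000,
        seed: int = 0,
        alpha: float = 0.05,
    ) -> SelectivityProfile:
        """Column selectivity tested against a cross-column bootstrap null."""
        site = self.gamma_site_csis()
        null = bootstrap_null(pool, n_sites=site.size, n_boot=n_boot, seed=seed)
        return test_selectivity(site, null, alpha=alpha)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = []
        lines.append("Laminar attention-field analysis")
        lines.append("=" * 64)
        lines.append(
            f"trials: {m.recording.n_trials} "
            f"(correct: {int(m.trials['correct'].sum())})   "
            f"channels: {m.recording.n_channels}   "
            f"L4/5 boundary: ch {self.boundary_channel}"
        )
        lines.append(
            f"bins: {m.n_bins}   lag: {m.lag_ms:g} ms   "
            f"shuffles: {m.n_shuffle}   alpha: {m.alpha:g}   "
            f"persistence: {m.persistence_ms:g} ms"
        )
        lines.append(
            f"window: {m.info_window[0]:g}..{m.info_window[1]:g} ms   "
            f"N2pc: {m.n2pc_window[0]:g}..{m.n2pc_window[1]:g} ms"
        )
        lines.append("-" * 64)
        header = f"{'statistic':<38}{'peak':>8}{'t_pk':>7}{'N2pc':>6}"
        lines.append(header + "   intervals (ms)")
        for step in sorted(self.steps):
            for key, s in self.steps[step].items():
                if np.all(~np.isfinite(s.statistic)):
                    peak, t_pk = float("nan"), float("nan")
                else:
                    k = np.nanargmax(s.statistic)
                    peak, t_pk = s.statistic[k], s.times_ms[k]
                flag = "yes" if s.significant_in_window(self.n2pc_window) else "no"
                ivals = ", ".join(f"[{a:.0f},{b:.0f}]" for a, b in s.intervals) or "-"
                label = f"step {step} {key}"
                lines.append(
                    f"{label:<38}{peak:>8.3f}{t_pk:>7.0f}{flag:>6}   {ivals}"
                )
        lines.append("-" * 64)
        return "\n".join(lines)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """InfoTimeSeries as tidy frames keyed 'step<k>/<compartment>'."""
        out = {}
        for step, group in self.steps.items():
            for key, s in group.items():
                in_interval = np.zeros(s.times_ms.size, dtype=bool)
                for a, b in s.intervals:
                    in_interval |= (s.times_ms >= a) & (s.times_ms <= b)
                out[f"step{step}/{key}"] = pd.DataFrame(
                    {
                        "time_ms": s.times_ms,
                        "statistic_bits": s.statistic,
                        "p": s.p,
                        "null_q95": s.null_quantile,
                        "n_used": s.n_used,
                        "in_interval": in_interval,
                    }
                )
        return out

    def plot_information(self, step: int = 4, ax=None):
        """Line plot of one step's statistics with significance bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for key, s in self.steps[step].items():
            (line,) = ax.plot(s.times_ms, s.statistic, label=key)
            for a, b in s.intervals:
                ax.plot([a, b], [ax.get_ylim()[0]] * 2, lw=3, color=line.get_color())
        ax.axvspan(*self.n2pc_window, alpha=0.15, color="orange")
        ax.set_xlabel("time (ms re array onset)")
        ax.set_ylabel("bits")
        ax.set_title(STEP_NAMES[step])
        ax.legend()
        return ax

    def plot_csd(self, target_in_rf: bool = True, ax=None):
        """Image of the trial-averaged CSD for one condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        trials = self.model.trials
        sel = (trials["target_in_rf"] == target_in_rf) & trials["correct"]
        avg = np.nanmean(self.csd_stack.csd[sel.to_numpy()], axis=0)
        t = self.csd_stack.times_ms
        ax.imshow(
            avg, aspect="auto", origin="upper",
            extent=[t[0], t[-1], avg.shape[0] + 0.5, 0.5],
            cmap="RdBu", vmin=-np.nanmax(np.abs(avg)), vmax=np.nanmax(np.abs(avg)),
        )
        ax.axhline(self.boundary_channel - 0.5, ls="--", color="k", lw=0.8)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("interior channel")
        cond = "target in RF" if target_in_rf else "distractor in RF"
        ax.set_title(f"trial-averaged CSD ({cond})")
        return ax


def four_step_analysis(
    recording: SessionRecording, trials: pd.DataFrame, **kwargs
) -> LaminarAttentionResults:
    """Convenience wrapper: build the session model and fit all four steps."""
    return LaminarAttentionModel(recording, trials, **kwargs).fit()
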