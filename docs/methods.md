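# Methods

This note documents the models and procedures implemented in `laminfo`, the
assumptions behind them, the parameters that matter, and the design choices
made where the methodology was genuinely open.

## Signals and preprocessing

A session couples a laminar LFP (trials × channels × time, mV; 32 channels
at 0.1 mm spacing, 1 kHz analysis rate) with one extracortical channel and a
behavioural table (target-in-RF flag, hemifield, RF stimulus color, saccade
time, correctness).  All traces are baseline-corrected per trial by
subtracting the mean over the 300 ms before array onset (a shorter window is
available for scalp-style traces), and clipped 10 ms before the saccade:
clipped samples become NaN, every averaging step counts available trials per
timepoint, and fully clipped trials are flagged rather than dropped.  Only
correct trials enter information analyses.

Band power uses zero-phase 4th-order Butterworth filters and the squared
analytic-signal envelope halved, so a pure in-band sinusoid of amplitude a
measures a²/2.  Multiunit activity (high-rate recordings only, ≥6 kHz) is
the classic four-stage chain: low-pass 3 kHz → high-pass 300 Hz → full-wave
rectification → low-pass 150 Hz.

## CSD, alignment, compartments

CSD is the negative scaled second spatial difference of the LFP on interior
channels; the outermost channel at each end is dropped (no padding by
default; the estimate is linear and annihilates affine depth profiles
exactly).  Conductivity σ defaults to 0.4 S/m and acts as a pure scale.

Laminar alignment finds the granular input sink: the earliest channel whose
trial-averaged CSD drops below −k·SD of its own pre-array baseline inside a
25–100 ms search window, sustained for ≥5 ms.  *Choices:* k defaults to 4
(not lower) because the search spans ~75 correlated samples on ~30 channels,
where a 2·SD excursion of the trial-averaged noise is a routine event; the
5 ms sustain requirement discards single-sample spikes (an input sink is
sustained); among channels crossing in the same sample, the strongest sink
at the crossing time wins, then the deeper channel.  These choices are
validated by boundary recovery on generated sessions (within ±2 channels of
truth in all calibration runs).  The detected channel is taken as the centre
of L4, so the L4/5 boundary is that channel + 2.  Compartments are disjoint
5-site means: L4 = boundary and 4 channels above, L2/3 = next 5 above,
L5/6 = 5 below.

## Information statistics

All statistics are plug-in estimates on discretized signals, in bits.
Continuous samples are binned at each timepoint independently across trials
into five uniform-count (quantile) bins; tied values share a bin, so the
labelling is invariant to strictly monotone transforms.  The attention
variable stays in its native binary states (contra/ipsi for the
extracortical analyses, in-RF/opposite for the within-column ones).

The specific information of an outcome x,
I(X=x;S) = Σ_s p(s|x)·[log₂ 1/p(x) − log₂ 1/p(x|s)], follows the
DeWeese–Meister form; its p(x)-weighted sum recovers I(X;S) exactly, which
the tests assert to 1e−12 against an independent pure-python enumerator of
the empirical joint distribution.  Minimum information takes the expected
per-outcome minimum across two sources; information transmission is the
difference of two minimum informations, with Z_future at t, Z_past and
Y_past at t − 10 ms, and the joint source {Z_past, Y_past} coded as the
Cartesian pair of labels (25 states, no re-binning).  Trials missing any
required sample are excluded at that timepoint only.

### Monte-Carlo significance

Nulls are built from 5000 shuffles (1000 in the reduced multi-session runs)
with the add-one permutation p-value p = (1 + #{null ≥ observed})/(1 + N),
one-sided because the statistics are nonnegative.  Each timepoint draws its
permutations from a counter-keyed substream of the master seed, so per-
timepoint results do not depend on evaluation order.  Persistence filtering
keeps maximal runs of consecutive significant milliseconds lasting ≥10 ms;
multi-session consensus keeps timepoints significant in strictly more than
75% of sessions.

*What is permuted.*  For condition-information statistics (MI between a
signal and target position) the trial assignment of the condition is
shuffled; for signal–signal MI, one signal's trial order.  For information
transmission the null permutes the trial assignment of the **source**
Y_past, keeping X and Z fixed.  The reason is structural: the 25-state
joint term carries a finite-sample upward bias that the 5-state term lacks,
so a null that destroys the X–Z relationship (shuffling X) misattributes
that bias difference to transmission, flagging any compartment that merely
sits next to an informative extracortical signal — in calibration runs the
granular compartment showed identical spurious intervals to the extra-
granular ones under an X-shuffle null.  Permuting Y preserves the X–Z
structure and the joint-term bias in the null and tests exactly the
hypothesis "these laminar currents transmit nothing".

*Sensitivity structure.*  I_min-based transmission registers only where the
target information in Z is *growing* across the lag — the headroom
I(X;Z_future) − I(X;Z_past) — and a source can be credited only with filling
that headroom.  Transmission detection therefore concentrates on the rising
phase of the attention effect; on a long plateau the statistic is near zero
for every source.  This is a property of the statistic, not of the
implementation.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
latent CSD components built as zero-sum sink/source pairs of depth-Gaussian
profiles (the source is rescaled so its depth sum matches the sink's, so the
depth integral of the latent CSD is zero at machine precision at every
timepoint) times smooth temporal envelopes:

* **granular pair** — L4 input sink (alpha-function envelope, onset 50 ms,
  τ = 20 ms, amplitude 0.6) with a deep return source; not attention-
  modulated, mild (5%) trial-amplitude jitter;
* **extragranular pair** — sustained L2/3 sink with an L5/6 source (linear
  ramp, onset 120 ms, 70 ms rise, amplitude 0.5), 15% trial-amplitude
  jitter.  Target-in-RF trials scale this pair by (1 + attention_gain·c),
  where the color-coupling factor c is 1 + coupling_gain_preferred when the
  RF color matches the column's preference and 1 otherwise.

The laminar LFP is the exact double cumulative sum inverting the second-
difference operator (integration constants zero, so the two shallowest
channels carry the affine extension), plus a common-mode gamma-band
component and channel-independent recording noise.  The extracortical trace
is the same distance-weighted forward sum the analysis uses (evaluation
point 0.3 mm above the shallowest contact), plus an independent slow
(≤30 Hz) background and band-limited noise.  Saccade times are truncated-
normal (median 225 ms, SD 50 ms, floor 100 ms); 90% of trials are correct;
the 2×2 design (attention × RF color) is balanced and interleaved.

*Noise model.*  All recording noise is white within the emulated 1–100 Hz
acquisition band and rescaled to its per-sample SD (LFP 0.007 mV per
channel, extracortical 0.05 plus background 0.10 in forward units).
Band-limited noise is both what the acquisition chain would deliver and
necessary for the per-millisecond significance traces to form persistent
runs rather than flickering sample by sample.

*Gamma selectivity.*  The gamma component (30–150 Hz band-limited noise,
tapered to 50–250 ms, trial-RMS-normalized over the 75–200 ms response
window) is added identically to every channel, so its second spatial
difference — hence its CSD footprint — is exactly zero, and band power is
higher by gamma_power_ratio when the preferred color is in the RF.

*Calibration of the free parameters.*  Component amplitudes, depth extents
and noise levels are free parameters of the generator; they were fixed once
against two requirements a real column-survey session meets: the extragranular attention effect is detectable within a
single session, and target information in the extracortical signal is still
rising through the 150–190 ms window (the transmission statistic's
sensitivity region).  The defaults give a per-timepoint attention
discriminability around d′ ≈ 2.5–3 at the ramp plateau.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: 1/f spectra and oscillatory structure beyond the
injected gamma; volume conduction from other columns or areas (the
background is pure noise); eye-movement artifacts beyond a saccade
timestamp; spiking; site-to-site heterogeneity of color tuning within a
column.  The last one matters for the selectivity test below.

## Columnar selectivity

Site CSI uses gamma power from correct distractor-in-RF trials (red vs
green), the column CCSI is the mean of the 15 aligned site CSIs, and the
column-level test compares the column's signed-rank statistic (site CSIs
against zero, zeros dropped) with the distribution of the same statistic
over 1000 bootstrap pseudo-columns, each 15 values resampled with
replacement from the pooled site CSIs of all columns; two-sided p via the
add-one rule, preferred color from the CCSI sign.  The wording of the
underlying procedure is ambiguous; this statistic-vs-null-statistic
realization is calibrated by construction for columns exchangeable with the
pool, which the tests verify (false-positive rate ≈ α on pool-resampled
columns, ≥90% detection of ratio-2 columns).

*Known limitation:* synthetic `none`-preference columns are **not**
exchangeable with pseudo-columns — their 15 sites share one gamma
realization, so their CSIs are nearly identical and any tiny shared offset
makes the column sign-consistent, which a site-resampling null cannot
calibrate.  Real columns have heterogeneous site tuning; emulating that
per-site heterogeneity is impossible here without corrupting the CSD (any
channel-independent in-band component explodes under the second spatial
difference).  Selectivity false-positive calibration is therefore defined
on pool-resampled columns.

## Selectivity-conditioned transmission

Transmission is computed separately for trials with the preferred vs the
non-preferred color in the RF (≥20 correct trials per subset), differenced
per compartment and timepoint, with the subset average also reported.  The
conditioned experiments use attention_gain 0.25 with coupling_gain 0.8: with
the flagship attention gain the preferred-color subset's binary target MI
saturates before the N2pc window, and a growth-sensitive statistic then
under-credits the stronger condition — the moderate gain keeps both subsets
on the rising phase, where the preferred color transmits more.  The
across-session correlate scales the coupling gain with the column's expected
|CSI| and reports the Spearman correlation of measured |CCSI| against the
160–180 ms mean difference.

## Forward model

ERP_cal sums CSD over depths divided by the Euclidean distance to the
evaluation point; the lateral offset h is 0 (the electrode is assumed in the
column's plane) and the global scale is omitted, so only waveform shape and
between-condition differences are meaningful.  ERP_cal is computed per trial
from the clipped CSD so trial attrition matches the observed trace.  The
default comparison geometry excludes interior rows more than two channels
above the aligned L2/3 span: those contacts sit outside cortex (probes are
inserted with superficial contacts above the brain), carry no cortical
current, and would contribute the largest 1/r weights of pure noise.  The
explicit-geometry path retains all interior depths and is what the exact
noiseless round-trip check uses.

The calculated-vs-observed comparison reports (a) sign agreement of the
target-minus-distractor difference over 150–190 ms, (b) the Pearson
correlation of the post-onset difference waveforms, and (c) each waveform's
first divergence time — the first post-onset sample whose difference exceeds
its pointwise 95% CI for a sustained 20 ms (10 ms runs occasionally arise
from band-limited noise alone).

## Problem sizes used in the study-level checks

Type-I calibration: 1000 independent Gaussian pairs × 300 trials × 5000
shuffles.  Transmission recovery: 20 modulated + 20 null sessions, 1000
shuffles, analysis window 120–220 ms.  Selectivity: 20 ratio-2 + 10 neutral
columns (a 450-value pool), 1000 bootstrap draws, 400 pool-resampled null
columns.  Conditioned transmission: 6 coupled + 4 uncoupled sessions, and 8
sessions spanning gamma ratios 1.1–5 for the selectivity correlate.
Forward consistency: 4 pooled sessions (an across-session grand average).
Each session holds 150 trials per condition (600 total).

## Degenerate inputs and numerical conventions

Binning of an all-constant sample vector returns single-bin labels with a
warning; information statistics treat 0·log(1/0) as 0; permutation p-values
are never exactly zero (add-one rule); fewer than two usable trials (or one
condition state) at a timepoint yields NaN, which persistence filtering
treats as non-significant; all-tied selectivity columns return p = 1 and a
degenerate flag; undefined rank correlations (constant input) return NaN
with the session count intact.  Signal arrays are float32 end to end;
latent templates and all information statistics are float64.
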