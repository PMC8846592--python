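# laminfo

Laminar current source density and information-transmission analysis of
attention-associated extracortical fields.

## The problem

Attention-indexing ERP components such as the N2pc — the contralateral-minus-
ipsilateral potential difference ~150–190 ms after a visual search array
appears — are measured outside the brain, but the cortical circuitry that
generates them is not visible to the scalp electrode.  Linking them to their
laminar origin requires simultaneous recordings of a cortical column (a
linear multielectrode array spanning supragranular L2/3, granular L4 and
infragranular L5/6) and of an extracortical electrode just above it, plus an
analysis that can say *which layers' synaptic currents carry the attention
signal that appears extracortically*.

`laminfo` implements that analysis as a tested, reusable pipeline for
trial-structured laminar LFP recordings (trials × 32 channels at 0.1 mm ×
time at 1 kHz) with one extracortical channel and a behavioural trial table.
It ships a synthetic-session generator with known ground truth, so every
stage is validated by parameter recovery.

## The methods at its core

* **Current source density.**  CSD(t, d) = −σ·[x(t, d−z) + x(t, d+z) −
  2x(t, d)]/z², the second spatial derivative of the laminar LFP x across
  depth d (spacing z, conductivity σ).  Sessions are aligned at the L4/5
  boundary via the earliest post-stimulus (granular input) sink, and each
  laminar compartment is the mean of five contiguous depths.
* **Information statistics.**  Plug-in entropy H(S) = Σ p(s)·log₂ 1/p(s) and
  mutual information I(X;Y) on five uniform-count bins, computed per
  millisecond across trials; redundancy-style minimum information
  I_min(X; S₁, S₂) = Σₓ p(x)·min{I(X=x;S₁), I(X=x;S₂)}; and lagged
  information transmission

      I_T(X; Y_past → Z_future) = I_min(X; Z_future, {Z_past, Y_past})
                                − I_min(X; Z_future, Z_past),

  the target-position information that arrives in the extracortical signal Z
  beyond what its own past carried, attributable to the laminar currents Y
  10 ms earlier.  Significance comes from Monte-Carlo shuffle nulls with the
  add-one permutation p-value, a 10 ms persistence rule, and a >75%
  across-session consensus.
* **Columnar feature selectivity.**  Per-site color selectivity index
  CSI = (r_red − r_green)/(r_red + r_green) from gamma-band (30–150 Hz)
  power evoked by distractors, its column average CCSI, and a signed-rank
  statistic tested against 1000 bootstrap pseudo-columns of 15 pooled site
  values.
* **Forward model.**  ERP_cal(dᵢ, t) = Σⱼ CSD(dⱼ, t)/√(h² + (dⱼ − dᵢ)²) —
  the extracortical potential implied by the column's currents, compared
  against the observed trace.

## Worked example

```python
import laminfo as L

cfg = L.SynthConfig(seed=42)                       # one synthetic session
rec, trials, truth = L.generate_session(cfg)

model = L.LaminarAttentionModel(rec, trials, n_shuffle=1000, seed=0,
                                info_window=(120, 220))
res = model.fit()                                  # the four-step analysis
print(res.summary())
```

```
Laminar attention-field analysis
================================================================
trials: 600 (correct: 537)   channels: 32   L4/5 boundary: ch 16
bins: 5   lag: 10 ms   shuffles: 1000   alpha: 0.05   persistence: 10 ms
window: 120..220 ms   N2pc: 150..190 ms
----------------------------------------------------------------
statistic                                 peak   t_pk  N2pc   intervals (ms)
step 1 extracortical                     0.783    217   yes   [123,220]
step 2 L2/3                              0.674    185   yes   [125,220]
step 2 L4                                0.042    216    no   -
step 2 L5/6                              0.644    219   yes   [129,220]
step 3 L2/3                              0.856    193   yes   [128,220]
step 3 L4                                0.076    220    no   -
step 3 L5/6                              0.843    208   yes   [132,220]
step 4 L2/3                              0.109    150   yes   [144,172]
step 4 L4                                0.053    148    no   -
step 4 L5/6                              0.080    149   yes   [143,158]
----------------------------------------------------------------
```

Reading the table: step 1 is MI between the extracortical signal and target
position (in bits, peaking at 0.78); step 2 the same per CSD compartment;
step 3 MI between each compartment and the extracortical signal; step 4 the
lagged information transmission.  The `N2pc` column marks persistent
significant intervals overlapping 150–190 ms.  The generator confines
attention modulation to the extragranular (L2/3 sink / L5/6 source) pair,
and the analysis recovers exactly that: target information and transmission
in L2/3 and L5/6, nothing in L4.

```python
cmp = res.erp_comparison()      # forward-modelled vs observed extracortical ERP
```

prints sign agreement `True`, a difference-waveform correlation of 0.96, and
first-divergence times of 127 ms (ERP_cal) vs 122 ms (observed) — the
column's currents reproduce the timing and polarity of the attention-related
extracortical difference.

A command-line layer wraps the same library:

```bash
laminfo synth   --seed 1 --out data/           # one session (HDF5 + CSV)
laminfo info    --session data/session_000.h5 --out results/
laminfo run-all --config pipeline.toml --seed 1 --out results/
```

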