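# flyephys

Analytics for *Drosophila* circadian electrophysiology and behavior: spike-train
irregularity and timing-reliability statistics, postsynaptic-potential (PSP)
event analysis, a second-order Gaussian-mixture model of PSP interval structure
with surrogate-train generation, ROC-based transmission-performance scoring,
calcium-activated potassium (KCa) current isolation, and sleep scoring from
activity-monitor counts.

The package is aimed at electrophysiologists quantifying how neuromodulators
reshape the firing of circadian output neurons (e.g. pars intercerebralis
neurons downstream of clock cells), and it ships a full synthetic-data layer so
every analysis stage can be validated against known ground truth without any
recordings.

## What it computes

**Interval statistics.** For interspike intervals Δt₁…Δtₙ:

- CV = σ(Δt)/⟨Δt⟩ — global irregularity,
- CV2ᵢ = 2|Δtᵢ₊₁ − Δtᵢ|/(Δtᵢ₊₁ + Δtᵢ), reported as the mean over adjacent
  pairs — local irregularity,
- LV = (1/(n−1)) Σ 3(Δtᵢ − Δtᵢ₊₁)²/(Δtᵢ + Δtᵢ₊₁)² — local variation,
- the spike-frequency adaptation index ISI₁/ISIₓ, the peak instantaneous rate
  max(1/Δt), and an exponential decay fit r(t) = A·e^(−t/τ) + C to the
  instantaneous-rate-versus-time plot.

For a gamma renewal process with shape κ, E[CV] = 1/√κ and E[LV] = 3/(2κ+1);
these closed forms anchor the test suite.

**Waveform features and timing reliability.** Spikes are detected from dV/dt
threshold crossings; each spike yields its onset threshold, amplitude,
afterhyperpolarization depth, and onset rapidness (mean dVm/dt from the onset
threshold to the point of peak dVm/dt). The internal consistency of onset
rapidness across repeated recordings is quantified with Cronbach's alpha,
α = k·c̄/(v̄ + (k−1)·c̄).

**Second-order interval model.** Adjacent PSP intervals, normalized by each
cell's mean rate and log-transformed, are modelled as a full-covariance
bivariate Gaussian mixture fitted by EM (component count selected by BIC
within 3–5; a 22×22 log-binned histogram is kept for visualization and
goodness-of-fit). Rate-matched surrogate PSP trains are generated by a
first-order chain whose next log-interval is drawn from the mixture's
conditional density via rejection sampling (200 burn-in draws discarded), with
the target mean frequency drawn from a beta rate model, and binned into 10-ms
binary signals.

**Transmission performance.** Presynaptic-to-postsynaptic convergence ratios
are computed over a grid of 8900 lag tolerances δ ∈ [0.01, 0.9) s and pooled
into a tie-corrected ROC AUC against rate-matched Poisson nulls: AUC 0.5 is
chance, 1 is perfect discrimination.

**KCa currents.** The cadmium-sensitive difference current of paired
voltage-clamp series (without Cd²⁺ minus with 5×10⁻⁴ M CdCl₂) is taken as the
KCa current; per-step peak amplitudes give the I–V relationship.

**Sleep.** A minute is asleep iff it lies in a run of ≥5 consecutive
zero-count minutes; summaries report sleep minutes, bout counts, active time
and waking activity per ZT window, with Trikinetics DAM monitor-file I/O.

## Worked example

```python
import numpy as np
import flyephys as fe
from flyephys import synthgen

# gamma renewal train: rate 10 Hz, shape 4, 5000 events
spec = synthgen.RenewalSpec(rate=10.0, shape=4.0, n_events=5000, seed=1)
isis = fe.isis_from_times(synthgen.gen_renewal_train(spec))
print(f"CV  = {fe.compute_cv(isis):.3f}")   # 0.501  (1/sqrt(4) = 0.500)
print(f"LV  = {fe.compute_lv(isis):.3f}")   # 0.341  (3/(2*4+1) = 0.333)

# second-order mixture of a synthetic PSP train with three planted clusters
psp = synthgen.gen_psp_train(synthgen.three_cluster_spec(),
                             n_events=5000, mean_rate=5.0, seed=3)
model = fe.SecondOrderIntervalModel.from_event_series([np.diff(psp)])
res = model.fit(k_range=(2, 3, 4), seed=0)
print(res.summary())

rate = fe.BetaRateModel(a=2.0, b=5.0, scale_Hz=12.0)
train = res.simulate_train(rate, n_events=2000, seed=7)
print(f"target {train.target_frequency_Hz:.3f} Hz, "
      f"realized {train.realized_frequency_Hz():.3f} Hz")
```

Output:

```
CV  = 0.501
LV  = 0.341
Second-order interval mixture (EM, full covariance)
=======================================================
components: 3   observations: 4998
final log-likelihood/pt: -0.714543  iterations: 5
BIC by k: 2: 12421.6, 3: 7287.4, 4: 7307.6
log range x: [-2.015, 1.116]  y: [-2.015, 1.116]

comp   weight   mean_x   mean_y    var_x    var_y   cov_xy
   0   0.3335   0.7469  -1.6531   0.0397   0.0402   0.0006
   1   0.3331  -1.6538  -0.4482   0.0399   0.0396   0.0005
   2   0.3333  -0.4491   0.7467   0.0399   0.0399  -0.0001

target 3.471 Hz, realized 3.493 Hz
```

BIC selects the three planted components, the recovered means match the
planted cyclic arrangement (up to the known rate-normalization shift), and the
surrogate train's realized mean frequency tracks the beta-sampled target
within 1%.

A `flyephys` console command exposes the same operations on files
(`flyephys simulate renewal ...`, `flyephys detect-spikes ...`,
`flyephys gmm-fit ...`, `flyephys sleep ...`); every subcommand takes an
explicit `--seed` where randomness is involved.

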