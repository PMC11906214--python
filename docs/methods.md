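# Methods

This note documents the models and procedures implemented in `flyephys`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data layer does and does not emulate.

## Interval statistics

CV uses the population standard deviation (divide by n); the sample/population
difference is O(1/n) and immaterial at the train lengths analysed, but the
convention is exposed (`variance_convention`). CV2 is reported as the mean of
the per-pair values 2|Δtᵢ₊₁ − Δtᵢ|/(Δtᵢ₊₁ + Δtᵢ); LV follows the Shinomoto
local-variation form with the 1/(n−1) prefactor. For gamma renewal trains with
shape κ these have closed-form expectations (CV = 1/√κ, LV = 3/(2κ+1), mean
CV2 = 1 at κ = 1), which the tests verify to within three Monte-Carlo standard
errors over replicate trains.

The adaptation index is ISI₁/ISIₓ: 1 means no adaptation, values toward 0 mean
interval prolongation. The axis-label convention ISIₓ/ISI₁ is available via
`orientation="nth_over_first"`; the default matches the "closer to 0 means
prolongation" reading. The decay constant τ is obtained by bounded
least-squares (A, C ≥ 0) of A·e^(−t/τ) + C to instantaneous rates 1/Δtᵢ
plotted at each interval's **end** time (start and midpoint conventions are
available; the choice shifts τ by less than the fit noise at realistic rates).
Fits with amplitude indistinguishable from zero are flagged `degenerate` —
τ is unidentifiable for constant-rate data and should not be interpreted.

## Spike detection and waveform features

Detection is a dV/dt threshold crossing (default 10 V/s) followed by a local
voltage-maximum search; candidates closer than `min_separation_ms` (default
2 ms) merge keeping the larger peak, so the detected count is monotone
non-increasing in the threshold. The onset point of each spike is where dV/dt
first exceeds `onset_fraction` (default 0.05) of that spike's maximal dV/dt —
no universal criterion exists, so the fraction is a parameter. Threshold,
amplitude and AHP are read off the voltage at onset, peak and the post-peak
minimum (window 50 ms, truncated at the next spike's onset). Onset rapidness
is the chord slope from the onset sample to the sample of peak dV/dt, which on
a noise-free linear rise equals the rendered slope exactly; spikes whose
windows hit the trace edge are flagged invalid and excluded from statistics.

Cronbach's alpha is computed in the standard covariance form
α = k·c̄/(v̄ + (k−1)·c̄) with sample (ddof = 1) covariances. By default the
items are the individual action potentials (columns of a [datasets × spikes]
matrix) and covariances are taken across datasets; because how the repeated
"datasets" of a recording are delimited (sweeps, time blocks) is a design
choice of the analyst, the orientation is exposed (`items="rows"` treats the
datasets as items). When the total variance v̄ + (k−1)·c̄ is zero the
statistic is 0/0 and is signalled as `UndefinedReliabilityError` rather than
returned as a number.

## PSP events and distributions

PSPs are detected from the Gaussian-smoothed (σ = 0.5 ms) derivative; the
event time is the derivative-threshold crossing (onset-like), and the
amplitude is the local peak minus the **median** voltage of the preceding
20 ms — a robust baseline that tolerates overlapping decay tails. Events
below the amplitude threshold are dropped; closer-than-`min_separation`
events merge keeping the larger amplitude. Amplitude ECDFs and interval KDEs
(scipy Gaussian KDE) pool events across cells by default; per-cell
aggregation is a caller-side choice since the appropriate unit of
replication (event vs cell) depends on the design.

## Second-order interval mixture

Preprocessing multiplies each cell's intervals by the cell's mean event rate
(equivalently divides by the mean interval), making them dimensionless with
sample mean exactly 1, then forms adjacent log pairs (log uᵢ, log uᵢ₊₁) and
aggregates across cells. A 22×22 histogram over the per-condition [1st, 99th]
percentile log range is kept for visualization and goodness-of-fit; the
mixture itself is fitted to the **continuous** pairs — fitting binned counts
would discard within-bin information for no benefit.

EM is implemented directly (vectorized numpy) so the per-iteration
log-likelihood trajectory is part of the results object and its monotonicity
is asserted on every iteration; convergence is declared when the per-point
log-likelihood improves by less than 10⁻⁶. Covariances are ridged with 10⁻⁶
on the diagonal only when nearly singular; because a ridged M-step is no
longer an exact EM step, a sub-tolerance decrease immediately after ridging
terminates the run at the previous (monotone) iterate instead of failing.
Component count is selected by lowest BIC (6k−1 free parameters per k);
restarts (default 3) keep the best likelihood. sklearn's GaussianMixture is
used in the test suite as an independent cross-check of the estimates, never
as the implementation.

Surrogate trains are built as a first-order chain: given the current
log-interval x, the next is drawn from the mixture's conditional density
p(y|x), which for a Gaussian mixture is itself a univariate mixture with
responsibility-reweighted weights. Two samplers implement the same kernel:
an exact closed-form conditional sampler (the oracle) and rejection sampling
against a uniform proposal whose envelope is 1.05× the maximum conditional
density on a 1024-point grid (rebuilt on a finer grid if ever violated;
an observed acceptance probability below 10⁻³ raises). The proposal support
spans the component means ±8 SD — deliberately wider than the histogram's
percentile range so no appreciable conditional mass is truncated; the two
samplers are statistically indistinguishable at n = 10⁴ (two-sample KS).
The chain starts from the model's x-marginal and discards exactly 200
burn-in draws.

Rate matching: a target frequency f is drawn from a beta rate model —
frequencies scaled into (0,1) by `scale_Hz` (1.05× the largest observed
frequency when fitted, so the support strictly contains the data) with
Beta(a,b) parameters obtained by moment matching. Chain log-intervals are
exponentiated and divided by f·m, where m is the model-implied mean
normalized interval (closed-form lognormal-mixture mean). For a model fitted
to rate-normalized data m ≈ 1 and this reduces to plain division by f; the
m factor makes the realized mean frequency track f (within 5% at n = 2000)
for *any* mixture, including planted test mixtures whose mean normalized
interval is not 1. Trains are binned into 10-ms binary signals (bin = 1 iff
≥1 event).

## Convergence ratios and ROC

The convergence ratio of a presynaptic to a postsynaptic 10-ms binary signal
at lag tolerance δ is the fraction of presynaptic event bins with at least
one postsynaptic event within ⌈δ/10 ms⌉ bins (forward window); it is 1 when
the postsynaptic train contains the presynaptic one and monotone
non-decreasing in δ. The δ grid is the half-open arithmetic grid
[0.01, 0.9) s at 10⁻⁴ — exactly 8900 values. The score construction is kept
behind a strategy function (`score_fn`) so alternative definitions can be
swapped without touching the ROC code. Processing performance pools the
per-δ scores of condition trains and rate-matched Poisson null trains
(binarized identically) into one tie-corrected rank AUC
(Mann–Whitney U / n₊n₋), which equals the trapezoidal area under the ROC
curve; the brute-force pairwise probability P(s₊ > s₋) + ½P(tie) and
sklearn's `roc_auc_score` serve as oracles in the tests.

## KCa isolation

The KCa current is the pointwise difference (without Cd²⁺ − with Cd²⁺) of
sweep sets on identical command-voltage grids (the standard protocol is
200-ms pulses, −80…+60 mV in 10-mV steps). The I–V summary takes the per-step
signed maximum within the pulse window after blanking the first 5 ms
(capacitance transient; no criterion exists in the field for this cutoff, so
it is a parameter), with an absolute-value convention behind a flag. No leak
subtraction or conductance fitting is performed.

## Sleep scoring

A minute is asleep iff it lies in a maximal run of ≥5 consecutive zero-count
minutes; a bout is such a run. Windows are half-open in ZT minutes
(ZT0–12 = [0, 720)) and pooled across days. Bouts straddling a window
boundary are attributed to the window containing their first minute by
default (`bout_attribution="split"` apportions them pro rata) — the
convention is documented because no standard exists. "Active time" is the
number of awake minutes with ≥1 count, distinct from awake minutes; waking
activity is total counts per awake minute and is undefined (None) for a
fully asleep record. The first day after loading is excluded by trimming to
the second occurrence of ZT0. The DAM reader/writer use a documented
tab-delimited monitor dialect (index, date, time, status, six spare columns,
light flag, 32 channel counts); rows with a non-OK status are dropped with a
log entry, and all file fixtures in the tests are generated programmatically
through the writer.

## Synthetic-data layer

The generators define the study conditions for all tests:

- gamma renewal trains (rate, shape, n, seed) — iid Gamma(κ) intervals;
- spike traces — baseline at threshold, linear rise at the requested onset
  slope, shifted-exponential repolarization landing exactly at threshold −
  AHP, exponential recovery (τ = 10 ms) truncated at the next onset, plus
  Gaussian noise. The baseline-at-threshold choice makes every rendered
  feature (threshold, amplitude, AHP, slope) exactly recoverable, at the cost
  of not emulating a subthreshold depolarizing approach;
- PSP trains — first-order chains through a planted bivariate mixture. The
  canned three-component spec uses a cyclic mean arrangement
  ((−1.2, 0), (0, 1.2), (1.2, −1.2), equal weights, isotropic variance 0.04)
  whose x- and y-marginals coincide, which guarantees both that the chain
  mixes across components and that consecutive pairs are marginally
  distributed as the planted joint — the condition under which
  parameter-recovery oracles are exact;
- subthreshold PSP traces — additive difference-of-exponentials kernels
  (rise 2 ms, decay 15 ms);
- paired voltage-clamp sweeps — series A = passive + planted KCa component,
  series B = passive, optionally averaged over noisy sweeps, with the planted
  component returned as the subtraction oracle;
- activity records — scripted active/inactive bouts; active minutes draw
  Poisson counts clipped below at 1 so a scripted active minute can never be
  scored asleep, making bout scripts exact fixtures.

What passing these tests shows — and does not. The generators produce
stationary, stereotyped, single-channel data with known ground truth. They do
not emulate electrode drift, seal instability, overlapping spike/PSP
waveforms beyond the rendered spans, bursting or nonstationary rates, or
monitor hardware artifacts; performance on real recordings therefore depends
on detector thresholds chosen against the recording's noise, which the
synthetic results do not certify.

## Problem sizes and numerical choices

Closed-form oracle tests use trains of 5000 intervals with 20 Monte-Carlo
replicates (3-SE bands); mixture recovery uses n = 5000 pairs; BIC selection
consistency uses 100 seeds at n = 2000 with 3 restarts; sampler-equivalence
checks use 10⁴ draws per sampler over 20 seeds at a fixed conditioning value
(iid draws, so KS assumptions hold exactly — pooled chain output is
autocorrelated and would make KS p-values non-uniform). These sizes give the
oracle comparisons sub-percent precision while keeping the full suite around
a minute of runtime on one core.

Known limitations: the second-order model is first-order Markov by
construction and cannot represent longer-range serial structure; the beta
rate model's frequency scaling is a modelling choice (no canonical scale
exists for mapping beta support to Hz); the convergence-ratio definition is
one member of a family and is deliberately pluggable; and Cronbach's alpha is
undefined (not 1) when there is no variance anywhere in the slope matrix.
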