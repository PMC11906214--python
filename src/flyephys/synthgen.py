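"""Synthetic-data generators with known ground truth.

Every downstream stage of the package (spike detection, waveform feature
extraction, interval statistics, the second-order interval mixture model,
cadmium-subtraction, sleep scoring) is testable against data produced here:

* gamma renewal spike trains with controlled rate and shape,
* spikes rendered on a noisy membrane-potential trace with a parameterized
  stereotyped waveform (threshold, amplitude, afterhyperpolarization, onset
  slope),
* PSP trains whose adjacent log-interval pairs follow a planted bivariate
  Gaussian mixture,
* subthreshold PSP traces,
* paired voltage-clamp sweep sets differing by a known cadmium-sensitive
  component,
* 1-min binned locomotor-activity records with scripted inactivity bouts.

All generators are pure functions of (spec, seed) and return their ground
truth in the same schema the corresponding detector emits, so detection and
fitting stages can be scored by direct comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _mixture
from .kca_currents import SweepSet
from .sleep_behavior import ActivityRecord
from .spike_waveform import VoltageTrace


class OverlapError(ValueError):
    """Raised when planted events are closer than the rendered waveform span."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RenewalSpec:
    """Gamma renewal process: iid Gamma(shape) intervals with mean 1/rate.

    shape=1 gives a Poisson process; larger shapes give more regular trains
    (CV of the intervals is 1/sqrt(shape)).
    """

    rate: float
    shape: float = 1.0
    n_events: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0 or self.shape <= 0:
            raise ValueError("rate and shape must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be a positive integer")


@dataclass(frozen=True)
class WaveformSpec:
    """Stereotyped action-potential waveform parameters.

    The spike is rendered as a linear rise from threshold to peak at
    ``onset_slope_Vps``, an exponential repolarization to ``ahp_mV`` below
    threshold, and an exponential recovery back to baseline.  The trace
    baseline sits at threshold so the rendered afterhyperpolarization depth
    equals ``ahp_mV`` exactly; Gaussian noise of ``noise_sd_mV`` is added on
    top.  Amplitude must exceed 10x the noise SD so planted spikes are
    detectable by construction.
    """

    threshold_mV: float = -40.0
    amplitude_mV: float = 40.0
    ahp_mV: float = 8.0
    onset_slope_Vps: float = 50.0
    noise_sd_mV: float = 0.0
    sampling_rate_Hz: float = 20_000.0
    repol_tau_ms: float = 1.5
    ahp_tau_ms: float = 10.0

    def __post_init__(self):
        if self.amplitude_mV <= 0 or self.onset_slope_Vps <= 0:
            raise ValueError("amplitude and onset slope must be positive")
        if self.ahp_mV < 0 or self.noise_sd_mV < 0:
            raise ValueError("ahp_mV and noise_sd_mV must be non-negative")
        if self.noise_sd_mV > 0 and self.amplitude_mV <= 10.0 * self.noise_sd_mV:
            raise ValueError("amplitude_mV must exceed 10x noise_sd_mV")


@dataclass(frozen=True)
class ClusterSpec:
    """Planted bivariate Gaussian mixture over adjacent log-interval pairs."""

    weights: tuple
    means: tuple
    covariances: tuple

    def arrays(self):
        return _mixture.validate_mixture(self.weights, self.means, self.covariances)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def mean_normalized_interval(self) -> float:
        """Closed-form E[exp(log u)] under the y-marginal (lognormal mixture)."""
        w, mu, cov = self.arrays()
        return _mixture.mean_exp_marginal(w, mu, cov, axis=1)


def three_cluster_spec(spread: float = 1.2, var: float = 0.04) -> ClusterSpec:
    """Three well-separated components in a cyclic arrangement.

    Means (-s, 0), (0, s), (s, -s) with equal weights and isotropic variance:
    the x- and y-marginals coincide, so a first-order chain driven by the
    conditional density visits all components and its consecutive pairs are
    distributed exactly as the planted joint.
    """
    s = float(spread)
    eye = ((var, 0.0), (0.0, var))
    return ClusterSpec(
        weights=(1 / 3, 1 / 3, 1 / 3),
        means=((-s, 0.0), (0.0, s), (s, -s)),
        covariances=(eye, eye, eye),
    )


def single_cluster_spec(var: float = 0.05, mean: float = 0.0) -> ClusterSpec:
    """One spherical component centred on the diagonal."""
    return ClusterSpec(
        weights=(1.0,),
        means=((mean, mean),),
        covariances=(((var, 0.0), (0.0, var)),),
    )


@dataclass(frozen=True)
class Bout:
    """One scripted activity bout: active or inactive for a whole number of minutes."""

    active: bool
    duration_min: int
    counts_per_min: float = 0.0

    def __post_init__(self):
        if self.duration_min < 1 or int(self.duration_min) != self.duration_min:
            raise ValueError("duration_min must be a positive integer")
        if self.active and self.counts_per_min <= 0:
            raise ValueError("active bouts need counts_per_min > 0")


# ---------------------------------------------------------------------------
# generators


def gen_renewal_train(spec: RenewalSpec) -> np.ndarray:
    """Event times (s) of a gamma renewal train; reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    isis = rng.gamma(spec.shape, scale=1.0 / (spec.rate * spec.shape), size=spec.n_events)
    return np.cumsum(isis)


def gen_voltage_trace(
    times,
    wf: WaveformSpec,
    duration_s: float | None = None,
    seed: int = 0,
) -> tuple[VoltageTrace, pd.DataFrame]:
    """Render planted spikes onto a noisy membrane-potential trace.

    Each event time is treated as the spike onset.  Returns the trace and a
    ground-truth table in the detector/extractor schema (onset_time_s,
    peak_time_s, threshold_mV, amplitude_mV, ahp_mV, onset_slope_Vps) with
    the *rendered* (sample-quantized) onset slope.
    """
    times = np.sort(np.asarray(times, dtype=float))
    fs = wf.sampling_rate_Hz
    if duration_s is None:
        duration_s = (times[-1] if times.size else 0.0) + 0.1
    n = int(round(duration_s * fs))
    baseline = wf.threshold_mV
    v = np.full(n, baseline)

    n_rise = max(2, int(round(wf.amplitude_mV / (wf.onset_slope_Vps * 1000.0) * fs)))
    n_rep = max(2, int(round(6.0 * wf.repol_tau_ms * 1e-3 * fs)))
    peak = wf.threshold_mV + wf.amplitude_mV
    trough = wf.threshold_mV - wf.ahp_mV
    rendered_slope = wf.amplitude_mV / 1000.0 * fs / n_rise

    onset_idx = np.round(times * fs).astype(int)
    rows = []
    for k, i0 in enumerate(onset_idx):
        i_peak = i0 + n_rise
        i_rep_end = i_peak + n_rep
        next_onset = onset_idx[k + 1] if k + 1 < onset_idx.size else n
        if i_rep_end >= next_onset:
            raise OverlapError(
                f"events at {times[k]:.4f}s and beyond overlap the waveform span"
            )
        if i_rep_end >= n:
            raise OverlapError("event waveform extends past the trace end")
        # linear rise threshold -> peak
        v[i0 : i_peak + 1] = baseline + wf.amplitude_mV * np.arange(n_rise + 1) / n_rise
        # shifted exponential repolarization hitting the trough exactly
        t = np.arange(1, n_rep + 1) / fs
        tau = wf.repol_tau_ms * 1e-3
        w = (np.exp(-t / tau) - np.exp(-t[-1] / tau)) / (1.0 - np.exp(-t[-1] / tau))
        v[i_peak + 1 : i_rep_end + 1] = trough + (peak - trough) * w
        # AHP recovery toward baseline, truncated at the next onset
        n_rec = next_onset - i_rep_end - 1
        if n_rec > 0 and wf.ahp_mV > 0:
            t = np.arange(1, n_rec + 1) / fs
            tau = wf.ahp_tau_ms * 1e-3
            v[i_rep_end + 1 : next_onset] = baseline - wf.ahp_mV * np.exp(-t / tau)
        rows.append(
            {
                "onset_time_s": i0 / fs,
                "peak_time_s": i_peak / fs,
                "threshold_mV": wf.threshold_mV,
                "amplitude_mV": wf.amplitude_mV,
                "ahp_mV": wf.ahp_mV,
                "onset_slope_Vps": rendered_slope,
            }
        )
    if wf.noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, wf.noise_sd_mV, size=n)
    trace = VoltageTrace(samples_mV=v, sampling_rate_Hz=fs)
    truth = pd.DataFrame(
        rows,
        columns=[
            "onset_time_s",
            "peak_time_s",
            "threshold_mV",
            "amplitude_mV",
            "ahp_mV",
            "onset_slope_Vps",
        ],
    )
    return trace, truth


def gen_psp_train(
    clusters: ClusterSpec,
    n_events: int,
    mean_rate: float,
    seed: int = 0,
    burn_in: int = 200,
) -> np.ndarray:
    """PSP event times whose adjacent log-interval pairs follow the planted mixture.

    The train is built as a first-order chain: the next log-interval is drawn
    from the planted conditional density given the current one (exact
    closed-form sampling).  Intervals are exponentiated and scaled by
    1 / (mean_rate * m), where m is the planted mixture's closed-form mean
    normalized interval, so the realized mean rate matches ``mean_rate``.
    """
    if n_events < 2:
        raise ValueError("n_events must be at least 2")
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    w, mu, cov = clusters.arrays()
    rng = np.random.default_rng(seed)
    draws = _mixture.sample_chain(w, mu, cov, n_events, rng, burn_in=burn_in, method="exact")
    intervals = np.exp(draws) / (mean_rate * clusters.mean_normalized_interval())
    return np.cumsum(intervals)


def gen_psp_trace(
    times,
    amplitudes_mV,
    baseline_mV: float = -60.0,
    tau_rise_ms: float = 2.0,
    tau_decay_ms: float = 15.0,
    noise_sd_mV: float = 0.0,
    sampling_rate_Hz: float = 10_000.0,
    duration_s: float | None = None,
    seed: int = 0,
) -> tuple[VoltageTrace, pd.DataFrame]:
    """Render subthreshold PSPs (difference-of-exponentials kernel) additively."""
    times = np.asarray(times, dtype=float)
    amps = np.broadcast_to(np.asarray(amplitudes_mV, dtype=float), times.shape)
    fs = sampling_rate_Hz
    if duration_s is None:
        duration_s = (times.max() if times.size else 0.0) + 10.0 * tau_decay_ms * 1e-3
    n = int(round(duration_s * fs))
    v = np.full(n, baseline_mV)
    tr, td = tau_rise_ms * 1e-3, tau_decay_ms * 1e-3
    t_kernel = np.arange(int(round(8.0 * td * fs))) / fs
    kernel = np.exp(-t_kernel / td) - np.exp(-t_kernel / tr)
    kernel /= kernel.max()
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * fs))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            v[i0 : i0 + seg] += a * kernel[:seg]
    if noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_mV, size=n)
    truth = pd.DataFrame({"time_s": times, "amplitude_mV": amps})
    return VoltageTrace(samples_mV=v, sampling_rate_Hz=fs), truth


def gen_activity_record(
    script: list[Bout],
    seed: int = 0,
    start_zt_min: int = 0,
    fly_id: str = "synthetic",
) -> ActivityRecord:
    """1-min activity counts realizing the scripted bouts exactly.

    Inactive minutes get 0 counts; active minutes get Poisson counts with the
    stated mean, clipped below at 1 so an "active" minute can never be scored
    asleep.
    """
    if not script:
        raise ValueError("script must contain at least one bout")
    rng = np.random.default_rng(seed)
    chunks = []
    for bout in script:
        if bout.active:
            c = rng.poisson(bout.counts_per_min, size=bout.duration_min)
            chunks.append(np.maximum(c, 1))
        else:
            chunks.append(np.zeros(bout.duration_min, dtype=int))
    counts = np.concatenate(chunks)
    return ActivityRecord(counts=counts, start_zt_min=start_zt_min, fly_id=fly_id)


@dataclass
class PairedSweeps:
    """Two voltage-clamp series and the planted cadmium-sensitive component."""

    without_cd: SweepSet
    with_cd: SweepSet
    kca_truth: SweepSet = field(repr=False, default=None)


def gen_paired_sweeps(
    kca_pA,
    passive_pA,
    voltages_mV,
    sampling_rate_Hz: float = 10_000.0,
    pulse_window_ms: tuple[float, float] = (0.0, 200.0),
    noise_sd_pA: float = 0.0,
    n_sweeps: int = 1,
    seed: int = 0,
) -> PairedSweeps:
    """Paired sweep sets: series A = passive + KCa, series B = passive.

    ``kca_pA`` and ``passive_pA`` are (n_steps, n_samples) arrays on the same
    step grid; mismatched shapes raise.  With ``n_sweeps`` > 1, each series is
    an average of that many sweeps with iid Gaussian noise per sweep, which is
    how repeated voltage-clamp acquisitions are usually reduced.
    """
    kca = np.asarray(kca_pA, dtype=float)
    passive = np.asarray(passive_pA, dtype=float)
    voltages = np.asarray(voltages_mV, dtype=float)
    if kca.shape != passive.shape or kca.shape[0] != voltages.size:
        raise ValueError("kca, passive and voltage grids must align")
    rng = np.random.default_rng(seed)

    def realize(clean):
        if noise_sd_pA == 0:
            return clean.copy()
        sweeps = clean[None] + rng.normal(0.0, noise_sd_pA, size=(n_sweeps,) + clean.shape)
        return sweeps.mean(axis=0)

    mk = lambda arr: SweepSet(
        voltages_mV=voltages,
        currents_pA=arr,
        sampling_rate_Hz=sampling_rate_Hz,
        pulse_window_ms=pulse_window_ms,
    )
    return PairedSweeps(
        without_cd=mk(realize(passive + kca)),
        with_cd=mk(realize(passive)),
        kca_truth=mk(kca.copy()),
    )
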