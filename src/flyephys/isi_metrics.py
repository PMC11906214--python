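"""Interspike-interval statistics.

Global and local irregularity measures of a spike (or PSP) train:

* CV     = sigma(dt) / mean(dt)                      (global irregularity)
* CV2_i  = 2 |dt_{i+1} - dt_i| / (dt_{i+1} + dt_i)   (local, averaged)
* LV     = 1/(n-1) sum 3 (dt_i - dt_{i+1})^2 / (dt_i + dt_{i+1})^2

together with the spike-frequency adaptation index (ratio of the first to the
x-th interval), the peak instantaneous rate max(1/dt), and an exponential
decay fit r(t) = A exp(-t/tau) + C to the instantaneous-rate-versus-time
plot.  For a gamma renewal process with shape kappa the expectations are
CV = 1/sqrt(kappa) and LV = 3/(2 kappa + 1); mean CV2 = 1 for a Poisson
train.  These closed forms are the module's main correctness surface.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit


class IsiDataError(ValueError):
    """Raised on non-positive intervals or too few of them."""


def _check_isis(isis, n_min):
    x = np.asarray(isis, dtype=float)
    if x.ndim != 1 or x.size < n_min:
        raise IsiDataError(f"need at least {n_min} intervals, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise IsiDataError("intervals must be positive and finite")
    return x


def isis_from_times(event_times_s) -> np.ndarray:
    """Successive differences of an ordered event-time vector."""
    t = np.asarray(event_times_s, dtype=float)
    d = np.diff(t)
    if np.any(d <= 0):
        raise IsiDataError("event times must be strictly increasing")
    return d


def compute_cv(isis, variance_convention: str = "population") -> float:
    """Coefficient of variation SD(dt)/mean(dt) (population SD by default)."""
    x = _check_isis(isis, 2)
    ddof = 0 if variance_convention == "population" else 1
    return float(np.std(x, ddof=ddof) / np.mean(x))


def cv2_pairs(isis) -> np.ndarray:
    """Per-adjacent-pair CV2 values 2|dt_{i+1}-dt_i|/(dt_{i+1}+dt_i)."""
    x = _check_isis(isis, 2)
    return 2.0 * np.abs(np.diff(x)) / (x[1:] + x[:-1])


def compute_cv2(isis) -> float:
    """Mean CV2 over all adjacent interval pairs."""
    x = _check_isis(isis, 3)
    return float(np.mean(cv2_pairs(x)))


def compute_lv(isis) -> float:
    """Local variation: mean of 3 (dt_i - dt_{i+1})^2 / (dt_i + dt_{i+1})^2."""
    x = _check_isis(isis, 3)
    num = (x[:-1] - x[1:]) ** 2
    den = (x[:-1] + x[1:]) ** 2
    return float(np.mean(3.0 * num / den))


def adaptation_index(isis, x: int, orientation: str = "first_over_nth") -> float:
    """Spike-frequency adaptation index ISI_1 / ISI_x (1-based x).

    A value of 1 means no adaptation; values toward 0 mean the intervals
    lengthen over the train (adaptation with ISI prolongation).  Pass
    ``orientation="nth_over_first"`` for the reciprocal convention.
    """
    d = _check_isis(isis, 2)
    if not 2 <= x <= d.size:
        raise ValueError(f"x must lie in [2, {d.size}]")
    r = d[0] / d[x - 1]
    if orientation == "nth_over_first":
        return float(1.0 / r)
    if orientation != "first_over_nth":
        raise ValueError("orientation must be 'first_over_nth' or 'nth_over_first'")
    return float(r)


def peak_rate(isis) -> float:
    """Largest instantaneous frequency max(1/dt), in Hz."""
    x = _check_isis(isis, 1)
    return float(np.max(1.0 / x))


@dataclass
class ExponentialDecayFit:
    """Result of fitting r(t) = A exp(-t / tau) + C to instantaneous rates.

    ``degenerate`` flags fits where the amplitude is indistinguishable from
    zero (constant-rate data), in which case tau is unidentifiable.
    """

    amplitude_Hz: float
    tau_s: float
    offset_Hz: float
    degenerate: bool
    residual_rms_Hz: float

    def predict(self, t):
        return self.amplitude_Hz * np.exp(-np.asarray(t) / self.tau_s) + self.offset_Hz


def decay_tau(
    event_times_s,
    rate_timestamp: str = "end",
    degenerate_rtol: float = 1e-3,
) -> ExponentialDecayFit:
    """Fit an exponential decay to the instantaneous-rate-versus-time plot.

    Rates 1/dt_i are plotted at each interval's end time (or start/midpoint
    via ``rate_timestamp``) and r(t) = A exp(-t/tau) + C is fitted by bounded
    least squares with A, C >= 0.  Raises a RuntimeError with diagnostics on
    non-convergence.
    """
    t = np.asarray(event_times_s, dtype=float)
    d = isis_from_times(t)
    if d.size < 4:
        raise IsiDataError("need at least 4 intervals for a decay fit")
    rates = 1.0 / d
    ts = {"end": t[1:], "start": t[:-1], "mid": (t[:-1] + t[1:]) / 2.0}
    try:
        tt = ts[rate_timestamp]
    except KeyError:
        raise ValueError("rate_timestamp must be 'end', 'start' or 'mid'") from None
    tt = tt - tt[0]

    span = rates.max() - rates.min()
    p0 = (max(span, 1e-9), max((tt[-1] - tt[0]) / 3.0, 1e-6), max(rates.min(), 0.0))
    model = lambda x, a, tau, c: a * np.exp(-x / tau) + c
    try:
        popt, _ = curve_fit(
            model,
            tt,
            rates,
            p0=p0,
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"decay fit did not converge (n={d.size}, rate span {span:.3g} Hz): {err}"
        ) from err
    a, tau, c = popt
    resid = rates - model(tt, *popt)
    degenerate = a <= degenerate_rtol * max(rates.mean(), 1e-12)
    return ExponentialDecayFit(
        amplitude_Hz=float(a),
        tau_s=float(tau),
        offset_Hz=float(c),
        degenerate=bool(degenerate),
        residual_rms_Hz=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class IsiMetricSet:
    """All interval statistics of one train, computed in one pass."""

    n: int
    cv: float
    cv2: float
    lv: float
    adaptation_index: float
    peak_rate_Hz: float
    decay_tau_s: float
    decay_offset_Hz: float
    decay_degenerate: bool

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_train(event_times_s, adaptation_x: int | None = None) -> IsiMetricSet:
    """Compute the full metric set from event times.

    ``adaptation_x`` defaults to the last interval (the 1st-to-nth ratio).
    """
    t = np.asarray(event_times_s, dtype=float)
    d = isis_from_times(t)
    if adaptation_x is None:
        adaptation_x = d.size
    fit = decay_tau(t)
    return IsiMetricSet(
        n=int(d.size),
        cv=compute_cv(d),
        cv2=compute_cv2(d),
        lv=compute_lv(d),
        adaptation_index=adaptation_index(d, adaptation_x),
        peak_rate_Hz=peak_rate(d),
        decay_tau_s=fit.tau_s,
        decay_offset_Hz=fit.offset_Hz,
        decay_degenerate=fit.degenerate,
    )
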