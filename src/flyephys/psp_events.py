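"""Postsynaptic-potential (PSP) event detection and distribution summaries.

PSPs are subthreshold depolarizations detected from the smoothed derivative
of a sharp-electrode voltage trace; amplitudes are measured against a robust
pre-event baseline.  Summaries are the empirical cumulative distribution of
amplitudes and a kernel density estimate of inter-event intervals, with
pooling across cells as the default aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gaussian_kde

from .spike_waveform import VoltageTrace, dvdt_Vps


@dataclass
class PspEventSeries:
    """Detected PSP events of one cell under one condition."""

    event_times_s: np.ndarray
    amplitudes_mV: np.ndarray
    cell_id: str = "cell0"
    condition: str = ""
    inter_event_intervals_s: np.ndarray = field(init=False)

    def __post_init__(self):
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.amplitudes_mV = np.asarray(self.amplitudes_mV, dtype=float)
        if self.event_times_s.size != self.amplitudes_mV.size:
            raise ValueError("times and amplitudes must align")
        if np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes_mV <= 0):
            raise ValueError("amplitudes must be positive")
        self.inter_event_intervals_s = np.diff(self.event_times_s)

    @property
    def n_events(self) -> int:
        return self.event_times_s.size

    def mean_rate_Hz(self) -> float:
        if self.n_events < 2:
            raise ValueError("need >= 2 events for a rate")
        return float(1.0 / np.mean(self.inter_event_intervals_s))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.event_times_s,
                "amplitude_mV": self.amplitudes_mV,
                "interval_s": np.concatenate(([np.nan], self.inter_event_intervals_s)),
                "cell": self.cell_id,
                "condition": self.condition,
            }
        )


def detect_psps(
    trace: VoltageTrace,
    amp_threshold_mV: float = 1.0,
    dvdt_threshold_Vps: float = 0.2,
    min_separation_ms: float = 10.0,
    baseline_window_ms: float = 20.0,
    smooth_ms: float = 0.5,
    cell_id: str = "cell0",
    condition: str = "",
) -> PspEventSeries:
    """Detect PSP-like events from the smoothed voltage derivative.

    A candidate opens where the smoothed dV/dt rises through
    ``dvdt_threshold_Vps``; its peak is the local maximum of the smoothed
    voltage before the derivative next turns negative for good.  The event
    amplitude is peak minus the median voltage over the preceding
    ``baseline_window_ms`` (robust to overlapping decay tails); events below
    ``amp_threshold_mV`` are dropped and events closer than
    ``min_separation_ms`` are merged keeping the larger amplitude.

    A threshold below the estimated derivative noise floor triggers a warning
    (not an error): detection will run but likely return noise events.
    """
    fs = trace.sampling_rate_Hz
    sigma = smooth_ms * 1e-3 * fs
    v_s = gaussian_filter1d(trace.samples_mV, sigma) if sigma > 0 else trace.samples_mV
    d = np.gradient(v_s) * fs / 1000.0
    noise_floor = 1.4826 * np.median(np.abs(d - np.median(d)))
    if dvdt_threshold_Vps < noise_floor:
        warnings.warn(
            f"dV/dt threshold {dvdt_threshold_Vps:.3g} V/s is below the estimated "
            f"noise floor {noise_floor:.3g} V/s",
            stacklevel=2,
        )
    above = d >= dvdt_threshold_Vps
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    base_win = max(1, int(round(baseline_window_ms * 1e-3 * fs)))
    search = max(1, int(round(5 * baseline_window_ms * 1e-3 * fs)))
    cands = []
    for c in crossings:
        stop = c + 1
        while stop < v_s.size and d[stop] > 0:
            stop += 1
        stop = min(max(stop + 1, c + 2), min(c + search, v_s.size))
        p = c + int(np.argmax(v_s[c:stop]))
        baseline = float(np.median(trace.samples_mV[max(0, c - base_win) : max(1, c)]))
        amp = float(v_s[p] - baseline)
        if amp >= amp_threshold_mV:
            cands.append((c, amp))  # event time = onset (derivative crossing)
    min_sep = int(round(min_separation_ms * 1e-3 * fs))
    merged: list[tuple[int, float]] = []
    for p, amp in sorted(set(cands)):
        if merged and p - merged[-1][0] < min_sep:
            if amp > merged[-1][1]:
                merged[-1] = (p, amp)
        else:
            merged.append((p, amp))
    idx = np.array([p for p, _ in merged], dtype=int)
    amps = np.array([a for _, a in merged], dtype=float)
    return PspEventSeries(
        event_times_s=trace.t0_s + idx / fs,
        amplitudes_mV=amps,
        cell_id=cell_id,
        condition=condition,
    )


def pool_series(series_list: list[PspEventSeries], attr: str) -> np.ndarray:
    """Pool an attribute (amplitudes_mV or inter_event_intervals_s) across cells."""
    return np.concatenate([np.asarray(getattr(s, attr)) for s in series_list])


def ecdf_amplitude(series) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF of PSP amplitudes.

    Accepts one series or a list (pooled).  Returns (sorted unique
    amplitudes, cumulative probabilities); the last probability is exactly 1.
    """
    if isinstance(series, PspEventSeries):
        amps = series.amplitudes_mV
    else:
        amps = pool_series(list(series), "amplitudes_mV")
    if amps.size == 0:
        raise ValueError("need at least one event for an ECDF")
    x = np.sort(amps)
    uniq, counts = np.unique(x, return_counts=True)
    return uniq, np.cumsum(counts) / x.size


def interval_density(
    series,
    bandwidth: float | str = "scott",
    grid_points: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of inter-event intervals on a grid covering the support.

    ``bandwidth`` is passed to scipy's gaussian_kde (rule name or a numeric
    factor).  The returned density integrates to ~1 over the grid.  Raises on
    fewer than two events (a single event has no interval).
    """
    if isinstance(series, PspEventSeries):
        ivals = series.inter_event_intervals_s
    else:
        ivals = pool_series(list(series), "inter_event_intervals_s")
    if ivals.size < 1:
        raise ValueError("interval density undefined for fewer than two events")
    try:
        kde = gaussian_kde(ivals, bw_method=bandwidth)
    except np.linalg.LinAlgError as err:
        raise ValueError("interval density undefined: intervals have no spread") from err
    pad = 4.0 * np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(ivals.min() - pad, ivals.max() + pad, grid_points)
    return grid, kde(grid)
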