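"""Action-potential detection, waveform features, and timing reliability.

Detects spikes in an intracellular voltage trace by a dV/dt criterion,
extracts per-spike waveform features (onset threshold, amplitude,
afterhyperpolarization depth, and onset rapidness — the mean dVm/dt from the
onset threshold to the point of peak dVm/dt), and quantifies the internal
consistency of onset rapidness across repeated recordings with Cronbach's
alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_COLUMNS = [
    "onset_time_s",
    "peak_time_s",
    "threshold_mV",
    "amplitude_mV",
    "ahp_mV",
    "onset_slope_Vps",
    "valid",
]


class NonUniformSamplingError(ValueError):
    """Raised when a time/voltage table is not uniformly sampled."""


class UndefinedReliabilityError(ZeroDivisionError):
    """Raised when Cronbach's alpha is 0/0 (no variance anywhere)."""


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential in mV."""

    samples_mV: np.ndarray
    sampling_rate_Hz: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples_mV = np.asarray(self.samples_mV, dtype=float)
        if self.samples_mV.ndim != 1:
            raise ValueError("samples_mV must be 1-D")
        if not np.all(np.isfinite(self.samples_mV)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate_Hz <= 0:
            raise ValueError("sampling_rate_Hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples_mV.size / self.sampling_rate_Hz

    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples_mV.size) / self.sampling_rate_Hz

    @classmethod
    def from_table(cls, time_s, samples_mV, rtol: float = 1e-6) -> "VoltageTrace":
        """Build from explicit (time, voltage) columns, checking uniformity."""
        t = np.asarray(time_s, dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=rtol, atol=0):
            raise NonUniformSamplingError("time column is not uniformly sampled")
        return cls(samples_mV=samples_mV, sampling_rate_Hz=1.0 / dt[0], t0_s=t[0])


@dataclass
class WaveformReliability:
    """Cronbach's alpha of onset-rapidness slopes.

    k is the number of items entering the statistic, v_bar the mean per-item
    variance, c_bar the mean off-diagonal inter-item covariance.
    """

    k: int
    v_bar: float
    c_bar: float
    alpha: float


def dvdt_Vps(trace: VoltageTrace) -> np.ndarray:
    """Central-difference dV/dt in V/s (mV samples, seconds time base)."""
    return np.gradient(trace.samples_mV) * trace.sampling_rate_Hz / 1000.0


def detect_spikes(
    trace: VoltageTrace,
    dvdt_threshold_Vps: float = 10.0,
    min_separation_ms: float = 2.0,
    search_window_ms: float = 5.0,
) -> pd.DataFrame:
    """Detect action-potential peaks by a dV/dt threshold crossing.

    A candidate is opened wherever dV/dt rises through the threshold; its peak
    is the voltage maximum within ``search_window_ms`` of the crossing.
    Candidates closer than ``min_separation_ms`` are merged keeping the larger
    peak.  Returns a table with peak_time_s and peak index (times only; use
    :func:`extract_features` for the waveform features).
    """
    if trace.duration_s < 0.01:
        raise ValueError("trace must be at least 10 ms long")
    if dvdt_threshold_Vps <= 0:
        raise ValueError("dvdt_threshold_Vps must be positive")
    d = dvdt_Vps(trace)
    above = d >= dvdt_threshold_Vps
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above.size and above[0]:
        crossings = np.concatenate(([0], crossings))
    win = max(1, int(round(search_window_ms * 1e-3 * trace.sampling_rate_Hz)))
    v = trace.samples_mV
    peaks = []
    for c in crossings:
        stop = min(c + win, v.size)
        peaks.append(c + int(np.argmax(v[c:stop])))
    # merge within min_separation keeping the larger peak
    min_sep = int(round(min_separation_ms * 1e-3 * trace.sampling_rate_Hz))
    merged: list[int] = []
    for p in sorted(set(peaks)):
        if merged and p - merged[-1] < min_sep:
            if v[p] > v[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    idx = np.asarray(merged, dtype=int)
    return pd.DataFrame(
        {
            "peak_index": idx,
            "peak_time_s": trace.t0_s + idx / trace.sampling_rate_Hz,
        }
    )


def extract_features(
    trace: VoltageTrace,
    peak_times_s,
    onset_fraction: float = 0.05,
    ahp_window_ms: float = 50.0,
    rise_window_ms: float = 10.0,
) -> pd.DataFrame:
    """Per-spike waveform features.

    For each peak: the point of maximal dV/dt is located in the
    ``rise_window_ms`` preceding the peak; the onset is the last sample before
    it whose dV/dt is still below ``onset_fraction`` times that maximum, plus
    one.  Threshold is the voltage at onset, amplitude the peak-minus-threshold
    excursion, AHP the drop of the post-peak minimum below threshold within
    ``ahp_window_ms`` (truncated at the next spike's onset), and onset slope
    the chord dV/dt from the onset sample to the sample of peak dV/dt.

    Spikes whose measurement windows are truncated by the trace edge are
    flagged ``valid=False`` and should be excluded from statistics.
    """
    if not 0 < onset_fraction < 1:
        raise ValueError("onset_fraction must lie in (0, 1)")
    fs = trace.sampling_rate_Hz
    v = trace.samples_mV
    d = dvdt_Vps(trace)
    peaks = np.round((np.asarray(peak_times_s, dtype=float) - trace.t0_s) * fs).astype(int)
    peaks = np.sort(peaks)
    rise_win = max(2, int(round(rise_window_ms * 1e-3 * fs)))
    ahp_win = max(1, int(round(ahp_window_ms * 1e-3 * fs)))
    rows = []
    for k, p in enumerate(peaks):
        valid = True
        lo = max(0, p - rise_win)
        if p - lo < 2 or p >= v.size - 1:
            rows.append(_edge_row(trace, p, fs))
            continue
        seg = d[lo : p + 1]
        i_dmax = lo + int(np.argmax(seg))
        dmax = d[i_dmax]
        if dmax <= 0:
            rows.append(_edge_row(trace, p, fs))
            continue
        onset = lo
        below = np.nonzero(d[lo:i_dmax] < onset_fraction * dmax)[0]
        if below.size:
            onset = lo + below[-1] + 1
        elif lo == 0:
            valid = False
        threshold = v[onset]
        amplitude = v[p] - threshold
        stop = p + 1 + ahp_win
        if k + 1 < peaks.size:
            stop = min(stop, peaks[k + 1] - 1)
        if stop > v.size:
            stop = v.size
            valid = False
        ahp = threshold - float(np.min(v[p:stop])) if stop > p else np.nan
        if i_dmax > onset:
            slope = (v[i_dmax] - v[onset]) / ((i_dmax - onset) / fs) / 1000.0
        else:
            slope = dmax
        rows.append(
            {
                "onset_time_s": trace.t0_s + onset / fs,
                "peak_time_s": trace.t0_s + p / fs,
                "threshold_mV": threshold,
                "amplitude_mV": amplitude,
                "ahp_mV": max(ahp, 0.0) if np.isfinite(ahp) else np.nan,
                "onset_slope_Vps": slope,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _edge_row(trace, p, fs):
    return {
        "onset_time_s": np.nan,
        "peak_time_s": trace.t0_s + p / fs,
        "threshold_mV": np.nan,
        "amplitude_mV": np.nan,
        "ahp_mV": np.nan,
        "onset_slope_Vps": np.nan,
        "valid": False,
    }


def cronbach_alpha(slopes, items: str = "columns") -> WaveformReliability:
    """Cronbach's alpha of a [datasets x spikes] matrix of onset slopes.

    alpha = k * c_bar / (v_bar + (k - 1) * c_bar), where k is the number of
    items, v_bar the mean of the per-item variances, and c_bar the mean
    off-diagonal entry of the inter-item covariance matrix (sample covariance,
    ddof=1).  With ``items="columns"`` (default) the items are the individual
    action potentials and covariances are taken across datasets; pass
    ``items="rows"`` to treat the datasets as items instead — how the repeated
    observations were delimited in a recording is a choice the caller owns.

    Raises UndefinedReliabilityError when v_bar + (k-1) c_bar = 0 (the
    statistic is 0/0, e.g. when every dataset is identical under the default
    orientation).
    """
    m = np.asarray(slopes, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("slopes must be a matrix with >= 2 datasets and >= 2 spikes")
    if not np.all(np.isfinite(m)):
        raise ValueError("slopes must not contain missing cells")
    if items == "rows":
        m = m.T
    elif items != "columns":
        raise ValueError("items must be 'columns' or 'rows'")
    k = m.shape[1]
    cov = np.cov(m, rowvar=False, ddof=1)
    v_bar = float(np.mean(np.diag(cov)))
    off = cov[~np.eye(k, dtype=bool)]
    c_bar = float(np.mean(off))
    denom = v_bar + (k - 1) * c_bar
    if denom == 0.0:
        raise UndefinedReliabilityError("total variance is zero; alpha is 0/0")
    return WaveformReliability(k=k, v_bar=v_bar, c_bar=c_bar, alpha=k * c_bar / denom)
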