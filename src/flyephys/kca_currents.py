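"""Calcium-activated potassium (KCa) current isolation.

Voltage-clamp sweep sets are recorded twice — once in normal saline and once
with 5e-4 M CdCl2, which blocks calcium entry and hence KCa activation.  The
cadmium-sensitive difference current (without Cd minus with Cd) is taken as
the KCa current; per-step peak amplitudes summarize the I-V relationship.

The standard protocol is 200-ms pulses from -80 to +60 mV in 10-mV steps
(15 steps) from a -90 mV pre-pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FULL_PROTOCOL_MV = np.arange(-80.0, 61.0, 10.0)


class GridMismatchError(ValueError):
    """Raised when two sweep sets do not share a voltage-step/time grid."""


@dataclass
class SweepSet:
    """A family of voltage-clamp current traces, one per command-voltage step.

    Attributes
    ----------
    voltages_mV : (n_steps,) command voltage per step.
    currents_pA : (n_steps, n_samples) current trace per step.
    sampling_rate_Hz : acquisition rate.
    pulse_window_ms : (start, stop) of the command pulse within each trace.
    """

    voltages_mV: np.ndarray
    currents_pA: np.ndarray
    sampling_rate_Hz: float
    pulse_window_ms: tuple[float, float] = (0.0, 200.0)

    def __post_init__(self):
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        if self.currents_pA.ndim != 2 or self.currents_pA.shape[0] != self.voltages_mV.size:
            raise ValueError("currents_pA must be (n_steps, n_samples)")

    @property
    def n_steps(self) -> int:
        return self.voltages_mV.size


@dataclass
class KcaIV:
    """Per-step peak KCa amplitudes plus the overall peak."""

    voltages_mV: np.ndarray
    peak_pA: np.ndarray
    overall_peak_pA: float = field(init=False)

    def __post_init__(self):
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.peak_pA = np.asarray(self.peak_pA, dtype=float)
        self.overall_peak_pA = float(np.max(self.peak_pA))


def subtract_series(without_cd: SweepSet, with_cd: SweepSet) -> SweepSet:
    """Cadmium-subtraction: pointwise (without Cd) - (with Cd) per step.

    Both sweep sets must share the command-voltage grid, trace length and
    sampling rate; otherwise a GridMismatchError is raised.
    """
    if (
        without_cd.n_steps != with_cd.n_steps
        or not np.allclose(without_cd.voltages_mV, with_cd.voltages_mV)
    ):
        raise GridMismatchError("voltage-step grids differ between series")
    if without_cd.currents_pA.shape != with_cd.currents_pA.shape:
        raise GridMismatchError("trace lengths differ between series")
    if not np.isclose(without_cd.sampling_rate_Hz, with_cd.sampling_rate_Hz):
        raise GridMismatchError("sampling rates differ between series")
    return SweepSet(
        voltages_mV=without_cd.voltages_mV.copy(),
        currents_pA=without_cd.currents_pA - with_cd.currents_pA,
        sampling_rate_Hz=without_cd.sampling_rate_Hz,
        pulse_window_ms=without_cd.pulse_window_ms,
    )


def iv_curve(kca: SweepSet, blank_ms: float = 5.0, absolute: bool = False) -> KcaIV:
    """Per-step peak current within the pulse window.

    The first ``blank_ms`` of the pulse are blanked to skip the capacitance
    transient.  The peak is the signed maximum (outward-current convention);
    pass ``absolute=True`` for the largest magnitude instead.
    """
    start_ms, stop_ms = kca.pulse_window_ms
    if blank_ms >= stop_ms - start_ms:
        raise ValueError("blank_ms must be shorter than the pulse window")
    fs = kca.sampling_rate_Hz
    i0 = int(round((start_ms + blank_ms) * 1e-3 * fs))
    i1 = int(round(stop_ms * 1e-3 * fs))
    i1 = min(i1, kca.currents_pA.shape[1])
    seg = kca.currents_pA[:, i0:i1]
    if absolute:
        peaks = seg[np.arange(seg.shape[0]), np.argmax(np.abs(seg), axis=1)]
    else:
        peaks = seg.max(axis=1)
    return KcaIV(voltages_mV=kca.voltages_mV, peak_pA=peaks)
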