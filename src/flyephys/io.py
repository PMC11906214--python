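"""File I/O: HDF5 traces and sweep sets, CSV event tables and records.

HDF5 layout for a voltage trace: datasets ``signal`` (mV) and ``time`` (s),
attributes ``sampling_rate_Hz`` and ``units``.  Sweep sets store one group
per step with the command voltage as an attribute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kca_currents import SweepSet
from .sleep_behavior import ActivityRecord
from .spike_waveform import VoltageTrace


def write_trace_h5(path, trace: VoltageTrace, units: str = "mV"):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=trace.samples_mV)
        f.create_dataset("time", data=trace.time_s())
        f.attrs["sampling_rate_Hz"] = trace.sampling_rate_Hz
        f.attrs["units"] = units


def read_trace_h5(path) -> VoltageTrace:
    import h5py

    with h5py.File(path, "r") as f:
        return VoltageTrace(
            samples_mV=f["signal"][:],
            sampling_rate_Hz=float(f.attrs["sampling_rate_Hz"]),
            t0_s=float(f["time"][0]) if "time" in f else 0.0,
        )


def read_trace_csv(path) -> VoltageTrace:
    """Delimited text with time (s) and voltage (mV) columns."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return VoltageTrace.from_table(df[cols[0]].to_numpy(), df[cols[1]].to_numpy())


def write_sweeps_h5(path, sweeps: SweepSet):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_Hz"] = sweeps.sampling_rate_Hz
        f.attrs["pulse_window_ms"] = sweeps.pulse_window_ms
        for i, v in enumerate(sweeps.voltages_mV):
            g = f.create_group(f"step{i:02d}")
            g.attrs["command_mV"] = v
            g.create_dataset("current_pA", data=sweeps.currents_pA[i])


def read_sweeps_h5(path) -> SweepSet:
    import h5py

    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f.keys() if k.startswith("step"))
        voltages = np.array([f[k].attrs["command_mV"] for k in keys])
        currents = np.stack([f[k]["current_pA"][:] for k in keys])
        return SweepSet(
            voltages_mV=voltages,
            currents_pA=currents,
            sampling_rate_Hz=float(f.attrs["sampling_rate_Hz"]),
            pulse_window_ms=tuple(f.attrs["pulse_window_ms"]),
        )


def read_event_times_csv(path) -> np.ndarray:
    """One-column CSV of event times in seconds (header optional)."""
    df = pd.read_csv(path)
    col = df.columns[0]
    try:
        first = float(col)
        return np.concatenate(([first], df[col].to_numpy(dtype=float)))
    except ValueError:
        return df[col].to_numpy(dtype=float)


def write_activity_csv(path, record: ActivityRecord):
    pd.DataFrame(
        {"minute": np.arange(record.n_minutes), "zt_min": record.zt_min(), "counts": record.counts}
    ).to_csv(path, index=False)


def read_activity_csv(path, fly_id: str = "csv") -> ActivityRecord:
    df = pd.read_csv(path)
    start = int(df["zt_min"].iloc[0]) if "zt_min" in df else 0
    return ActivityRecord(counts=df["counts"].to_numpy(), start_zt_min=start, fly_id=fly_id)
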