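"""Readers and writers for rasters, traces and spike trains.

Rasters travel as two-column CSV (unit_id, time_ms) or as JSON lists per
unit; full simulation traces (membrane potential, current, synaptic u and
x) can be written as per-step CSV or, for whole experiments, a single HDF5
file. All formats round-trip exactly at double precision except CSV traces,
which keep 10 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "save_raster_csv",
    "load_raster_csv",
    "save_raster_json",
    "load_raster_json",
    "save_spike_train",
    "load_spike_train",
    "save_traces_csv",
    "save_experiment_hdf5",
    "load_experiment_hdf5",
]


def save_raster_csv(raster, path) -> None:
    """Write per-unit spike trains as (unit_id, time_ms) rows."""
    rows = [(unit, t) for unit, train in enumerate(raster) for t in np.asarray(train)]
    df = pd.DataFrame(rows, columns=["unit_id", "time_ms"])
    df.to_csv(path, index=False)


def load_raster_csv(path, n_units: int | None = None) -> list:
    df = pd.read_csv(path)
    n = n_units if n_units is not None else (int(df["unit_id"].max()) + 1 if len(df) else 0)
    return [
        np.sort(df.loc[df["unit_id"] == unit, "time_ms"].to_numpy(dtype=float))
        for unit in range(n)
    ]


def save_raster_json(raster, path) -> None:
    Path(path).write_text(
        json.dumps({str(u): list(map(float, t)) for u, t in enumerate(raster)})
    )


def load_raster_json(path) -> list:
    data = json.loads(Path(path).read_text())
    return [np.asarray(data[str(u)], dtype=float) for u in range(len(data))]


def save_spike_train(train, path) -> None:
    """One-column CSV of spike times in ms."""
    np.savetxt(path, np.asarray(train, dtype=float), fmt="%.10g",
               header="time_ms", comments="")


def load_spike_train(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, skiprows=1, dtype=float))


def save_traces_csv(result, path) -> None:
    """Per-step traces as a wide CSV: time plus V/I/u/x columns per unit."""
    n = result.n_units
    data = {"time_ms": result.times}
    for i in range(n):
        data[f"V_{i}"] = result.V_trace[:, i]
        data[f"I_{i}"] = result.I_trace[:, i]
        data[f"u_{i}"] = result.u_trace[:, i]
        data[f"x_{i}"] = result.x_trace[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def save_experiment_hdf5(results, path) -> None:
    """Write a whole sweep's traces and rasters to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        for res in results:
            g = f.create_group(f"step_{res.step_index:04d}")
            g.attrs["direction"] = res.direction
            g.attrs["step_index"] = res.step_index
            g.create_dataset("times", data=res.times)
            g.create_dataset("V", data=res.V_trace)
            g.create_dataset("I", data=res.I_trace)
            g.create_dataset("u", data=res.u_trace)
            g.create_dataset("x", data=res.x_trace)
            for i, train in enumerate(res.raster):
                g.create_dataset(f"raster/{i}", data=np.asarray(train, dtype=float))


def load_experiment_hdf5(path) -> list:
    """Load a sweep written by :func:`save_experiment_hdf5`."""
    import h5py

    from .circuit import SimulationResult

    results = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            n_units = g["V"].shape[1]
            raster = [np.asarray(g[f"raster/{i}"]) for i in range(n_units)]
            results.append(
                SimulationResult(
                    raster=raster,
                    V_trace=np.asarray(g["V"]), I_trace=np.asarray(g["I"]),
                    u_trace=np.asarray(g["u"]), x_trace=np.asarray(g["x"]),
                    direction=str(g.attrs["direction"]),
                    step_index=int(g.attrs["step_index"]),
                    times=np.asarray(g["times"]),
                )
            )
    return results
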