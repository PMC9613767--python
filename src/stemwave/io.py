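"""Result serialization: HDF5 arrays, CSV summaries."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .abm import AbmResult
from .pde import ContinuumResult

__all__ = ["save_continuum_hdf5", "load_continuum_hdf5",
           "save_abm_hdf5", "profiles_to_csv", "speed_table_to_csv"]


def _write_meta(g, params=None, config=None, seed=None):
    if params is not None:
        g.attrs["params"] = json.dumps(
            {k: (v if isinstance(v, (int, float, str, bool)) else str(v))
             for k, v in vars(params).items()}
        )
    if config is not None:
        g.attrs["config"] = json.dumps(config)
    if seed is not None:
        g.attrs["seed"] = int(seed)


def save_continuum_hdf5(path, result: ContinuumResult, config=None, seed=None):
    """Datasets /x, /t, /u, /v plus parameter attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("x", data=result.x)
        fh.create_dataset("t", data=result.t)
        fh.create_dataset("u", data=result.u)
        fh.create_dataset("v", data=result.v)
        fh.attrs["kind"] = result.kind
        _write_meta(fh, result.params, config, seed)


def load_continuum_hdf5(path):
    """Return (x, t, u, v, attrs)."""
    with h5py.File(path, "r") as fh:
        return (fh["x"][:], fh["t"][:], fh["u"][:], fh["v"][:],
                dict(fh.attrs))


def save_abm_hdf5(path, result: AbmResult, config=None, seed=None):
    """Datasets /t_mcs, /profiles, /csc_count, /tc_count and the final
    lattice as an integer grid (0 empty, 1 CSC, 2..2+rho_max TC by rho)."""
    state = result.final_state
    lattice = np.where(
        state.kind == 2, 2 + state.rho.astype(np.int16),
        state.kind.astype(np.int16),
    )
    with h5py.File(path, "w") as fh:
        fh.create_dataset("t_mcs", data=result.times)
        fh.create_dataset("profiles", data=result.profiles)
        fh.create_dataset("csc_count", data=result.csc_count)
        fh.create_dataset("tc_count", data=result.tc_count)
        fh.create_dataset("lattice", data=lattice)
        _write_meta(fh, result.params, config,
                    seed if seed is not None else result.params.seed)


def profiles_to_csv(path, times, x, profiles):
    df = pd.DataFrame(np.asarray(profiles), columns=np.asarray(x))
    df.insert(0, "t", np.asarray(times))
    df.to_csv(path, index=False)


def speed_table_to_csv(path, rows):
    """rows: iterable of dicts (e.g. alpha / numerical / theoretical)."""
    pd.DataFrame(list(rows)).to_csv(path, index=False)
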