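"""Reading univariate activity series from text, CSV, or HDF5."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np


def read_series(path, hdf5_dataset: str = "activity") -> np.ndarray:
    """Load a univariate series from single-column text, CSV, or HDF5."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return np.asarray(f[hdf5_dataset][:], dtype=float).ravel()
    if suffix == ".csv":
        data = np.genfromtxt(path, delimiter=",", names=None, skip_header=0)
        if data.ndim > 1:  # take the last column (freq/value layouts)
            data = data[:, -1]
        if np.isnan(data).any():  # header row
            data = np.genfromtxt(path, delimiter=",", skip_header=1)
            if data.ndim > 1:
                data = data[:, -1]
        return data.astype(float)
    return np.loadtxt(path, dtype=float).ravel()
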