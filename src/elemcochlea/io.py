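"""Result serialisation: tidy CSV with metadata header, HDF5 bundles, and
plain-text matrix export for inspection.

CSV files carry run metadata (config hash, package version) as ``#``-prefixed
comment lines before the header row; HDF5 bundles store the full
configuration JSON as a root attribute.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "write_sweep_csv",
    "read_sweep_csv",
    "write_hdf5",
    "read_hdf5",
    "save_matrix_text",
    "load_matrix_text",
]


def write_sweep_csv(df: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    lines = [f"# elemcochlea {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_sweep_csv(path) -> tuple[pd.DataFrame, dict]:
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        for line in iter(fh.readline, ""):
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
        df = pd.read_csv(fh)
    return df, metadata


def write_hdf5(path, arrays: dict[str, np.ndarray], config: dict | None = None,
               metadata: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["elemcochlea_version"] = __version__
        if config is not None:
            fh.attrs["config"] = json.dumps(config)
        for key, value in (metadata or {}).items():
            fh.attrs[key] = value
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))
    return path


def read_hdf5(path) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as fh:
        arrays = {name: fh[name][()] for name in fh}
        attrs = dict(fh.attrs)
    if "config" in attrs:
        attrs["config"] = json.loads(attrs["config"])
    return arrays, attrs


def save_matrix_text(matrix: np.ndarray, path, header: str = "") -> Path:
    """Plain-text matrix dump (complex supported) for external inspection."""
    path = Path(path)
    np.savetxt(path, matrix, header=header)
    return path


def load_matrix_text(path, dtype=complex) -> np.ndarray:
    return np.loadtxt(path, dtype=dtype, ndmin=2)
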