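"""Delimited-text I/O for time-series data matrices and run manifests.

The interchange format is a plain tab- or comma-delimited numeric table
with a header of node names (the natural representation for region x time
matrices); floats are written at 10 significant digits so metric results
survive a write/read round-trip.
"""

from __future__ import annotations

import hashlib
import json
import time

import numpy as np
import pandas as pd

__all__ = ["read_timeseries", "write_timeseries", "write_manifest"]


def read_timeseries(path) -> pd.DataFrame:
    """Read a timepoints x nodes table; rejects missing cells and duplicate
    node names, naming the offending row/column."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    header = first.rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValueError(f"duplicate node name {dup!r}")
    df = pd.read_csv(path, sep=sep)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric values in column {non_numeric[0]!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValueError(f"missing value at row {row}, column {col!r}")
    return df


def write_timeseries(data, path, nodes: list[str] | None = None) -> None:
    """Write a matrix or DataFrame as a tab-delimited table with node header."""
    if not isinstance(data, pd.DataFrame):
        data = np.asarray(data)
        if nodes is None:
            nodes = [f"X{i+1}" for i in range(data.shape[1])]
        data = pd.DataFrame(data, columns=nodes)
    data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, parameters: dict, seed: int | None,
                   inputs: list[str] = ()) -> None:
    """Record command, resolved parameters, input hashes and the master seed."""
    from . import __version__

    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
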