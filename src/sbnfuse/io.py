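"""Plain-text I/O: labelled matrix CSVs, tract tables, geometry, run logs.

All matrices are written as CSV with ROI labels as both header row and
first column, floats serialized with ``%.12g`` so a write/read round trip
is exact to 12 significant digits.  ROI indices are 0-based in tract
tables; labels (``roi_1`` ...) are 1-based, human-facing names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import InvalidNetworkError, WeightedNetwork
from .synthetic import TRACT_COLUMNS, CohortManifest, RoiGeometry


def write_matrix(network: WeightedNetwork, path: str | Path) -> None:
    """Write a labelled square matrix CSV."""
    df = pd.DataFrame(network.weights, index=network.node_labels,
                      columns=network.node_labels)
    df.to_csv(path, float_format="%.12g", index_label="roi")


def read_matrix(path: str | Path) -> WeightedNetwork:
    """Read a labelled square matrix CSV into a validated network.

    Asymmetry within 1e-9 is symmetrized by averaging; beyond that it is
    an error naming the offending cell.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise InvalidNetworkError(f"matrix in {path} is not square: {df.shape}")
    return WeightedNetwork(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def write_tract_table(table: pd.DataFrame, path: str | Path) -> None:
    table[TRACT_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_tract_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tract table {path} lacks columns {sorted(missing)}")
    return df


def write_geometry(geometry: RoiGeometry, path: str | Path) -> None:
    pd.DataFrame({
        "label": geometry.roi_labels,
        "x": geometry.centroids[:, 0],
        "y": geometry.centroids[:, 1],
        "z": geometry.centroids[:, 2],
        "voxels": geometry.voxel_counts,
    }).to_csv(path, index=False, float_format="%.12g")


def read_geometry(path: str | Path) -> RoiGeometry:
    df = pd.read_csv(path)
    return RoiGeometry(
        roi_labels=[str(x) for x in df["label"]],
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        voxel_counts=df["voxels"].to_numpy(dtype=int),
    )


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=2))


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
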