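"""HDF5 containers for epochs, covariance sets, means fields, and filters.

The on-disk layout is deliberately minimal: one HDF5 file with datasets
``epochs`` (trials x channels x samples, float64) and ``labels`` (one integer
per trial), or ``covs`` (trials x n x n) for precomputed covariances, plus an
optional JSON side-car (same path with ``.json`` appended) for metadata such
as sampling rate and channel names.  Means fields are stored as a
``means`` dataset (classes x n_h x n x n) with h-grid and diagnostics in the
file attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .means import MeansField
from .spatial import SpatialFilter
from .spd import TrialCovarianceSet

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_covariances",
    "read_covariances",
    "write_means_field",
    "read_means_field",
    "write_spatial_filter",
    "read_spatial_filter",
]


def _write_sidecar(path, metadata) -> None:
    if metadata is not None:
        Path(str(path) + ".json").write_text(json.dumps(metadata, indent=2))


def read_sidecar(path) -> dict | None:
    side = Path(str(path) + ".json")
    return json.loads(side.read_text()) if side.exists() else None


def write_epochs(path, epochs: np.ndarray, labels, metadata: dict | None = None) -> None:
    """Write an (n_trials, n_channels, n_samples) epoch stack with labels."""
    epochs = np.asarray(epochs, dtype=np.float64)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs)
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
    _write_sidecar(path, metadata)


def read_epochs(path):
    with h5py.File(path, "r") as f:
        return f["epochs"][...], f["labels"][...]


def write_covariances(path, cset: TrialCovarianceSet, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("covs", data=cset.matrices)
        if cset.labels is not None:
            f.create_dataset("labels", data=np.asarray(cset.labels, dtype=np.int64))
        f.create_dataset("weights", data=cset.weights)
    _write_sidecar(path, metadata)


def read_covariances(path) -> TrialCovarianceSet:
    with h5py.File(path, "r") as f:
        covs = f["covs"][...]
        labels = f["labels"][...] if "labels" in f else None
        weights = f["weights"][...] if "weights" in f else None
    return TrialCovarianceSet(covs, labels, weights)


def write_means_field(path, fld: MeansField) -> None:
    n_h = len(fld.h_values)
    dim = fld.dim
    stack = np.empty((len(fld.classes), n_h, dim, dim))
    for i, cls in enumerate(fld.classes):
        for j, h in enumerate(fld.h_values):
            stack[i, j] = fld.means[(cls, h)]
    with h5py.File(path, "w") as f:
        f.create_dataset("means", data=stack)
        f.attrs["h_values"] = np.asarray(fld.h_values)
        f.attrs["classes"] = np.asarray(fld.classes)
    meta = {
        "h_values": list(fld.h_values),
        "diagnostics": {
            f"{cls}|{h}": [int(it), float(res)]
            for (cls, h), (it, res) in fld.diagnostics.items()
        },
        "retained": None
        if fld.retained is None
        else {str(cls): np.asarray(idx).tolist() for cls, idx in fld.retained.items()},
    }
    _write_sidecar(path, meta)


def read_means_field(path) -> MeansField:
    with h5py.File(path, "r") as f:
        stack = f["means"][...]
        h_values = tuple(float(h) for h in f.attrs["h_values"])
        classes = list(f.attrs["classes"])
    means = {
        (cls, h): stack[i, j]
        for i, cls in enumerate(classes)
        for j, h in enumerate(h_values)
    }
    return MeansField(means, classes, h_values)


def write_spatial_filter(path, filt: SpatialFilter) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=filt.weights)
    _write_sidecar(path, {"stage_log": filt.stage_log})


def read_spatial_filter(path) -> SpatialFilter:
    with h5py.File(path, "r") as f:
        W = f["W"][...]
    meta = read_sidecar(path) or {}
    return SpatialFilter(W, stage_log=meta.get("stage_log", []))
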