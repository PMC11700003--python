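"""HDF5 volume bundles: co-registered grids plus provenance metadata."""

from __future__ import annotations

import json

import h5py
import numpy as np

__all__ = ["write_volumes", "read_volumes"]


def write_volumes(path, volumes: dict, metadata: dict | None = None) -> None:
    """Write named volumes (same grid) and a JSON metadata attribute."""
    with h5py.File(path, "w") as f:
        for name, arr in volumes.items():
            f.create_dataset(name, data=np.asarray(arr), compression="gzip",
                             compression_opts=4)
        f.attrs["metadata"] = json.dumps(metadata or {}, default=str)


def read_volumes(path):
    """Read back (volumes dict, metadata dict)."""
    vols = {}
    with h5py.File(path, "r") as f:
        for name in f:
            vols[name] = f[name][...]
        meta = json.loads(f.attrs.get("metadata", "{}"))
    return vols, meta
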