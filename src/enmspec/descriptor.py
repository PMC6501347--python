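"""Inverse-distance (Coulomb) matrix descriptor of a C-alpha trace.

The descriptor is the N x N symmetric matrix with zero diagonal and
``1 / |R_I - R_J|`` off the diagonal, indexed in sequence order.  Sequence
order is deliberately NOT canonicalized (no sorted-norm permutation): the
training pipeline doubles datasets with reversed copies, which is only
meaningful for an order-dependent input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chainio import ChainStructure


@dataclass(frozen=True)
class CoulombMatrix:
    """Symmetric inverse-distance matrix (1/Angstrom) with provenance."""

    matrix: np.ndarray
    source_id: str = ""
    window_offset: int | None = None
    orientation: str = "direct"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"descriptor must be square, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def coulomb_matrix(
    chain: ChainStructure, *, standardize: bool = False
) -> CoulombMatrix:
    """Compute the inverse-distance descriptor of a chain.

    Raises on coincident residues (zero pairwise distance).  ``standardize``
    (off by default — the network consumes the raw matrix) rescales to zero
    mean / unit variance over the off-diagonal entries.
    """
    d = squareform(pdist(chain.coords))
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] < 1e-9):
        i, j = np.argwhere((d < 1e-9) & off)[0]
        raise ValueError(f"coincident residues {i} and {j} in {chain.source_id}")
    c = np.zeros_like(d)
    c[off] = 1.0 / d[off]
    if standardize:
        mu, sd = c[off].mean(), c[off].std()
        c[off] = (c[off] - mu) / (sd if sd > 0 else 1.0)
    return CoulombMatrix(
        matrix=c,
        source_id=chain.source_id,
        window_offset=chain.window_offset,
        orientation=chain.orientation,
    )


def stack_descriptors(matrices: Sequence[CoulombMatrix]) -> np.ndarray:
    """Stack descriptors into an (S, N, N) array; shapes must agree."""
    sizes = {m.n for m in matrices}
    if len(sizes) != 1:
        raise ValueError(f"mixed descriptor sizes {sorted(sizes)}")
    return np.stack([m.matrix for m in matrices])


def write_descriptor_set(
    path: str | Path,
    matrices: Sequence[CoulombMatrix],
    targets: np.ndarray | None = None,
) -> None:
    """Write a dataset of descriptors (and optional targets) to one HDF5 file.

    Layout: ``/coulomb`` (S, N, N) float32, optional ``/targets`` (S, 10)
    float64, plus per-sample provenance arrays.
    """
    import h5py

    x = stack_descriptors(matrices)
    with h5py.File(path, "w") as f:
        f.create_dataset("coulomb", data=x.astype(np.float32))
        if targets is not None:
            f.create_dataset("targets", data=np.asarray(targets, dtype=float))
        f.create_dataset(
            "source_id",
            data=np.array([m.source_id for m in matrices], dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.create_dataset(
            "window_offset",
            data=np.array(
                [-1 if m.window_offset is None else m.window_offset for m in matrices]
            ),
        )
        f.create_dataset(
            "orientation",
            data=np.array([m.orientation for m in matrices], dtype=object),
            dtype=h5py.string_dtype(),
        )


def read_descriptor_set(path: str | Path):
    """Read back a descriptor set; returns (X, targets_or_None, manifest dict)."""
    import h5py

    with h5py.File(path, "r") as f:
        x = f["coulomb"][...].astype(np.float64)
        y = f["targets"][...] if "targets" in f else None
        meta = {
            "source_id": [s.decode() if isinstance(s, bytes) else s for s in f["source_id"][...]],
            "window_offset": f["window_offset"][...].tolist(),
            "orientation": [s.decode() if isinstance(s, bytes) else s for s in f["orientation"][...]],
        }
    return x, y, meta
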