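"""Residue pruning: fitting longer chains into the fixed-size surrogate.

A chain longer than the network input is reduced by removing residues under
one of three schemes — uniformly random, random outside a protective sphere
around the mechanical hinge, or random outside a sphere displaced away from
the hinge (the control) — and the surrogate ensemble's predictions on the
pruned structures are scored against the exact spectrum of the FULL chain.
The systematic MAPE difference between the schemes localizes the residues
that matter mechanically.

Pruned structures intentionally contain backbone gaps; only the
inverse-distance descriptor (which needs no bonding) ever consumes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .betagm import ENMParams, SpectrumTarget, betagm_spectrum
from .chainio import ChainStructure
from .descriptor import coulomb_matrix

logger = logging.getLogger(__name__)

SCHEME_KINDS = ("random", "protected_sphere", "displaced_sphere")


@dataclass(frozen=True)
class PruningScheme:
    """Specification of one residue-removal procedure."""

    kind: str = "random"
    n_remove: int = 20
    sphere_radius: float = 10.0
    hinge_centre: np.ndarray | None = None
    min_centre_displacement: float = 20.0
    n_structures: int = 100
    n_placements: int = 10
    placement_mode: str = "per_placement"  # or "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"kind must be one of {SCHEME_KINDS}")
        if self.n_remove <= 0 or self.n_structures <= 0:
            raise ValueError("counts must be positive")
        if self.sphere_radius <= 0 or self.min_centre_displacement <= 0:
            raise ValueError("radii must be positive")
        if self.hinge_centre is not None:
            object.__setattr__(
                self, "hinge_centre", np.asarray(self.hinge_centre, dtype=float)
            )


@dataclass(frozen=True)
class PruningReport:
    """Ensemble statistics of one pruning experiment."""

    scheme_kind: str
    true_eigenvalues: np.ndarray  # (n_outputs,)
    mean_predicted: np.ndarray  # (n_outputs,)
    std_predicted: np.ndarray  # (n_outputs,)
    overall_mape: float
    n_structures: int
    n_models: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std_predicted) < 0):
            raise ValueError("standard deviations must be non-negative")


def hinge_centre(
    chain: ChainStructure,
    residue_index: int | None = None,
    coordinate: np.ndarray | None = None,
) -> np.ndarray:
    """Hinge location: the sequence-middle C-alpha by default.

    The default is the coordinate of residue ``floor(N / 2)``; an explicit
    residue index or coordinate overrides it (the linker centre of a real
    two-domain protein is structure-specific knowledge).
    """
    if coordinate is not None:
        return np.asarray(coordinate, dtype=float)
    if residue_index is None:
        residue_index = len(chain) // 2
    return chain.coords[residue_index].copy()


def _keep_subset(chain: ChainStructure, removed: np.ndarray, tag: str) -> ChainStructure:
    keep = np.setdiff1d(np.arange(len(chain)), removed)
    return ChainStructure(
        source_id=f"{chain.source_id}|{tag}",
        residue_names=tuple(chain.residue_names[i] for i in keep),
        coords=chain.coords[keep],
        orientation=chain.orientation,
        window_offset=chain.window_offset,
    )


def _draw_outside_sphere(
    chain: ChainStructure,
    centre: np.ndarray,
    radius: float,
    n_remove: int,
    rng: np.random.Generator,
) -> np.ndarray:
    dist = np.linalg.norm(chain.coords - centre, axis=1)
    removable = np.flatnonzero(dist >= radius)
    if len(removable) < n_remove:
        raise ValueError(
            f"sphere protects too many residues: {len(removable)} removable, "
            f"{n_remove} required"
        )
    return rng.choice(removable, size=n_remove, replace=False)


def prune(
    chain: ChainStructure,
    scheme: PruningScheme,
    target_size: int = 100,
) -> list[ChainStructure]:
    """Produce ``scheme.n_structures`` pruned copies of a chain.

    Residue order is preserved; removal is uniform over the removable set.
    For ``protected_sphere`` the removable set excludes residues within
    ``sphere_radius`` of the hinge centre; for ``displaced_sphere`` each
    sphere centre is drawn from residue positions at least
    ``min_centre_displacement`` away from the hinge, then residues outside
    that sphere are removed.  Deterministic per ``scheme.seed``.
    """
    n = len(chain)
    if n - scheme.n_remove != target_size:
        raise ValueError(
            f"chain length {n} minus n_remove {scheme.n_remove} must equal the "
            f"surrogate input size {target_size}"
        )
    rng = np.random.default_rng(scheme.seed)
    centre = (
        scheme.hinge_centre
        if scheme.hinge_centre is not None
        else hinge_centre(chain)
    )

    out: list[ChainStructure] = []
    if scheme.kind == "random":
        for s in range(scheme.n_structures):
            removed = rng.choice(n, size=scheme.n_remove, replace=False)
            out.append(_keep_subset(chain, removed, f"random{s}"))
    elif scheme.kind == "protected_sphere":
        for s in range(scheme.n_structures):
            removed = _draw_outside_sphere(
                chain, centre, scheme.sphere_radius, scheme.n_remove, rng
            )
            out.append(_keep_subset(chain, removed, f"protected{s}"))
    else:  # displaced_sphere
        dist_to_hinge = np.linalg.norm(chain.coords - centre, axis=1)
        candidates = np.flatnonzero(dist_to_hinge >= scheme.min_centre_displacement)
        if len(candidates) == 0:
            raise ValueError(
                "no residue lies at least "
                f"{scheme.min_centre_displacement} A from the hinge centre: "
                "structure too small for the displaced-sphere control"
            )
        if scheme.placement_mode == "per_placement":
            n_place = scheme.n_placements
            per_place = max(1, scheme.n_structures // n_place)
        else:  # one independent placement per structure
            n_place = scheme.n_structures
            per_place = 1
        for p in range(n_place):
            c_idx = candidates[rng.integers(len(candidates))]
            sphere_c = chain.coords[c_idx]
            for s in range(per_place):
                removed = _draw_outside_sphere(
                    chain, sphere_c, scheme.sphere_radius, scheme.n_remove, rng
                )
                out.append(_keep_subset(chain, removed, f"displaced{p}.{s}"))
    return out


def pruning_experiment(
    chain: ChainStructure,
    models: Sequence,
    scheme: PruningScheme,
    params: ENMParams | None = None,
    *,
    true_spectrum: SpectrumTarget | None = None,
) -> PruningReport:
    """Score a surrogate ensemble on pruned copies of a longer chain.

    The reference is the exact model spectrum of the FULL chain.  Every
    pruned structure's descriptor is fed to every model in the ensemble;
    the report carries the per-eigenvalue mean and standard deviation over
    (structures x models) and the overall MAPE against the reference.
    ``models`` may be any objects exposing ``predict(descriptors)``.
    """
    if len(models) == 0:
        raise ValueError("model ensemble is empty")
    params = params or ENMParams()
    if true_spectrum is None:
        true_spectrum = betagm_spectrum(chain, params)
    truth = true_spectrum.eigenvalues

    target_size = getattr(
        getattr(models[0], "config", None), "input_size", len(chain) - scheme.n_remove
    )
    pruned = prune(chain, scheme, target_size=target_size)
    descriptors = [coulomb_matrix(c) for c in pruned]

    all_preds = []  # (models, structures, n_outputs)
    for model in models:
        all_preds.append(np.asarray(model.predict(descriptors), dtype=float))
    preds = np.stack(all_preds)
    flat = preds.reshape(-1, preds.shape[-1])
    rel = np.abs(flat - truth) / np.abs(truth)
    return PruningReport(
        scheme_kind=scheme.kind,
        true_eigenvalues=truth,
        mean_predicted=flat.mean(axis=0),
        std_predicted=flat.std(axis=0),
        overall_mape=float(100.0 * rel.mean()),
        n_structures=len(pruned),
        n_models=len(models),
    )
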