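"""Chain input/output and synthetic structure generation.

This module owns the :class:`ChainStructure` record that every other stage
consumes: an ordered C-alpha trace of a single protein chain together with
residue identities.  It provides

* a PDB reader restricted to C-alpha atoms of one chain,
* a seeded generator of protein-like synthetic traces (self-avoiding walks
  with tunable compactness) and a two-domain "dumbbell" variant,
* fixed-length sliding-window decoy construction with sequence-reversal
  augmentation,
* the radius-of-gyration shape statistic,
* plain-text (TSV) serialization of chains and dataset manifests.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard amino-acid 3-letter codes (glycine listed separately where needed).
AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
_NON_GLY = [a for a in AMINO_ACIDS if a != "GLY"]

#: Fixed virtual bond length between consecutive C-alphas (Angstrom).
CA_BOND_LENGTH = 3.8
#: Consecutive C-alpha distance bounds for a break-free chain (Angstrom).
BREAK_BOUNDS = (2.5, 4.5)
#: Minimum distance between non-consecutive C-alphas in synthetic chains.
EXCLUDED_VOLUME = 4.0
#: Elastic-network interaction cutoff used for the connectivity check.
DEFAULT_CUTOFF = 7.5


class ChainError(ValueError):
    """Raised for malformed or unusable chain input."""


@dataclass(frozen=True)
class ChainStructure:
    """Ordered C-alpha trace of a single chain.

    Parameters
    ----------
    source_id:
        Free-text label identifying the parent structure.
    residue_names:
        3-letter residue codes, one per site, in chain order.
    coords:
        ``(N, 3)`` float array of C-alpha positions in Angstrom.
    orientation:
        ``"direct"`` or ``"reversed"``.
    window_offset:
        0-based index of the first residue within the parent chain, or
        ``None`` for full chains.
    """

    source_id: str
    residue_names: tuple[str, ...]
    coords: np.ndarray
    orientation: str = "direct"
    window_offset: int | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ChainError(f"coords must be (N, 3), got {coords.shape}")
        if len(self.residue_names) != len(coords):
            raise ChainError(
                f"{len(self.residue_names)} residue names but {len(coords)} coordinates"
            )
        if len(coords) < 4:
            raise ChainError(f"chain needs at least 4 residues, got {len(coords)}")
        if not np.all(np.isfinite(coords)):
            raise ChainError("non-finite coordinates")
        if self.orientation not in ("direct", "reversed"):
            raise ChainError(f"orientation must be direct|reversed, got {self.orientation!r}")
        object.__setattr__(self, "residue_names", tuple(self.residue_names))
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    @property
    def is_glycine(self) -> np.ndarray:
        """Boolean mask, True where the residue is glycine."""
        return np.array([name == "GLY" for name in self.residue_names])

    def consecutive_distances(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def break_positions(self, bounds: tuple[float, float] = BREAK_BOUNDS) -> np.ndarray:
        """Indices i where the (i, i+1) virtual bond violates the bounds."""
        d = self.consecutive_distances()
        return np.flatnonzero((d <= bounds[0]) | (d >= bounds[1]))

    def is_break_free(self, bounds: tuple[float, float] = BREAK_BOUNDS) -> bool:
        return self.break_positions(bounds).size == 0


@dataclass(frozen=True)
class ShapeStats:
    """Simple shape summary of a chain."""

    radius_of_gyration: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.radius_of_gyration < 0:
            raise ValueError("radius of gyration must be non-negative")


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_calpha_trace(pdb_text: str, chain_id: str | None = None) -> ChainStructure:
    """Extract the C-alpha trace of one chain from PDB-format text.

    Only the first MODEL is considered; HETATM records and non-CA atoms are
    ignored; for alternate locations altloc ``A`` is preferred, otherwise the
    first occurrence is kept.  Residues are returned in file order (insertion
    codes preserved in the ordering).

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file.
    chain_id:
        Chain identifier; ``None`` selects the first chain that contains
        C-alpha atoms.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pdb", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ChainError("no MODEL found in PDB text")
    model = models[0]

    chains: dict[str, list] = {}
    for chain in model:
        residues = []
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / water
                continue
            if "CA" not in residue:
                continue
            residues.append(residue)
        if residues:
            chains[chain.id] = residues

    if not chains:
        raise ChainError("no chain with CA atoms found")
    if chain_id is None:
        chain_id = next(iter(chains))
    if chain_id not in chains:
        raise ChainError(
            f"chain {chain_id!r} not found; available chains: {sorted(chains)}"
        )

    names: list[str] = []
    coords: list[np.ndarray] = []
    for residue in chains[chain_id]:
        atom = residue["CA"]
        if atom.is_disordered():
            # prefer altloc A, else first stored conformer
            alts = sorted(atom.disordered_get_id_list())
            chosen = "A" if "A" in alts else alts[0]
            atom = atom.disordered_get(chosen)
        names.append(residue.get_resname().strip())
        coords.append(atom.get_coord().astype(float))

    if len(coords) < 4:
        raise ChainError(
            f"chain {chain_id!r} has only {len(coords)} CA residues (need >= 4)"
        )
    return ChainStructure(
        source_id=chain_id, residue_names=tuple(names), coords=np.array(coords)
    )


# ---------------------------------------------------------------------------
# Synthetic chain generation
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _propose_step(
    prev_dir: np.ndarray,
    rng: np.random.Generator,
    angle_range: tuple[float, float],
) -> np.ndarray:
    """New bond direction at a bond angle drawn in ``angle_range`` (degrees)."""
    theta = np.deg2rad(rng.uniform(*angle_range))
    # supplementary: bond angle theta between (-prev_dir) and new_dir
    axis = np.cross(prev_dir, _random_unit(rng))
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        axis = np.cross(prev_dir, np.array([1.0, 0.0, 0.0]))
        norm = np.linalg.norm(axis)
    axis = axis / norm
    # rotate prev_dir by (pi - theta) about a random perpendicular axis
    alpha = np.pi - theta
    d = (
        prev_dir * np.cos(alpha)
        + np.cross(axis, prev_dir) * np.sin(alpha)
        + axis * np.dot(axis, prev_dir) * (1 - np.cos(alpha))
    )
    return d / np.linalg.norm(d)


def _grow_walk(
    n: int,
    compactness: float,
    rng: np.random.Generator,
    angle_range: tuple[float, float],
    bond_length: float,
    start: np.ndarray | None = None,
    start_dir: np.ndarray | None = None,
    existing: np.ndarray | None = None,
    attractor: np.ndarray | None = None,
    n_candidates: int = 24,
    max_backtracks: int = 400,
) -> np.ndarray | None:
    """Grow an excluded-volume walk of ``n`` beads; None on failure.

    ``compactness`` is the probability of taking, among geometrically valid
    candidate steps, the one closest to the running centroid (or to the
    explicit ``attractor``); otherwise a valid candidate is chosen uniformly.
    """
    pts = [np.zeros(3) if start is None else np.asarray(start, float)]
    if n == 1:
        return np.array(pts)
    d0 = _random_unit(rng) if start_dir is None else np.asarray(start_dir, float)
    pts.append(pts[0] + bond_length * d0)
    backtracks = 0
    while len(pts) < n:
        prev_dir = (pts[-1] - pts[-2]) / bond_length
        candidates = []
        for _ in range(n_candidates):
            d = _propose_step(prev_dir, rng, angle_range)
            p = pts[-1] + bond_length * d
            body = np.array(pts[:-1])
            ok = np.all(np.linalg.norm(body - p, axis=1) >= EXCLUDED_VOLUME)
            if ok and existing is not None and len(existing):
                ok = np.all(np.linalg.norm(existing - p, axis=1) >= EXCLUDED_VOLUME)
            if ok:
                candidates.append(p)
        if not candidates:
            backtracks += 1
            if backtracks > max_backtracks or len(pts) <= 2:
                return None
            del pts[-1]
            continue
        target = attractor if attractor is not None else np.mean(pts, axis=0)
        if rng.random() < compactness:
            dist = [np.linalg.norm(p - target) for p in candidates]
            choice = candidates[int(np.argmin(dist))]
        else:
            choice = candidates[rng.integers(len(candidates))]
        pts.append(choice)
    return np.array(pts)


def _draw_names(
    n: int, gly_fraction: float, rng: np.random.Generator
) -> tuple[str, ...]:
    names = []
    for _ in range(n):
        if rng.random() < gly_fraction:
            names.append("GLY")
        else:
            names.append(_NON_GLY[rng.integers(len(_NON_GLY))])
    return tuple(names)


def network_is_connected(coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True if the cutoff contact graph plus backbone bonds is connected."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import squareform, pdist

    n = len(coords)
    adj = squareform(pdist(coords)) < cutoff
    np.fill_diagonal(adj, False)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = True
    adj[idx + 1, idx] = True
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    return ncomp == 1


def generate_synthetic_chain(
    n: int,
    compactness: float,
    gly_fraction: float = 0.08,
    seed: int = 0,
    *,
    bond_length: float = CA_BOND_LENGTH,
    angle_range: tuple[float, float] = (80.0, 150.0),
    cutoff: float = DEFAULT_CUTOFF,
    max_attempts: int = 50,
    source_id: str | None = None,
) -> ChainStructure:
    """Generate a protein-like synthetic C-alpha trace.

    Consecutive sites are exactly ``bond_length`` apart, non-consecutive
    pairs at least 4 Angstrom apart, and the walk is biased toward its
    running centroid with strength ``compactness`` so the expected radius of
    gyration decreases as ``compactness`` approaches 1.  The resulting
    elastic network (backbone plus ``cutoff`` contacts) is guaranteed
    connected.  Deterministic given ``seed``.
    """
    if n < 4:
        raise ChainError(f"need n >= 4, got {n}")
    if not 0.0 <= compactness <= 1.0:
        raise ValueError("compactness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        coords = _grow_walk(n, compactness, rng, angle_range, bond_length)
        if coords is None:
            continue
        if not network_is_connected(coords, cutoff):
            continue
        names = _draw_names(n, gly_fraction, rng)
        candidate = ChainStructure(
            source_id=source_id or f"synth-n{n}-c{compactness:g}-s{seed}",
            residue_names=names,
            coords=coords,
        )
        # loosely-coiled walks can leave internal mechanisms (extra zero
        # modes); only mechanically sound chains are protein-like
        if _count_zero_modes(candidate, cutoff) == 6:
            return candidate
    raise ChainError(
        f"could not generate a valid chain (n={n}, compactness={compactness}) "
        f"after {max_attempts} attempts"
    )


def _count_zero_modes(chain: ChainStructure, cutoff: float) -> int:
    from scipy.linalg import eigh

    from .betagm import ENMParams, build_betagm_hessian  # deferred import

    h = build_betagm_hessian(chain, ENMParams(cutoff=cutoff))
    evals = eigh(h.matrix, eigvals_only=True)
    return int(np.sum(evals <= 1e-8 * max(float(evals[-1]), 1e-300)))


def generate_dumbbell_chain(
    n: int = 120,
    linker_length: int = 4,
    gly_fraction: float = 0.08,
    seed: int = 0,
    *,
    domain_compactness: float = 0.95,
    linker_angle_range: tuple[float, float] = (95.0, 120.0),
    bond_length: float = CA_BOND_LENGTH,
    cutoff: float = DEFAULT_CUTOFF,
    min_hinge_eigenvalue: float = 1e-4,
    max_attempts: int = 120,
    source_id: str | None = None,
) -> ChainStructure:
    """Generate a two-domain chain joined by a short linker.

    Two compact globular domains are connected by ``linker_length`` residues
    centred on the sequence middle, so the sequence midpoint lies inside the
    linker — a synthetic stand-in for a hinged two-domain protein.  Draws
    are resampled until the default elastic network has exactly six zero
    modes and a lowest non-zero eigenvalue of at least
    ``min_hinge_eigenvalue`` (single-strand linkers can otherwise leave
    free-dihedral mechanisms), so the fixture is always a mechanically
    sound hinge.
    """
    from .betagm import betagm_spectrum  # deferred: betagm imports chainio

    if n < 4 * linker_length:
        raise ChainError("dumbbell needs n >> linker_length")
    n_a = (n - linker_length) // 2
    n_b = n - linker_length - n_a
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        dom_a = _grow_walk(
            n_a, domain_compactness, rng, (80.0, 150.0), bond_length
        )
        if dom_a is None:
            continue
        # extend the linker away from domain A's centroid
        out_dir = dom_a[-1] - np.mean(dom_a, axis=0)
        nrm = np.linalg.norm(out_dir)
        out_dir = out_dir / nrm if nrm > 1e-9 else _random_unit(rng)
        far_point = dom_a[-1] + out_dir * bond_length * (linker_length + n_b)
        linker = _grow_walk(
            linker_length + 1,
            1.0,
            rng,
            linker_angle_range,
            bond_length,
            start=dom_a[-1],
            start_dir=out_dir,
            existing=dom_a[:-1],
            attractor=far_point,
        )
        if linker is None:
            continue
        linker = linker[1:]  # first point duplicates dom_a[-1]
        body = np.vstack([dom_a, linker[:-1]])
        centre_b = linker[-1] + out_dir * bond_length * 2.5
        dom_b = _grow_walk(
            n_b + 1,
            domain_compactness,
            rng,
            (80.0, 150.0),
            bond_length,
            start=linker[-1],
            start_dir=out_dir,
            existing=body,
            attractor=centre_b,
        )
        if dom_b is None:
            continue
        coords = np.vstack([dom_a, linker, dom_b[1:]])
        if len(coords) != n:
            continue
        if not network_is_connected(coords, cutoff):
            continue
        names = _draw_names(n, gly_fraction, rng)
        candidate = ChainStructure(
            source_id=source_id or f"dumbbell-n{n}-s{seed}",
            residue_names=names,
            coords=coords,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = betagm_spectrum(candidate)
        if spec.zero_mode_count == 6 and spec.eigenvalues[0] >= min_hinge_eigenvalue:
            return candidate
    raise ChainError(f"could not generate dumbbell chain after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Decoys, reversal, shape statistics
# ---------------------------------------------------------------------------

def make_decoys(
    chain: ChainStructure,
    window: int = 100,
    *,
    break_bounds: tuple[float, float] = BREAK_BOUNDS,
    on_break: str = "skip",
) -> list[ChainStructure]:
    """Cut fixed-length decoys by sliding a window along the chain.

    A chain of length ``window + N`` yields ``N + 1`` decoys, one per
    offset, each holding residues ``[k, k + window)`` with coordinates
    unmodified.  Windows spanning a chain break are skipped with a warning
    (``on_break="skip"``) or raise (``on_break="error"``).
    """
    n = len(chain)
    if n < window:
        raise ChainError(f"chain of length {n} shorter than window {window}")
    breaks = chain.break_positions(break_bounds)
    decoys = []
    for k in range(n - window + 1):
        in_window = [b for b in breaks if k <= b < k + window - 1]
        if in_window:
            msg = (
                f"window [{k}, {k + window}) of {chain.source_id} spans a "
                f"chain break at bond {in_window[0]}"
            )
            if on_break == "error":
                raise ChainError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        offset = k if chain.window_offset is None else chain.window_offset + k
        decoys.append(
            ChainStructure(
                source_id=chain.source_id,
                residue_names=chain.residue_names[k : k + window],
                coords=chain.coords[k : k + window],
                orientation=chain.orientation,
                window_offset=offset,
            )
        )
    return decoys


def reverse_chain(chain: ChainStructure) -> ChainStructure:
    """Reverse the sequence order of a chain; involution."""
    flipped = "reversed" if chain.orientation == "direct" else "direct"
    return ChainStructure(
        source_id=chain.source_id,
        residue_names=chain.residue_names[::-1],
        coords=chain.coords[::-1].copy(),
        orientation=flipped,
        window_offset=chain.window_offset,
    )


def radius_of_gyration(coords_or_chain) -> ShapeStats:
    """Root-mean-square distance of sites from their centroid."""
    coords = (
        coords_or_chain.coords
        if isinstance(coords_or_chain, ChainStructure)
        else np.asarray(coords_or_chain, dtype=float)
    )
    centred = coords - coords.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))
    return ShapeStats(radius_of_gyration=rg, n_residues=len(coords))


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_chain_table(chain: ChainStructure, path: str | Path) -> None:
    """Write one chain as a TSV table (index, residue, x, y, z)."""
    df = pd.DataFrame(
        {
            "index": np.arange(len(chain)),
            "residue": chain.residue_names,
            "x": chain.coords[:, 0],
            "y": chain.coords[:, 1],
            "z": chain.coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_chain_table(
    path: str | Path,
    source_id: str | None = None,
    orientation: str = "direct",
    window_offset: int | None = None,
) -> ChainStructure:
    df = pd.read_csv(path, sep="\t")
    return ChainStructure(
        source_id=source_id or Path(path).stem,
        residue_names=tuple(df["residue"]),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        orientation=orientation,
        window_offset=window_offset,
    )


def write_manifest(chains: Sequence[ChainStructure], path: str | Path) -> pd.DataFrame:
    """Write a dataset manifest (one row per sample) as TSV; returns it."""
    rows = []
    for i, c in enumerate(chains):
        rows.append(
            {
                "sample": i,
                "source_id": c.source_id,
                "window_offset": -1 if c.window_offset is None else c.window_offset,
                "orientation": c.orientation,
                "n_residues": len(c),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def manifest_frame(chains: Sequence[ChainStructure]) -> pd.DataFrame:
    """In-memory manifest DataFrame for a list of chains."""
    return pd.DataFrame(
        {
            "sample": np.arange(len(chains)),
            "source_id": [c.source_id for c in chains],
            "window_offset": [
                -1 if c.window_offset is None else c.window_offset for c in chains
            ],
            "orientation": [c.orientation for c in chains],
            "n_residues": [len(c) for c in chains],
        }
    )
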