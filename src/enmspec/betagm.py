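"""Elastic-network engine: ANM Hessian, beta-carbon augmented model, spectra.

Builds the harmonic-network Hessian of a C-alpha trace, optionally augmented
with effective C-beta centroids placed from the local backbone geometry and
analytically reduced back to C-alpha coordinates, and extracts the lowest
non-zero eigenvalues of the resulting quadratic form.

Conventions (all configurable through :class:`ENMParams`):

* contact pairs are those with reference distance strictly below the cutoff
  (default 7.5 Angstrom);
* consecutive C-alpha pairs are always bonded with ``k_backbone`` and are not
  double-counted as contact pairs;
* unit masses; eigenvalues are those of the Hessian itself, in units of the
  spring constants (energy / Angstrom^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chainio import ChainStructure

logger = logging.getLogger(__name__)

ZERO_MODE_RTOL = 1e-8
#: Consecutive C-alphas farther apart than this carry no backbone spring
#: (a chain break is not a covalent bond).
BACKBONE_BOND_MAX = 4.5


class SpectrumError(ValueError):
    """Raised when a Hessian cannot deliver the requested spectrum."""


@dataclass(frozen=True)
class ENMParams:
    """Parameters of the elastic-network models.

    ``model`` selects between the plain C-alpha anisotropic network
    (``"anm_calpha"``) and the C-beta augmented model (``"beta_gm"``).
    """

    cutoff: float = 7.5
    k_alpha_alpha: float = 1.0
    k_alpha_beta: float = 1.0
    k_beta_beta: float = 1.0
    k_backbone: float = 1.0
    cbeta_offset: float = 3.0
    model: str = "beta_gm"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for name in ("k_alpha_alpha", "k_alpha_beta", "k_beta_beta", "k_backbone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cbeta_offset <= 0:
            raise ValueError("cbeta_offset must be positive")
        if self.model not in ("anm_calpha", "beta_gm"):
            raise ValueError(f"unknown model {self.model!r}")

    def scaled(self, c: float) -> "ENMParams":
        """All spring constants multiplied by ``c``."""
        return ENMParams(
            cutoff=self.cutoff,
            k_alpha_alpha=c * self.k_alpha_alpha,
            k_alpha_beta=c * self.k_alpha_beta,
            k_beta_beta=c * self.k_beta_beta,
            k_backbone=c * self.k_backbone,
            cbeta_offset=self.cbeta_offset,
            model=self.model,
        )


@dataclass(frozen=True)
class EffectiveHessian:
    """3N x 3N symmetric Hessian in C-alpha displacement coordinates."""

    matrix: np.ndarray
    params: ENMParams
    n_sites: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3 * self.n_sites, 3 * self.n_sites):
            raise ValueError(f"matrix shape {m.shape} inconsistent with n_sites")
        asym = np.max(np.abs(m - m.T))
        if asym > 1e-10 * max(1.0, np.max(np.abs(m))):
            raise ValueError(f"Hessian not symmetric (max asymmetry {asym:g})")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class SpectrumTarget:
    """The lowest non-zero fluctuation eigenvalues, ascending."""

    eigenvalues: np.ndarray
    zero_mode_count: int
    source_id: str = ""
    window_offset: int | None = None
    orientation: str = "direct"

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev <= 0):
            raise ValueError("eigenvalues must be strictly positive")
        if np.any(np.diff(ev) < 0):
            raise ValueError("eigenvalues must be ascending")
        object.__setattr__(self, "eigenvalues", ev)


class CBetaPlacement(NamedTuple):
    """Positions and linearized placement maps of the effective C-betas.

    ``indices[k]`` is the residue index carrying the k-th centroid;
    ``positions[k]`` its coordinate; ``jacobians[k]`` the 3x9 derivative of
    the position with respect to the stacked parent C-alpha coordinates
    (residues ``i-1``, ``i``, ``i+1``).
    """

    indices: np.ndarray
    positions: np.ndarray
    jacobians: np.ndarray


# ---------------------------------------------------------------------------
# Pair inventory and energies
# ---------------------------------------------------------------------------

def _calpha_pairs(
    ref_coords: np.ndarray, params: ENMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (i, j), i < j, and spring constants for a C-alpha-only network.

    Consecutive residues are bonded with ``k_backbone`` regardless of the
    cutoff, unless they sit beyond :data:`BACKBONE_BOND_MAX` (a chain break
    is not a bond — the pair then falls back to the cutoff rule); all other
    pairs are included iff their reference distance is strictly below the
    cutoff.
    """
    n = len(ref_coords)
    dist = squareform(pdist(ref_coords))
    pairs = []
    ks = []
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 and dist[i, j] < BACKBONE_BOND_MAX:
                pairs.append((i, j))
                ks.append(params.k_backbone)
            elif dist[i, j] < params.cutoff:
                pairs.append((i, j))
                ks.append(params.k_alpha_alpha)
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(ks)


def pair_energy_total(
    coords: np.ndarray,
    ref_coords: np.ndarray,
    params: ENMParams,
    pairs: np.ndarray | None = None,
    ks: np.ndarray | None = None,
) -> float:
    """Total harmonic pair energy ``sum (k/2)(|r_ij| - |r_ij0|)^2``.

    The pair list is fixed by the reference geometry (cutoff contacts plus
    backbone bonds) unless given explicitly; serves as the finite-difference
    oracle for the analytic Hessians.
    """
    coords = np.asarray(coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    if coords.shape != ref_coords.shape:
        raise ValueError(
            f"coords {coords.shape} and ref_coords {ref_coords.shape} differ"
        )
    if pairs is None or ks is None:
        pairs, ks = _calpha_pairs(ref_coords, params)
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    d0 = np.linalg.norm(ref_coords[pairs[:, 0]] - ref_coords[pairs[:, 1]], axis=1)
    return float(np.sum(0.5 * ks * (d - d0) ** 2))


def _assemble_pair_hessian(
    ref_coords: np.ndarray, pairs: np.ndarray, ks: np.ndarray
) -> np.ndarray:
    """ANM Hessian over an explicit pair list.

    The off-diagonal 3x3 block of an interacting pair is
    ``-k (r_mu r_nu) / |r0|^2`` with ``r = r_i0 - r_j0``; diagonal blocks
    accumulate the negated sum of the row (translation invariance).
    """
    n = len(ref_coords)
    h = np.zeros((3 * n, 3 * n))
    for (i, j), k in zip(pairs, ks):
        r = ref_coords[i] - ref_coords[j]
        d2 = float(r @ r)
        if d2 < 1e-16:
            raise ValueError(f"coincident interacting sites ({i}, {j})")
        block = (k / d2) * np.outer(r, r)
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
    return h


def build_anm_hessian(
    coords: np.ndarray, params: ENMParams | None = None
) -> EffectiveHessian:
    """Anisotropic-network Hessian of a C-alpha trace."""
    params = params or ENMParams(model="anm_calpha")
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 sites")
    pairs, ks = _calpha_pairs(coords, params)
    h = _assemble_pair_hessian(coords, pairs, ks)
    return EffectiveHessian(matrix=h, params=params, n_sites=len(coords))


# ---------------------------------------------------------------------------
# C-beta placement
# ---------------------------------------------------------------------------

def cbeta_position(
    r_prev: np.ndarray, r_i: np.ndarray, r_next: np.ndarray, offset: float
) -> np.ndarray | None:
    """Effective C-beta of residue i from its three local C-alphas.

    The centroid sits at distance ``offset`` from ``r_i`` along the in-plane
    bisector direction ``v = 2 r_i - r_prev - r_next``; ``None`` when the
    trace is locally collinear (|v| ~ 0).
    """
    v = 2.0 * r_i - r_prev - r_next
    nv = np.linalg.norm(v)
    if nv < 1e-6:
        return None
    return r_i + offset * v / nv


def place_cbeta(chain: ChainStructure, params: ENMParams | None = None) -> CBetaPlacement:
    """Place effective C-beta centroids and their placement Jacobians.

    Terminal residues and glycines carry no centroid; locally collinear
    geometry omits the centroid with a warning.  Each Jacobian is the exact
    derivative of the placement map at the reference coordinates, depending
    only on C-alphas ``i-1``, ``i``, ``i+1``.
    """
    params = params or ENMParams()
    if len(chain) < 3:
        raise ValueError("need at least 3 residues to place C-betas")
    coords = chain.coords
    gly = chain.is_glycine
    c = params.cbeta_offset
    eye = np.eye(3)
    indices, positions, jacobians = [], [], []
    for i in range(1, len(chain) - 1):
        if gly[i]:
            continue
        v = 2.0 * coords[i] - coords[i - 1] - coords[i + 1]
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            warnings.warn(
                f"residue {i} of {chain.source_id}: locally collinear trace, "
                "C-beta omitted",
                stacklevel=2,
            )
            continue
        u = v / nv
        proj = (eye - np.outer(u, u)) / nv  # d(v/|v|)/dv
        jac = np.zeros((3, 9))
        jac[:, 0:3] = -c * proj          # d/d r_{i-1}
        jac[:, 3:6] = eye + 2.0 * c * proj  # d/d r_i
        jac[:, 6:9] = -c * proj          # d/d r_{i+1}
        indices.append(i)
        positions.append(coords[i] + c * u)
        jacobians.append(jac)
    return CBetaPlacement(
        indices=np.array(indices, dtype=int),
        positions=np.array(positions).reshape(-1, 3),
        jacobians=np.array(jacobians).reshape(-1, 3, 9),
    )


# ---------------------------------------------------------------------------
# Full beta-model Hessian
# ---------------------------------------------------------------------------

def _mixed_pairs(
    alpha_coords: np.ndarray,
    placement: CBetaPlacement,
    params: ENMParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Site coordinates, pair list and constants of the two-bead network.

    Sites 0..N-1 are C-alphas, sites N.. are the centroids in placement
    order.  Alpha-alpha pairs follow :func:`_calpha_pairs`; alpha-beta and
    beta-beta pairs are pure cutoff contacts.
    """
    n = len(alpha_coords)
    m = len(placement.indices)
    sites = np.vstack([alpha_coords, placement.positions]) if m else alpha_coords
    pairs, ks = _calpha_pairs(alpha_coords, params)
    pairs = list(map(tuple, pairs))
    ks = list(ks)
    if m:
        dist = squareform(pdist(sites))
        for a in range(n):
            for b in range(m):
                if dist[a, n + b] < params.cutoff:
                    pairs.append((a, n + b))
                    ks.append(params.k_alpha_beta)
        for a in range(m):
            for b in range(a + 1, m):
                if dist[n + a, n + b] < params.cutoff:
                    pairs.append((n + a, n + b))
                    ks.append(params.k_beta_beta)
    return sites, np.array(pairs, dtype=int).reshape(-1, 2), np.array(ks)


def _projection_matrix(n: int, placement: CBetaPlacement) -> np.ndarray:
    """Map from C-alpha displacements to (alpha, beta) displacements."""
    m = len(placement.indices)
    b = np.zeros((3 * (n + m), 3 * n))
    b[: 3 * n, : 3 * n] = np.eye(3 * n)
    for k, i in enumerate(placement.indices):
        row = 3 * (n + k)
        jac = placement.jacobians[k]
        b[row : row + 3, 3 * (i - 1) : 3 * (i - 1) + 3] = jac[:, 0:3]
        b[row : row + 3, 3 * i : 3 * i + 3] = jac[:, 3:6]
        b[row : row + 3, 3 * (i + 1) : 3 * (i + 1) + 3] = jac[:, 6:9]
    return b


def build_betagm_hessian(
    chain: ChainStructure, params: ENMParams | None = None
) -> EffectiveHessian:
    """C-alpha-reduced Hessian of the C-beta augmented network.

    Assembles the two-bead ANM Hessian (backbone bonds, cutoff contacts in
    the alpha-alpha, alpha-beta and beta-beta sectors) and eliminates the
    centroid coordinates through their linear placement maps, yielding a
    3N x 3N quadratic form in the C-alpha displacements.
    """
    params = params or ENMParams()
    if len(chain) < 4:
        raise ValueError("need at least 4 residues")
    placement = place_cbeta(chain, params)
    sites, pairs, ks = _mixed_pairs(chain.coords, placement, params)
    if not _sites_connected(sites, pairs, len(chain)):
        raise SpectrumError(
            "elastic network is disconnected under the cutoff "
            f"({params.cutoff} A); increase the cutoff or reject the structure"
        )
    h_full = _assemble_pair_hessian(sites, pairs, ks)
    b = _projection_matrix(len(chain), placement)
    h = b.T @ h_full @ b
    h = 0.5 * (h + h.T)  # clean round-off asymmetry
    return EffectiveHessian(matrix=h, params=params, n_sites=len(chain))


def _sites_connected(sites: np.ndarray, pairs: np.ndarray, n_alpha: int) -> bool:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(sites)
    if len(pairs) == 0:
        return n <= 1
    data = np.ones(len(pairs))
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp == 1


def build_hessian(chain: ChainStructure, params: ENMParams | None = None) -> EffectiveHessian:
    """Dispatch on ``params.model``."""
    params = params or ENMParams()
    if params.model == "anm_calpha":
        return build_anm_hessian(chain.coords, params)
    return build_betagm_hessian(chain, params)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

def spectrum(
    hessian: EffectiveHessian,
    n_modes: int = 10,
    *,
    source_id: str = "",
    window_offset: int | None = None,
    orientation: str = "direct",
    return_vectors: bool = False,
):
    """Lowest ``n_modes`` non-zero eigenvalues of an effective Hessian.

    Eigenvalues below ``1e-8 * max(eigenvalue)`` count as zero modes; a
    connected, non-collinear structure has exactly six (rigid translations
    and rotations) and a warning is emitted otherwise.
    """
    from scipy.linalg import eigh

    evals, evecs = eigh(hessian.matrix)
    tol = ZERO_MODE_RTOL * max(float(evals[-1]), 1e-300)
    nonzero = evals > tol
    zero_count = int(np.sum(~nonzero))
    if np.sum(nonzero) < n_modes:
        raise SpectrumError(
            f"only {int(np.sum(nonzero))} non-zero eigenvalues, need {n_modes}"
        )
    if zero_count != 6:
        warnings.warn(
            f"{zero_count} zero modes instead of 6: structure may be "
            "collinear or disconnected",
            stacklevel=2,
        )
    idx = np.flatnonzero(nonzero)[:n_modes]
    target = SpectrumTarget(
        eigenvalues=evals[idx],
        zero_mode_count=zero_count,
        source_id=source_id,
        window_offset=window_offset,
        orientation=orientation,
    )
    if return_vectors:
        return target, evecs[:, idx]
    return target


def betagm_spectrum(
    chain: ChainStructure, params: ENMParams | None = None, n_modes: int = 10
) -> SpectrumTarget:
    """Convenience: model Hessian of a chain, then its low spectrum."""
    params = params or ENMParams()
    h = build_hessian(chain, params)
    return spectrum(
        h,
        n_modes,
        source_id=chain.source_id,
        window_offset=chain.window_offset,
        orientation=chain.orientation,
    )
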