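import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from enmspec import chainio
from enmspec.betagm import (
    ENMParams,
    SpectrumError,
    betagm_spectrum,
    build_anm_hessian,
    build_betagm_hessian,
    pair_energy_total,
    place_cbeta,
    spectrum,
)

# ---------------------------------------------------------------------------
# Independent oracles (deliberately NOT using the package internals)
# ---------------------------------------------------------------------------


def oracle_pair_list(ref, cutoff, k_contact, k_backbone, n_alpha):
    """Backbone bonds between consecutive alphas + strict-cutoff contacts."""
    dist = squareform(pdist(ref))
    pairs, ks = [], []
    for i in range(len(ref)):
        for j in range(i + 1, len(ref)):
            if j == i + 1 and i < n_alpha - 1 and j < n_alpha:
                pairs.append((i, j))
                ks.append(k_backbone)
            elif dist[i, j] < cutoff:
                pairs.append((i, j))
                ks.append(k_contact)
    return pairs, ks


def oracle_energy(coords, ref, pairs, ks):
    e = 0.0
    for (i, j), k in zip(pairs, ks):
        d = np.linalg.norm(coords[i] - coords[j])
        d0 = np.linalg.norm(ref[i] - ref[j])
        e += 0.5 * k * (d - d0) ** 2
    return e


def fd_hessian(energy_fn, x0, eps=1e-5):
    """Central finite-difference Hessian of a scalar function of flat coords."""
    n = len(x0)
    h = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            xpp = x0.copy(); xpp[a] += eps; xpp[b] += eps
            xpm = x0.copy(); xpm[a] += eps; xpm[b] -= eps
            xmp = x0.copy(); xmp[a] -= eps; xmp[b] += eps
            xmm = x0.copy(); xmm[a] -= eps; xmm[b] -= eps
            val = (
                energy_fn(xpp) - energy_fn(xpm) - energy_fn(xmp) + energy_fn(xmm)
            ) / (4 * eps**2)
            h[a, b] = h[b, a] = val
    return h


def oracle_cbeta_positions(coords, gly_mask, offset):
    """Centroid of residue i from alphas i-1, i, i+1 (None if absent)."""
    out = []
    for i in range(len(coords)):
        if i == 0 or i == len(coords) - 1 or gly_mask[i]:
            out.append(None)
            continue
        v = 2 * coords[i] - coords[i - 1] - coords[i + 1]
        nv = np.linalg.norm(v)
        out.append(None if nv < 1e-6 else coords[i] + offset * v / nv)
    return out


def oracle_composed_energy(flat_alpha, ref_chain, params):
    """Two-bead pair energy with centroids recomputed from displaced alphas.

    The pair list and rest lengths are fixed by the reference geometry; the
    centroid positions follow the displaced alpha coordinates nonlinearly.
    At the reference configuration all springs are relaxed, so the true
    Hessian equals the linearized (projected) one exactly.
    """
    coords = flat_alpha.reshape(-1, 3)
    ref = ref_chain.coords
    gly = ref_chain.is_glycine
    n = len(ref)

    ref_cb = oracle_cbeta_positions(ref, gly, params.cbeta_offset)
    cb_idx = [i for i, p in enumerate(ref_cb) if p is not None]
    ref_sites = np.vstack([ref] + [ref_cb[i] for i in cb_idx])
    cur_cb = oracle_cbeta_positions(coords, gly, params.cbeta_offset)
    cur_sites = np.vstack([coords] + [cur_cb[i] for i in cb_idx])

    dist = squareform(pdist(ref_sites))
    e = 0.0
    for a in range(len(ref_sites)):
        for b in range(a + 1, len(ref_sites)):
            if b == a + 1 and b < n:
                k = params.k_backbone
            elif dist[a, b] < params.cutoff:
                if a < n and b < n:
                    k = params.k_alpha_alpha
                elif a < n or b < n:
                    k = params.k_alpha_beta
                else:
                    k = params.k_beta_beta
            else:
                continue
            d = np.linalg.norm(cur_sites[a] - cur_sites[b])
            e += 0.5 * k * (d - dist[a, b]) ** 2
    return e


# ---------------------------------------------------------------------------
# pair_energy_total
# ---------------------------------------------------------------------------


class TestPairEnergy:
    def test_equilibrium_zero(self, zigzag_chain, default_params):
        c = zigzag_chain.coords
        assert pair_energy_total(c, c, default_params) == 0.0

    def test_two_beads_closed_form(self):
        params = ENMParams(cutoff=7.5, k_backbone=1.0)
        ref = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        moved = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert pair_energy_total(moved, ref, params) == pytest.approx(0.5)

    def test_beyond_cutoff_zero(self):
        params = ENMParams(cutoff=7.5)
        ref = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        moved = np.array([[0.0, 0, 0], [15.0, 0, 0]])
        # two free beads: the only candidate pair is consecutive -> backbone
        # spring always applies, so suppress it to test the cutoff rule
        params = ENMParams(cutoff=7.5, k_backbone=0.0)
        assert pair_energy_total(moved, ref, params) == pytest.approx(0.0)

    def test_length_mismatch(self, default_params):
        with pytest.raises(ValueError):
            pair_energy_total(np.zeros((3, 3)), np.zeros((4, 3)), default_params)

    def test_matches_oracle(self, small_synthetic_chain, default_params):
        ref = small_synthetic_chain.coords
        rng = np.random.default_rng(0)
        moved = ref + 0.1 * rng.normal(size=ref.shape)
        pairs, ks = oracle_pair_list(
            ref, default_params.cutoff, default_params.k_alpha_alpha,
            default_params.k_backbone, len(ref),
        )
        expected = oracle_energy(moved, ref, pairs, ks)
        assert pair_energy_total(moved, ref, default_params) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# ANM Hessian
# ---------------------------------------------------------------------------


class TestAnmHessian:
    def test_two_beads_x_axis(self):
        params = ENMParams(k_backbone=1.0)
        ref = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        h = build_anm_hessian(ref, params).matrix
        pair_block = h[0:3, 3:6]
        np.testing.assert_allclose(pair_block, np.diag([-1.0, 0.0, 0.0]), atol=1e-12)
        # diagonal blocks are the negated pair block
        np.testing.assert_allclose(h[0:3, 0:3], np.diag([1.0, 0.0, 0.0]), atol=1e-12)

    def test_rows_sum_to_zero(self, small_synthetic_chain, default_params):
        h = build_anm_hessian(small_synthetic_chain.coords, default_params).matrix
        n = len(small_synthetic_chain)
        blocks = h.reshape(n, 3, n, 3)
        np.testing.assert_allclose(blocks.sum(axis=2), 0.0, atol=1e-10)

    def test_matches_fd_oracle(self, default_params):
        chain = chainio.generate_synthetic_chain(5, 0.6, seed=21)
        ref = chain.coords
        pairs, ks = oracle_pair_list(
            ref, default_params.cutoff, default_params.k_alpha_alpha,
            default_params.k_backbone, len(ref),
        )
        h_fd = fd_hessian(
            lambda x: oracle_energy(x.reshape(-1, 3), ref, pairs, ks),
            ref.reshape(-1).astype(float),
            eps=1e-4,
        )
        h = build_anm_hessian(ref, default_params).matrix
        np.testing.assert_allclose(h, h_fd, atol=1e-6)

    def test_coincident_points_raise(self, default_params):
        ref = np.array([[0.0, 0, 0], [0.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            build_anm_hessian(ref, default_params)


# ---------------------------------------------------------------------------
# C-beta placement
# ---------------------------------------------------------------------------


class TestPlaceCbeta:
    def test_glycine_skipped(self, make_chain):
        step = 3.8 / np.sqrt(2)
        coords = [(step * i, step * (i % 2), 0.2 * i) for i in range(5)]
        chain = make_chain(coords, gly_at=(2,))
        placement = place_cbeta(chain)
        assert 2 not in placement.indices
        assert 1 in placement.indices and 3 in placement.indices

    def test_terminals_skipped(self, zigzag_chain):
        placement = place_cbeta(zigzag_chain)
        assert 0 not in placement.indices
        assert len(zigzag_chain) - 1 not in placement.indices

    def test_right_angle_closed_form(self, make_chain):
        coords = [
            (0, 0, 0), (3.8, 0, 0), (3.8, 3.8, 0), (7.6, 3.8, 0), (7.6, 7.6, 0)
        ]
        chain = make_chain(coords)
        placement = place_cbeta(chain, ENMParams(cbeta_offset=3.0))
        k = list(placement.indices).index(1)
        expected = np.array([3.8, 0, 0]) + 3.0 * np.array([1, -1, 0]) / np.sqrt(2)
        np.testing.assert_allclose(placement.positions[k], expected, atol=1e-12)

    def test_collinear_omitted_with_warning(self, make_chain):
        coords = [(3.8 * i, 0, 0) for i in range(4)]
        coords += [(3.8 * 3, 3.8, 0)]
        chain = make_chain(coords)
        with pytest.warns(UserWarning, match="collinear"):
            placement = place_cbeta(chain)
        assert 1 not in placement.indices
        assert 2 not in placement.indices

    def test_jacobians_match_fd(self, small_synthetic_chain, default_params):
        chain = small_synthetic_chain
        placement = place_cbeta(chain, default_params)
        coords = chain.coords
        eps = 1e-6
        for k, i in enumerate(placement.indices[:5]):
            jac_fd = np.zeros((3, 9))
            for a in range(9):
                ri = a // 3 + i - 1
                comp = a % 3
                cp = coords.copy(); cp[ri, comp] += eps
                cm = coords.copy(); cm[ri, comp] -= eps
                pp = oracle_cbeta_positions(
                    cp, chain.is_glycine, default_params.cbeta_offset
                )[i]
                pm = oracle_cbeta_positions(
                    cm, chain.is_glycine, default_params.cbeta_offset
                )[i]
                jac_fd[:, a] = (pp - pm) / (2 * eps)
            np.testing.assert_allclose(placement.jacobians[k], jac_fd, atol=1e-6)


# ---------------------------------------------------------------------------
# beta-model Hessian
# ---------------------------------------------------------------------------


class TestBetagmHessian:
    def test_reduces_to_anm_when_beta_springs_off(self, small_synthetic_chain):
        params = ENMParams(k_alpha_beta=0.0, k_beta_beta=0.0)
        h_beta = build_betagm_hessian(small_synthetic_chain, params).matrix
        h_anm = build_anm_hessian(small_synthetic_chain.coords, params).matrix
        np.testing.assert_allclose(h_beta, h_anm, atol=1e-10)

    def test_symmetric_rows_zero(self, small_synthetic_chain, default_params):
        h = build_betagm_hessian(small_synthetic_chain, default_params).matrix
        np.testing.assert_allclose(h, h.T, atol=1e-10)
        n = len(small_synthetic_chain)
        blocks = h.reshape(n, 3, n, 3)
        np.testing.assert_allclose(blocks.sum(axis=2), 0.0, atol=1e-9)

    def test_matches_fd_of_composed_energy(self, default_params):
        chain = chainio.generate_synthetic_chain(6, 0.7, seed=33)
        h = build_betagm_hessian(chain, default_params).matrix
        h_fd = fd_hessian(
            lambda x: oracle_composed_energy(x, chain, default_params),
            chain.coords.reshape(-1).astype(float),
            eps=1e-4,
        )
        np.testing.assert_allclose(h, h_fd, atol=1e-5)

    def test_disconnected_raises(self, make_chain):
        coords = [(3.8 * i, 0.4 * (i % 2), 0) for i in range(4)]
        coords += [(200 + 3.8 * i, 0.4 * (i % 2), 0) for i in range(4)]
        chain = make_chain(np.array(coords))
        with pytest.raises(SpectrumError, match="cutoff"):
            build_betagm_hessian(chain, ENMParams())


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


class TestSpectrum:
    def test_dimer_nonzero_eigenvalue(self):
        # one spring of constant k between two beads: single stretch mode 2k,
        # five remaining rigid modes for the dimer
        params = ENMParams(k_backbone=1.0)
        h = build_anm_hessian(np.array([[0.0, 0, 0], [3.0, 0, 0]]), params)
        with pytest.warns(UserWarning):
            target = spectrum(h, n_modes=1)
        assert target.eigenvalues[0] == pytest.approx(2.0, rel=1e-12)
        assert target.zero_mode_count == 5

    def test_six_zero_modes_100mer(self, chain100, default_params):
        spec = betagm_spectrum(chain100, default_params)
        assert spec.zero_mode_count == 6
        assert np.all(spec.eigenvalues > 0)
        assert np.all(np.diff(spec.eigenvalues) >= 0)
        assert len(spec.eigenvalues) == 10

    def test_rigid_motion_invariance(self, chain100, default_params):
        from scipy.spatial.transform import Rotation

        spec = betagm_spectrum(chain100, default_params)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = chainio.ChainStructure(
            source_id="moved",
            residue_names=chain100.residue_names,
            coords=chain100.coords @ rot.T + np.array([5.0, -3.0, 12.0]),
        )
        spec2 = betagm_spectrum(moved, default_params)
        np.testing.assert_allclose(
            spec2.eigenvalues, spec.eigenvalues, rtol=1e-8
        )

    def test_sequence_reversal_invariance(self, chain100, default_params):
        spec = betagm_spectrum(chain100, default_params)
        spec_rev = betagm_spectrum(chainio.reverse_chain(chain100), default_params)
        np.testing.assert_allclose(
            spec_rev.eigenvalues, spec.eigenvalues, rtol=1e-8
        )

    def test_linearity_in_spring_constants(self, small_synthetic_chain, default_params):
        c = 2.7
        spec = betagm_spectrum(small_synthetic_chain, default_params)
        spec_scaled = betagm_spectrum(small_synthetic_chain, default_params.scaled(c))
        np.testing.assert_allclose(
            spec_scaled.eigenvalues, c * spec.eigenvalues, rtol=1e-10
        )

    def test_collinear_zero_mode_count(self, default_params):
        # exactly collinear harmonic networks leave every transverse
        # displacement free at quadratic order: 2N + 1 mechanisms (the dimer
        # special case 2*2 + 1 = 5 is covered above)
        n = 5
        coords = np.array([[3.8 * i, 0.0, 0.0] for i in range(n)])
        h = build_anm_hessian(coords, default_params)
        with pytest.warns(UserWarning):
            target = spectrum(h, n_modes=3)
        assert target.zero_mode_count == 2 * n + 1

    def test_too_many_modes_requested(self, default_params):
        h = build_anm_hessian(np.array([[0.0, 0, 0], [3.0, 0, 0]]), default_params)
        with pytest.raises(SpectrumError):
            spectrum(h, n_modes=3)

    def test_synthetic_chains_pass_zero_mode_check(self, default_params):
        for seed in range(4):
            chain = chainio.generate_synthetic_chain(40, 0.5, seed=seed + 50)
            spec = betagm_spectrum(chain, default_params)
            assert spec.zero_mode_count == 6
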