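import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enmspec import chainio
from enmspec.chainio import (
    ChainError,
    ChainStructure,
    generate_synthetic_chain,
    make_decoys,
    radius_of_gyration,
    read_calpha_trace,
    reverse_chain,
)


class TestReadCalphaTrace:
    def test_minimal_pdb(self, minimal_pdb_text):
        chain = read_calpha_trace(minimal_pdb_text, "A")
        assert len(chain) == 5
        np.testing.assert_allclose(chain.coords[0], [11.639, 6.071, -5.147])
        np.testing.assert_allclose(chain.coords[-1], [1.596, 5.741, 3.466])
        assert chain.residue_names == ("MET", "GLY", "LYS", "TRP", "VAL")

    def test_glycine_tracked(self, minimal_pdb_text):
        chain = read_calpha_trace(minimal_pdb_text)
        assert chain.residue_names[1] == "GLY"
        assert chain.is_glycine[1]
        assert not chain.is_glycine[0]

    def test_hetatm_and_non_ca_ignored(self, minimal_pdb_text):
        # the file contains N, C, CB and a HETATM water: only 5 CA survive
        chain = read_calpha_trace(minimal_pdb_text)
        assert len(chain) == 5

    def test_altloc_a_kept(self, altloc_pdb_text):
        chain = read_calpha_trace(altloc_pdb_text, "A")
        assert len(chain) == 5
        np.testing.assert_allclose(chain.coords[1], [9.580, 6.922, -2.855])

    def test_missing_chain_names_available(self, minimal_pdb_text):
        with pytest.raises(ChainError, match="A"):
            read_calpha_trace(minimal_pdb_text, "Z")

    def test_too_short_raises(self, minimal_pdb_text):
        # keep only the first three CA records of the valid file
        lines = [l for l in minimal_pdb_text.splitlines() if " CA " in l][:3]
        text = "\n".join(lines) + "\nEND\n"
        with pytest.raises(ChainError):
            read_calpha_trace(text)


class TestChainStructure:
    def test_rejects_short(self):
        with pytest.raises(ChainError):
            ChainStructure("x", ("ALA",) * 3, np.zeros((3, 3)))

    def test_rejects_nonfinite(self):
        coords = np.zeros((4, 3))
        coords[2, 1] = np.nan
        with pytest.raises(ChainError):
            ChainStructure("x", ("ALA",) * 4, coords)

    def test_break_detection(self, make_chain):
        coords = [(3.8 * i, 0, 0.5 * (i % 2)) for i in range(5)]
        coords[4] = (100.0, 0, 0)
        chain = make_chain(coords)
        assert not chain.is_break_free()
        assert 3 in chain.break_positions()


class TestGenerateSyntheticChain:
    def test_deterministic(self):
        a = generate_synthetic_chain(100, 0.7, seed=1)
        b = generate_synthetic_chain(100, 0.7, seed=1)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.residue_names == b.residue_names

    def test_bond_lengths_fixed(self, chain100):
        d = chain100.consecutive_distances()
        np.testing.assert_allclose(d, 3.8, atol=1e-9)

    def test_excluded_volume(self, chain100):
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(chain100.coords))
        n = len(chain100)
        mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > 1
        assert dist[mask].min() >= 4.0

    def test_network_connected(self, chain100):
        assert chainio.network_is_connected(chain100.coords)

    def test_compactness_reduces_rg(self):
        # mean Rg over independent draws must drop with the compactness bias
        rg = {c: [] for c in (0.1, 0.9)}
        for c in rg:
            for seed in range(50):
                chain = generate_synthetic_chain(100, c, seed=seed + 1000)
                rg[c].append(radius_of_gyration(chain).radius_of_gyration)
        assert np.mean(rg[0.9]) < np.mean(rg[0.1])

    def test_glycine_fraction(self):
        chain = generate_synthetic_chain(100, 0.5, gly_fraction=1.0, seed=2)
        assert all(name == "GLY" for name in chain.residue_names)

    def test_too_short_raises(self):
        with pytest.raises(ChainError):
            generate_synthetic_chain(3, 0.5, seed=0)


class TestDumbbell:
    def test_deterministic_and_shaped(self):
        a = chainio.generate_dumbbell_chain(seed=4)
        b = chainio.generate_dumbbell_chain(seed=4)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert len(a) == 120
        assert a.is_break_free()

    def test_less_globular_than_compact_chain(self):
        dumbbell = chainio.generate_dumbbell_chain(seed=4)
        compact = generate_synthetic_chain(120, 0.9, seed=4)
        assert (
            radius_of_gyration(dumbbell).radius_of_gyration
            > radius_of_gyration(compact).radius_of_gyration
        )


class TestMakeDecoys:
    def test_count_law_105(self, default_params):
        chain = generate_synthetic_chain(105, 0.6, seed=3)
        assert len(make_decoys(chain, 100)) == 6

    def test_exact_window_identity(self, chain100):
        (decoy,) = make_decoys(chain100, 100)
        np.testing.assert_array_equal(decoy.coords, chain100.coords)
        assert decoy.window_offset == 0

    def test_offsets(self):
        chain = generate_synthetic_chain(103, 0.6, seed=9)
        offsets = [d.window_offset for d in make_decoys(chain, 100)]
        assert offsets == [0, 1, 2, 3]

    @given(n_extra=st.integers(0, 12))
    @settings(max_examples=6, deadline=None)
    def test_count_law_property(self, n_extra):
        chain = generate_synthetic_chain(20 + n_extra, 0.6, seed=n_extra)
        assert len(make_decoys(chain, 20)) == n_extra + 1

    def test_shorter_than_window_raises(self, chain100):
        with pytest.raises(ChainError):
            make_decoys(chain100, 101)

    def test_break_window_skipped_with_warning(self, make_chain):
        coords = [(3.8 * i, 0.5 * (i % 2), 0) for i in range(6)]
        coords = np.array(coords, dtype=float)
        coords[3:] += np.array([30.0, 0, 0])  # break between 2 and 3
        chain = make_chain(coords)
        with pytest.warns(UserWarning, match="break"):
            decoys = make_decoys(chain, 4)
        # windows [0,4), [1,5), [2,6) all span bond 2-3
        assert decoys == []

    def test_break_window_error_mode(self, make_chain):
        coords = np.array([(3.8 * i, 0.5 * (i % 2), 0) for i in range(6)])
        coords[3:] += np.array([30.0, 0, 0])
        chain = make_chain(coords)
        with pytest.raises(ChainError):
            make_decoys(chain, 4, on_break="error")


class TestReverseChain:
    def test_involution(self, chain100):
        again = reverse_chain(reverse_chain(chain100))
        np.testing.assert_array_equal(again.coords, chain100.coords)
        assert again.residue_names == chain100.residue_names
        assert again.orientation == "direct"

    def test_first_equals_last(self, chain100):
        rev = reverse_chain(chain100)
        np.testing.assert_array_equal(rev.coords[0], chain100.coords[-1])
        assert rev.orientation == "reversed"
        assert rev.source_id == chain100.source_id

    def test_preserves_rg(self, chain100):
        assert radius_of_gyration(reverse_chain(chain100)) == radius_of_gyration(
            chain100
        )


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]).radius_of_gyration == 0.0

    def test_two_points(self):
        stats = radius_of_gyration([[0, 0, 0], [2.0, 0, 0]])
        assert stats.radius_of_gyration == pytest.approx(1.0)
        assert stats.n_residues == 2

    def test_four_points_closed_form(self):
        pts = [[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]]
        assert radius_of_gyration(pts).radius_of_gyration == pytest.approx(
            np.sqrt(0.5)
        )

    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=20, deadline=None)
    def test_translation_invariant(self, shift, seed):
        pts = np.random.default_rng(seed).normal(size=(8, 3))
        a = radius_of_gyration(pts).radius_of_gyration
        b = radius_of_gyration(pts + shift).radius_of_gyration
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestSerialization:
    def test_chain_table_roundtrip(self, tmp_path, chain100):
        path = tmp_path / "chain.tsv"
        chainio.write_chain_table(chain100, path)
        back = chainio.read_chain_table(path, source_id=chain100.source_id)
        np.testing.assert_allclose(back.coords, chain100.coords, atol=1e-5)
        assert back.residue_names == chain100.residue_names

    def test_manifest(self, tmp_path, chain100):
        decoys = make_decoys(chain100, 50)
        df = chainio.write_manifest(decoys, tmp_path / "manifest.tsv")
        assert len(df) == 51
        assert set(df["orientation"]) == {"direct"}
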