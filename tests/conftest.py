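"""Shared fixtures.

Heavy session-scoped fixtures (synthetic dataset, trained surrogate models)
are only materialized by the tests that request them — the unit-test part of
the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from enmspec import chainio
from enmspec.betagm import ENMParams


# deterministic, non-glycine-free residue draw for tiny hand-built chains
def _names(n: int, gly_at: tuple[int, ...] = ()) -> tuple[str, ...]:
    return tuple("GLY" if i in gly_at else "ALA" for i in range(n))


@pytest.fixture
def make_chain():
    """Factory for hand-built chains from explicit coordinates."""

    def _make(coords, gly_at=(), source_id="test", **kw):
        coords = np.asarray(coords, dtype=float)
        return chainio.ChainStructure(
            source_id=source_id,
            residue_names=_names(len(coords), gly_at),
            coords=coords,
            **kw,
        )

    return _make


@pytest.fixture
def zigzag_chain(make_chain):
    """Planar 6-residue zigzag with realistic 3.8 A bonds, no glycines."""
    step = 3.8 / np.sqrt(2)
    coords = [(step * i, step * (i % 2), 0.3 * i) for i in range(6)]
    return make_chain(coords)


@pytest.fixture
def small_synthetic_chain():
    return chainio.generate_synthetic_chain(30, compactness=0.6, seed=11)


@pytest.fixture
def chain100():
    return chainio.generate_synthetic_chain(100, compactness=0.6, seed=5)


@pytest.fixture(scope="session")
def default_params():
    return ENMParams()


MINIMAL_PDB = """\
HEADER    TEST PROTEIN
ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  MET A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   MET A   1      10.759   5.278  -4.190  1.00  0.00           C
ATOM      4  CA  GLY A   2       9.580   6.922  -2.855  1.00  0.00           C
ATOM      5  CA  LYS A   3       6.887   6.640  -0.345  1.00  0.00           C
ATOM      6  CB  LYS A   3       6.295   7.989  -0.205  1.00  0.00           C
ATOM      7  CA  TRP A   4       4.094   4.516   0.905  1.00  0.00           C
ATOM      8  CA  VAL A   5       1.596   5.741   3.466  1.00  0.00           C
HETATM    9  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  MET A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      2  CA AGLY A   2       9.580   6.922  -2.855  0.50  0.00           C
ATOM      3  CA BGLY A   2       9.000   6.000  -2.000  0.50  0.00           C
ATOM      4  CA  LYS A   3       6.887   6.640  -0.345  1.00  0.00           C
ATOM      5  CA  TRP A   4       4.094   4.516   0.905  1.00  0.00           C
ATOM      6  CA  VAL A   5       1.596   5.741   3.466  1.00  0.00           C
TER
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture
def altloc_pdb_text():
    return ALTLOC_PDB
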