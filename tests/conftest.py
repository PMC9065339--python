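from __future__ import annotations

import numpy as np
import pytest

from drugsite import ContactRule, FixtureSpec, ResidueGraph, ResidueKey, make_complex


def graph_from_adjacency(adj: np.ndarray) -> ResidueGraph:
    """Wrap a bare adjacency matrix in a ResidueGraph with dummy residue keys."""
    adj = np.asarray(adj, dtype=bool)
    keys = [ResidueKey("A", i + 1, "", "GLY") for i in range(adj.shape[0])]
    return ResidueGraph(keys, adj, ContactRule(), "testgraph")


def random_graph(n: int, p: float, rng: np.random.Generator) -> ResidueGraph:
    """Erdős–Rényi G(n, p) as a ResidueGraph."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = adj | adj.T
    return graph_from_adjacency(adj)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def helix_complex(tmp_path):
    """50-residue helix with ligand contacting residues 10–12, plus truth."""
    spec = FixtureSpec(n_residues=50, geometry="helix",
                       ligand_contacts=frozenset({10, 11, 12}), seed=7)
    path, truth = make_complex(spec, tmp_path / "helix50.pdb")
    return spec, path, truth


# hand-written minimal PDB: 3 residues + 1 hetero entity + 1 water
MINI_PDB = """\
HEADER    MINI FIXTURE
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LEU A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    4  C1  DRG A 101       0.000   0.000   6.400  1.00  0.00           C
HETATM    5  O   HOH A 201       0.000   5.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p
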