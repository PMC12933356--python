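"""Shared fixtures: packaged networks and a molecule-graph test set."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from rxnkit.datasets import formose_main
from rxnkit.species_graph import MolecularGraph


def mol_from_spec(elements: str, edges) -> MolecularGraph:
    """Build a molecular graph from an element string and edge list.

    ``elements`` is a whitespace-separated symbol list; ``edges`` index
    pairs into it.
    """
    g = nx.Graph()
    for i, el in enumerate(elements.split()):
        g.add_node(i, element=el)
    g.add_edges_from(edges)
    return MolecularGraph(g)


def aldose_chain(n: int) -> MolecularGraph:
    """Open-chain aldose CnH2nOn: OHC-(CHOH)_{n-2}-CH2OH."""
    g = nx.Graph()
    idx = 0

    def add(el):
        nonlocal idx
        g.add_node(idx, element=el)
        idx += 1
        return idx - 1

    carbons = [add("C") for _ in range(n)]
    for a, b in zip(carbons, carbons[1:]):
        g.add_edge(a, b)
    # C1: aldehyde (C=O as single graph edge, one H)
    o1 = add("O")
    g.add_edge(carbons[0], o1)
    g.add_edge(carbons[0], add("H"))
    # C2..C(n-1): one H, one OH
    for c in carbons[1:-1]:
        g.add_edge(c, add("H"))
        o = add("O")
        g.add_edge(c, o)
        g.add_edge(o, add("H"))
    # Cn: two H, one OH
    cn = carbons[-1]
    g.add_edge(cn, add("H"))
    g.add_edge(cn, add("H"))
    o = add("O")
    g.add_edge(cn, o)
    g.add_edge(o, add("H"))
    return MolecularGraph(g)


def _remove_one_h(mol: MolecularGraph, hydroxyl_index: int) -> MolecularGraph:
    """Deprotonate the ``hydroxyl_index``-th O-H oxygen (skips carbonyls)."""
    g = mol.graph.copy()
    hydroxyls = [
        n
        for n, el in g.nodes(data="element")
        if el == "O" and any(g.nodes[m]["element"] == "H" for m in g[n])
    ]
    o = hydroxyls[hydroxyl_index]
    hs = [m for m in g[o] if g.nodes[m]["element"] == "H"]
    g.remove_node(hs[0])
    return MolecularGraph(nx.convert_node_labels_to_integers(g), charge=-1)


GLYCERALDEHYDE = aldose_chain(3)
DIHYDROXYACETONE = mol_from_spec(
    "C C C O O O H H H H H H",
    # HOCH2-CO-CH2OH: C1(H2)(O-H) - C2(=O) - C3(H2)(O-H)
    [(0, 1), (1, 2), (1, 3), (0, 4), (2, 5),
     (0, 6), (0, 7), (4, 8), (2, 9), (2, 10), (5, 11)],
)


def molecule_test_set() -> dict[str, MolecularGraph]:
    """~15 connected molecular graphs: the C1-C5 cast plus small species."""
    glycolaldehyde = aldose_chain(2)
    ribose_open = aldose_chain(5)
    # beta-furanose ring form of the pentose: C1-C2-C3-C4-O(ring)-C1, C5 exocyclic
    furanose = mol_from_spec(
        "C C C C C O O O O O H H H H H H H H H H",
        [(0, 1), (1, 2), (2, 3), (3, 5), (5, 0),  # ring with O5
         (0, 6), (6, 10), (0, 11),  # C1: OH + H
         (1, 7), (7, 12), (1, 13),  # C2: OH + H
         (2, 8), (8, 14), (2, 15),  # C3: OH + H
         (3, 4), (3, 16),           # C4: H + C5
         (4, 9), (9, 17), (4, 18), (4, 19)],  # C5: H2 + OH
    )
    mols = {
        "H2": mol_from_spec("H H", [(0, 1)]),
        "H2O": mol_from_spec("O H H", [(0, 1), (0, 2)]),
        "OH-": mol_from_spec("O H", [(0, 1)]),
        "formaldehyde": mol_from_spec("C O H H", [(0, 1), (0, 2), (0, 3)]),
        "formyl_anion": mol_from_spec("C O H", [(0, 1), (0, 2)]),
        "glycolaldehyde": glycolaldehyde,
        "glycolaldehyde_alkoxide": _remove_one_h(glycolaldehyde, 0),
        "glyceraldehyde": GLYCERALDEHYDE,
        "glyceraldehyde_alkoxide": _remove_one_h(GLYCERALDEHYDE, 1),
        "glyceraldehyde_2_alkoxide": _remove_one_h(GLYCERALDEHYDE, 0),
        "dihydroxyacetone": DIHYDROXYACETONE,
        "dihydroxyacetone_alkoxide": _remove_one_h(DIHYDROXYACETONE, 0),
        "ribose_open": ribose_open,
        "ribose_furanose": furanose,
        "pentose_alkoxide": _remove_one_h(ribose_open, 3),
        "methanediol": mol_from_spec(
            "C O O H H H H", [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (2, 6)]
        ),
    }
    return mols


@pytest.fixture(scope="session")
def formose():
    return formose_main()


@pytest.fixture(scope="session")
def molecules():
    return molecule_test_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
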