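"""Molecular graphs, canonical species keys, and discovered networks.

Species identity is constitutional: an element-labeled simple graph of
atoms and bonds, with stereochemistry deliberately ignored (diastereomers
collapse to one key) and charge carried as metadata only.  Canonical keys
are produced by iterative neighborhood (color) refinement to a stable
partition, followed by exhaustive individualization of residual symmetric
classes and lexicographically minimal serialization — a small, exact
canonical-labeling scheme adequate for the <= ~30-atom species this
package meets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import groupby

import networkx as nx

__all__ = [
    "MolecularGraph",
    "CanonicalKey",
    "fragments",
    "canonical_key",
    "hill_formula",
    "build_discovered_network",
    "match_to_reference",
]


@dataclass
class MolecularGraph:
    """A connected element-labeled simple graph (one molecule/fragment)."""

    graph: nx.Graph  # nodes carry attribute "element"
    charge: int | None = None

    def __post_init__(self):
        if self.graph.number_of_nodes() == 0:
            raise ValueError("empty molecular graph")
        if any(self.graph.has_edge(n, n) for n in self.graph):
            raise ValueError("self-loops not allowed")

    @property
    def elements(self) -> dict:
        return dict(self.graph.nodes(data="element"))

    def formula(self) -> str:
        return hill_formula(Counter(el for _, el in self.graph.nodes(data="element")))


@dataclass(frozen=True)
class CanonicalKey:
    key: str
    formula: str


def hill_formula(counts: dict) -> str:
    """Hill-order formula: C first, then H, then the rest alphabetically."""
    parts = []
    for el in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
        n = counts.get(el, 0)
        if n:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def fragments(config, bonds) -> list[MolecularGraph]:
    """Connected components of the bond graph as molecular graphs.

    ``config`` needs ``symbols``; ``bonds`` a bond table with index pairs.
    Fragments are ordered by their smallest atom index (deterministic).
    """
    g = nx.Graph()
    for i, sym in enumerate(config.symbols):
        g.add_node(i, element=sym)
    g.add_edges_from(bonds.bonds)
    comps = sorted(nx.connected_components(g), key=min)
    return [MolecularGraph(g.subgraph(c).copy()) for c in comps]


# ---------------------------------------------------------------------------
# canonical labeling


def _refine(g: nx.Graph, colors: dict) -> dict:
    """Iterative neighborhood color refinement to a stable partition."""
    while True:
        sig = {
            n: (colors[n], tuple(sorted(colors[m] for m in g[n]))) for n in g
        }
        palette = {s: i for i, s in enumerate(sorted(set(sig.values())))}
        new = {n: palette[sig[n]] for n in g}
        if new == colors:
            return colors
        colors = new


def _serialize(g: nx.Graph, order: list) -> str:
    pos = {n: i for i, n in enumerate(order)}
    rows = []
    for n in order:
        nbrs = ",".join(str(pos[m]) for m in sorted(g[n], key=pos.__getitem__))
        rows.append(f"{g.nodes[n]['element']}:{nbrs}")
    return "|".join(rows)


def _canonical_serial(g: nx.Graph, colors: dict) -> str:
    cells: dict[int, list] = {}
    for n, c in colors.items():
        cells.setdefault(c, []).append(n)
    ambiguous = [c for c, ns in cells.items() if len(ns) > 1]
    if not ambiguous:
        order = sorted(g, key=colors.__getitem__)
        return _serialize(g, order)
    # individualize each vertex of the smallest ambiguous cell and recurse;
    # the lexicographically smallest serialization is canonical
    cell = min(ambiguous, key=lambda c: (len(cells[c]), c))
    best = None
    for n in cells[cell]:
        branched = dict(colors)
        branched[n] = max(colors.values()) + 1
        s = _canonical_serial(g, _refine(g, branched))
        if best is None or s < best:
            best = s
    return best


def canonical_key(mol: MolecularGraph) -> CanonicalKey:
    """Relabeling-invariant key for a connected molecular graph.

    Isomorphic graphs always map to equal keys; distinct keys certify
    non-isomorphism (the serialization encodes the full adjacency).
    """
    g = mol.graph
    if not nx.is_connected(g):
        raise ValueError("canonical_key requires a connected graph")
    init = {n: el for n, el in g.nodes(data="element")}
    palette = {el: i for i, el in enumerate(sorted(set(init.values())))}
    colors = _refine(g, {n: palette[init[n]] for n in g})
    return CanonicalKey(_canonical_serial(g, colors), mol.formula())


# ---------------------------------------------------------------------------
# discovered networks


def build_discovered_network(events, trajectory=None):
    """Assemble a topology-only reaction network from an event stream.

    Species are the union of canonical keys seen on either side of any
    event; each distinct (reactants, products) pair becomes one step with
    an occurrence count in its provenance metadata.  Free energies are
    absent (None is not representable in the step type, so Ga_fwd = dG = 0
    with provenance "discovered").
    """
    from .netmodel import ElementaryStep, ReactionNetwork, Species

    seen: dict[str, Species] = {}
    merged: dict[tuple, dict] = {}
    for ev in events:
        before = tuple(sorted(ev.species_before))
        after = tuple(sorted(ev.species_after))
        if before == after:
            continue
        key = (before, after)
        merged.setdefault(key, {"count": 0, "hint": ev.reaction_hint})
        merged[key]["count"] += 1
        for k in before + after:
            seen.setdefault(k, Species(label=k, name=k))
    steps = []
    for idx, ((before, after), info) in enumerate(sorted(merged.items()), 1):
        steps.append(
            ElementaryStep(
                id=f"D{idx}",
                reactants=dict(Counter(before)),
                products=dict(Counter(after)),
                Ga_fwd=0.0,
                dG=0.0,
                step_class=(
                    info["hint"]
                    if info["hint"] in ("aldol_retroaldol", "enolization")
                    else "other"
                ),
                provenance="discovered",
            )
        )
    meta = {"kind": "discovered", "counts": {s.id: merged[k]["count"]
            for s, k in zip(steps, sorted(merged))}}
    return ReactionNetwork(sorted(seen.values(), key=lambda s: s.label), steps, meta)


def match_to_reference(discovered, reference, label_map=None) -> dict:
    """Coverage report of a discovered network against a reference.

    Steps are compared as unordered (reactants, products) multiset pairs
    after applying ``label_map`` (reference label -> canonical key); a step
    also matches in reverse orientation.  Unmappable labels are reported,
    not raised.
    """
    label_map = label_map or {}
    unmapped = set()
    disc_labels = {s.label for s in discovered.species}

    def norm(step, check_mapping=False):
        def side(coeffs):
            out = []
            for lab, nu in coeffs.items():
                mapped = label_map.get(lab, lab)
                if check_mapping and mapped not in disc_labels:
                    unmapped.add(lab)
                out += [mapped] * nu
            return tuple(sorted(out))

        return side(step.reactants), side(step.products)

    disc = {}
    for st in discovered.steps:
        r, p = norm(st)
        disc[(r, p)] = st.id
        disc[(p, r)] = st.id
    found, missing = [], []
    ref_keys = set()
    for st in reference.steps:
        r, p = norm(st, check_mapping=True)
        (found if (r, p) in disc else missing).append(st.id)
        ref_keys |= {(r, p), (p, r)}
    novel = sorted(
        {sid for key, sid in disc.items() if key not in ref_keys}
    )
    return {
        "found": found,
        "missing": missing,
        "novel": novel,
        "coverage": len(found) / len(reference.steps) if reference.steps else 1.0,
        "unmapped_labels": sorted(unmapped),
    }
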