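"""Bond perception and monitored bond-class change detection.

A pair (i, j) is bonded when r_ij <= scale * (radius_i + radius_j) with
single-bond covalent radii; each bond belongs to an order-normalized
element-pair class ("C-C", "C-H", ...).  Reaction detection is restricted
to a monitored subset of classes — C-C (aldol/retroaldol), C-H
(enolization), H-H (H2 formation) and O-O by default — so that trivial
proton transfers (H-O) and complexation changes (anything-Ca, C-O) do not
trigger the search schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import Configuration

__all__ = [
    "COVALENT_RADII",
    "BondTable",
    "MonitorPolicy",
    "ReactionEvent",
    "bond_class",
    "perceive_bonds",
    "diff_bonds",
]

#: single-bond covalent radii, Angstrom (Cordero et al. 2008)
COVALENT_RADII = {
    "H": 0.31,
    "He": 0.28,
    "C": 0.76,  # sp3
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Ar": 1.06,
}

DEFAULT_SCALE = 1.2

#: reaction-type hint per monitored bond class
CLASS_HINTS = {
    "C-C": "aldol_retroaldol",
    "C-H": "enolization",
    "H-H": "H2_formation",
    "O-O": "none",
}


def bond_class(sym_i: str, sym_j: str) -> str:
    """Order-normalized element-pair class, e.g. ('H','C') -> 'C-H'."""
    a, b = sorted((sym_i, sym_j))
    return f"{a}-{b}"


@dataclass(frozen=True)
class BondTable:
    """Perceived bonds of one snapshot: unordered index pairs + classes."""

    bonds: frozenset  # of (i, j) tuples with i < j
    class_of: dict  # (i, j) -> class string
    n_atoms: int = -1  # -1 when unknown

    def __post_init__(self):
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond ({i},{j})")

    def classes(self) -> set[str]:
        return set(self.class_of.values())


@dataclass(frozen=True)
class MonitorPolicy:
    """Which bond classes mark a reaction event."""

    monitored: frozenset = frozenset({"C-C", "C-H", "H-H", "O-O"})

    def is_monitored(self, cls: str) -> bool:
        return cls in self.monitored


@dataclass
class ReactionEvent:
    """A detected change in monitored bond classes between two snapshots."""

    step_index: int
    time_fs: float
    formed: list  # of (i, j, class)
    broken: list  # of (i, j, class)
    reaction_hint: str
    species_before: list = field(default_factory=list)  # canonical keys
    species_after: list = field(default_factory=list)

    def __post_init__(self):
        if not self.formed and not self.broken:
            raise ValueError("event with no bond change")
        overlap = {(i, j) for i, j, _ in self.formed} & {
            (i, j) for i, j, _ in self.broken
        }
        if overlap:
            raise ValueError(f"bonds both formed and broken: {overlap}")

    def to_record(self) -> dict:
        return {
            "step_index": self.step_index,
            "time_fs": self.time_fs,
            "formed": [[i, j, c] for i, j, c in self.formed],
            "broken": [[i, j, c] for i, j, c in self.broken],
            "reaction_hint": self.reaction_hint,
            "species_before": self.species_before,
            "species_after": self.species_after,
        }


def perceive_bonds(
    config: Configuration,
    radii: dict | None = None,
    scale: float = DEFAULT_SCALE,
) -> BondTable:
    """Distance-criterion bond perception (deterministic).

    Pair (i, j) is bonded iff r_ij <= scale * (radius_i + radius_j).
    Minimum-image distances are used when the configuration has a cell.
    """
    radii = COVALENT_RADII if radii is None else radii
    try:
        r = np.array([radii[s] for s in config.symbols])
    except KeyError as exc:
        raise KeyError(f"no covalent radius for element {exc}") from None
    pos = config.positions
    d = pos[None, :, :] - pos[:, None, :]
    if config.cell is not None:
        d -= config.cell * np.round(d / config.cell)
    dist = np.sqrt((d * d).sum(axis=-1))
    cutoff = scale * (r[:, None] + r[None, :])
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    bonds = frozenset(zip(ii.tolist(), jj.tolist()))
    class_of = {
        (i, j): bond_class(config.symbols[i], config.symbols[j]) for i, j in bonds
    }
    return BondTable(bonds, class_of, n_atoms=len(config))


def diff_bonds(
    old: BondTable,
    new: BondTable,
    policy: MonitorPolicy = MonitorPolicy(),
    step_index: int = 0,
    time_fs: float = 0.0,
) -> ReactionEvent | None:
    """Monitored-class difference between two bond tables, or ``None``.

    Changes in unmonitored classes (H-O proton transfers, X-Ca complexation,
    C-O) are ignored; if only those changed, no event is produced.
    """
    if old.n_atoms >= 0 and new.n_atoms >= 0 and old.n_atoms != new.n_atoms:
        raise ValueError(
            f"atom-count mismatch: {old.n_atoms} vs {new.n_atoms}"
        )
    formed = [
        (i, j, new.class_of[(i, j)])
        for (i, j) in sorted(new.bonds - old.bonds)
        if policy.is_monitored(new.class_of[(i, j)])
    ]
    broken = [
        (i, j, old.class_of[(i, j)])
        for (i, j) in sorted(old.bonds - new.bonds)
        if policy.is_monitored(old.class_of[(i, j)])
    ]
    if not formed and not broken:
        return None
    changed = {c for _, _, c in formed + broken}
    for cls in ("C-C", "C-H", "H-H", "O-O"):
        if cls in changed:
            hint = CLASS_HINTS[cls]
            break
    else:
        hint = "other"
    return ReactionEvent(step_index, time_fs, formed, broken, hint)
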