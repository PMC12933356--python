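"""Free-energy reaction networks and energetic-span analysis.

A :class:`ReactionNetwork` is a list of :class:`Species` and elementary
steps, each step carrying a forward activation free energy ``Ga_fwd`` and a
reaction free energy ``dG`` (kcal/mol).  Reverse barriers are never stored:
they follow from ``Ga_fwd - dG`` (all steps are kinetically reversible).

The module also implements the barrier-floor adjustment — uniformly raising
very small forward *and* reverse barriers of fast proton transfers to a
minimum value while leaving every reaction free energy (hence every
equilibrium constant) untouched — and the energetic-span (overall-barrier)
analysis of a free-energy profile: the largest difference between a
transition state and the most stable state preceding it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Species",
    "ElementaryStep",
    "ReactionNetwork",
    "FreeEnergyProfile",
    "ValidationError",
    "PathError",
    "STEP_CLASSES",
    "reverse_barrier",
    "apply_barrier_floor",
    "build_profile",
    "energetic_span",
    "span_at",
    "validate_network",
]

GTOL = 1e-9  # absolute tolerance for all free-energy comparisons, kcal/mol

STEP_CLASSES = frozenset(
    {
        "aldol_retroaldol",
        "enolization",
        "hydride_shift",
        "proton_transfer",
        "cyclization",
        "other",
    }
)


class ValidationError(ValueError):
    """A network or step violates a structural invariant."""


class PathError(ValueError):
    """A sequence of steps cannot be chained into a profile."""


@dataclass(frozen=True)
class Species:
    """A labeled chemical entity.

    Parameters
    ----------
    label : str
        Short identifier, unique within a network (e.g. ``"4"``, ``"OH-"``).
    name : str
        Human-readable name.
    composition : mapping
        Element symbol -> atom count (positive integers).
    charge : int
        Elementary charge.
    rel_G : float, optional
        Relative Gibbs free energy on the profile reference scale, kcal/mol.
    tags : frozenset of str
        Free-form markers such as ``"fixed"`` or ``"monitored"``.
    """

    label: str
    name: str = ""
    composition: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0
    rel_G: float | None = None
    tags: frozenset = frozenset()

    def __post_init__(self):
        for el, n in self.composition.items():
            if not (isinstance(n, int) and n > 0):
                raise ValidationError(
                    f"species {self.label!r}: count of {el} must be a "
                    f"positive integer, got {n!r}"
                )
        if not isinstance(self.charge, int):
            raise ValidationError(f"species {self.label!r}: charge must be int")

    @property
    def n_carbon(self) -> int:
        return self.composition.get("C", 0)


@dataclass(frozen=True)
class ElementaryStep:
    """A reversible elementary step with mass-action stoichiometry.

    ``Ga_fwd`` is the forward activation free energy and ``dG`` the reaction
    free energy, both kcal/mol on the same thermochemical footing.  The
    transition state may not lie below either endpoint:
    ``Ga_fwd >= max(0, dG) - 1e-9``.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    Ga_fwd: float
    dG: float
    step_class: str = "other"
    #: "text" | "supplementary", or a {"Ga_fwd": ..., "dG": ...} mapping when
    #: the two values have different provenance
    provenance: str | Mapping[str, str] = "text"

    def provenance_of(self, field_name: str) -> str:
        if isinstance(self.provenance, str):
            return self.provenance
        return self.provenance.get(field_name, "text")

    def __post_init__(self):
        if self.step_class not in STEP_CLASSES:
            raise ValidationError(
                f"step {self.id!r}: unknown step_class {self.step_class!r}"
            )
        for side, coeffs in (("reactants", self.reactants), ("products", self.products)):
            if not coeffs:
                raise ValidationError(f"step {self.id!r}: empty {side}")
            for lab, nu in coeffs.items():
                if not (isinstance(nu, int) and nu >= 1):
                    raise ValidationError(
                        f"step {self.id!r}: coefficient of {lab!r} must be "
                        f"an integer >= 1, got {nu!r}"
                    )
        # Ga < max(0, dG) (TS below an endpoint) is reported by
        # validate_network rather than rejected here: raw-transcribed fast
        # proton transfers may carry tiny barriers below their dG until the
        # barrier floor lifts them.
        if self.Ga_fwd < -GTOL:
            raise ValidationError(
                f"step {self.id!r}: negative Ga_fwd={self.Ga_fwd}"
            )


@dataclass
class ReactionNetwork:
    """Species plus elementary steps, with run metadata."""

    species: list[Species]
    steps: list[ElementaryStep]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [s.label for s in self.species]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate species labels")
        ids = [s.id for s in self.steps]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate step ids")
        self._by_label = {s.label: s for s in self.species}
        self._by_id = {s.id: s for s in self.steps}

    def species_by_label(self, label: str) -> Species:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown species label {label!r}") from None

    def step_by_id(self, step_id: str) -> ElementaryStep:
        try:
            return self._by_id[step_id]
        except KeyError:
            raise KeyError(f"unknown step id {step_id!r}") from None

    @property
    def species_labels(self) -> list[str]:
        return [s.label for s in self.species]

    @property
    def step_ids(self) -> list[str]:
        return [s.id for s in self.steps]


@dataclass
class FreeEnergyProfile:
    """Alternating state/TS free-energy ladder.

    ``entries`` is an ordered list of ``(kind, label, G)`` with ``kind`` in
    ``{"state", "ts"}``; it begins with a state at G = 0 and strictly
    alternates.  Every TS must lie at or above both adjacent states.
    """

    entries: list[tuple[str, str, float]]

    def __post_init__(self):
        e = self.entries
        if not e or e[0][0] != "state" or abs(e[0][2]) > GTOL:
            raise ValidationError("profile must start with a state at G = 0")
        for i, (kind, _, _) in enumerate(e):
            want = "state" if i % 2 == 0 else "ts"
            if kind != want:
                raise ValidationError("profile must alternate state/ts")
        for i in range(1, len(e) - 1, 2):
            g_ts = e[i][2]
            if g_ts < max(e[i - 1][2], e[i + 1][2]) - GTOL:
                raise ValidationError(
                    f"TS {e[i][1]!r} lies below an adjacent state"
                )

    @property
    def states(self) -> list[tuple[str, float]]:
        return [(lab, g) for kind, lab, g in self.entries if kind == "state"]

    @property
    def transition_states(self) -> list[tuple[str, float]]:
        return [(lab, g) for kind, lab, g in self.entries if kind == "ts"]


# ---------------------------------------------------------------------------
# operations


def reverse_barrier(step: ElementaryStep) -> float:
    """Activation free energy of the reverse reaction, ``Ga_fwd - dG``."""
    return step.Ga_fwd - step.dG


def apply_barrier_floor(
    network: ReactionNetwork,
    floor: float = 5.0,
    which: str = "proton_transfer",
) -> ReactionNetwork:
    """Raise small forward/reverse barriers to at least ``floor`` kcal/mol.

    For every step selected by ``which`` (``"proton_transfer"`` — the
    default, targeting the fast acid/base steps — or ``"all"``), the forward
    barrier becomes ``max(Ga_fwd, floor, floor + dG)``.  This guarantees both
    forward and reverse barriers >= ``floor`` while leaving ``dG`` — and so
    every equilibrium constant — exactly unchanged.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if which not in ("proton_transfer", "all"):
        raise ValueError("which must be 'proton_transfer' or 'all'")
    new_steps = []
    for st in network.steps:
        if which == "all" or st.step_class == "proton_transfer":
            ga = max(st.Ga_fwd, floor, floor + st.dG)
            st = replace(st, Ga_fwd=ga)
        new_steps.append(st)
    meta = dict(network.meta)
    meta["barrier_floor"] = {"floor": floor, "which": which}
    return ReactionNetwork(list(network.species), new_steps, meta)


def build_profile(
    network: ReactionNetwork, step_ids: Sequence[str]
) -> FreeEnergyProfile:
    """Accumulate a free-energy ladder along an ordered list of steps.

    The reference state (G = 0) is the infinitely separated reactants of the
    first step.  State free energies are cumulative sums of ``dG``; each TS
    sits at the preceding state plus that step's ``Ga_fwd``.  Steps must be
    chainable: every step must consume at least one product of its
    predecessor (spectator species are allowed to flow through).
    """
    if not step_ids:
        raise PathError("empty step list")
    steps = [network.step_by_id(sid) for sid in step_ids]
    for prev, nxt in zip(steps, steps[1:]):
        if not (set(prev.products) & set(nxt.reactants)):
            raise PathError(
                f"step {nxt.id!r} consumes no product of {prev.id!r}"
            )
    entries: list[tuple[str, str, float]] = [("state", "reactants", 0.0)]
    g = 0.0
    for st in steps:
        entries.append(("ts", f"TS({st.id})", g + st.Ga_fwd))
        g += st.dG
        entries.append(("state", f"after {st.id}", g))
    return FreeEnergyProfile(entries)


def energetic_span(profile: FreeEnergyProfile) -> tuple[float, str, str]:
    """Overall barrier of a profile (energetic-span analysis).

    Returns ``(span, ts_label, state_label)`` where ``span`` is the maximum
    over transition states j of ``G_TS(j) - min_i<=j G_state(i)`` — the
    effective barrier that controls the rate of the whole multistep segment.
    """
    ts = profile.transition_states
    if not ts:
        raise ValueError("profile contains no transition state")
    best = -math.inf
    best_ts = best_state = ""
    min_g = math.inf
    min_lab = ""
    for kind, lab, g in profile.entries:
        if kind == "state":
            if g < min_g:
                min_g, min_lab = g, lab
        elif g - min_g > best:
            best, best_ts, best_state = g - min_g, lab, min_lab
    return best, best_ts, best_state


def span_at(profile: FreeEnergyProfile, ts_label: str) -> tuple[float, str]:
    """Span of one named TS relative to the most stable preceding state.

    Useful when a specific late transition state (e.g. a retroaldol cleavage)
    is to be measured against the deepest intermediate of the whole pathway
    even though an earlier TS may dominate the global span.
    """
    min_g = math.inf
    min_lab = ""
    for kind, lab, g in profile.entries:
        if kind == "state" and g < min_g:
            min_g, min_lab = g, lab
        elif kind == "ts" and lab == ts_label:
            return g - min_g, min_lab
    raise KeyError(f"no transition state labelled {ts_label!r}")


def _element_totals(
    network: ReactionNetwork, coeffs: Mapping[str, int]
) -> tuple[dict[str, int], int]:
    elements: dict[str, int] = {}
    charge = 0
    for lab, nu in coeffs.items():
        sp = network.species_by_label(lab)
        for el, n in sp.composition.items():
            elements[el] = elements.get(el, 0) + nu * n
        charge += nu * sp.charge
    return elements, charge


def validate_network(network: ReactionNetwork) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    report: list[str] = []
    known = set(network.species_labels)
    for st in network.steps:
        missing = (set(st.reactants) | set(st.products)) - known
        if missing:
            report.append(f"{st.id}: dangling species label(s) {sorted(missing)}")
            continue
        r_el, r_q = _element_totals(network, st.reactants)
        p_el, p_q = _element_totals(network, st.products)
        if r_el != p_el:
            report.append(
                f"{st.id}: element imbalance {r_el} -> {p_el}"
            )
        if r_q != p_q:
            report.append(f"{st.id}: charge imbalance {r_q} -> {p_q}")
        if st.Ga_fwd < max(0.0, st.dG) - GTOL:
            report.append(f"{st.id}: Ga_fwd below endpoint (dG={st.dG})")
    return report
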