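"""The reaction-search driver: biased MD with bond-change monitoring.

Each search cycle: the bias depth ramps up linearly, steering the selected
fragments toward a reactive-proximity target; every frame the bonds are
re-perceived and diffed against the cycle's reference bonding in the
monitored classes only.  A change that persists for ``n_persist``
consecutive frames (hysteresis against thermal flicker) fires a
:class:`ReactionEvent`, flips the schedule to release at twice speed, and
once the depth reaches its lower threshold the reference bonding is
refreshed and the next cycle begins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..species_graph import canonical_key, fragments
from .bias import BiasSchedule, _BiasForceField, advance_bias, contact_target
from .bonds import (
    BondTable,
    MonitorPolicy,
    ReactionEvent,
    diff_bonds,
    perceive_bonds,
)
from .calculators import Calculator, SumCalculator
from .md import md_step
from .system import Configuration, maxwell_boltzmann_init

__all__ = ["SearchResult", "run_search"]

N_PERSIST = 5


@dataclass
class SearchResult:
    """Outcome of a reaction search run."""

    trajectory: list  # of Configuration, every `stride` steps
    frame_times: list  # fs
    frame_meta: list  # dicts: energy, bias depth, phase
    events: list  # of ReactionEvent
    final: Configuration


def _event_species(
    config: Configuration, old: BondTable, new: BondTable, event: ReactionEvent
) -> ReactionEvent:
    """Attach canonical species keys of the fragments touched by the event."""
    touched = {i for i, j, _ in event.formed + event.broken} | {
        j for i, j, _ in event.formed + event.broken
    }

    def keys(table):
        out = []
        for frag in fragments(config, table):
            if touched & set(frag.graph.nodes):
                out.append(canonical_key(frag).key)
        return sorted(out)

    event.species_before = keys(old)
    event.species_after = keys(new)
    return event


def run_search(
    config: Configuration,
    calculator: Calculator,
    policy: MonitorPolicy = MonitorPolicy(),
    bias: BiasSchedule | None = None,
    target_groups: tuple[list[int], list[int]] | None = None,
    n_steps: int = 10000,
    dt: float = 0.5,
    thermostat: tuple[float, float] | None = (1500.0, 100.0),
    seed: int | None = None,
    init_T: float | None = None,
    stride: int = 50,
    n_persist: int = N_PERSIST,
    bond_scale: float = 1.2,
) -> SearchResult:
    """Run biased reaction-search MD.

    ``target_groups`` selects the two fragments (atom-index lists) the bias
    pulls together; when omitted, the two largest fragments of the initial
    bonding are used.  ``init_T`` draws Maxwell-Boltzmann velocities before
    the run (seeded); the run itself is deterministic given the seed.
    """
    if init_T is not None:
        config = maxwell_boltzmann_init(config, init_T, seed)
    else:
        config = config.copy()

    ref_bonds = perceive_bonds(config, scale=bond_scale)
    if bias is None:
        bias = BiasSchedule()
    bias = replace(bias, reference=ref_bonds)

    if target_groups is None:
        frags = sorted(
            (frag.graph.nodes for frag in fragments(config, ref_bonds)),
            key=len,
            reverse=True,
        )
        if len(frags) < 2:
            raise ValueError("need at least two fragments to define a bias target")
        target_groups = (sorted(frags[0]), sorted(frags[1]))

    ga, gb = target_groups
    indices = list(ga) + list(gb)
    target = contact_target(config, ga, gb)

    events: list[ReactionEvent] = []
    trajectory = [config.copy()]
    frame_times = [0.0]
    frame_meta = [{"energy": None, "bias_depth": bias.depth, "phase": bias.phase}]

    pending: tuple | None = None  # (signature, count, event)
    forces = None
    for step in range(1, n_steps + 1):
        total = SumCalculator([calculator, _BiasForceField(bias, (indices, target))])
        config, energy, forces = md_step(config, total, dt, thermostat, forces=None)

        bonds = perceive_bonds(config, scale=bond_scale)
        candidate = diff_bonds(
            bias.reference, bonds, policy, step_index=step, time_fs=step * dt
        )
        fire = None
        if candidate is None or bias.phase != "growing":
            pending = None
        else:
            sig = (tuple(candidate.formed), tuple(candidate.broken))
            if pending is not None and pending[0] == sig:
                pending = (sig, pending[1] + 1, candidate)
            else:
                pending = (sig, 1, candidate)
            if pending[1] >= n_persist:
                fire = pending[2]
                pending = None
        if fire is not None:
            fire = _event_species(config, bias.reference, bonds, fire)
            events.append(fire)
        bias = advance_bias(bias, dt, fire, current_bonds=bonds)
        if bias.reference_fresh:
            # new cycle: rebuild the proximity target from the fresh geometry
            target = contact_target(config, ga, gb)

        if step % stride == 0 or step == n_steps:
            trajectory.append(config.copy())
            frame_times.append(step * dt)
            frame_meta.append(
                {"energy": energy, "bias_depth": bias.depth, "phase": bias.phase}
            )
    return SearchResult(trajectory, frame_times, frame_meta, events, config)
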