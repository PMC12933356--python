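"""Deterministic fixtures with closed-form ground truths.

Networks: ``ab`` (A<=>B, equilibrium ratio exp(-dG/RT)), ``abc`` (chain),
``autocat_toy`` (template catalysis A + C -> 2C whose key-step rate grows
superlinearly while food lasts).  Configurations: ``harmonic`` (analytic
period), ``association_md`` (two Morse particles set up to bind under the
bias), ``water_box`` (jittered water lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netmodel import ElementaryStep, ReactionNetwork, Species
from .rtip.system import Configuration

__all__ = ["FixtureSpec", "make_fixture", "FIXTURES"]


@dataclass
class FixtureSpec:
    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _species(label, comp=None, charge=0):
    return Species(label, label, comp or {"C": 1, "H": 2, "O": 1}, charge)


def _ab(params, seed):
    dG = params.get("dG", -1.0)
    Ga = params.get("Ga", 8.0)
    net = ReactionNetwork(
        [_species("A"), _species("B")],
        [ElementaryStep("R1", {"A": 1}, {"B": 1}, Ga, dG, "other")],
        meta={"name": "ab", "equilibrium_ratio_B_over_A": "exp(-dG/RT)"},
    )
    return net


def _abc(params, seed):
    return ReactionNetwork(
        [_species("A"), _species("B"), _species("C")],
        [
            ElementaryStep("R1", {"A": 1}, {"B": 1}, params.get("Ga1", 8.0),
                           params.get("dG1", -1.0), "other"),
            ElementaryStep("R2", {"B": 1}, {"C": 1}, params.get("Ga2", 10.0),
                           params.get("dG2", -2.0), "other"),
        ],
        meta={"name": "abc"},
    )


def _autocat_toy(params, seed):
    # A + C -> 2C: template-catalyzed conversion of food A into catalyst C,
    # plus a slow uncatalyzed background A -> C that seeds the cycle.
    return ReactionNetwork(
        [_species("A"), _species("C")],
        [
            ElementaryStep("Rbg", {"A": 1}, {"C": 1}, params.get("Ga_bg", 22.0),
                           -5.0, "other"),
            ElementaryStep("Rcat", {"A": 1, "C": 1}, {"C": 2},
                           params.get("Ga_cat", 10.0), -5.0, "other"),
        ],
        meta={
            "name": "autocat_toy",
            "notes": "rate(Rcat) = k[A][C] grows superlinearly in t early on",
        },
    )


def _harmonic(params, seed):
    m = params.get("mass", 12.011)
    config = Configuration(
        ["C"], np.array([[params.get("x0", 0.7), 0.0, 0.0]]),
        masses=np.array([m]),
    )
    return config


def _association_md(params, seed):
    # two carbon atoms: their association forms a monitored C-C bond
    r0 = params.get("separation", 4.0)
    config = Configuration(
        ["C", "C"],
        np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
    )
    return config


def _water_box(params, seed):
    n = params.get("n_molecules", 8)
    spacing = params.get("spacing", 3.1)
    jitter = params.get("jitter", 0.05)
    rng = np.random.default_rng(seed)
    geom = np.array(  # gas-phase water, Angstrom
        [[0.0, 0.0, 0.119], [0.0, 0.763, -0.477], [0.0, -0.763, -0.477]]
    )
    side = int(np.ceil(n ** (1 / 3)))
    symbols, positions = [], []
    count = 0
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if count >= n:
                    break
                origin = spacing * np.array([ix, iy, iz])
                offs = geom + origin + jitter * rng.standard_normal((3, 3))
                symbols += ["O", "H", "H"]
                positions += list(offs)
                count += 1
    return Configuration(symbols, np.array(positions))


FIXTURES = {
    "ab": _ab,
    "abc": _abc,
    "autocat_toy": _autocat_toy,
    "harmonic": _harmonic,
    "association_md": _association_md,
    "water_box": _water_box,
}


def make_fixture(spec: FixtureSpec):
    """Build a named fixture (network or configuration), seeded."""
    try:
        builder = FIXTURES[spec.name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {spec.name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder(spec.params, spec.seed)
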