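"""Pluggable energy/force calculators and toy reactive potentials.

A calculator is any object with ``energy_forces(config) -> (E, F)`` where
``E`` is kcal/mol and ``F`` the (N, 3) forces in kcal/mol/Angstrom, with
``F = -dE/dx`` (checked numerically by :func:`check_forces`).  The shipped
:class:`MorseCalculator` is a documented toy: pairwise Morse wells with
element-pair depths that permit bond exchange.  It makes no claim of
chemical accuracy — its purpose is a reactive surface on which the search
engine's behavior can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .bonds import COVALENT_RADII, bond_class
from .system import Configuration

__all__ = [
    "Calculator",
    "MorseCalculator",
    "HarmonicWellCalculator",
    "SumCalculator",
    "check_forces",
]


class Calculator(Protocol):
    def energy_forces(self, config: Configuration) -> tuple[float, np.ndarray]:
        ...


#: default Morse well depths per element-pair class, kcal/mol (toy values)
DEFAULT_DEPTHS = {
    "C-C": 85.0,
    "C-H": 100.0,
    "C-O": 90.0,
    "H-O": 110.0,
    "H-H": 104.0,
    "O-O": 50.0,
    "C-Ca": 15.0,
    "H-Ca": 8.0,
    "O-Ca": 40.0,
    "Ca-Ca": 5.0,
}
DEFAULT_DEPTH = 30.0


@dataclass
class MorseCalculator:
    """Pairwise Morse potential V(r) = De[(1 - e^{-a(r-re)})^2 - 1].

    ``re`` defaults to the sum of covalent radii of the pair; ``a`` controls
    the well stiffness.  ``cutoff`` truncates the interaction (with no
    smoothing — adequate for the toy fixtures this surface serves).
    """

    depths: dict = field(default_factory=dict)  # class -> De, kcal/mol
    a: float = 2.0  # 1/Angstrom
    re_scale: float = 1.0
    cutoff: float = 8.0

    def _params(self, si: str, sj: str) -> tuple[float, float]:
        cls = bond_class(si, sj)
        de = self.depths.get(cls, DEFAULT_DEPTHS.get(cls, DEFAULT_DEPTH))
        re = self.re_scale * (COVALENT_RADII[si] + COVALENT_RADII[sj])
        return de, re

    def energy_forces(self, config: Configuration) -> tuple[float, np.ndarray]:
        pos = config.positions
        n = len(config)
        energy = 0.0
        forces = np.zeros_like(pos)
        for i in range(n - 1):
            for j in range(i + 1, n):
                d = config.displacement(i, j)
                r = float(np.linalg.norm(d))
                if r > self.cutoff or r < 1e-12:
                    continue
                de, re = self._params(config.symbols[i], config.symbols[j])
                ex = np.exp(-self.a * (r - re))
                energy += de * ((1.0 - ex) ** 2 - 1.0)
                # dV/dr = 2 De a ex (1 - ex)
                dvdr = 2.0 * de * self.a * ex * (1.0 - ex)
                f = dvdr * d / r  # force on atom i is +dV/dr * rhat(i->j)...
                # V decreasing in r means attraction: F_i = dV/dr * unit(i->j)
                forces[i] += f
                forces[j] -= f
        return energy, forces


@dataclass
class HarmonicWellCalculator:
    """Independent 3-D harmonic tethers: V = 1/2 k |x - x0|^2 per atom.

    The standard analytic fixture — period 2*pi*sqrt(m/k) per atom — used
    for integrator verification.
    """

    k: float = 100.0  # kcal/mol/A^2
    centers: np.ndarray | None = None

    def energy_forces(self, config: Configuration) -> tuple[float, np.ndarray]:
        x0 = self.centers if self.centers is not None else np.zeros_like(config.positions)
        dx = config.positions - x0
        energy = 0.5 * self.k * float(np.sum(dx * dx))
        return energy, -self.k * dx


@dataclass
class SumCalculator:
    """Sum of component calculators (e.g. physical surface + bias)."""

    parts: list

    def energy_forces(self, config: Configuration) -> tuple[float, np.ndarray]:
        energy = 0.0
        forces = np.zeros_like(config.positions)
        for part in self.parts:
            e, f = part.energy_forces(config)
            energy += e
            forces += f
        return energy, forces


def check_forces(
    calc: Calculator, config: Configuration, h: float = 1e-5
) -> float:
    """Max relative deviation between analytic forces and central differences."""
    _, f = calc.energy_forces(config)
    num = np.zeros_like(f)
    pos = config.positions
    for i in range(len(config)):
        for k in range(3):
            orig = pos[i, k]
            pos[i, k] = orig + h
            ep, _ = calc.energy_forces(config)
            pos[i, k] = orig - h
            em, _ = calc.energy_forces(config)
            pos[i, k] = orig
            num[i, k] = -(ep - em) / (2 * h)
    scale = max(np.abs(f).max(), np.abs(num).max(), 1e-10)
    return float(np.abs(f - num).max() / scale)
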