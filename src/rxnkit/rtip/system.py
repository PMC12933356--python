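"""Atomic configurations and velocity initialization.

Units: positions Angstrom, velocities Angstrom/fs, masses amu, energies
kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..constants import A_FS_SQ_AMU_TO_KCAL, KB_KCAL, KCAL_PER_MOL_A_TO_A_FS2

__all__ = [
    "ATOMIC_MASSES",
    "Configuration",
    "kinetic_temperature",
    "maxwell_boltzmann_init",
]

#: standard atomic weights, amu (CIAAW abridged)
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.0026,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Ar": 39.948,
}


@dataclass
class Configuration:
    """A molecular snapshot: element symbols, Cartesian coordinates,
    velocities and masses, with an optional orthorhombic periodic cell."""

    symbols: list[str]
    positions: np.ndarray  # (N, 3) Angstrom
    velocities: np.ndarray | None = None  # (N, 3) Angstrom/fs
    masses: np.ndarray | None = None  # (N,) amu
    cell: np.ndarray | None = None  # (3,) orthorhombic box lengths, Angstrom

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.symbols)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (n, 3):
                raise ValueError("velocities must have shape (n_atoms, 3)")
        if self.masses is None:
            try:
                self.masses = np.array([ATOMIC_MASSES[s] for s in self.symbols])
            except KeyError as exc:
                raise KeyError(f"no tabulated mass for element {exc}") from None
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses must have shape (n_atoms,)")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.symbols)

    def copy(self) -> "Configuration":
        return Configuration(
            list(self.symbols),
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            None if self.cell is None else self.cell.copy(),
        )

    def displacement(self, i: int, j: int) -> np.ndarray:
        """Vector from atom i to atom j, minimum-image if periodic."""
        d = self.positions[j] - self.positions[i]
        if self.cell is not None:
            d -= self.cell * np.round(d / self.cell)
        return d


def kinetic_temperature(config: Configuration, remove_com_dof: bool = True) -> float:
    """Instantaneous kinetic temperature (K) from equipartition."""
    v = config.velocities
    ke = 0.5 * float(np.sum(config.masses * np.sum(v * v, axis=1)))
    ke *= A_FS_SQ_AMU_TO_KCAL  # kcal/mol
    dof = 3 * len(config) - (3 if remove_com_dof and len(config) > 1 else 0)
    if dof <= 0:
        return 0.0
    return 2.0 * ke / (dof * KB_KCAL)


def maxwell_boltzmann_init(
    config: Configuration, T: float, seed: int | None = None
) -> Configuration:
    """Draw velocities from the Maxwell-Boltzmann distribution at ``T`` (K).

    Center-of-mass momentum is removed afterwards, so the sampled kinetic
    temperature has 3N-3 degrees of freedom.  Reproducible via ``seed``.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    rng = np.random.default_rng(seed)
    out = config.copy()
    if T == 0:
        out.velocities = np.zeros_like(out.velocities)
        return out
    sigma = np.sqrt(KB_KCAL * T * KCAL_PER_MOL_A_TO_A_FS2 / out.masses)
    out.velocities = rng.standard_normal((len(out), 3)) * sigma[:, None]
    p = (out.masses[:, None] * out.velocities).sum(axis=0)
    out.velocities -= p / out.masses.sum()
    return out
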