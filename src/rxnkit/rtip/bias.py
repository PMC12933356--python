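"""Oscillating Gaussian attractive bias on an invariant configurational metric.

The bias energy is

    E_bias = -D * exp(-m^2 / (2 sigma^2)),

where ``m`` is the minimized root-mean-square deviation (RMSD) between the
biased atoms' current coordinates and a *reactive-proximity target*
geometry, minimized over all rigid rotations and translations (Kabsch
superposition).  Because the metric is invariant under global rotation and
translation, so is the bias energy, and its forces carry zero net force and
zero net torque.

The bias depth ``D`` grows linearly in time to steer fragments together;
when a monitored bond change is detected the schedule flips to *shrinking*
at twice the growth rate to release the products; on reaching the lower
threshold the bonding reference is refreshed and growth restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bonds import COVALENT_RADII, BondTable, ReactionEvent
from .system import Configuration

__all__ = [
    "BiasSchedule",
    "kabsch_rmsd",
    "contact_target",
    "bias_energy_forces",
    "advance_bias",
]


@dataclass
class BiasSchedule:
    """State of the oscillating bias.

    ``depth`` (kcal/mol) is the current well depth D; ``width`` the Gaussian
    sigma in metric (Angstrom RMSD) units; ``grow_rate`` kcal/mol per fs.
    ``phase`` is ``"growing"`` or ``"shrinking"`` (release runs at twice
    ``grow_rate``).  ``reference`` is the bonding snapshot that defines the
    current search cycle.
    """

    depth: float = 0.0
    width: float = 0.5
    grow_rate: float = 0.02
    phase: str = "growing"
    d_min: float = 0.5
    d_max: float = 40.0
    reference: BondTable | None = None
    reference_fresh: bool = False  # True on the step the reference updated

    def __post_init__(self):
        if not (0 <= self.d_min < self.d_max):
            raise ValueError("need 0 <= d_min < d_max")
        if not (0 <= self.depth <= self.d_max):
            raise ValueError("depth outside [0, d_max]")
        if self.phase not in ("growing", "shrinking"):
            raise ValueError(f"bad phase {self.phase!r}")


def kabsch_rmsd(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Minimized RMSD between coordinate sets and its gradient wrt ``x``.

    Returns ``(m, dm_dx)`` where ``m`` minimizes over rigid motions of ``y``.
    At the optimum the translation places both centroids at the origin and
    the rotation satisfies the Kabsch stationarity condition, so the
    gradient reduces to the aligned residuals: ``dm/dx_i = r_i / (N m)``
    with ``r_i = x'_i - R y'_i`` (primes: centroid-shifted).  The residuals
    sum to zero (no net force) and their cross products with ``x'`` vanish
    (no net torque).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = yc.T @ xc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T  # maps yc onto xc
    resid = xc - yc @ rot.T
    msd = float(np.sum(resid * resid)) / n
    m = np.sqrt(msd)
    if m < 1e-12:
        return m, np.zeros_like(x)
    return m, resid / (n * m)


def contact_target(
    config: Configuration,
    group_a: list[int],
    group_b: list[int],
    gap_scale: float = 1.0,
) -> np.ndarray:
    """Reactive-proximity target coordinates for two fragments.

    The fragments keep their internal geometry; fragment B is translated
    along the axis joining the closest heavy-atom (non-H) pair so that this
    pair's distance becomes ``gap_scale`` times the sum of its covalent
    radii.  Returns target coordinates for the atoms in
    ``group_a + group_b`` (in that order).
    """
    if not group_a or not group_b:
        raise ValueError("empty fragment selection")
    pos = config.positions

    def heavies(group):
        h = [i for i in group if config.symbols[i] != "H"]
        return h or list(group)

    best = None
    for i in heavies(group_a):
        for j in heavies(group_b):
            r = float(np.linalg.norm(pos[j] - pos[i]))
            if best is None or r < best[0]:
                best = (r, i, j)
    r, i, j = best
    target_r = gap_scale * (
        COVALENT_RADII[config.symbols[i]] + COVALENT_RADII[config.symbols[j]]
    )
    axis = pos[j] - pos[i]
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    shift = (target_r - r) * axis
    out = [pos[k].copy() for k in group_a]
    out += [pos[k] + shift for k in group_b]
    return np.array(out)


def bias_energy_forces(
    config: Configuration,
    bias: BiasSchedule,
    targets: tuple[list[int], np.ndarray],
) -> tuple[float, np.ndarray]:
    """Bias energy (kcal/mol) and forces on all atoms.

    ``targets`` is ``(atom_indices, target_coords)``; only those atoms feel
    the bias.  Energy is ``-D exp(-m^2/(2 sigma^2))`` with ``m`` the
    minimized RMSD between the atoms' current and target coordinates.
    """
    indices, target = targets
    if len(indices) == 0:
        raise ValueError("empty bias selection")
    if bias.depth < 0:
        raise ValueError("negative bias depth")
    forces = np.zeros_like(config.positions)
    if bias.depth == 0.0:
        return 0.0, forces
    x = config.positions[indices]
    m, dm_dx = kabsch_rmsd(x, target)
    gauss = np.exp(-(m * m) / (2.0 * bias.width**2))
    energy = -bias.depth * gauss
    # dE/dm = D * m / sigma^2 * gauss ; F = -dE/dx
    dedm = bias.depth * m / bias.width**2 * gauss
    forces[indices] = -dedm * dm_dx
    return energy, forces


@dataclass
class _BiasForceField:
    """Adapter exposing the bias as a calculator-compatible object."""

    bias: BiasSchedule
    targets: tuple

    def energy_forces(self, config: Configuration):
        return bias_energy_forces(config, self.bias, self.targets)


def advance_bias(
    bias: BiasSchedule,
    dt: float,
    event: ReactionEvent | None = None,
    current_bonds: BondTable | None = None,
) -> BiasSchedule:
    """Advance the bias schedule by ``dt`` fs.

    Growing: D increases by ``grow_rate * dt`` up to ``d_max``.  On an
    ``event`` the phase flips to shrinking, which decreases D at twice the
    growth rate; at or below ``d_min`` the bonding reference is replaced by
    ``current_bonds`` and growth restarts (``reference_fresh`` marks that
    transition for callers tracking search cycles).
    """
    phase, depth, reference = bias.phase, bias.depth, bias.reference
    fresh = False
    if event is not None and phase == "growing":
        phase = "shrinking"
    if phase == "growing":
        depth = min(depth + bias.grow_rate * dt, bias.d_max)
    else:
        depth = depth - 2.0 * bias.grow_rate * dt
        if depth <= bias.d_min:
            depth = bias.d_min
            phase = "growing"
            if current_bonds is not None:
                reference = current_bonds
            fresh = True
    return replace(
        bias, depth=depth, phase=phase, reference=reference, reference_fresh=fresh
    )
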