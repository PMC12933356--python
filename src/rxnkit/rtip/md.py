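"""Velocity-Verlet dynamics with an optional Berendsen thermostat.

Time is femtoseconds.  The Berendsen thermostat rescales velocities each
step by lambda = sqrt(1 + (dt/tau)(T_target/T_inst - 1)); lambda is capped
to [0.8, 1.25] to guard the zero-temperature start and large mismatches.
"""

from __future__ import annotations

import numpy as np

from ..constants import KCAL_PER_MOL_A_TO_A_FS2
from .calculators import Calculator, SumCalculator
from .system import Configuration, kinetic_temperature

__all__ = ["md_step", "run_md"]

_LAMBDA_MIN, _LAMBDA_MAX = 0.8, 1.25


def _accelerations(forces: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return forces / masses[:, None] * KCAL_PER_MOL_A_TO_A_FS2


def md_step(
    config: Configuration,
    calculator: Calculator,
    dt: float,
    thermostat: tuple[float, float] | None = None,
    forces: np.ndarray | None = None,
) -> tuple[Configuration, float, np.ndarray]:
    """One velocity-Verlet step; returns (new config, energy, new forces).

    ``thermostat`` is ``(T_target_K, tau_fs)`` or ``None`` for NVE.
    Passing the previous step's ``forces`` avoids one calculator call.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = config.copy()
    if forces is None:
        _, forces = calculator.energy_forces(out)
    a0 = _accelerations(forces, out.masses)
    out.positions = out.positions + out.velocities * dt + 0.5 * a0 * dt * dt
    energy, new_forces = calculator.energy_forces(out)
    a1 = _accelerations(new_forces, out.masses)
    out.velocities = out.velocities + 0.5 * (a0 + a1) * dt
    if thermostat is not None:
        t_target, tau = thermostat
        t_inst = kinetic_temperature(out)
        if t_inst <= 0:
            lam = _LAMBDA_MAX
        else:
            lam = np.sqrt(
                max(0.0, 1.0 + (dt / tau) * (t_target / t_inst - 1.0))
            )
            lam = min(max(lam, _LAMBDA_MIN), _LAMBDA_MAX)
        out.velocities = out.velocities * lam
    return out, energy, new_forces


def run_md(
    config: Configuration,
    calculator: Calculator,
    n_steps: int,
    dt: float,
    thermostat: tuple[float, float] | None = None,
    stride: int = 1,
):
    """Plain MD driver; returns (final config, times fs, frames, energies).

    ``energies`` are potential energies at the saved frames; kinetic energy
    can be recovered from the frame velocities.
    """
    frames = [config.copy()]
    times = [0.0]
    e0, forces = calculator.energy_forces(config)
    energies = [e0]
    cur = config
    for i in range(1, n_steps + 1):
        cur, e, forces = md_step(cur, calculator, dt, thermostat, forces)
        if i % stride == 0 or i == n_steps:
            frames.append(cur.copy())
            times.append(i * dt)
            energies.append(e)
    return cur, np.array(times), frames, np.array(energies)
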