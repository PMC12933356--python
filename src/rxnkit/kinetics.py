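"""Transition-state-theory microkinetics on free-energy reaction networks.

Rate constants come from the Eyring equation,

    k = (k_B T / h) * exp(-Ga / R T),

with a 1 mol/L standard state, so a bimolecular k carries units
L mol^-1 s^-1 with no extra volume factor.  Reverse rate constants are
always derived from the forward barrier and the reaction free energy,
which enforces detailed balance k_fwd / k_rev = exp(-dG / R T) to machine
precision.

Two integrators are provided: a fixed-step explicit Euler scheme (the
historical choice for this class of model, usable once fast proton
transfers have been floored) and an adaptive stiff BDF solver
(:func:`scipy.integrate.solve_ivp`), which is the recommended production
path.  Selected species (water by default) can be held at constant
concentration; their cumulative exchange with the free pool is tracked so
element/charge bookkeeping still closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import KB_OVER_H, R_KCAL, T_SIM, WATER_CONC
from .netmodel import (
    ElementaryStep,
    ReactionNetwork,
    apply_barrier_floor,
    reverse_barrier,
    validate_network,
)

__all__ = [
    "KineticConfig",
    "SimState",
    "TimeSeries",
    "IntegrationError",
    "eyring_k",
    "step_rates",
    "quasi_equilibrium",
    "integrate",
    "sign_change_time",
    "carbon_pool_series",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class KineticConfig:
    """Run configuration for :func:`integrate`.

    ``T`` is the kinetic temperature (K); the packaged formose runs use
    338.15 K (65 C) with free energies tabulated at 55 C.  ``dt`` is the
    fixed Euler step (s); ``floor`` the barrier-floor value applied before
    integration (set ``floor_which`` to ``"all"`` to floor every step, or
    ``None``/``floor=0`` to skip).  ``fixed_species`` are held constant.
    """

    T: float = T_SIM
    dt: float = 5.0e-12
    t_end: float = 1.0e-9
    floor: float = 5.0
    floor_which: str | None = "proton_transfer"
    std_conc: float = 1.0
    fixed_species: Mapping[str, float] = field(
        default_factory=lambda: {"H2O": WATER_CONC}
    )
    solver: str = "adaptive_stiff"  # or "fixed_explicit"
    rtol: float = 1.0e-8
    atol: float = 1.0e-20
    n_save: int = 400
    seed: int | None = None  # reserved; the model is deterministic

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if any(c < 0 for c in self.fixed_species.values()):
            raise ValueError("fixed concentrations must be >= 0")
        if self.solver not in ("fixed_explicit", "adaptive_stiff"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class SimState:
    """Instantaneous concentrations (mol/L) at time ``t`` (s)."""

    t: float
    conc: dict[str, float]

    def __post_init__(self):
        neg = {k: v for k, v in self.conc.items() if v < 0}
        if neg:
            raise ValueError(f"negative concentrations: {neg}")


@dataclass
class TimeSeries:
    """Trajectory of a kinetic run.

    ``conc`` has shape (n_times, n_species) in mol/L, ``net_rate`` shape
    (n_times, n_steps) in mol L^-1 s^-1 (forward minus reverse).
    ``fixed_exchange`` records the cumulative amount (mol/L) of each fixed
    species injected into (+) or removed from (-) the free pool, closing
    the element/charge books.
    """

    times: np.ndarray
    species: list[str]
    conc: np.ndarray
    step_ids: list[str]
    net_rate: np.ndarray
    fixed_exchange: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.conc.shape != (len(self.times), len(self.species)):
            raise ValueError("conc shape mismatch")
        if self.net_rate.shape != (len(self.times), len(self.step_ids)):
            raise ValueError("net_rate shape mismatch")

    def conc_of(self, label: str) -> np.ndarray:
        return self.conc[:, self.species.index(label)]

    def net_rate_of(self, step_id: str) -> np.ndarray:
        return self.net_rate[:, self.step_ids.index(step_id)]


# ---------------------------------------------------------------------------


def eyring_k(Ga: float, T: float, molecularity: int = 1) -> float:
    """Eyring rate constant for a barrier ``Ga`` (kcal/mol) at ``T`` (K).

    Units are s^-1 for molecularity 1 and L mol^-1 s^-1 for molecularity 2
    under the 1 mol/L standard state.  ``molecularity`` only documents the
    units — the numerical value is (k_B T/h) exp(-Ga/RT) either way.
    """
    if Ga < 0:
        raise ValueError(f"negative activation free energy: {Ga}")
    if T <= 0:
        raise ValueError("T must be > 0")
    del molecularity
    return KB_OVER_H * T * math.exp(-Ga / (R_KCAL * T))


def _rate_constants(
    network: ReactionNetwork, T: float
) -> tuple[np.ndarray, np.ndarray]:
    kf = np.array([eyring_k(s.Ga_fwd, T) for s in network.steps])
    kr = np.array([eyring_k(reverse_barrier(s), T) for s in network.steps])
    return kf, kr


def step_rates(
    network: ReactionNetwork, state: SimState, T: float = T_SIM
) -> dict[str, tuple[float, float, float]]:
    """Mass-action forward/reverse/net rates (mol L^-1 s^-1) per step."""
    kf, kr = _rate_constants(network, T)
    out: dict[str, tuple[float, float, float]] = {}
    for i, st in enumerate(network.steps):
        vf = kf[i]
        for lab, nu in st.reactants.items():
            vf *= state.conc[lab] ** nu
        vr = kr[i]
        for lab, nu in st.products.items():
            vr *= state.conc[lab] ** nu
        out[st.id] = (vf, vr, vf - vr)
    return out


def quasi_equilibrium(
    step: ElementaryStep, known_conc: Mapping[str, float], T: float = T_SIM
) -> float:
    """Concentration of a step's single unknown species at equilibrium.

    Solves K_eq = exp(-dG/RT) = prod[products]/prod[reactants] for the one
    species of the step absent from ``known_conc``.  With an appreciably
    endothermic step this is the quasi-steady concentration of a fleeting
    intermediate (e.g. the formyl anion upstream of formaldehyde coupling).
    """
    labels = set(step.reactants) | set(step.products)
    unknown = [lab for lab in labels if lab not in known_conc]
    if len(unknown) != 1:
        raise ValueError(
            f"need exactly one unknown species, got {unknown or 'none'}"
        )
    (lab,) = unknown
    keq = math.exp(-step.dG / (R_KCAL * T))
    # K = P / R with the unknown factored out
    num = 1.0
    for l, nu in step.products.items():
        if l != lab:
            num *= known_conc[l] ** nu
    den = 1.0
    for l, nu in step.reactants.items():
        if l != lab:
            den *= known_conc[l] ** nu
    if lab in step.products:
        nu = step.products[lab]
        return (keq * den / num) ** (1.0 / nu)
    nu = step.reactants[lab]
    return (num / (keq * den)) ** (1.0 / nu)


# ---------------------------------------------------------------------------
# integration


def _assemble(network: ReactionNetwork, config: KineticConfig):
    """Vectorized mass-action right-hand side and friends."""
    labels = network.species_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n_sp, n_st = len(labels), len(network.steps)
    kf, kr = _rate_constants(network, config.T)

    # stoichiometry matrices: nu_r[i, j] = coeff of species i in reactants of j
    nu_r = np.zeros((n_sp, n_st))
    nu_p = np.zeros((n_sp, n_st))
    for j, st in enumerate(network.steps):
        for lab, nu in st.reactants.items():
            nu_r[index[lab], j] += nu
        for lab, nu in st.products.items():
            nu_p[index[lab], j] += nu
    nu_net = nu_p - nu_r

    fixed_idx = np.array(
        [index[lab] for lab in config.fixed_species if lab in index], dtype=int
    )
    free_mask = np.ones(n_sp, dtype=bool)
    free_mask[fixed_idx] = False

    def rates(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cc = np.clip(c, 0.0, None)
        logc = np.log(np.where(cc > 0, cc, 1.0))
        vf = kf * np.exp(nu_r.T @ logc)
        vr = kr * np.exp(nu_p.T @ logc)
        # a zero concentration kills the product it participates in
        vf = np.where((nu_r.T @ (cc <= 0)) > 0, 0.0, vf)
        vr = np.where((nu_p.T @ (cc <= 0)) > 0, 0.0, vr)
        return vf, vr

    def rhs(c: np.ndarray) -> np.ndarray:
        vf, vr = rates(c)
        dc = nu_net @ (vf - vr)
        dc[fixed_idx] = 0.0
        return dc

    def jac(c: np.ndarray) -> np.ndarray:
        # d v_j / d c_i = nu_{ij} v_j / c_i; entries where a concentration
        # is zero are set to 0 (inexact there, which Newton tolerates)
        cc = np.clip(c, 1e-150, None)
        vf, vr = rates(c)
        with np.errstate(over="ignore", invalid="ignore"):
            dvf = nu_r * (vf[None, :] / cc[:, None])
            dvr = nu_p * (vr[None, :] / cc[:, None])
        dv = np.nan_to_num(dvf - dvr, nan=0.0, posinf=0.0, neginf=0.0)
        J = nu_net @ dv.T
        J[fixed_idx, :] = 0.0
        return J

    return labels, index, nu_net, fixed_idx, free_mask, rates, rhs, jac


def integrate(
    network: ReactionNetwork,
    config: KineticConfig,
    init: SimState,
) -> TimeSeries:
    """Integrate the mass-action ODEs of a validated network.

    The barrier floor in ``config`` is applied before rate evaluation (pass
    ``floor_which=None`` if the network was floored already or should not
    be).  Species listed in ``config.fixed_species`` are pinned; their
    cumulative exchange with the pool is reported in the result.
    """
    report = validate_network(network)
    if report:
        raise ValueError("invalid network: " + "; ".join(report))
    if config.floor_which is not None and config.floor > 0:
        network = apply_barrier_floor(network, config.floor, config.floor_which)

    labels, index, nu_net, fixed_idx, free_mask, rates, rhs, jac = _assemble(
        network, config
    )
    c0 = np.zeros(len(labels))
    for lab, v in init.conc.items():
        c0[index[lab]] = v
    for lab, v in config.fixed_species.items():
        if lab in index:
            c0[index[lab]] = v

    if config.solver == "fixed_explicit":
        times, conc = _integrate_euler(c0, rhs, config)
    else:
        times, conc = _integrate_stiff(c0, rhs, jac, config, t0=init.t)

    vf = np.empty((len(times), nu_net.shape[1]))
    vr = np.empty_like(vf)
    for i in range(len(times)):
        vf[i], vr[i] = rates(conc[i])
    net = vf - vr

    # cumulative exchange with each fixed species: the free pool's gain of a
    # fixed species per unit time is -sum_j nu_net[fixed, j] * v_j
    fixed_exchange = {}
    for fi in fixed_idx:
        flux = -(nu_net[fi] @ net.T)
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (flux[1:] + flux[:-1]) * np.diff(times))]
        )
        fixed_exchange[labels[fi]] = cum

    return TimeSeries(
        times=times,
        species=labels,
        conc=conc,
        step_ids=network.step_ids,
        net_rate=net,
        fixed_exchange=fixed_exchange,
    )


def _integrate_euler(c0, rhs, config: KineticConfig):
    n_steps = max(1, int(round(config.t_end / config.dt)))
    stride = max(1, n_steps // max(1, config.n_save - 1))
    times = [0.0]
    saved = [c0.copy()]
    c = c0.copy()
    undershoot_tol = 1e-15
    for i in range(1, n_steps + 1):
        c = c + config.dt * rhs(c)
        if np.any(c < -undershoot_tol):
            raise IntegrationError(
                f"concentration went negative at step {i} "
                f"(min {c.min():.3e} M); the fixed explicit solver is "
                "unstable here - use solver='adaptive_stiff'"
            )
        np.clip(c, 0.0, None, out=c)
        if i % stride == 0 or i == n_steps:
            times.append(i * config.dt)
            saved.append(c.copy())
    return np.array(times), np.array(saved)


def _integrate_stiff(c0, rhs, jac, config: KineticConfig, t0=0.0):
    t_end = config.t_end
    # log-spaced output after an initial linear ramp resolves both the
    # nanosecond equilibration of the anions and the seconds-scale chemistry
    t_small = max(1e-12, t_end * 1e-12)
    n = config.n_save
    times = np.unique(
        np.concatenate(
            [[0.0], np.geomspace(t_small, t_end, n - 1)]
        )
    )
    sol = solve_ivp(
        lambda t, c: rhs(c),
        (0.0, t_end),
        c0,
        method="BDF",
        jac=lambda t, c: jac(c),
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise IntegrationError(f"stiff solver failed: {sol.message}")
    conc = np.clip(sol.y.T, 0.0, None)
    return sol.t + t0, conc


def sign_change_time(series: TimeSeries, step_id: str) -> float | None:
    """First zero crossing of a step's net rate, linearly interpolated.

    Returns ``None`` if the net rate never changes sign.  Leading samples
    with exactly zero rate (before any reactant exists) are skipped.
    """
    v = series.net_rate_of(step_id)
    t = series.times
    nz = np.nonzero(v)[0]
    if nz.size == 0:
        return None
    i0 = nz[0]
    s = np.sign(v[i0:])
    flips = np.nonzero(np.diff(s) != 0)[0]
    if flips.size == 0:
        return None
    i = i0 + flips[0]
    v1, v2 = v[i], v[i + 1]
    if v2 == v1:
        return float(t[i])
    return float(t[i] - v1 * (t[i + 1] - t[i]) / (v2 - v1))


def carbon_pool_series(
    series: TimeSeries, network: ReactionNetwork, max_carbon: int = 5
) -> dict[str, np.ndarray]:
    """Per-carbon-count pooled concentrations C1..Cn over time.

    Each pool sums the concentrations of all non-fixed species with that
    carbon count; multiplying each pool by its carbon count and summing
    gives the conserved total carbon (fixed species excluded).
    """
    fixed = set(series.fixed_exchange)
    pools = {f"C{k}": np.zeros_like(series.times) for k in range(1, max_carbon + 1)}
    for i, lab in enumerate(series.species):
        if lab in fixed:
            continue
        nc = network.species_by_label(lab).n_carbon
        if 1 <= nc <= max_carbon:
            pools[f"C{nc}"] += series.conc[:, i]
    return pools
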