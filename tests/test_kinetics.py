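"""Eyring rates, mass action, detailed balance, integration, observables."""

import math

import numpy as np
import pytest

from rxnkit.constants import KB_OVER_H, R_KCAL
from rxnkit.datasets import load_packaged
from rxnkit.fixtures import FixtureSpec, make_fixture
from rxnkit.kinetics import (
    IntegrationError,
    KineticConfig,
    SimState,
    TimeSeries,
    carbon_pool_series,
    eyring_k,
    integrate,
    quasi_equilibrium,
    sign_change_time,
    step_rates,
)
from rxnkit.netmodel import ElementaryStep, ReactionNetwork, Species

T = 338.15
RT = R_KCAL * T


class TestEyring:
    def test_zero_barrier_is_attempt_frequency(self):
        assert eyring_k(0.0, T) == pytest.approx(KB_OVER_H * T, rel=1e-12)
        assert eyring_k(0.0, T) == pytest.approx(7.046e12, rel=1e-4)

    def test_bimolecular_value(self):
        # 11.7 kcal/mol at 338.15 K, 1 M standard state
        assert eyring_k(11.7, T, molecularity=2) == pytest.approx(1.93e5, rel=5e-3)

    def test_barrier_ratio_identity(self):
        assert eyring_k(10.0, T) / eyring_k(11.0, T) == pytest.approx(
            math.exp(1.0 / RT), rel=1e-12
        )

    def test_monotone_decreasing(self):
        ks = [eyring_k(g, T) for g in np.linspace(0, 30, 50)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            eyring_k(-1.0, T)


class TestStepRates:
    def test_detailed_balance_at_equilibrium(self, formose):
        """At concentrations satisfying K_eq, every net rate vanishes."""
        st = formose.step_by_id("R1")
        conc = {"1": 0.35, "OH-": 0.06, "H2O": 55.3}
        conc["2"] = quasi_equilibrium(st, conc, T)
        rates = step_rates(formose, SimState(0.0, {**{l: 0.0 for l in formose.species_labels}, **conc}), T)
        vf, vr, vnet = rates["R1"]
        assert vnet == pytest.approx(0.0, abs=vf * 1e-12)

    def test_detailed_balance_constant(self, formose):
        for st in formose.steps:
            kf = eyring_k(st.Ga_fwd, T)
            kr = eyring_k(st.Ga_fwd - st.dG, T)
            assert kf / kr == pytest.approx(math.exp(-st.dG / RT), rel=1e-12)

    def test_hand_mass_action(self):
        # A<=>B with both barriers equal: kf = kr = k; [A]=2, [B]=1 -> vnet = k
        net = make_fixture(FixtureSpec("ab", {"dG": 0.0, "Ga": 8.0}))
        k = eyring_k(8.0, T)
        rates = step_rates(net, SimState(0.0, {"A": 2.0, "B": 1.0}), T)
        vf, vr, vnet = rates["R1"]
        assert (vf, vr, vnet) == pytest.approx((2 * k, k, k), rel=1e-12)

    def test_unknown_species_rejected(self, formose):
        with pytest.raises(KeyError):
            step_rates(formose, SimState(0.0, {"1": 0.1}), T)


class TestQuasiEquilibrium:
    def test_formyl_anion(self, formose):
        c = quasi_equilibrium(
            formose.step_by_id("R1"), {"1": 0.35, "OH-": 0.06, "H2O": 55.3}, T
        )
        assert c == pytest.approx(5.6e-14, rel=0.02)

    def test_symmetric_unit_equilibrium(self):
        st = ElementaryStep("s", {"A": 1}, {"B": 1}, 5.0, 0.0)
        assert quasi_equilibrium(st, {"A": 1.0}, T) == pytest.approx(1.0)

    def test_agrees_with_ode_steady_state(self):
        """The algebraic solution matches integrating the isolated step."""
        net = make_fixture(FixtureSpec("ab", {"dG": -1.7, "Ga": 6.0}))
        cfg = KineticConfig(T=T, t_end=1e-4, floor_which=None, solver="adaptive_stiff")
        series = integrate(net, cfg, SimState(0.0, {"A": 1.0, "B": 0.0}))
        a_end = series.conc_of("A")[-1]
        b_pred = quasi_equilibrium(net.step_by_id("R1"), {"A": a_end}, T)
        assert series.conc_of("B")[-1] == pytest.approx(b_pred, rel=1e-3)

    def test_requires_exactly_one_unknown(self, formose):
        st = formose.step_by_id("R1")
        with pytest.raises(ValueError):
            quasi_equilibrium(st, {"1": 0.35}, T)
        with pytest.raises(ValueError):
            quasi_equilibrium(st, {"1": 1, "OH-": 1, "H2O": 1, "2": 1}, T)


class TestIntegration:
    def test_ab_equilibrium_ratio(self):
        """A<=>B with dG = -1.0 kcal/mol settles at [B]/[A] = exp(1/RT) ~ 4.43,
        independent of the barrier and of flooring."""
        expected = math.exp(1.0 / RT)
        assert expected == pytest.approx(4.43, abs=0.01)
        for ga, floor_which in [(8.0, None), (3.0, "all")]:
            net = make_fixture(FixtureSpec("ab", {"dG": -1.0, "Ga": ga}))
            cfg = KineticConfig(T=T, t_end=1e-3, floor_which=floor_which)
            s = integrate(net, cfg, SimState(0.0, {"A": 1.0, "B": 0.0}))
            ratio = s.conc_of("B")[-1] / s.conc_of("A")[-1]
            assert ratio == pytest.approx(expected, rel=1e-6)

    def test_null_dynamics(self):
        net = make_fixture(FixtureSpec("ab"))
        cfg = KineticConfig(T=T, t_end=1e-6)
        s = integrate(net, cfg, SimState(0.0, {"A": 0.0, "B": 0.0}))
        assert np.all(s.conc == 0.0)
        assert np.all(s.net_rate == 0.0)

    def test_solver_equivalence_abc(self):
        """Fixed explicit Euler at 5e-12 s and the stiff solver agree to
        0.5% at matched times on the A<=>B<=>C fixture."""
        net = make_fixture(FixtureSpec("abc"))
        t_end = 2e-7
        init = SimState(0.0, {"A": 1.0, "B": 0.0, "C": 0.0})
        fixed = integrate(
            net,
            KineticConfig(T=T, dt=5e-12, t_end=t_end, solver="fixed_explicit",
                          floor_which=None, n_save=40),
            init,
        )
        stiff = integrate(
            net,
            KineticConfig(T=T, t_end=t_end, solver="adaptive_stiff",
                          floor_which=None, rtol=1e-10, atol=1e-16),
            init,
        )
        for lab in "ABC":
            interp = np.interp(fixed.times, stiff.times, stiff.conc_of(lab))
            mask = interp > 1e-12
            rel = np.abs(fixed.conc_of(lab)[mask] - interp[mask]) / interp[mask]
            assert rel.max() < 5e-3

    def test_euler_conservation_long_run(self):
        """Element totals drift < 1e-9 relative over 1e6 fixed steps."""
        net = make_fixture(FixtureSpec("abc"))
        cfg = KineticConfig(T=T, dt=5e-12, t_end=5e-6, solver="fixed_explicit",
                            floor_which=None, n_save=100)
        s = integrate(net, cfg, SimState(0.0, {"A": 0.7, "B": 0.2, "C": 0.1}))
        total = s.conc.sum(axis=1)  # every species is one carbon here
        assert np.abs(total - total[0]).max() / total[0] < 1e-9

    def test_autocatalysis_superlinear_growth(self):
        """The template-catalyzed step accelerates while food remains."""
        net = make_fixture(FixtureSpec("autocat_toy"))
        cfg = KineticConfig(T=T, t_end=1e-3, floor_which=None)
        s = integrate(net, cfg, SimState(0.0, {"A": 1.0, "C": 1e-6}))
        v = s.net_rate_of("Rcat")
        assert np.all(v[5:20] > 0)
        assert v.max() / v[5] > 10  # accelerates by an order of magnitude

    def test_conservation_formose(self, formose):
        """Carbon is conserved exactly; H/O close once the fixed-water
        exchange ledger is included."""
        cfg = KineticConfig(T=T, t_end=0.5, floor=5.0, floor_which="all",
                            n_save=200)
        init = SimState(0.0, {"1": 0.35, "4": 0.05, "OH-": 0.06})
        s = integrate(formose, cfg, init)
        comp = {sp.label: sp.composition for sp in formose.species}
        for element in ("C", "H", "O"):
            tot = sum(
                comp[lab].get(element, 0) * s.conc[:, i]
                for i, lab in enumerate(s.species)
                if lab != "H2O"
            )
            water = comp["H2O"].get(element, 0) * s.fixed_exchange["H2O"]
            closed = tot - water
            drift = np.abs(closed - closed[0]).max() / abs(closed[0])
            # the exchange ledger is a trapezoid quadrature of the sampled
            # flux, so closure is grid-limited rather than solver-limited
            assert drift < 1e-4, element
        # charge: OH- is free, anions balance it exactly
        q = sum(
            formose.species_by_label(lab).charge * s.conc[:, i]
            for i, lab in enumerate(s.species)
            if lab != "H2O"
        )
        assert np.abs(q - q[0]).max() < 1e-9

    def test_euler_instability_raises(self):
        net = make_fixture(FixtureSpec("ab", {"dG": 0.0, "Ga": 0.0}))
        cfg = KineticConfig(T=T, dt=1e-9, t_end=1e-6, solver="fixed_explicit",
                            floor_which=None)
        with pytest.raises(IntegrationError, match="adaptive"):
            integrate(net, cfg, SimState(0.0, {"A": 1.0, "B": 0.0}))


class TestObservables:
    def test_sign_change_linear(self):
        t = np.linspace(0, 2, 21)
        series = TimeSeries(
            times=t,
            species=["A"],
            conc=np.ones((21, 1)),
            step_ids=["S"],
            net_rate=(t - 1.0).reshape(-1, 1),
        )
        assert sign_change_time(series, "S") == pytest.approx(1.0)

    def test_sign_change_none_for_monotone(self):
        t = np.linspace(0, 2, 21)
        series = TimeSeries(
            times=t, species=["A"], conc=np.ones((21, 1)),
            step_ids=["S"], net_rate=-np.ones((21, 1)),
        )
        assert sign_change_time(series, "S") is None

    def test_carbon_pools_formose(self, formose):
        cfg = KineticConfig(T=T, t_end=1e-3, floor_which="all")
        init = SimState(0.0, {"1": 0.35, "4": 0.05, "OH-": 0.06})
        s = integrate(formose, cfg, init)
        pools = carbon_pool_series(s, formose)
        assert pools["C1"][0] == pytest.approx(0.35, rel=1e-6)
        assert pools["C2"][0] == pytest.approx(0.05, rel=1e-6)
        total = sum(k * pools[f"C{k}"] for k in range(1, 6))
        assert np.abs(total - total[0]).max() / total[0] < 1e-9

    def test_carbon_pools_zero(self, formose):
        s = TimeSeries(
            times=np.array([0.0, 1.0]),
            species=formose.species_labels,
            conc=np.zeros((2, len(formose.species))),
            step_ids=formose.step_ids,
            net_rate=np.zeros((2, len(formose.steps))),
        )
        pools = carbon_pool_series(s, formose)
        assert all(np.all(p == 0) for p in pools.values())
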