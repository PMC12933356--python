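"""Network model: barriers, barrier floor, profiles, span analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnkit.constants import R_KCAL
from rxnkit.netmodel import (
    ElementaryStep,
    FreeEnergyProfile,
    ReactionNetwork,
    Species,
    ValidationError,
    PathError,
    apply_barrier_floor,
    build_profile,
    energetic_span,
    reverse_barrier,
    span_at,
    validate_network,
)


def _step(Ga, dG, step_class="other", id="S"):
    return ElementaryStep(id, {"A": 1}, {"B": 1}, Ga, dG, step_class)


def _net(*steps):
    comp = {"C": 1, "H": 2, "O": 1}
    return ReactionNetwork(
        [Species("A", "A", comp), Species("B", "B", comp)], list(steps)
    )


@pytest.mark.parametrize(
    "ga,dg,expected",
    [(5.0, 0.0, 5.0), (14.8, 3.2, 11.6), (18.5, -10.0, 28.5)],
)
def test_reverse_barrier_arithmetic(ga, dg, expected):
    assert reverse_barrier(_step(ga, dg)) == pytest.approx(expected, abs=1e-9)


def test_ts_below_endpoint_flagged():
    with pytest.raises(ValidationError):
        _step(-0.5, -1.0)  # negative barrier is a hard error
    # TS below the product endpoint is constructible (pre-floor transcripts)
    # but reported by validation
    net = _net(_step(2.0, 3.0))
    assert any("below endpoint" in line for line in validate_network(net))


@pytest.mark.parametrize(
    "ga,dg,expected_ga,expected_rev",
    [
        (2.0, 0.0, 5.0, 5.0),
        (10.0, -2.0, 10.0, 12.0),  # untouched: both already >= floor
        (1.0, 3.0, 8.0, 5.0),
    ],
)
def test_barrier_floor_formula(ga, dg, expected_ga, expected_rev):
    net = _net(_step(ga, dg, "proton_transfer"))
    out = apply_barrier_floor(net, 5.0).steps[0]
    assert out.Ga_fwd == pytest.approx(expected_ga, abs=1e-9)
    assert reverse_barrier(out) == pytest.approx(expected_rev, abs=1e-9)
    assert out.dG == dg


@given(
    ga=st.floats(0.0, 30.0),
    dg=st.floats(-25.0, 25.0),
    floor=st.floats(0.0, 10.0),
)
@settings(max_examples=200, deadline=None)
def test_barrier_floor_preserves_equilibrium(ga, dg, floor):
    """Flooring raises both barriers to >= floor but never changes K_eq."""
    ga = max(ga, dg, 0.0)
    net = _net(_step(ga, dg, "proton_transfer"))
    out = apply_barrier_floor(net, floor).steps[0]
    assert out.Ga_fwd >= floor - 1e-12
    assert reverse_barrier(out) >= floor - 1e-12
    keq_before = math.exp(-dg / (R_KCAL * 338.15))
    keq_after = math.exp(-out.dG / (R_KCAL * 338.15))
    assert keq_after == keq_before  # dG bitwise unchanged


def test_barrier_floor_scope():
    """Default flooring touches proton transfers only; 'all' touches every step."""
    net = _net(
        _step(1.0, 0.0, "proton_transfer", id="S1"),
        ElementaryStep("S2", {"B": 1}, {"A": 1}, 1.0, 0.0, "enolization"),
    )
    by_default = {s.id: s.Ga_fwd for s in apply_barrier_floor(net, 5.0).steps}
    assert by_default == {"S1": 5.0, "S2": 1.0}
    all_steps = {s.id: s.Ga_fwd for s in apply_barrier_floor(net, 5.0, "all").steps}
    assert all_steps == {"S1": 5.0, "S2": 5.0}


def test_single_step_profile():
    prof = build_profile(_net(_step(7.0, -3.0)), ["S"])
    assert [g for _, _, g in prof.entries] == pytest.approx([0.0, 7.0, -3.0])
    value, ts, state = energetic_span(prof)
    assert value == pytest.approx(7.0)


def test_profile_requires_chainable_steps():
    comp = {"C": 1, "H": 2, "O": 1}
    net = ReactionNetwork(
        [Species(l, l, comp) for l in "ABCD"],
        [
            ElementaryStep("S1", {"A": 1}, {"B": 1}, 5.0, -1.0),
            ElementaryStep("S2", {"C": 1}, {"D": 1}, 5.0, -1.0),
        ],
    )
    with pytest.raises(PathError):
        build_profile(net, ["S1", "S2"])


def test_random_profile_matches_hand_accumulation(rng):
    """Cumulative state/TS heights equal running sums of dG and Ga."""
    comp = {"C": 1, "H": 2, "O": 1}
    labels = [chr(ord("A") + i) for i in range(5)]
    dgs = rng.uniform(-5, 5, 4)
    gas = [max(0.0, dg) + rng.uniform(0.5, 8.0) for dg in dgs]
    steps = [
        ElementaryStep(f"S{i}", {labels[i]: 1}, {labels[i + 1]: 1}, gas[i], dgs[i])
        for i in range(4)
    ]
    net = ReactionNetwork([Species(l, l, comp) for l in labels], steps)
    prof = build_profile(net, [s.id for s in steps])
    g = 0.0
    expected = [0.0]
    for ga, dg in zip(gas, dgs):
        expected += [g + ga, g + dg]
        g += dg
    assert [e[2] for e in prof.entries] == pytest.approx(expected)


def _random_profile(rng) -> FreeEnergyProfile:
    n_steps = rng.integers(1, 6)
    entries = [("state", "s0", 0.0)]
    g = 0.0
    for i in range(n_steps):
        dg = rng.uniform(-8, 8)
        ga = max(0.0, dg) + rng.uniform(0.0, 10.0)
        entries.append(("ts", f"t{i}", g + ga))
        g += dg
        entries.append(("state", f"s{i+1}", g))
    return FreeEnergyProfile(entries)


def test_span_matches_bruteforce_oracle(rng):
    """max-over-TS of (G_TS - min preceding G) against an O(n^2) double loop."""
    for _ in range(1000):
        prof = _random_profile(rng)
        states = prof.states
        best = -np.inf
        # brute force: all (state i, ts j) pairs with i at or before j
        for j, (_, g_ts) in enumerate(prof.transition_states):
            for i in range(j + 1):
                best = max(best, g_ts - states[i][1])
        value, _, _ = energetic_span(prof)
        assert value == pytest.approx(best, abs=1e-9)


def test_span_depends_only_on_energy_differences(rng):
    """Adding a constant to every profile entry cannot change the span: the
    span computed from consecutive differences alone must agree."""
    for _ in range(50):
        prof = _random_profile(rng)
        value, _, _ = energetic_span(prof)
        diffs = [
            g2 - g1
            for (_, _, g1), (_, _, g2) in zip(prof.entries, prof.entries[1:])
        ]
        assert value == pytest.approx(_span_from_diffs(diffs), abs=1e-9)


def _span_from_diffs(diffs):
    g = 0.0
    heights = [0.0]
    for d in diffs:
        g += d
        heights.append(g)
    best = -np.inf
    min_state = heights[0]
    for i in range(1, len(heights), 2):
        min_state = min(min_state, heights[i - 1])
        best = max(best, heights[i] - min_state)
    return best


def test_reverse_step_involution():
    """Reversing a step twice reproduces the forward (Ga, dG) pair."""
    st_ = _step(14.8, 3.2)
    rev = ElementaryStep("rev", st_.products, st_.reactants,
                         reverse_barrier(st_), -st_.dG)
    assert reverse_barrier(rev) == pytest.approx(st_.Ga_fwd)
    assert -rev.dG == pytest.approx(st_.dG)


# --- validation -----------------------------------------------------------


def test_packaged_formose_validates_clean(formose):
    assert validate_network(formose) == []


def test_element_imbalance_reported():
    comp = {"C": 1, "H": 2, "O": 1}
    net = ReactionNetwork(
        [Species("CH2O", "formaldehyde", comp)],
        [ElementaryStep("bad", {"CH2O": 1}, {"CH2O": 2}, 5.0, 0.0)],
    )
    report = validate_network(net)
    assert len(report) == 1 and "element imbalance" in report[0] and "bad" in report[0]


def test_charge_imbalance_reported():
    net = ReactionNetwork(
        [
            Species("X-", "anion", {"O": 1, "H": 1}, charge=-1),
            Species("X", "neutral", {"O": 1, "H": 1}, charge=0),
        ],
        [ElementaryStep("q", {"X-": 1}, {"X": 1}, 5.0, 0.0)],
    )
    report = validate_network(net)
    assert any("charge imbalance" in line and "q" in line for line in report)


def test_dangling_label_reported():
    net = ReactionNetwork(
        [Species("A", "A", {"C": 1})],
        [ElementaryStep("d", {"A": 1}, {"GHOST": 1}, 5.0, 0.0)],
    )
    assert any("dangling" in line for line in validate_network(net))


def test_retroaldol_span_reference_states(formose):
    """The late retroaldol TS measured against each pathway's deepest
    intermediate separates the enolization and hydride-shift routes."""
    enol = ["R4", "R5", "R6", "R11", "R12", "R13", "R18", "R19",
            "R20", "R21", "R22", "R23", "R27", "R28"]
    hyd = ["R4", "R5", "R6", "R14", "R15", "R16", "R17", "R18", "R19",
           "R24", "R25", "R26", "R27", "R28"]
    span_e, state_e = span_at(build_profile(formose, enol), "TS(R28)")
    span_h, state_h = span_at(build_profile(formose, hyd), "TS(R28)")
    assert span_e == pytest.approx(18.0, abs=1e-9)
    assert span_h == pytest.approx(22.2, abs=1e-9)
    assert state_e == "after R22" and state_h == "after R25"
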