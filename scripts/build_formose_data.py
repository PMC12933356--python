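"""Generate src/rxnkit/data/*.json packaged networks."""
import sys

sys.path.insert(0, "src")  # allow running before installation

from rxnkit.netmodel import ElementaryStep, ReactionNetwork, Species, validate_network
from rxnkit.io import save_network

T = "text"
S = "supplementary"


def sp(label, name, c, h, o, charge, rel_G=None, tags=()):
    comp = {}
    if c:
        comp["C"] = c
    if h:
        comp["H"] = h
    if o:
        comp["O"] = o
    return Species(label, name, comp, charge, rel_G, frozenset(tags))


# relative free energies on the cumulative profile scale (n CH2O + catalyst
# pool at G = 0); used for documentation / profile cross-checks only.
SPECIES = [
    sp("1", "formaldehyde", 1, 2, 1, 0, 0.0),
    sp("2", "formyl anion", 1, 1, 1, -1, 15.2, ("monitored",)),
    sp("3", "glycolaldehyde alkoxide anion", 2, 3, 2, -1, -12.8),
    sp("4", "glycolaldehyde", 2, 4, 2, 0, -19.7),
    sp("5", "glycolaldehyde enolate anion", 2, 3, 2, -1, -14.2),
    sp("6", "glyceraldehyde alkoxide anion", 3, 5, 3, -1, -24.2),
    sp("7", "glyceraldehyde", 3, 6, 3, 0, -29.5),
    sp("8", "linear pentose alkoxide anion", 5, 9, 5, -1, -48.0),
    sp("9", "pentose alkoxide anion", 5, 9, 5, -1, -49.0),
    sp("10", "furanose alkoxide anion", 5, 9, 5, -1, -51.0),
    sp("11", "ribose", 5, 10, 5, 0, -48.3),
    sp("12", "glyceraldehyde enolate anion", 3, 5, 3, -1, -26.5),
    sp("13", "enol dehydroglycerol", 3, 6, 3, 0, -18.5),
    sp("14", "dihydroxyacetone enolate anion", 3, 5, 3, -1, -26.3),
    sp("15", "glyceraldehyde alkoxide anion (O-1)", 3, 5, 3, -1, -27.5),
    sp("16", "dihydroxyacetone alkoxide anion", 3, 5, 3, -1, -45.0),
    sp("17", "dihydroxyacetone", 3, 6, 3, 0, -28.3),
    sp("18", "ketotetrose alkoxide anion", 4, 7, 4, -1, -34.3),
    sp("19", "ketotetrose", 4, 8, 4, 0, -37.6),
    sp("20", "ketotetrose enolate anion", 4, 7, 4, -1, -33.6),
    sp("21", "tetrose enediol", 4, 8, 4, 0, -31.6),
    sp("22", "aldotetrose enolate anion", 4, 7, 4, -1, -44.0),
    sp("23", "aldotetrose", 4, 8, 4, 0, -41.0),
    sp("24", "ketotetrose alkoxide anion (O-2)", 4, 7, 4, -1, -38.1),
    sp("25", "aldotetrose alkoxide anion (O-1)", 4, 7, 4, -1, -48.2),
    sp("26", "aldotetrose alkoxide anion", 4, 7, 4, -1, -38.0, ("monitored",)),
    sp("H2O", "water", 0, 2, 1, 0, tags=("fixed",)),
    sp("OH-", "hydroxide", 0, 1, 1, -1),
]

# id, reactants, products, class, Ga_fwd, dG, Ga_prov, dG_prov
STEPS = [
    ("R1", {"1": 1, "OH-": 1}, {"2": 1, "H2O": 1}, "proton_transfer", 15.4, 15.2, S, T),
    ("R2", {"2": 1, "1": 1}, {"3": 1}, "aldol_retroaldol", 11.7, -28.0, T, S),
    ("R3", {"3": 1, "H2O": 1}, {"4": 1, "OH-": 1}, "proton_transfer", 1.0, -6.9, S, S),
    ("R4", {"4": 1, "OH-": 1}, {"5": 1, "H2O": 1}, "enolization", 18.5, 5.5, T, S),
    ("R5", {"5": 1, "1": 1}, {"6": 1}, "aldol_retroaldol", 10.0, -10.0, S, T),
    ("R6", {"6": 1, "H2O": 1}, {"7": 1, "OH-": 1}, "proton_transfer", 1.0, -5.3, S, S),
    ("R7", {"5": 1, "7": 1}, {"8": 1}, "aldol_retroaldol", 15.4, -4.3, T, S),
    ("R8", {"8": 1}, {"9": 1}, "proton_transfer", 3.0, -1.0, S, S),
    ("R9", {"9": 1}, {"10": 1}, "cyclization", 8.0, -2.0, S, S),
    ("R10", {"10": 1, "H2O": 1}, {"11": 1, "OH-": 1}, "proton_transfer", 3.5, 2.7, S, S),
    ("R11", {"7": 1, "OH-": 1}, {"12": 1, "H2O": 1}, "enolization", 12.0, 3.0, S, S),
    ("R12", {"12": 1, "H2O": 1}, {"13": 1, "OH-": 1}, "proton_transfer", 9.6, 8.0, S, T),
    ("R13", {"13": 1, "OH-": 1}, {"14": 1, "H2O": 1}, "proton_transfer", 1.0, -7.8, S, S),
    ("R14", {"7": 1, "OH-": 1}, {"15": 1, "H2O": 1}, "proton_transfer", 3.0, 2.0, S, S),
    ("R15", {"15": 1}, {"16": 1}, "hydride_shift", 14.8, -17.5, T, S),
    ("R16", {"16": 1, "H2O": 1}, {"17": 1, "OH-": 1}, "proton_transfer", 16.8, 16.7, S, S),
    ("R17", {"17": 1, "OH-": 1}, {"14": 1, "H2O": 1}, "enolization", 3.9, 2.0, S, S),
    ("R18", {"14": 1, "1": 1}, {"18": 1}, "aldol_retroaldol", 12.0, -8.0, S, S),
    ("R19", {"18": 1, "H2O": 1}, {"19": 1, "OH-": 1}, "proton_transfer", 1.0, -3.3, S, S),
    ("R20", {"19": 1, "OH-": 1}, {"20": 1, "H2O": 1}, "enolization", 6.0, 4.0, S, S),
    ("R21", {"20": 1, "H2O": 1}, {"21": 1, "OH-": 1}, "proton_transfer", 9.9, 2.0, S, S),
    ("R22", {"21": 1, "OH-": 1}, {"22": 1, "H2O": 1}, "proton_transfer", 2.0, -12.4, S, S),
    ("R23", {"22": 1, "H2O": 1}, {"23": 1, "OH-": 1}, "proton_transfer", 4.0, 3.0, S, S),
    ("R24", {"19": 1, "OH-": 1}, {"24": 1, "H2O": 1}, "proton_transfer", 3.0, -0.5, S, S),
    ("R25", {"24": 1}, {"25": 1}, "hydride_shift", 14.8, -10.1, T, S),
    ("R26", {"25": 1, "H2O": 1}, {"23": 1, "OH-": 1}, "proton_transfer", 7.5, 7.2, S, S),
    ("R27", {"23": 1, "OH-": 1}, {"26": 1, "H2O": 1}, "proton_transfer", 4.0, 3.0, S, S),
    ("R28", {"26": 1}, {"4": 1, "5": 1}, "aldol_retroaldol", 12.0, 4.1, S, S),
]

steps = [
    ElementaryStep(i, r, p, Ga, dG, cls, {"Ga_fwd": gp, "dG": dp})
    for i, r, p, cls, Ga, dG, gp, dp in STEPS
]
net = ReactionNetwork(
    SPECIES,
    steps,
    meta={
        "name": "formose_main",
        "thermochemistry_T_K": 328.15,
        "kinetics_T_K": 338.15,
        "notes": (
            "Formose reaction network: formaldehyde dimerization (R1-R3), "
            "glycolaldehyde-to-glyceraldehyde aldol chemistry (R4-R6), "
            "C3+C2 ribose route (R7-R10), aldose-ketose tautomerization via "
            "enolization and 1,2-hydride shift, and the aldotetrose "
            "retroaldol cleavage closing the autocatalytic cycle (R27-R28). "
            "Values flagged 'supplementary' are transcription estimates "
            "constrained by the text-stated aggregates; see docs/methods.md."
        ),
    },
)
rep = validate_network(net)
assert not rep, rep

# consistency: dG sums against the species ladder
bylab = {s.label: s for s in net.species}
for st in steps:
    lhs = sum(bylab[l].rel_G * n for l, n in st.reactants.items() if bylab[l].rel_G is not None and l not in ("H2O", "OH-"))
    rhs = sum(bylab[l].rel_G * n for l, n in st.products.items() if bylab[l].rel_G is not None and l not in ("H2O", "OH-"))
    # proton-transfer bookkeeping with H2O/OH- is folded into the ladder
    if abs((rhs - lhs) - st.dG) > 1e-9:
        print(f"ladder mismatch {st.id}: {rhs - lhs:+.1f} vs dG {st.dG:+.1f}")

save_network(net, "src/rxnkit/data/formose_main.json")

# --- branched extension R29-R32 (optional data entries) --------------------
branched_species = SPECIES + [
    sp("27", "branched pentose alkoxide anion", 5, 9, 5, -1, -47.0),
    sp("28", "branched pentose", 5, 10, 5, 0, -46.0),
    sp("29", "branched pentose alkoxide anion (retroaldol-ready)", 5, 9, 5, -1, -47.0),
]
branched_steps = steps + [
    ElementaryStep("R29", {"22": 1, "1": 1}, {"27": 1}, 18.8, -3.0,
                   "aldol_retroaldol", {"Ga_fwd": T, "dG": S}),
    ElementaryStep("R30", {"27": 1, "H2O": 1}, {"28": 1, "OH-": 1}, 5.0, 1.0,
                   "proton_transfer", {"Ga_fwd": S, "dG": S}),
    ElementaryStep("R31", {"28": 1, "OH-": 1}, {"29": 1, "H2O": 1}, 5.0, -1.0,
                   "proton_transfer", {"Ga_fwd": S, "dG": S}),
    ElementaryStep("R32", {"29": 1}, {"4": 1, "12": 1}, 13.0, 0.8,
                   "aldol_retroaldol", {"Ga_fwd": S, "dG": S}),
]
bnet = ReactionNetwork(
    branched_species,
    branched_steps,
    meta={"name": "formose_branched",
          "notes": "R29-R32 branched-pentose autocatalytic shortcut."},
)
rep = validate_network(bnet)
assert not rep, rep
save_network(bnet, "src/rxnkit/data/formose_branched.json")

# --- toy networks ----------------------------------------------------------
ab = ReactionNetwork(
    [sp("A", "A", 1, 2, 1, 0), sp("B", "B", 1, 2, 1, 0)],
    [ElementaryStep("R1", {"A": 1}, {"B": 1}, 8.0, -1.0, "other", S)],
    meta={"name": "ab",
          "notes": "A<=>B; equilibrium [B]/[A] = exp(1.0/RT) ~ 4.43 at 338.15 K."},
)
assert not validate_network(ab)
save_network(ab, "src/rxnkit/data/ab.json")

abc = ReactionNetwork(
    [sp("A", "A", 1, 2, 1, 0), sp("B", "B", 1, 2, 1, 0), sp("C", "C", 1, 2, 1, 0)],
    [
        ElementaryStep("R1", {"A": 1}, {"B": 1}, 8.0, -1.0, "other", S),
        ElementaryStep("R2", {"B": 1}, {"C": 1}, 10.0, -2.0, "other", S),
    ],
    meta={"name": "abc", "notes": "A<=>B<=>C chain fixture."},
)
assert not validate_network(abc)
save_network(abc, "src/rxnkit/data/abc.json")

print("ok")
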