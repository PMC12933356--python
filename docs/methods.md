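# Methods

## Scope and model

`rxnkit` couples two computational layers around one chemical object, a
free-energy reaction network:

1. **Microkinetics.** Every elementary step carries a forward activation
   free energy `Ga` and a reaction free energy `dG` (kcal/mol, 1 mol/L
   standard state). Transition-state theory converts barriers to rate
   constants, `k = (k_B T / h) exp(-Ga/RT)`, and mass action turns the
   network into an ODE system for the concentrations. Reverse barriers are
   never independent data: `Ga_rev = Ga - dG`, which makes detailed balance
   (`k_f/k_r = exp(-dG/RT)`) an identity rather than a property to verify
   numerically.
2. **Reaction search.** Classical MD on a pluggable calculator, with an
   attractive Gaussian bias `E = -D exp(-m^2/2sigma^2)` whose metric `m` is
   the Kabsch-minimized RMSD between the biased atoms and a reactive-
   proximity target. The metric is exactly invariant under global rotation
   and translation, so the bias exerts zero net force and zero net torque.
   The depth `D` ramps up linearly; a persistent change in a monitored
   bond class flips the schedule to release at twice the growth rate, and
   at the lower threshold the bonding reference is refreshed and the next
   search cycle begins.

The packaged chemistry is the formose reaction under Ca²⁺/OH⁻ catalysis:
formaldehyde dimerization through the formyl anion (umpolung), aldol
growth of glycolaldehyde to trioses/tetroses/pentoses, aldose–ketose
tautomerization via enolization and via 1,2-hydride shift, ribose
formation by C3+C2 coupling, and the retroaldol cleavage of aldotetrose
that closes the glycolaldehyde autocatalytic cycle. The catalyst pair is
implicit: its effect lives in the free energies, not in the species list.

## Transcription of the free-energy network

`data/formose_main.json` holds 28 species (the numbered intermediates
**1**–**26** plus explicit H₂O and OH⁻) and 28 steps R1–R28. Every value
carries a provenance flag:

* `"text"` — quoted directly in the source narrative (e.g. dG(R1) = +15.2,
  Ga(R2) = 11.7, Ga(R4) = 18.5, Ga(R7) = 15.4, Ga(R15) = Ga(R25) = 14.8,
  dG(R12) = +8.0).
* `"supplementary"` — not individually quoted; estimated **once** so that
  every aggregate the narrative does state is reproduced exactly:
  R1–R3 sum −19.7; dG(R5) = −10.0; profile drop of 4.6 from
  glyceraldehyde to ribose; composed barrier 12.6 = dG(R11) + Ga(R12);
  glyceraldehyde→(dihydroxyacetone enolate) net +3.2; R18+R19 = −11.3;
  ketose→aldose spans 13.9 (enolization) and 14.8 (hydride shift); the
  20.6 span from the dihydroxyacetone alkoxide (**16**) to TS17; neutral
  linear tetroses inside the −37.0…−42.0 window; retroaldol spans 18.0
  (enolization pathway) and 22.2 (hydride pathway) measured from each
  pathway's deepest intermediate.

Those span constraints force two structural conclusions worth recording.
First, the 18.0/22.2 pair shares a single retroaldol TS, so the two
numbers can only differ through the pathway *minima*: the hydride route
must pass through an intermediate 4.2 kcal/mol deeper than the enolization
route's deepest state. The transcription places these minima on the
anionic intermediates (**22** and **25**), consistent with the stated
Ca²⁺ stabilization of alkoxides. Second, the spans are measured from the
global minimum of the whole pathway profile, not of a tetrose
sub-segment; `span_at(profile, ts)` exposes exactly this reading, while
`energetic_span(profile)` keeps the standard max–min definition.

**Known limitation.** The early-time autocatalysis observables cannot be
reproduced from the narrative values alone, independent of the estimated
entries. Every glycolaldehyde-consuming channel in the 28-step topology
passes through enolization R4 (Ga = 18.5), so at the stated initial
conditions the enolate supply — and with it the aldol condensation rate —
is capped at `k4·[4]·[OH⁻] ≈ 2.3e-2 M/s`, and glycolaldehyde depletion at
a timescale `≥ 1/(2 k4 [OH⁻]) ≈ 1.1 s`. The reported early condensation
rate (−4.2e-2 M/s) and rate-sign crossover (0.76 s) lie beyond the cap;
with the packaged network they come out at −1.25e-2 M/s and ≈7.6 s, while
the *late* forward retroaldol rate (≈2.1e-4 M/s at 10–20 s) and the
formyl-anion window (5.70→2.97e-14 M with coupling 3.86→1.93e-9 M/s) land
on the reported values. The corresponding two acceptance tests assert the
reported numbers at face value and fail; they are kept failing rather
than weakened.

## Kinetic conventions

* Temperatures: free energies are tabulated at 328.15 K (55 °C); rates
  and equilibria are evaluated at the run temperature, 338.15 K (65 °C)
  for the packaged conditions. This convention reproduces the printed
  formyl-anion and coupling values; evaluating at 55 °C does not.
* Constants: `R = 1.987204e-3 kcal/mol/K`, `k_B/h = 2.083661e10 s⁻¹K⁻¹`
  (CODATA 2018), so `k(Ga=0, 338.15 K) = 7.046e12 s⁻¹`.
* Standard state 1 mol/L; bimolecular constants are L mol⁻¹ s⁻¹ with no
  volume factor. Water is an explicit species held at 55.3 M by default;
  the cumulative exchange with fixed species is ledgered so element and
  charge books close.
* Barrier floor: `Ga' = max(Ga, floor, floor + dG)` raises both barriers
  of fast steps to ≥ 5.0 kcal/mol while leaving `dG` — and every K_eq —
  bitwise unchanged. The default scope is proton-transfer-class steps;
  the packaged formose run floors **all** steps, because the estimated
  ladder leaves sub-5 reverse barriers in two enolization-class steps
  (R17, R20) that would defeat the purpose of the floor. Span analyses
  always use the unfloored network.
* Integrators: explicit Euler at a fixed 5e-12 s step (historical scheme;
  guarded — a negative excursion beyond 1e-15 M aborts with advice to use
  the stiff path) and the BDF solver of `scipy.integrate.solve_ivp` with
  an analytic Jacobian (`rtol 1e-8`, `atol 1e-20`, log-spaced output),
  which is the production path; the two agree to ≤0.5% on the A⇌B⇌C
  fixture. The packaged 10 s formose run takes under a second of CPU.
* Quantization: free energies are serialized at 0.1 kcal/mol (the data's
  own precision). A 0.1 kcal/mol input shift moves an equilibrium
  concentration by ~16% at 338 K, which is why the quasi-steady formyl
  anion evaluates to 5.70e-14 M against a printed 5.6e-14 M; agreement is
  asserted at 2%.

## Search-engine conventions

* Units: Å, fs, amu, kcal/mol; `1 (kcal/mol/Å)/amu = 4.184e-4 Å/fs²`.
* Bond perception: `r_ij ≤ 1.2 (r_i + r_j)` with Cordero single-bond
  covalent radii. Ten bond classes arise from {C,H,O,Ca}; only C-C, C-H,
  H-H and O-O are monitored by default — H-O (protonation equilibria),
  C-O and all X-Ca changes (complexation) do not trigger the schedule.
* Hysteresis: a monitored change must persist 5 consecutive frames before
  an event fires, suppressing thermal flicker at high temperature.
* The proximity target places the two fragments' closest heavy atoms at
  the sum of their covalent radii, keeping internal geometries rigid; it
  is rebuilt at each cycle start. The metric function is isolated so a
  different invariant metric can be swapped in without touching the
  engine.
* Defaults mirror the production protocol: dt 0.5 fs, 10⁴ steps,
  Berendsen thermostat at 1500 K (λ capped to [0.8, 1.25], which also
  guards a zero-temperature start); growth rate 0.02 kcal/mol/fs, width
  0.5 Å, thresholds D_min 0.5 / D_max 40 kcal/mol are engineering choices
  (the source protocol does not state them).
* The shipped calculator is a pairwise Morse toy (element-pair depths,
  `re` = sum of covalent radii) that permits bond exchange. It is
  documented, not physical: passing fixtures shows the *engine* is
  correct (schedule algebra, invariances, determinism, event bookkeeping),
  not that the toy surface reproduces any real chemistry. Production use
  plugs in a quantum-chemical calculator through the same two-method
  interface.
* Periodic boundaries: optional orthorhombic minimum-image convention
  when a cell is supplied; none by default.

## Species identity

Canonical keys are constitution-only: iterative neighborhood color
refinement, exhaustive individualization of residual symmetric cells, and
lexicographically minimal adjacency serialization. Stereochemistry is
deliberately out of scope (diastereomers collapse), and charges are
metadata because geometry alone cannot assign them — proton-transfer-
ambiguous pairs are surfaced by the coverage report rather than resolved.
Key injectivity is verified in the tests against VF2 isomorphism on a
~16-molecule cast (C1–C5 sugars and fragments); the scheme is exact but
exponential in the worst case, fine at ≤ ~30 atoms.

## Fixture ground truths

* `ab`: A⇌B, `[B]/[A] → exp(-dG/RT)` (≈4.43 at dG = −1, 338.15 K),
  independent of the barrier and of flooring.
* `abc`: chain fixture for solver-equivalence and conservation checks.
* `autocat_toy`: A + C → 2C template catalysis; the catalyzed step's rate
  grows superlinearly while food remains.
* `harmonic`: period `2π√(m/k)`; energy-conservation checks compare
  period-averaged total energy (velocity Verlet has bounded oscillation
  but no secular drift).
* `association_md`: two Morse carbons 4 Å apart; the bias must produce a
  C-C formation event, giving the search/extraction pipeline a known
  one-step answer.
* `water_box`: jittered lattice of rigid-geometry waters for perception,
  initialization and thermostat tests.

## Problem sizes used in the shipped checks

Desk-scale by design: the full formose integration runs to 10 s of model
time (600 saved samples), the Euler conservation check runs 10⁶ fixed
steps on the toy chain, MD checks run 10⁴ steps, and canonicalization is
exercised on ≤20-atom graphs. None of the shipped checks attempt the
cluster-scale 1500 K quantum-forces trajectories of the source protocol;
the engine's correctness surface is the fixture/property suite.
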