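# Methods

## Model

Particles are hard spheres of diameter σ (the length unit) carrying two
attractive surface patches whose body-frame directions subtend 135°, the
interior angle of a regular octagon — eight particles can therefore close
into an unstrained ring in which every patch is bonded.  Pair attraction
follows the Kern–Frenkel form: a square well of depth ε_patch (kJ/mol)
active when the centre distance lies in σ ≤ r < λσ *and* one patch on each
particle points at the partner to within the angular half-width,
cos θ ≥ cos θ_max.  Defaults: λ = 1.1, cos θ_max = 0.95 (half-width ≈ 18°).
These narrow patches enforce one bond per patch: for a patch to reach two
partners simultaneously, the partners would have to sit closer than one
hard-core diameter apart (chord 2·1.1·sin 18° ≈ 0.66 σ < σ), which the core
forbids.  That constraint is what quantizes the order parameter and makes
every bond-graph component a simple chain or ring.

Two specificity rules: the **one-state** system (all particles α, any α–α
patch contact bonds) and the **two-state** system (half α, half β; only α–β
contacts carry energy, so the target ring strictly alternates).  Crowders
are inert hard spheres of the same diameter.

Energies are kJ/mol, temperature in kelvin, kT = R·T = 0.5404 kJ/mol at the
working temperature 65 K.

## Monte Carlo and the nonequilibrium drive

One MC step is one attempted single-particle move: a uniformly random
particle, then with probability ½ a translation uniform in a cube of
half-width 0.3 σ, otherwise a rotation about a uniformly random axis by an
angle uniform in [0, 0.4 rad) (crowders only translate).  Acceptance is

p = min(1, exp(−(ΔE − ε_drive·Δn)/kT)),

where Δn is the change in target-bond count incident to the moved particle
and ΔE the *physical* (undriven) energy change; hard-core overlaps are
rejected outright.  The drive enters the acceptance ratio only — the stored
energy remains the Kern–Frenkel energy — so bond formation is rewarded and
bond breaking penalized relative to detailed balance: a dissipative ratchet.
Each accepted move with Δn ≠ 0 contributes ε_drive·|Δn|/kT (k_B units) to
the housekeeping entropy production S; exchanged-heat entropy is excluded,
so S ≡ 0 at ε_drive = 0 and S is non-decreasing by construction.  The engine
keeps the bond count incrementally (ΔE is ±ε_patch·Δn exactly for a square
well) and cross-checks against a full recompute every 2×10⁶ steps and at the
end of every run; any mismatch aborts the run.

**Move sizes and box.**  The dilute 8-particle system assembles through
chain growth followed by chain–chain merging and ring closure, and clusters
move only through single-particle wiggles.  With very small moves or a very
dilute box the merging stage exceeds any practical step budget (in probes at
0.15 σ / 0.2 rad in a 10 σ box, all replicates were still unassembled at
10⁷ steps at every ε_patch).  The defaults — 4.5 σ box, 0.3 σ translations,
0.4 rad rotations — were calibrated once against the *equilibrium* regime
structure: the one-state system then shows the censored regime up to
ε_patch ≈ 7–8 kJ/mol, a fast-assembly window with median T_fas ≈ 4×10⁶
steps, and trap-dominated slowing at high ε_patch, with the two-state system
close behind (median ≈ 3.7×10⁶).  The crowded preset is 8 patchy particles
plus 48 crowders in a 6 σ box; the large preset is 1000 particles at the
8-particle number density (22.5 σ box), where the order parameter is
normalized by N and target detection is not applied.

## Observables

A **virtual bond** is a patch pair satisfying the geometric Kern–Frenkel
criterion under the active bond rule; if a patch has several geometric
partners (only possible for widened patches) the closest centre distance
wins, ties broken by lowest index.  R = (bond count)/8, quantized in
eighths.  The **target detector** requires a single cycle through all 8
particles with every patch slot filled, plus strict α/β alternation in the
two-state system.  **T_fas** is the first step at which the detector fires
starting from a random configuration; **T_stable** is the first step at
which the bond count drops below 8 starting from the ring — a strict
first-break trigger with no grace window.  Runs whose event does not occur
within the budget are censored and reported at the budget; medians enter
censored values at the budget, so a cell with more than half its replicates
censored reports the budget itself.

Because a single bond break ends T_stable, T_stable grows essentially as
exp(ε_patch/kT) from ε_patch = 2 on, with no low-ε plateau; kT ln 2 ≈ 0.37
kJ/mol per doubling means the "median exceeds twice the low-ε plateau"
segmentation places the stability boundary at the first grid point above
the lowest.  A detector with a recovery window would shift that boundary to
higher ε_patch; the strict trigger was kept for its unambiguity.

**Region segmentation.**  For T_fas sweeps, region I is the maximal low-ε
prefix with ≥ 50% censored replicates, region III the maximal high-ε suffix
whose median exceeds the global minimum by ≥ 1.3×, region II the remainder.
For T_stable sweeps, region B starts where the median exceeds twice the
low-ε plateau, the plateau being the median of replicate values pooled over
the two lowest grid points.  The thresholds operationalize boundaries the
reference figures draw by eye.

## Brownian dynamics

The square well has no forces, so the dynamics engine uses a smooth
analogue: a WCA core (strength 5 kJ/mol, cutoff 2^{1/6} σ) plus

E_att = −ε(t) · exp(−(r−σ)²/(2 r_w²)) · A(θ_i) · A(θ_j),
A(θ) = exp(−θ²/(2 a_w²)),

over the best-aligned patch pairing permitted by the bond rule.  Widths
r_w = 0.15 σ and a_w = 0.5 rad were fixed after probing showed that much
narrower patches (0.05/0.3) give a capture volume so small that no replicate
assembles within thousands of picoseconds at any drive amplitude, leaving
the drive response unobservable.  Forces and torques are analytic gradients
(τ = −u × ∂E/∂u for each engaged patch direction u), validated against
central differences to 1e−5 relative.

The drive is a global square-wave modulation of the well depth,
ε(t) = baseline ± amplitude with period 20 ps, floored at zero — purely
time-periodic, not phase-locked to bond events.  Integration is BAOAB
Langevin for translations plus a spherical-top rotational Langevin scheme on
lab-frame angular velocities (isotropic inertia, so no precession term);
units are kJ/mol–ps–amu (kJ/mol / amu = (σ/ps)²) with mass 1, inertia 0.4,
friction 1 ps⁻¹, timestep 0.005 ps.  At these settings a 400 ps equilibrium
run reproduces kT/2 per translational degree of freedom within 3%.  Bond
detection in BD applies the square-well geometric criterion to the
instantaneous configuration without the hard lower distance bound (the soft
core allows slight interpenetration), checked every 0.25 ps; T_fas is
therefore resolved to the detection interval.  The BD entropy series is
reported as zero: the housekeeping-entropy ledger is defined for the MC
acceptance bias, and no analogous per-event ledger is defined for the
time-periodic Hamiltonian.

## Test and acceptance conditions

The suite uses scaled study conditions chosen once: the two-particle
Boltzmann check samples a 2.5 σ box at ε_patch = 4 (bonded probability
≈ 0.33 in closed form, since the two patch cones are disjoint and
P(aligned) = (1 − cos θ_max) per particle) against 2.5×10⁶ MC steps with
blocked standard errors; drive-response monotonicity uses ε_patch = 3 with
drives {0, 5, 10} (10 replicates, 10⁷-step budget for T_fas, 3×10⁵ for
T_stable); the BD amplitude sweep uses a 3.5 σ box, amplitudes {0, 4, 10},
6 replicates, 6000 ps.  The acceptance script sweeps ε_patch 2–14 (5
replicates, 10⁶ steps) for the stability boundary and ε_drive 0–10 (5
replicates, 10⁷ steps) for the drive thresholds at ε_patch = 3.

What the synthetic conditions do *not* probe: hydrodynamics, solvent
granularity, polydispersity, patch-geometry disorder, and any mapping of MC
steps or reduced BD time to laboratory time.  Passing tests show the
engines sample and integrate their models correctly and reproduce the
qualitative regime structure, not that a specific laboratory system behaves
identically.

## Known limitations

- T_stable's strict first-break trigger places the stability takeoff near
  the bottom of the ε_patch grid (see above); quantities defined through it
  are systematically smaller than counterparts measured with grace windows.
- The MC drive threshold at ε_patch = 3 lands near 4–5 kJ/mol here; the
  ratchet is more efficient, relative to the equilibrium assembly boundary,
  than in the reference lattice-derived protocol.
- Kinetic traps (5-, 6- and 7-rings are geometrically bondable within the
  18° half-width) make T_fas non-monotone in ε_drive at large
  ε_patch + ε_drive; monotonicity is asserted only in the weak-interaction
  regime where the reference reports it.
- One MC "step" is one attempted move; absolute step counts are comparable
  between runs of this package only.
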