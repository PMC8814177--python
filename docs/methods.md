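# Methods

## Model overview

`cytoabm` simulates a metabolic pathway as a population of reactive agents
in a cubic volume of cytoplasm.  An agent follows the classic
⟨E, Per, Ac, see, action, do⟩ scheme: each tick it observes the part of the
environment inside its perception sphere, selects an action (move, bind,
wait, release) and applies it.  Three molecule classes exist: *metabolites*
(move only), *enzymes* and *complexes* (move and act).  The simulation is
driven by a single seeded RNG, so a run is a pure function of
(model, config, seed).

### Geometry and diffusion

Every molecule is a sphere.  Its radius comes from the molecular weight via
the mean partial specific volume of a protein in solution,
`r = (3 v̄ M / 4 π N_A)^{1/3}` with v̄ = 0.73 cm³/g.  Applying the same v̄ to
metabolites is a deliberate simplification: all species are treated
uniformly as weight-derived spheres (glucose ≈ 3.7 Å, a 54 kDa enzyme
≈ 25 Å).

Diffusion is Stokes–Einstein, `D = k_B T / 6 π η r`, at T = 298.15 K and
η = 0.0011 Pa·s.  Per tick (Δt = 1e-4 s) an agent takes one step of fixed
modulus `L = sqrt(2 D Δt)` along an isotropic random direction (cos θ
uniform on [−1, 1], φ uniform on [0, 2π)).  The fixed modulus — the 1-D
root-mean-square form used as a 3-D step — is the primary contract and is
what the MSD acceptance check verifies (`<x²> = 2 D t` over replicated free
walks).  Two documented alternatives exist for sensitivity studies:
`gaussian_steps` (per-axis Gaussian displacements of the same scale) and
`msd_3d` (`sqrt(6 D Δt)` modulus).

### The box and the long-step question

The default box is 1000 Å per side (1 attolitre) with reflecting walls.
Reflection was chosen over periodic wrapping because the volume represents
a portion of cytoplasm, not a torus; periodic boundaries remain available.

With these defaults the per-tick step of a small metabolite (~3000 Å)
exceeds the box side.  The simulator folds such steps specularly
(repeatedly, for steps longer than the side), which preserves the per-tick
displacement statistics; the practical consequence is that small-metabolite
positions decorrelate almost completely between ticks, i.e. the box is
effectively well mixed at the metabolite scale.  An alternative `reject`
policy treats an out-of-box endpoint as a failed attempt.  We analysed both
before choosing: under `reject`, any species whose step exceeds the box
diagonal (1732 Å) can never complete a move and freezes entirely, which
collapses the contact-range (5 Å) and Debye-range (10 Å) regimes into
indistinguishable inactivity.  Folding is therefore the default; `reject`
ships as a config option for exploring movement-policy sensitivity.

### Collision handling

A move is committed only if the endpoint overlaps no other agent (overlap =
centre distance < sum of radii; touching is legal).  On overlap, up to k = 5
fresh random directions are tried; otherwise the agent stays put.  Agents
are updated sequentially in a fresh uniformly-random order per phase per
tick, which avoids simultaneous-move tie-breaking and first-mover bias
while keeping determinism per seed.  All three molecule classes are
collision-checked identically.  A uniform-grid spatial index (cell = 1/8
side) backs the overlap and neighbour queries; wide queries fall back to a
vectorised full scan.  One knowing exception to strict non-overlap:
when a complex grows by binding a metabolite its radius increases by volume
additivity, and if the grown sphere would overlap a neighbour the complex
is nudged to a nearby free spot; in the rare case none is found within ten
tries, a transient overlap is tolerated and resolves on the next committed
move.

### Perception and binding

An enzyme (or non-saturated complex) perceives free cognate metabolites
whose surface-to-surface distance s is within the perception distance d
(closed ball).  Only one d is allowed per simulation — the regime under
study.  Candidates are tried in uniformly random order, each binding with
probability p(s); the first success binds.  The default law is

    p(s) = 1               for s ≤ 5 Å
    p(s) = (5/s)³          for 5 < s ≤ d
    p(s) = 0               for s > d

The 1/s³ decay mirrors the resonant long-range dipole potential
(U(r) ~ r⁻³) that the 300 Å regime abstracts, while keeping binding certain
at contact range.  The law is config-pluggable; `uniform` (p ≡ 1 inside the
sphere, used by the turnover oracle) and `sextic` (1/s⁶, van der Waals-like)
are included for comparison.  An optional `specificity` mode ranks
candidates by the specificity constant k_cat/K_m before the same
probabilistic trials; it requires K_m values and errors out at startup
without them.

### The reaction automaton

Binding a metabolite to a free enzyme opens a complex whose automaton
tracks the reaction, the direction, and the bound-substrate multiset.  For
reversible reactions the first bound metabolite fixes the direction; an
enzyme catalysing several reactions picks uniformly among the open options
at first binding.  A complex below saturation keeps moving and perceiving
the still-missing substrates.  At saturation the countdown is set to
`max(1, round((1/k_cat)/Δt))` ticks.

Tick phases: (1) all agents move; (2) enzymes and non-saturated complexes
perceive and bind; (3) saturated complexes decrement their countdown —
starting in the very tick they saturate — and release at zero.  With this
accounting a never-starved enzyme completes one cycle in exactly
`wait + 1` ticks including the re-binding tick, except that the release
tick itself overlaps the countdown, so the measured Vmax-limit rate equals
k_cat (the turnover acceptance check requires agreement within 10%).

Products are placed collision-free adjacent to the enzyme surface (random
directions on an expanding shell, bounded retries); if space cannot be
found, the whole release — never a partial one — is deferred to the next
tick.  Complex radii follow volume additivity,
`r_complex = (r_e³ + Σ r_m³)^{1/3}`.

Partial complexes never dissociate by default, matching the persistent
hexokinase–glucose complexes that define the short-range stall; an optional
`unbinding_timeout` returns the bound metabolites to the free pool after a
configurable number of unsaturated ticks.

### Conservation ledger

At any tick, for every species, free count + count bound in complexes −
initial count equals the net stoichiometric production summed over
completed catalytic events — an exact integer identity, checked in debug
mode, fuzzed over random pathways in the acceptance suite.

## Observables

Recorded every `record_every` ticks (default 100 → 10 ms sampling, Nyquist
50 Hz, ample for the few-Hz oscillations of interest): free-molecule
concentrations per species (mmol/l via `count / (1e-3 N_A V)`) and complex
counts per composition.  Molecules inside complexes are deliberately *not*
counted in their species' concentration; the complex plots are separate.

Derived quantities are pure functions of the series: depletion time (first
recorded time at which the count is zero and stays zero), dominant
frequency (maximum of the boxcar periodogram of the linearly detrended
series, zero bin excluded, significant only if the peak exceeds 4× the
median periodogram power), and synchrony (Pearson correlation of linearly
detrended series at zero lag, undefined for zero-variance input).  A
constant or purely linear series is reported as having no peak; detrending
residues below 1e-10 of the signal scale are treated as zero.

## The glycolysis fixture (synthetic-data generator)

The bundled network is the adapted yeast glycolysis: the main chain
(hexokinases HXK1/HXK2/GLK1 → PGI1 → PFK → FBA1 → TPI1 → TDH1-3 → PGK1 →
GPM1 → ENO1/ENO2 → CDC19) with the glycerol (GPD1, RHR2), trehalose (PGM1,
UGP1, TPS1, TPS2) and glycogen (GSY2) branches.  Isoenzymes are separate
reactions sharing substrates and products.  Fermentation (PDC1/5/6,
ADH1/5), adenylate kinase, ATPase, the UDP→UTP step and glucose transport
are excluded; the three control points (hexokinase/glucokinase, PFK,
pyruvate kinase) plus the branch-exit steps are irreversible.

Initial concentrations are all below 1 mmol/l.  Pyruvate (0.2), trehalose
(0.015) and NADH (0.086 mmol/l) are adopted as printed study values; every
other metabolite and all enzyme copy numbers are documented approximations
(flagged `approx=true` in the model files) chosen at physiologically
plausible relative magnitudes — glucose near the cap at 0.9 mmol/l
(≈ 540 molecules/aL), ATP 0.6, enzymes at a few to ten copies per
attolitre, ≈ 2200 agents in total.  Turnover numbers are
literature-typical magnitudes (10–10³ s⁻¹) per isoenzyme.  All of these are
overridable from a user-supplied table.  `scale` multiplies every particle
count (rounded, floored at one per nonzero species) for desk-scale runs.

What the generator does *not* emulate: allosteric regulation and
energy-charge feedback, glucose transport (both excluded by design),
crowding agents beyond the pathway's own molecules, realistic absolute
enzyme abundances, and intracellular structure.  Passing tests therefore
demonstrate the mechanics and the regime contrast of the model — not
quantitative agreement with in vivo glycolysis.

## Numerical choices

* Particle counts: `round(c · 1e-3 · N_A · V)` with half-up rounding;
  the concentration↔count conversion is exactly inverse for counts ≤ 1e6.
* Concentration scaling for imported models: divide by a common factor so
  the maximum lands 1% under the cap (order-preserving), then floor any
  positive species that would round to zero particles up to exactly one
  particle.
* Overlap test uses strict inequality with a 1e-12 relative tolerance, so
  touching spheres and released products resting on the enzyme surface are
  legal.
* wait-ticks use `round()` with a floor of one tick.
* Perception is a closed ball (s = d binds); candidate id arrays are sorted
  before permutation so set-iteration order never leaks into trajectories.
* Degenerate inputs: duration 0 yields only the initial snapshot; a model
  with no enzymes is inert but valid; zero-reaction SBML imports cleanly;
  impossible packings and unsatisfiable scaling raise explicit errors.

## Desk-scale problem sizes

The bundled study protocols run the regime comparison at particle scale 0.2
(≈ 450 agents) for 0.2 simulated seconds (2000 ticks) with five seeds per
regime, the turnover oracle with 500 substrate molecules for 1 s, and the
MSD check with 10³ replicas × 10³ ticks.  These sizes keep a full
reproduction around ten minutes on one CPU while leaving each comparison
comfortably outside its noise band.  The short-range stall is assessed
with fixed criteria chosen before any simulation was run: at 5 Å the mean
ATP drop is at most half the initial level and smaller than at 300 Å, and
hexokinase/glucokinase–glucose complexes are present in at least 60% of
recorded ticks of the run's second half.

## Known limitations

* Well-mixedness at the metabolite scale (from step folding) means the 5 Å
  regime stalls only relatively, not absolutely: contact encounters are
  rare but not impossible, so the regime contrast at desk scale is a
  factor of ~1.5 in consumed glucose rather than a hard plateau.
* Fixed step modulus underestimates displacement kurtosis relative to a
  true Wiener process; `gaussian_steps` quantifies the difference.
* Hydrodynamic interactions, soft potentials, anisotropic shapes and
  crowding-corrected viscosity are out of scope.
* One perception distance per simulation; mixed-range systems are not
  modelled.
* Enzyme copy numbers and most metabolite concentrations in the fixture
  are approximations; absolute rates should not be read as physiological.
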