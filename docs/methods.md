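# Methods

`particell` is a particle-based, multiscale modeling and simulation library:
one abstraction — the particle — is reused from molecular toys to
multicellular tissue models.  This note documents the model, the numerics,
the synthetic fixtures, and the design choices that were genuinely open.

## Dynamics

Each particle type prescribes one of two dynamics laws for its particles:

- **Newtonian**: `m_i d²r_i/dt² = f_i`, with `m_i` the inertial mass;
- **overdamped (Langevin)**: `m_i dr_i/dt = f_i`, with `m_i` acting as a
  drag coefficient.  Inertia is neglected, which is the appropriate regime
  for cells moving in a highly viscous environment.

The total force is the sum of three classes:

1. **Implicit** pair forces, derived from potentials bound to unordered
   pairs of particle types and applied automatically to every pair within
   a cutoff.  A binding may be scoped by cluster membership: *bound*
   (both particles in the same top-level cluster, e.g. intracellular) or
   *unbound* (different clusters, e.g. intercellular).  Particles outside
   any cluster count as unbound partners.
2. **Bonded** forces between explicitly enumerated particles: `Bond`
   (potential of the pair distance), `Angle` (potential of the angle at
   the middle particle) and `Dihedral` (potential of the torsion angle
   between the two planes).  Bonded terms ignore the global cutoff.
3. **Explicit** per-particle forces: constant (gravity), friction
   `-γv`, Gaussian thermal noise `sqrt(2γkT/dt)·ξ`, or a user callback.

A transport-DPD pair interaction is available for fluids, with the
standard Groot–Warren components: conservative `α(1-r/rc)r̂`, dissipative
`-γ(1-r/rc)²(r̂·v_rel)r̂`, and random `σ(1-r/rc)ξ r̂/√dt`.  The
fluctuation–dissipation balance `σ² = 2γkT` is applied only when
parameters are built through `DPDParams.thermalized`, so athermal DPD
fluids remain expressible.

Potentials are *process objects*: adding two potentials produces a
summation object that forwards evaluation to its children and returns the
sum, to arbitrary depth, with each child applying its own range.  The
functional conventions are fixed constants of this package: harmonic
`k(r-r0)²`, Lennard-Jones `A/r¹² - B/r⁶`, Morse `d[(1-e^{-a(r-r0)})²-1]`,
Coulomb `q/r`.  Below `r_min` a potential evaluates at `r_min` (abscissa
clamp), bounding repulsion when runtime insertion creates deep overlaps;
at and beyond `r_max` it is exactly zero.

## Chemical species

Particles carry a state vector aligned with the species declared by their
type.  States evolve by pairwise transport fluxes plus local reactions:

    dC_i/dt = Σ_j Q_ij + Q_i^R.

Fickian flux: `Q_ij = k (C_j - C_i)(1 - r/r_cut)²` inside the cutoff,
anti-symmetric and mass-conserving.  Active pumping transfers
`k C_source (1 - r/r_cut)²` per unit time from a source to a target
particle; the per-substep withdrawal is capped at the source content, so
pumping is conservative and never drives a state negative.  On a regular
grid with spacing `h`, choosing `k = D / (h²(1 - h/r_cut)²)` makes the
particle update *identical* to the FTCS finite-difference discretization
of the heat equation with coefficient `D·dt/h²`; this identity (the only
reading of the diffusivity relation under which it holds) is verified to
1e-12 per step in the tests.

Species are integrated in `n` sub-intervals per step (forward Euler,
simultaneous update across all particles and rules).  Halving the
sub-interval halves the splitting error (first order).  Negative
concentrations produced by an unstable choice of `k·dt` are clamped to
zero and counted (`universe.species_clamp_count`), making misuse visible.

## The simulation loop

Space is decomposed into a regular grid of cells with edge ≥ the global
cutoff.  Each step runs three stages:

- **Prep** — force accumulators and cached energies reset;
- **Force** — particles are sorted by containing cell (*Sort*), pair
  interactions evaluated within cells (*Force Self*) and between neighbor
  cells (*Force Pair*), then bonded terms, explicit forces, and species
  fluxes; pair forces are applied once per pair with equal and opposite
  signs, so momentum conservation is exact to accumulation roundoff;
- **Update** — explicit first-order forward integration (velocity-first
  for Newtonian, plain forward Euler for overdamped), boundary
  application, species sub-interval integration, destruction of bonded
  items whose energy exceeds their dissociation threshold, then events,
  in registration order.

The engine is single-threaded but preserves the Sort → Force-Pair
dependency contract; a literal pruned-enumeration implementation
(`reference_pairs`) is kept alongside the vectorized production path and
both are asserted equal to an all-pairs minimum-image scan.  Pairs at
exactly the cutoff are excluded (strict `<`, matching the flux law's
piecewise boundary).  For systems of ≤ 64 particles, or on periodic grids
coarser than 3 cells per axis (where half-space enumeration would double
count), the engine uses the all-pairs path directly — same arithmetic,
same strict cutoff.

Boundaries are per-axis: periodic (coordinates wrapped into `[0, L)`,
minimum-image distances) or reflective (positions mirrored, normal
velocity negated).  Under periodic boundaries the cutoff may not exceed
`L/2`.  Frozen particles accumulate forces but never move.  Planar (2-D)
models are 3-D simulations with the third force/velocity component zeroed.

### Integrator accuracy and the period measurement

The Newtonian update is velocity-first (symplectic) Euler: first-order
accurate, with a bounded O(dt) energy oscillation.  For a linear
oscillator the *frequency* of this map is second-order accurate (its
rotation angle satisfies `cos θ = 1 - ω²dt²/2`), while its initial phase
carries an O(dt) offset.  The oscillator fixture therefore measures the
period anchored at the release time — four times the first rest-length
crossing — which converges at the integrator's true first order; a
crossing-to-crossing measurement would cancel the phase offset and show
the superconvergent order 2 instead.

## Events and reproducibility

Events fire during Update, last, at every step whose completed-step count
is a multiple of their period, in registration order; callbacks may
create/destroy particles and bonds with effect before the next Force
stage.  One root seed spawns named child streams (`dpd`, `noise`,
`events`, `model`), so identical configurations reproduce bitwise.

The complete state — including every RNG stream state — serializes to
human-readable JSON with sorted keys and round-trippable floats, so a
checkpointed stochastic run continues bitwise-identically to an
uninterrupted one.  Code never serializes: custom potentials, forces,
reactions and event callbacks are referenced by registered name and must
be re-registered before import.  Model objects that hold Python state
outside the universe (the crypt agent model, the Delta-Notch coupling)
are rebuilt from their builders rather than checkpointed.

## Worked multicellular models (the synthetic-data layer)

All fixtures are generated from a seed at run time; none are stored.

**Oscillator / pendulum.** Two Newtonian particles under a harmonic
binding (analytic period `π√(m/k)` for `U = k(r-r0)²`), and a double
pendulum built from a frozen pivot, stiff harmonic bonds (length
excursion ≤ 5% at `k = 200`), and a constant downward force.

**Spheroid fusion.** Cells are single overdamped particles; all
intercellular mechanics come from one Morse potential (`d=0.1, a=6,
r0=1`, cutoff 2 cell diameters, clamp at `r=0.6`).  Spheroids are
pre-assembled by relaxing a ball-shaped lattice packing (5% jitter) to
mechanical rest (max displacement per step < 2e-3), given a random
orientation (the lattice seeding leaves crystalline facets that would
otherwise meet facet-to-facet), and placed so the closest cross-spheroid
cell pair sits at 0.9 diameters — surfaces in contact without the
ejection-scale clamp forces a bounding-box placement can produce on
rough surfaces.  Fusion proceeds by viscous sintering, which requires
cell rearrangement: a perfectly quiescent packing zips an initial
contact and then jams.  Each cell therefore carries a weak random
motility force (effective diffusivity `kT = 0.01`, an order of magnitude
below the adhesion scale), under which the neck keeps coarsening as it
does in bioprinting-scale spheroids.  Desk-scale runs use 500 cells per
spheroid rather than ~12,500.  The neck diameter is the largest
coordinate spread along a transverse axis among cells within ±0.5
diameters of the contact mid-plane, censused every 5 time units over a
75-time-unit run and smoothed with a 10-census moving window, a cadence
at which the neck-growth increment between censuses dominates the
census-to-census motility noise.

**Colonic crypt.** The crypt is unfolded to a periodic-by-reflective
sheet of 20×10 cell diameters; the top edge is the removal boundary
("base") and the lower 2/3 is proliferative.  Each cell is an overdamped
particle (Morse `d=0.08, a=5`, chosen so the confluent sheet sits near
one cell per unit area) carrying a G1→S→G2→M cycle; G1 durations are
N(2, 0.5) truncated at 0, S=G2=M=1.  Division copies the parent's clone
id to a daughter placed 0.1 diameters away in a uniform random planar
direction.  Clone ids are minted only at t=0, so the clone count is
non-increasing by construction; neutral drift plus removal drives the
population (steady state ≈ 205 cells) toward monoclonality.  The census
horizon for the scaled-down monoclonality check was calibrated once, by
measuring time-to-≤3-clones across ten seeds (range ≈ 340–1350 time
units), and fixed at t=1100.

**Delta–Notch.** A static 12×12 hexagonal monolayer; each cell carries
Notch `n` and Delta `d` evolving by the classic lateral-inhibition ODEs
`dn/dt = F(D̄) - n`, `dd/dt = v(G(n) - d)` with `F(x)=x^k/(a+x^k)`,
`G(n)=1/(1+bn^h)`, defaults `a=0.01, b=100, k=h=2, v=1`, and `D̄` the mean
Delta over neighbors within 1.1 cell diameters.  The ODEs integrate
through the species-reaction hook; the neighbor mean refreshes once per
step into a dedicated state slot.  From a ±5% perturbed homogeneous
steady state (found by root-finding) the sheet reaches a checkerboard
with neighbor-pair Pearson correlation ≈ −0.45.  For induction, a frozen
signal grid overlays the sheet with an FTCS-equivalent Fickian flux and a
clamped source edge; cells integrate the ODEs only where the local signal
exceeds 0.1.  The signal diffusivity (0.3) is set slower than the
intrinsic patterning time so pattern onset tracks the front; a cell
counts as locally patterned when its Delta departs from its neighbor mean
by more than 0.3.

**Membrane pump.** Two DPD fluid compartments separated by a
harmonically bonded membrane sheet (periodic in-plane); a frozen channel
particle pumps solute from nearby lower-compartment particles into the
channel and out to upper-compartment particles.  Both transfers are
conservative, so the total amount is exactly constant while the upper
compartment's total is non-decreasing.

### What the fixtures do and do not show

The fixtures exercise the engine's contracts (force correctness,
conservation, reproducibility) and the qualitative emergent behaviors the
models are known for (fusion neck growth, drift to monoclonality,
lateral-inhibition patterning).  They do not calibrate to any real
tissue: mechanics parameters are in reduced units, cells have no volume
dynamics or polarity, the crypt has no stem-cell hierarchy or contact
inhibition, and patterning uses a literature parameter set rather than
fitted kinetics.  Passing tests therefore demonstrates correctness of the
computational method, not quantitative agreement with experiments.

## Numerical choices and degenerate inputs

- Pair separations of exactly zero are excluded from implicit
  interactions (no direction is defined); potentials raise on `r ≤ 0`.
- Angle gradients are zeroed within `sin θ < 1e-8` of collinearity
  (bounded forces at a measure-zero singular set); dihedrals with a
  degenerate plane raise instead, since there the angle itself is
  undefined.
- Torsion potentials take the angle magnitude with the chain rule on the
  sign, so even potentials (harmonic in the angle) behave identically on
  both branches.
- Dissociation compares the energy computed in the Force stage against
  the threshold at the end of the same step: a bond breaks at the first
  step whose energy exceeds the threshold, never before.
- Non-finite forces or positions abort the step with the particle id and
  the stage name.
- `total_energy` recomputes deterministically (stochastic force terms are
  skipped), so energy reporting never consumes random-stream state.

## Known limitations

- Single-threaded; no GPU offload; desk-scale (≈10³–10⁴ particles).
- First-order integrators only.
- No long-range electrostatics; no cutoff smoothing (energies are
  truncated, not shifted).
- JSON import requires re-registration of named callbacks; agent state
  held outside the universe (crypt cycle states) is not checkpointed.
- Nested clusters classify bound/unbound by top-level cluster only.
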