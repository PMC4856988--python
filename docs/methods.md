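# Methods

## Model

Chromatin is a bead-and-spring polymer: beads of diameter sigma carry 3 kbp
(30 nm beads) or 1 kbp (20.8 nm), the two sizes sharing one volume density
of DNA so diameter scales as the cube root of content. Transcription
factors and heterochromatin-binding proteins are diffusing spheres
(diameter sigma by default). The force field has three terms, all in
reduced units (sigma = 1, k_BT = 1):

* **FENE backbone bonds** with maximum extension R0 = 1.6 sigma and spring
  constant K = 30 kT/sigma^2 (the Kremer–Grest convention; the spring
  constant is a standard choice, not a fitted value). Permanent loop
  anchors are extra FENE bonds treated identically to backbone bonds.
* **Kratky–Porod bending**, U = K_B (1 − cos θ) on consecutive bond
  vectors. K_B is set by inverting the *discrete-chain* relation
  ⟨cos θ⟩ = coth K_B − 1/K_B = exp(−b/l_p): for the default persistence
  length l_p = 3 sigma (90 nm) this gives K_B ≈ 3.5 kT. The naive
  continuum map l_p = K_B·sigma/kT would give K_B = 3 and realize only
  l_p ≈ 2.5 sigma at this stiffness, which is why the discrete inversion
  is the default; the continuum estimate is exposed separately.
* **Pair interactions.** All particle pairs repel through WCA sterics
  (LJ truncated and shifted at 2^(1/6) sigma_ij, epsilon = 1 kT). A factor
  and a cognate bead instead interact through a Lennard-Jones potential
  truncated and shifted to zero at 1.8 sigma_ij (54 nm for 30 nm beads),
  whose nominal depth epsilon comes from the affinity matrix. The realized
  well depth is epsilon minus the shift, ≈ 0.886 epsilon at the 1.8 sigma
  cutoff; run logs report both. The affinity matrix maps (factor species,
  bead color) and is directional; absent entries mean pure sterics. A bead
  carrying several colors takes the strongest affinity matching each
  species, so a pink+gray bead binds both the euchromatin factor and the
  heterochromatin protein.

Factors are multivalent simply because nothing prevents several beads from
sitting inside one factor's attraction range: bridging, clustering and the
resulting loops/rosettes/domains are emergent. The monovalent control caps
a factor's simultaneous cognate partners at one by granting attraction
only to the nearest in-range cognate bead each step.

## Units

Physical mapping assumes Stokes–Einstein drag at viscosity 10 cP (ten-fold
water) and T = 300 K: one time unit is tau = sigma^2/D with
D = kT/(3 pi eta sigma), i.e. ≈ 0.6 ms for 30 nm beads and ≈ 0.2 ms for
20.8 nm beads. Concentrations and volume fractions follow from the box
edge (3 um = 100 sigma in the standard setups): 250 factors ≈ 15 nM,
5000 beads ≈ 0.26% volume fraction (dilute).

## Dynamics

The box is periodic and cubic; every distance uses the minimum-image
convention; positions are stored unwrapped so displacement-based
quantities (MSD, radius of gyration) need no image bookkeeping.

Two integrators share one force kernel:

* **BAOAB Langevin** (production default): unit mass, unit friction for a
  1-sigma particle (friction scales with diameter), dt = 0.01 tau. Its
  diffusive behaviour reproduces the overdamped limit (D = kT/gamma) while
  remaining stable for the stiff FENE/WCA terms at this step; this mirrors
  the standard LAMMPS Langevin setup for Kremer–Grest polymers. A
  first-order overdamped update at dt = 0.01 tau would take per-step noise
  displacements of ~0.25 sigma and overstretch FENE bonds, and a stable
  overdamped step (~1e-3 tau) costs ten-fold more wall time — that is the
  design reason BAOAB is the default.
* **Euler–Maruyama** (overdamped, dt default 1e-3 tau): retained because
  free diffusion is exact at any step size and, with the thermostat off,
  the update is plain gradient descent; the physics checks (MSD = 6Dt,
  monotone energy descent, dimer force balance) use it.

The standard protocol grows each fiber as a self-avoiding random walk
(bond length 1 sigma, hard-core 0.8 sigma, backtracking on dead ends),
scatters factors uniformly with the same hard core, removes residual soft
overlaps by a short capped-force noise-free descent, equilibrates with all
affinities off, switches each species on at its activation time (10^4 tau
in the full-scale setups), applies any scheduled affinity changes, and
samples every 10^3 tau. Neighbor search is a Verlet list (skin 0.6 sigma)
rebuilt from a cell list when any particle has moved half a skin. Pair
parameters (epsilon, sigma_ij^2, factor/bead identity) are baked into the
pair list at rebuild time; Gaussian noise is generated in blocks by a
PCG64 generator seeded from the run seed, so a run is bit-reproducible
given its configuration and seed.

A FENE bond reaching R0, or a non-finite coordinate, aborts the run with
the offending bond and timestep named — integration instabilities are
never silently absorbed.

## Analyses

* **Clusters**: single-linkage connected components at minimum-image
  distance strictly below the cutoff (default 3 sigma = 90 nm). A cluster
  has ≥ 2 members; the mean cluster size is reported over clusters and
  equals 1 when none exist. The fraction clustered counts participants in
  clusters. Cluster color purity is the dominant-color share per cluster,
  summarized as the fraction of pure clusters and the fraction with
  purity ≥ 0.8.
* **Rosettogram**: rows are clusters (ordered by their first binding bead
  along the fiber), columns the high-affinity beads in fiber order; a
  pixel marks membership, colored by the nearest bound factor's species
  within binding range (ties to the smaller species index). Runs of
  abutting pixels in a row are rosette petals.
* **Disorganized fraction f_d**: the fraction of high-affinity beads that
  do not share a cluster with either of their nearest-neighbor
  high-affinity beads along the fiber. By construction
  f_d + (fraction sharing) = 1 per snapshot.
* **Contact maps**: a contact is a bead pair within 5 sigma (150 nm);
  counts from 40-bead bins are aggregated over snapshots (the
  high-resolution variant uses 3 sigma / 90 nm and no binning). Binning
  conserves total contacts.
* **P(s) and exponents**: contact probability versus genomic separation,
  normalized per pair and snapshot; exponents from least-squares log–log
  fits over stated ranges, with the standard error from the fit
  covariance. Degenerate (flat or empty) ranges are rejected. On
  block-patterned fibers the decay has two regimes set by the pattern's
  domain sizes; the package fits the intra-domain exponent below the
  smaller block scale and the inter-domain exponent beyond the larger,
  excluding the crossover between them (the split is a configuration
  choice, exposed rather than auto-detected).
* **Boundaries**: the Janus profiles sum each bin's contacts to the left
  and right within a window (default 100 beads); the difference signal is
  smoothed with a 5-bin moving average, and boundaries sit where it
  crosses zero with positive slope (sub-bin position by linear
  interpolation). The insulation variant takes local maxima of the
  difference's derivative. Boundary concordance between two sets is
  greedy nearest-first one-to-one matching within a tolerance (100 kbp in
  genomic units), reported as the fraction of the reference set recovered,
  with a uniform-random permutation null of equal cardinality available.
* **Steady state**: scalar time series (cluster size, Rg) are averaged
  over the final 20% of snapshots.

## Genome painting

ChromHMM-style intervals (BED, 0-based half-open; state parsed from
either "1_Active_Promoter"-style names or plain integers) and GC content
color the beads: ≥ 90 bp of states {1,4,5} → pink, ≥ 90 bp of states
{9,10} → light-green, GC strictly below the threshold → gray (or ≥ 90 bp
of state 13 when no GC track is supplied), otherwise blue. The 90 bp rule
pools the state group's total overlap within the bead by default (robust
to interval fragmentation; a contiguous-run mode is provided), and
painting is invariant to splitting an interval into abutting pieces.
N runs are excluded from the GC denominator; beads over 50% N paint blue.
The GC threshold is calibrated as the value putting exactly as many beads
strictly below it as carry the state-13 mark — the published thresholds
(41.8% for the 15 Mbp region, 48.4% for the whole chromosome) are
instances of this rule on real data.

The synthetic-annotation generator emulates the *marginal statistics* this
pipeline consumes: target fractions of pink-eligible and green-eligible
beads placed as short (90–400 bp) marks on distinct beads,
heterochromatin as geometric runs (~40 beads) of state 13, background
filler covering every remaining bp, and an AR(1) GC profile depressed
inside heterochromatin runs. It does not emulate state transition
grammar, CpG islands, isochore structure or annotation errors of real
ChromHMM tracks, so passing painting tests demonstrates the rules and
bookkeeping, not fidelity to any particular genome. A companion generator
emits synthetic FASTA realizing each bead's GC exactly, for end-to-end
tests of the sequence path.

## Study conditions and scaled-down test sizes

The shipped recipes carry the full-scale conditions (5000-bead fibers,
250 factors, 3 um box, activation at 10^4 tau, 5×10^4 tau duration;
20 × 2000 beads with five 500-copy species at 7.1 kT for the multi-color
system; 300/3000 factor/protein counts for the 15 Mbp chromosome setup).
`scale_recipe` shrinks counts and box together, preserving every volume
fraction and all length scales.

Full-scale runs take tens of CPU-minutes each, so the automated test
suite exercises the same physics at reduced size and duration, chosen
once as the package's standard desk-scale conditions: the single-species
system at scale 0.2 (1000 beads, 50 factors, box 58.5 sigma) run for
1.2×10^4 tau with two seeds; the two-species system at scale 0.2 for
5×10^3 tau; the block-patterned fiber at scale 0.2 for 8×10^3 tau; the
five-color system as two 500-bead fibers with 13 copies of each species
(preserving the full system's factor-to-bead ratio) for 5×10^3 tau; the
homogeneous-fiber null control as three independent scale-0.2 runs of
1.5×10^3 tau; all with binding activated after a 500 tau equilibration
and 250 tau sampling, steady window = final 20% of snapshots. Cluster sizes are intensive, so the
scaled systems approach comparable steady-state sizes, but coarsening is
slow (roughly logarithmic in time): quantities that mature late in the
full 5×10^4-tau protocol — the fraction of binding beads sharing a
cluster with a fiber neighbor, and the merging of neighboring block
clusters on patterned fibers — sit below their late-time values at these
conditions, and the corresponding assertions are expected to fail there
while the underlying physics (clustering, segregation, domain formation)
is fully exercised; those asserted ranges are kept at their
full-protocol values rather than widened to desk-scale ones.

The strong/weak affinities of the toy setups are shown only in the
original figure panels, so they are calibrated here (once) such that the
single-species toy model reproduces the ~12 factors/cluster steady state
at the desk-scale conditions; the calibrated defaults are written in the
recipes (strong cognate binding 8 kT nominal; weak non-specific binding
to all other chromatin beads; see `fig1a.yaml`). The 7.1 kT of the
five-color system is nominal epsilon, matching the convention above.

## Numerical choices and degenerate inputs

* Cluster cutoffs and contact thresholds are compared strictly ("within
  90 nm" = distance < cutoff); at-cutoff equality is a measure-zero event
  in floating point and excluded by construction in tests.
* GC threshold comparisons are strict "<" (a bead exactly at threshold is
  not gray).
* Zero-area intervals, unknown recipe keys, affinity events before time
  zero, anchors adjacent on the backbone, cutoffs of at least half the box
  edge, and painting through annotation gaps are all rejected with
  explicit errors.
* Ties in rosettogram coloring go to the smaller species index;
  boundary-set positions are sorted and deduplicated.
* The permutation null uses 200 uniform draws by default.

## Known limitations

* No hydrodynamic interactions, twist/supercoiling energetics or
  linking-number constraints; pre-formed loops are torsionally
  unconstrained.
* Binding kinetics are implicit (potential wells), so on/off rates are
  set by the well depth and diffusion, not by measured kon/koff.
* The scaled-down suite cannot observe late-time coarsening beyond its
  run length; cluster sizes quoted at desk scale sit at the early plateau
  of the slow-growth regime.
* Hi-C comparison operates on any externally supplied boundary list or
  square matrix; fetching, balancing and normalizing real Hi-C is out of
  scope.
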