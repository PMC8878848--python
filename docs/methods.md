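# Methods

## The cascade-selection protocol

One cycle consists of: (1) evaluate the reaction coordinate (RC) on the
previous cycle's pool of *N × M* snapshots (*N* segments × *M* recorded
frames); (2) rank the pool ascending and select the top *N* snapshots,
breaking ties deterministically by (cycle, replica, frame) and recycling
ids round-robin if the pool holds fewer distinct snapshots than *N*;
(3) regenerate each seed's velocities from the Maxwell–Boltzmann
distribution; (4) run *N* new independent segments.  Cycle 0 seeds every
replica from the reactant.  Ranking uses only the most recent cycle's
pool by default (`pool_scope="cycle"`); ranking over all snapshots ever
generated is available (`"global"`) but couples cycles and is not the
default.  Snapshot scoring of a multi-copy system uses the minimum
`d_COM` over copies — any copy binding ends the search; per-(snapshot,
copy) ranking is available via `rank_granularity="copy"`.

Termination, checked after every cycle, returns the first of:

- **cutoff** — the cycle's best RC value is below `cutoff`;
- **converged** — the L1 distance between the fixed-bin RC histograms
  averaged over the last `convergence_window` cycles and over the
  preceding window is below `convergence_tol` (bins span [0, max RC of
  cycle 0]; defaults: 5 cycles, 0.05, 20 bins).  This is the fallback for
  systems without a known bound-state distance;
- **max_cycles** — the cycle budget is exhausted.

Every snapshot stores the id of the snapshot that seeded its segment, so
each final snapshot below the cutoff yields a unique ancestor chain back
to the reactant — a complete binding pathway (`trace_binding_paths`).

If ligand copies aggregate (single-linkage clustering of copy–copy COM
distances below `aggregation_threshold`), the reset policy re-arranges
every copy *except* the one closest to the site, so concentration keeps
helping without discarding progress.

Reproducibility: a single run seed; every stochastic stream
(arrangement, velocity draws, segment noise, resets) derives its own seed
from `(run_seed, purpose, cycle, replica)` through a `SeedSequence` spawn
key.  Replicas are therefore independent of execution order, a resumed
run continues bit-for-bit identically to an uninterrupted one, and two
runs with the same configuration and seed produce byte-identical
`cycles.csv`.

## The toy substrate

At production scale this protocol drives an all-atom engine; this package's loop
is engine-agnostic (any `EngineAdapter` with `propagate` and
`regenerate_velocities` can be driven) and ships a reduced Langevin model
so every stage is testable at desk scale.  Reduced units: k_BT = 1,
mass = 1, lengths Å-like but without force-field meaning.

A single static landscape plays the protein:

- an attractive Gaussian well at the binding-site center,
  `U = −D exp(−r²/2σ²)` (defaults D = 10–12 k_BT, σ = 1.5);
- a soft harmonic core below `excluded_radius` (the protein interior,
  stiffness 50) and a harmonic outer wall beyond `confinement_radius`
  (the "box", stiffness 5);
- a compact-support pair repulsion `U = ε(1 − d/R)²` for `d < R` between
  particles of distinct ligand copies (ε = 5, R = 2) — the weak
  intermolecular repulsion that prevents aggregation in concentrated
  arrangements.

Ligand copies are single particles by default; an optional extended
ligand is a hexagonal ring of 6 sites held by a stiff elastic network
(all intra-copy pairs restrained to the regular-hexagon rest lengths,
spring constant 200).  A true rigid body would need constrained or
rigid-body Langevin integration; the near-rigid network exercises the
same COM/R_g/Δ coordinates at a fraction of the machinery, which is why
it was chosen.

The integrator is BAOAB Langevin splitting (superconvergent
configurational sampling; friction 1, dt 0.02 by default, giving
ω·dt ≤ 0.15 for the stiffest default term).  The frozen site-marker
particle carries no interactions — the landscape is anchored to
`site_center` — and exists so atom selections and XYZ archives have an
explicit site entry.  What the toy model does *not* emulate: solvent and
hydrodynamics, conformational gating of the site, rugged energy surfaces,
anisotropic ligands with internal torsions.  Passing tests therefore
validate the *protocol* (selection, bookkeeping, estimators,
reproducibility) and the engine's statistical mechanics, not force-field
realism.

## Fixtures and the study conditions

- **funnel-easy** (smoke scale): confinement radius 12, three copies
  arranged 7–10 from the site, N = M = 5, cutoff 3.0; plain dynamics
  binds readily, cascade runs finish in a few cycles in seconds.
- **funnel-hard** (the enrichment study): confinement radius 50, six
  copies arranged 38–43 from the site, N = M = 10, 10 integration steps
  per frame, cutoff 3.0, 50-cycle budget.  The "barrier" is entropic — a
  diffusive search of a ~5 × 10⁵ volume for a capture radius of ~3.2.
  The mean first-passage estimate MFPT ≈ V/(4πDa) ≈ 1.3 × 10⁴ time units
  against a plain-dynamics budget of 10³ predicts a ~7% hit probability
  for the unassisted search, while the selection ratchet advances the
  best copy a few length units per cycle and reaches the cutoff in ~15–25
  cycles.  The plain-dynamics reference is a single continuous trajectory
  with one ligand copy (the dilute conventional-MD control) given the
  identical total step budget (max_cycles × N × M × steps-per-frame).
  Trial counts (20 seeds) keep the whole study under ~3 minutes on one
  CPU.
- **double-well-1d**: U(x) = h(x² − 1)² + cx with h = 3, c = 1
  (barriers ≈ 4 and 2 k_BT, basin gap ΔF ≈ 1.83 k_BT by quadrature of
  the Boltzmann weight split at the barrier top).  Used to validate the
  MSM pipeline end-to-end on unbiased data: 20 segments × 4000 frames
  recover ΔF to well within 0.3 k_BT.
- **markov-2state**: exact discrete chains with stated flip
  probabilities, for lag-selection and estimator-consistency checks.

## MSM estimation choices

- Microstates: k-means (k-means++ init, fixed seed, ≤ 500 iterations,
  tolerance 1e-6) on the RC values; centers are relabeled ascending so
  state indices and profile tables are deterministic.  k defaults to 30
  and is clamped to the number of distinct values.
- Counting: sliding window at lag τ, never across segment boundaries —
  cascade segments are independent restarts, so cross-segment pairs are
  not transitions of the dynamics.
- Connectivity: estimation is restricted to the largest set connected
  under the symmetrized count graph, then states without outgoing counts
  are dropped (with a logged warning).
- Reversible estimator: the closed-form symmetrized-count estimator
  `T_ij = (c_ij + c_ji) / Σ_j (c_ij + c_ji)`, which satisfies detailed
  balance exactly with `π ∝` row sums of `C + Cᵀ`.  It is deterministic
  and sufficient at this scale; iterative reversible maximum likelihood
  is deliberately out of scope.
- Lag selection: smallest grid lag whose slowest implied timescale
  changes by < 20% (relative) against the next grid point; if none
  plateaus, the largest lag with a warning.  Complex or non-positive
  eigenvalues have no timescale (NaN); eigenvalues pinned at 1 give ∞.
- Free energies: `F_i = −k_BT ln(π_i/max π)`; zero-probability states get
  +∞; the minimum is zero by construction.

**Caveat — selection bias.**  Profiles built from cascade-selected
trajectories over-represent the approach to the bound state; they are
reported as-is, as the protocol's rough landscape, and are *not* asserted
against Boltzmann statistics.  The Boltzmann-recovery tests use unbiased
equilibrium sampling only.  Bias reweighting (TRAM/MBAR-style) is a
non-goal.

## Numerical details and degenerate inputs

- Forces are finite everywhere, including exactly at the site center
  (radial unit vector set to zero at r = 0) and at coincident particles.
- Non-finite coordinates during integration raise an error naming the
  step; infeasible copy packing raises an error naming the violated
  separation constraint and shell.
- `rmsd(superpose=True)` uses proper rotations only (Kabsch via
  `Rotation.align_vectors`); superposition of < 3 non-collinear points is
  the caller's responsibility.
- Δ counts each unordered atom pair once; the double-sum convention would
  only rescale by 2 and leave rankings unchanged.
- Composite scores: a single-component composite is the identity; with
  several components each is z-scored over the current cycle's pool
  before weighting (components with zero pool variance contribute zero).
- XYZ archives store coordinates with 17 significant digits, so resuming
  from disk is bit-exact; `cycles.csv` floats use 9 significant digits.

## Known limitations

- The toy engine validates protocol logic and sampling statistics, not
  chemistry; no claim transfers quantitatively to all-atom systems.
- The convergence criterion compares pooled histograms and can in
  principle fire during a long stall before binding; the cutoff criterion
  takes precedence whenever a bound snapshot exists.
- Kinetics (rates, mean first-passage times, committors) are out of
  scope: cascade selection destroys the time ordering that those
  estimators need.
- The external-engine adapter is a contract only; no driver for any MD
  package is included.
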