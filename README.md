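# pacsmd

Adaptive rare-event sampling of ligand-binding pathways by **parallel
cascade selection**, with a built-in toy Langevin engine and a
Markov-state-model (MSM) post-analysis — everything runs on one CPU in
minutes, no external structures or force fields required.

## The problem and the method

Ligand binding to a buried protein site is a rare event: a free ligand
spends almost all of its time diffusing, and unbiased molecular dynamics
seldom observes a complete binding pathway within an affordable budget.
Cascade selection attacks this with a ratchet instead of a bias.  Each
*cycle* runs *N* short, independent dynamics segments; every segment
records *M* snapshots; the pooled *N × M* snapshots are ranked in
ascending order of a reaction coordinate and the top *N* are used to
reseed the next cycle, with initial velocities regenerated from the
Maxwell–Boltzmann distribution at every restart.  No force is ever added
to the dynamics — selection plus velocity reshuffling alone drive the
system toward the target, and the run terminates once the best snapshot
satisfies

    RC < cutoff.

Two selection rules are built in:

- **ligand binding (LB)**: the coordinate is `d_COM`, the distance between
  the centers of mass of a ligand copy and of the binding-site atom
  selection, evaluated in a *ligand-concentrated* environment — several
  ligand copies arranged at random around the target, kept from
  aggregating by a weak compact-support repulsion.  A multi-copy snapshot
  is scored by its best copy (minimum `d_COM`).
- **targeted**: the coordinate is the Kabsch-superposition RMSD to a known
  product structure.

Also available as coordinates: the distance-matrix difference
`Δ = Σ_{i<j} |A_ij − B_ij|`, the radius of gyration `R_g`, and weighted
composites of any of these (z-scored over the current pool).

The sampled trajectories are post-processed into a free-energy profile:
*k*-means microstates on the coordinate, lag time `τ` chosen where the
implied timescales

    t_i(τ) = −τ / ln λ_i(τ)

plateau, a transition matrix estimated from sliding-window counts under a
detailed-balance constraint (counts are never taken across segment
boundaries), its stationary distribution `π`, and

    F_i = −k_B T ln( π_i / max_k π_k ),

so the most populated microstate sits at `F = 0`.  Because cascade
selection biases sampling toward the bound state, this profile is a
*rough* free-energy landscape; see `docs/methods.md`.

## Worked example

```sh
pacs fixture funnel-easy --seed 1 --out work
pacs run --config work/funnel-easy.yaml --out work/out
pacs msm --out work/out --k 8 --lags 1,2
```

which prints

```
wrote work/funnel-easy.yaml
terminated: cutoff after 5 cycles; best RC 2.658; 2 binding path(s); outputs in work/out
WARNING pacsmd.msm: implied timescales did not plateau on the lag grid [1, 2]; using the largest
lag 2, 8 connected microstates; profile written to work/out/free_energy.csv
```

Reading: starting from three ligand copies placed 7–10 length units from
the binding site, the cascade needed 5 cycles for the best copy to come
within the cutoff (`d_COM < 3.0`); its final approach distance was 2.66;
two of the final snapshots are bound, each with a complete ancestor chain
back to the reactant (in `paths.json`).  The smoke-scale run holds only
125 frames, too few for the implied timescales to plateau — hence the
honest warning from the MSM step.  The run directory also holds
`cycles.csv` (every snapshot's coordinate value, selection flag and
parent), per-cycle XYZ archives, and `manifest.json` (enough to resume or
reproduce the run bit for bit: `pacs resume --out work/out`).

The same protocol is available as a library:

```python
from pacsmd import make_fixture, run_pacs, profile_along_rc

fx = make_fixture("funnel-hard", seed=1)
result = run_pacs(fx["sampling"], fx["adapter"], fx["initial"])
model, table = profile_along_rc(result, k=20, lag_grid=(1, 2, 5))
```

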