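# Methods

`dockmd` rescored docking poses the way a post-docking MD study does: triage
a docking score table, judge pose stability over trajectories, locate the
most stable pose on a local free-energy landscape, and rescore it with
MM/GB-SA plus a geometric interaction fingerprint.  This note records the
models, the defaults and why, the numerical choices, and what the synthetic
study conditions do and do not demonstrate.

## Score triage

Inverse virtual screening docks one ligand against a receptor panel, so the
unit of analysis is the (ligand, target) complex and its AutoDock-Vina-style
affinity in kcal/mol.  The funnel applies three filters:

1. **screen** at −8.0 kcal/mol, **refine** at −9.0 kcal/mol.  Both are
   inclusive (a complex printed at exactly −8.0 passes): docking engines
   report one decimal, and treating the boundary as passing matches how
   panel studies tabulate their own survivors.
2. **validate** against the redocked co-crystallized ligand of the same
   receptor: the query must score *strictly* more negative.  A tie is not
   "better affinity", so it fails.
3. **classify**: survivors at or below −10.0 kcal/mol are strong targets;
   those in (−10.0, −9.0] are weak targets.  −10.0 itself is strong — the
   weak interval is open at its strong end.

Scores are compared as given; no rounding is applied to inputs.  Duplicate
(ligand, target) rows collapse to the best (most negative) score with a
logged collision.  The ligand–target network built from any stage carries
|score| as edge weight and is emitted as an edge-list TSV and GraphML with
lexicographic node order, so serializations are reproducible.

## Trajectory model, superposition, RMSD/RMSF

Coordinates are Å throughout, frames are 0-indexed, time is
`frame × timestep` with a 10 ps default timestep (the typical snapshot
interval for production-phase sampling).  Superposition solves the
orthogonal Procrustes problem (Kabsch) on a fit selection — degenerate
(collinear, <3 atom) selections are rejected — and applies the fitted rigid
transform to the whole frame.  The default alignment reference is the first
frame, standing in for the starting structure of a production run;
`calpha` and `backbone` selections are both available because aligning on
Cα while reporting backbone statistics is a common convention and the two
choices should not be conflated silently.

No mass weighting is used in alignment, RMSF or PCA: these are
atom-coordinate statistics, and mass weighting would change none of the
closed-form oracles while complicating comparisons.

Per-residue RMSF is the per-atom RMSF (root of the time-mean squared
deviation from the time-mean position) averaged over each residue's
selected atoms.  For the harmonic generator (below) the closed form is
RMSF = σ√3 for isotropic per-coordinate noise of scale σ.

## Pocket PCA

The pocket is frozen from a single reference conformation (the docked
pose): heavy atoms of every residue with any heavy atom within 4.5 Å of a
ligand heavy atom, plus the ligand heavy atoms.  Freezing from one frame
keeps a single displacement matrix; recomputing membership per frame would
make the coordinate space itself time-dependent.  All heavy atoms of pocket
residues are used (backbone-only is a configuration choice, not the
default).

PCA is the eigendecomposition of the covariance of mean-centered pocket
coordinates pooled over replicates.  Eigenvalues are clipped at zero
(round-off can produce −1e-17), sorted descending, and each eigenvector's
largest-magnitude component is made positive — eigenvectors are only
defined up to sign, and without a convention maps flip between BLAS builds.
Projections of the fitting frames have zero column means by construction;
the variance of the PC1 projection equals the first eigenvalue, which the
tests use as an identity check.

## Local free-energy landscape

Projections onto (PC1, PC2) are histogrammed on a regular 2D grid —
default 32 × 32 bins, a resolution chosen to resolve basins at the frame
counts the pipeline produces; the data range is padded by a 2% margin so
extreme frames do not sit on the boundary.  Bins are half-open with the
last bin right-closed, so every frame lands in exactly one microstate.

Free energies come from a weighted-histogram estimator over replicates:

    F(a) = −kT ln [ Σ_i n_ai / Σ_j N_j exp((f_j − V_aj)/kT) ]

with `n_ai` the count of microstate `a` in replicate `i`, `V_aj` the
time-averaged bias acting on `a` in replicate `j` (bias in kcal/mol,
averaged over the window (t_eq, t_sim]), and normalization constants `f_j`
iterated to a fixed point (tolerance 1e-8 kT, cap 1e4 iterations, error on
non-convergence).  The estimator includes the per-replicate frame counts
`N_j` in the denominator; for equal-length replicates this differs from
omitting them only by an additive constant, which the referencing removes.
With no bias (plain MD) the loop is skipped — all `f_j` = 0 — and F(a)
reduces to Boltzmann inversion of pooled frequencies, which a ten-line
histogram oracle verifies in the tests.

F is reported in kT (T = 300 K default, matching the production ensemble).
Unoccupied bins carry a 10 kT cap — the conventional "barely sampled"
ceiling for such maps — and occupied bins are clipped there too.  Two
reference modes exist because published maps are ambiguous about their
zero: `minimum` (global minimum at 0, the default) and `docked` (the bin
containing the docked pose's projection, conventionally (0, 0), at 0).
Neither is asserted to be *the* convention.

The minimum microstate breaks F-ties by larger pooled count, then lowest
bin index.  Its representative frame is the member frame nearest the
centroid of the bin's projections.  The pose neighborhood is the n frames
(default 100; 50 is a common alternative and both are supported) nearest
the representative in the (PC1, PC2) plane, with deterministic
(replicate, frame) tie-breaking.

## MM/GB-SA

Single-trajectory decomposition: for each neighborhood frame the complex,
receptor-alone and ligand-alone energies are evaluated **from the same
coordinates** and differenced,

    ΔG_bind = G(com) − G(rec) − G(lig),
    G = E_vdw + E_ele + G_GB + G_NP.

Because no species is re-simulated, internal bonded terms cancel exactly
and ΔE_int ≡ 0; the report records this, and records the entropy term as
*not computed* rather than silently folding an assumption into ΔG.  The
reported ΔG_bind therefore equals the enthalpy ΔH.  Born radii and surface
areas are recomputed per species, so desolvation on binding is captured
even though coordinates are shared.

Terms and constants (kcal/mol, Å, elementary charges):

* **Coulomb**: k_e q_i q_j / (ε_in r_ij), k_e = 332.0522173 kcal·Å/(mol·e²)
  (the constant of the AMBER force-field family; overridable).  ε_in = 1,
  ε_out = 80.
* **Lennard-Jones**: 12-6 with Lorentz–Berthelot combining (arithmetic σ,
  geometric ε).
* **Exclusions**: 1-2 and 1-3 pairs excluded, 1-4 pairs divided by 1.2
  (electrostatics) and 2.0 (LJ), derived from the bond graph.  These only
  matter for intramolecular sums; they cancel in the binding difference but
  are applied for completeness.
* **No distance cutoff** by default: a 10 Å cutoff belongs to MD force
  evaluation, not to rescoring a ~100-frame neighborhood; a cutoff
  parameter exists for large systems.
* **GB (HCT)**: pairwise descreening radii with offset 0.09 Å
  (Tsui–Case convention; an isolated atom's effective radius is its
  intrinsic radius minus the offset), the engulfed-neighbor branch included
  and checked against the concentric-shell limit H → 1/ρ − 1/S.  Energy
  uses the Still screening function
  f_GB = sqrt(r² + B_i B_j exp(−r²/4B_iB_j)) with self terms, no salt
  (no ionic-strength term is modelled).  Descreening can only *grow* an
  effective radius — burial removes solvent — and the tests assert this
  direction.
* **SASA**: LCPO — per-atom four-term linear combination of pairwise
  sphere-cap overlaps on solvent-expanded spheres (probe 1.4 Å), negative
  per-atom areas clamped to 0 with a notice.  The toy parameter set is the
  pairwise-exact one (P1=1, P2=−1, P3=P4=0), exact for two-sphere overlaps;
  real molecules supply published per-atom-type coefficients through the
  topology sidecar.  An independent sphere-point (Shrake–Rupley style,
  deterministic Fibonacci covering, 960 points) SASA serves as the numeric
  oracle.  The LCPO-vs-numeric comparison is run on clusters whose centers
  are ≥ 2.4× the mean vdW radius apart: spheres still bury ~30% of each
  other there, but triple overlaps — outside the pairwise set's validity
  domain — stay rare.
* **Nonpolar**: G_NP = γ·SASA + β with γ = 0.00542 kcal/(mol·Å²),
  β = 0.92 kcal/mol.  An *empty* species contributes zero to every term
  (the energy of nothing is zero); the β offset applies to species that
  exist, which makes ΔG_bind exactly 0 for a degenerate empty-ligand
  partition.

## Interactions

Contacts are residues with any heavy atom within 4.5 Å of a ligand heavy
atom, reported with per-residue occupancy over frames and the minimum
distance observed.  Hydrogen bonds use the common geometric convention —
donor–acceptor heavy-atom distance ≤ 3.5 Å and D–H···A angle ≥ 135° —
because published pose analyses rarely state their thresholds; both are
parameters.  Structures without hydrogens fall back to the distance-only
criterion with a logged caveat and no angle in the record.  Only
distance/geometry claims are made; no hydrophobic/electrostatic interaction
taxonomy is attempted.

## Synthetic study conditions

The generators define the conditions under which everything above is
verified:

* **Score tables**: uniform scores over (−12, −5) kcal/mol rounded to one
  decimal, straddling all three thresholds; co-crystal baselines drawn from
  the same range; ground-truth survivor sets computed at generation.
* **Toy complexes**: a host ring of coarse beads (default LJ σ = 1.5 Å, so
  the canonical 3 Å host–guest separation is sterically valid under the
  0.8×σ-sum no-overlap guarantee) with fully specified per-atom charges,
  LJ, GB and LCPO parameters — every energy term has a closed-form or
  brute-force reference.
* **Two-state trajectories**: iid Bernoulli choice between two reference
  conformations plus isotropic Gaussian noise.  Populations 0.8/0.2 at 1e5
  frames give ΔF = ln 4 ≈ 1.386 kT with a binomial standard error ≈ 0.008
  kT, comfortably inside the 0.05 kT recovery check.  True per-frame labels
  ride in trajectory metadata and are read only by tests — never by
  analysis code — so there is no leakage.
* **Harmonic trajectories**: reference + iid Gaussian displacements;
  RMSF = σ√3 exactly in expectation.
* Default ensemble temperature metadata is 300 K.

These conditions deliberately omit what real trajectories have: bonded
force-field correlations, anisotropic and time-correlated fluctuations,
solvent, conformational transitions slower than iid switching, and
hydrogens with realistic geometry.  Passing tests therefore demonstrate
*correctness of the estimators on their stated models*, not accuracy of
MM/GB-SA or LFEL conclusions on any real receptor.

## Pipeline and reproducibility

Stages run in the fixed order simulate → triage → stability → pca →
landscape → energy → interactions; any forward-ordered subset is allowed
and validated (including cross-stage dependencies) before anything
executes.  The global seed fans out to per-stage seeds through
sha256(seed:stage) mod 2³¹, so a stage can be rerun in isolation and
reproduce its in-pipeline behavior.  The run manifest records the package
version, per-stage parameters and the sha256 of every output; rerunning
with the same configuration and seed reproduces outputs byte-for-byte.
Stage failure writes a FAILED marker naming the stage and leaves partial
outputs in place.

Default problem sizes (2000 frames × 3 replicates for the pipeline demo;
1e5 frames for landscape recovery; 2e4 for RMSF recovery; 1e4 for PCA
recovery; 1000 tables for funnel sweeps) were chosen so statistical checks
sit well inside their tolerances while a full run stays interactive on a
laptop.

## Known limitations

* The Poisson–Boltzmann polar-solvation branch and normal-mode entropy are
  out of scope; the GB branch and enthalpy-only ΔG are what is computed,
  and the report says so explicitly.
* The energetics kernels are O(n²) dense-matrix sums — appropriate for
  pocket-scale rescoring, not for whole-protein force evaluation.
* PDB I/O targets v3.3 fixed-column conventions via MDAnalysis; exotic
  records (altlocs, insertion codes) are not round-tripped.
* The hydrogen-free H-bond fallback is a distance screen only and
  over-counts relative to an angle-aware criterion; it is flagged in logs.
* LCPO with the pairwise-exact toy coefficients degrades when three
  solvent-expanded spheres mutually overlap; dense geometries need the
  published fitted coefficient tables.
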