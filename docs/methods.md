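# Methods

## Scope and units

The package implements the analysis chain around ligand-unbinding
simulations: adaptive interacting-pair CV construction and restraint
scheduling, outcome labeling of downhill trajectories with committor-based
TS bisection, feature-set construction, and replica-ensemble classification
with RAD/RFI feature importance. It does not propagate real molecular
dynamics: MD engines enter only through file interfaces (PDB/DCD/XTC in,
colvars restraints out), and all in-package dynamics are the toy
propagators described below. Units are fixed at Å and ns throughout;
energies are kcal/mol where a force constant is involved and kT units in
the toy potentials; frame indices are 0-based; residue ids are taken
verbatim from the input file.

## Adaptive unbinding CV

A pair is *interacting* when its distance is below `d_interact` (default
3.5 Å) for strictly more than `occ_threshold` (default 50%) of a detection
segment — the boundary case (exactly half the frames) does not qualify.
The CV is the unweighted sum of the member distances, and the harmonic
restraint is `½·k·(CV − c)²` with `k` defaulting to 10 kcal mol⁻¹ Å⁻².

Three protocol details are deliberately configurable because they are
under-determined by common practice:

* **Discard rule.** Pairs are discarded when their *segment-mean* distance
  exceeds `d_discard` (default 11 Å). The mean (rather than an
  instantaneous value) is robust to single-frame excursions; every discard
  is logged per pair with the measured mean.
* **Center schedule.** The next center is
  `max(previous, CV(current frame) + delta_per_pair · N_active)`. The
  increment scales with the CV dimension, so adding or discarding pairs
  does not change the per-pair drive, and the max-clamp guarantees the
  center history is non-decreasing — an exact invariant of every run.
  `delta_per_pair` defaults to 0.1 Å per pair; the bundled funnel system
  uses 0.5 Å per pair, matched to its ~10 Å exit channel.
* **Re-admission.** A discarded pair that qualifies again under the
  ordinary detection rule is re-activated (the ledger keeps the full event
  history, and an event-log replay reconstructs the ledger exactly).

The protocol stops on ligand-centroid displacement > `stop_displacement`
(default 10 Å, the scale of a vestibule exit), on an empty active-pair set,
or after `max_iterations` (default 25).

Restraint export writes one colvars `distance` component per pair (the
colvar sums its components) plus a `harmonic` block; atom ids are written
1-based. The parser handles exactly this emitted subset and round-trips to
an equal `RestraintSpec`.

## Downhill labeling and TS bisection

The outcome score of a trajectory is a weighted sum of the CV's pair
distances (equal weights by default — the plain distance sum). The default
labeling averages the last 10% of frames and compares against two
thresholds (`IN` at or below `s_in`, `OUT` at or above `s_out`, otherwise
`UNDECIDED`); terminal-window averaging is robust to recrossings in short
paths, and a first-crossing mode is available. UNDECIDED trajectories are
excluded from IN fractions and from training sets.

Candidate windows along the path are scored by IN fraction with Wilson 95%
intervals; the TS candidate minimizes |IN fraction − 0.5| with ties broken
toward the earlier window.

## Feature sets

* **Shell pair distances.** "Within X Å of the ligand" selects protein
  heavy atoms whose minimum reference-frame distance to *any* ligand heavy
  atom is < X, then takes **all** ligand × selected-atom distances. This
  shell reading (default) reproduces the characteristic several-thousand
  feature count of a 6 Å set; the strict per-pair reading is available via
  `semantics="pair"`. An optional residue range (e.g. a loop segment) joins
  the selection regardless of cutoff.
* **Per-residue minima** ("allres"): the closest ligand distance per
  protein residue, recomputed every frame; frame-wise it is a lower bound
  on every pair feature of that residue.
* **Tracked waters.** The n (default 8) water molecules nearest the ligand
  at the reference frame are tracked *by identity* across all frames; fixed
  identity keeps the features physically continuous. Per-frame re-ranking
  is available via `track="rank"`.
* **Cartesian PCA.** Frames are superposed on the protein heavy atoms
  (least-squares rigid-body fit), the flattened coordinates pooled over the
  ensemble (optionally restricted to the analysis window so the model is
  fitted on exactly the data fed to the classifiers), and projected onto
  the top components (default 100; truncated with a warning beyond the data
  rank). Per-residue contributions are sums of squared loadings, summing to
  1 per component. A `superpose=False` path exists for pre-aligned input.
* **Water-site occupancy** uses a pure distance criterion (default 3.5 Å,
  no angle term) and also reports per-molecule continuous-residence segment
  lengths, for comparing how easily waters swap at a site.

Analysis windows are half-open `[t_start, t_end)`: a 0.05 ns window at
2×10⁻⁵ ns spacing holds exactly 2500 frames.

## MLTSA

Each of `n_models` (default 100) replicas draws its own train/validation
split of *simulations* (default 70/30; replica r is seeded `base_seed + r`
for both split and model), trains on all in-window frames of its training
simulations (every frame inherits its simulation's label), and is scored by
validation-*frame* accuracy. Standardization statistics (MLP only) come
from the training split alone; no simulation ever contributes frames to
both sides — asserted structurally in the tests.

Default hyperparameters: MLP — one hidden layer of 100 rectified units,
adam, at most 200 epochs; GBDT — 100 trees of depth 3, learning rate 0.1.
These are ordinary middle-of-the-road choices exposed in full through the
estimator's parameters.

* **RAD** removes a feature's variance by replacing its column with the
  feature's global mean over the whole data set, re-evaluates each
  replica's validation accuracy A_f, and reports `(A₀ − A_f)/A₀` averaged
  over replicas. The relative form makes profiles comparable across
  ensembles with different baseline accuracy. A constant feature has RAD
  exactly 0. A permutation variant (`method="permute"`) is provided.
* **RFI** averages the per-replica Gini (impurity-reduction) importances of
  the tree ensembles; each replica's vector sums to 1.
* **Residue aggregation** averages the values of all features carrying a
  residue id; descriptor-less features (PCA components, waters) pass
  through ungrouped.
* **Window scanning** retrains the ensemble per candidate time window to
  locate the earliest window from which outcomes are predictable.

## Synthetic systems

**Double-well committor system.** Overdamped (Brownian) dynamics — the
simplest propagator with a well-defined committor —

    x_{k+1} = x_k + (D/kT)·F(x_k)·dt + sqrt(2·D·dt)·ξ,

on `V(x) = B((x/a)² − 1)²` with minima at ±a and the saddle at 0. Defaults:
barrier B = 8 kT over a basin separation 2a = 2 Å, friction 1/ns so
D = 1 Å²/ns, integration step 1 ps. The 8 kT barrier makes commitment
essentially complete within ~0.1 ns while keeping basin escapes negligible
on the 5 ns scale, so the 0.05–0.1 ns window carries a strong but imperfect
outcome signal — calibrated once by pilot simulation and fixed. The
committor of any start point is available in closed form
(`p(x) ∝ ∫ exp(V/kT)`), and labels are first-touch basin assignments
(IN at −a, OUT at +a), extended unrecorded up to `max_extra_time` for
trajectories that have not committed by the last recorded frame.

Features: 3 of 50 (defaults) are `baseline + gain·x(t) + N(0, σ)` with
gain 1 and σ = 0.25 Å on a 5 Å baseline; the rest are baseline + noise.
Ensemble defaults mirror a ~150-trajectory, 2500-frame (2 ps spacing)
study; the tests and the acceptance script use 45 frames at 5 ps — ten
early-window frames per simulation — which leaves the frame-level signal
unchanged (it depends on the per-frame physics, not the recording density)
while keeping 100-replica trainings to seconds. What these ensembles do **not**
emulate: correlated noise between features, class imbalance,
non-monotone feature–coordinate relationships, and any real solvent or
protein physics — passing tests demonstrate the *analysis machinery*
(splits, importances, calibration), not force-field realism.

**OU-distance receptor.** Protein pseudo-atoms sit on a rigid 20 Å grid
(beyond every cutoff); each controlled ligand atom rides an exact-
discretization Ornstein–Uhlenbeck distance process (stationary mean/sd and
relaxation time per pair) along a fixed random direction from its anchor
atom, so pair occupancies are controlled exactly; waters are single-site
pseudo-molecules (every water feature reduces to one distance per
molecule). Uncontrolled atoms are parked tens of Å away.

**Funnel system.** One ligand atom caged by four pocket atoms at 2.9 Å,
with a Gaussian binding well (4 kcal/mol deep, 1.5 Å wide), harmonic
confinement to the exit axis (1 kcal mol⁻¹ Å⁻²), a soft back wall, and
channel atoms at 4 Å intervals that the ligand picks up as new interacting
pairs on its way out — exercising pair addition, discard and the monotone
ratchet together. Overdamped dynamics at kT = 0.593 kcal/mol with
D = 1 Å²/ns, a 0.0005 ns integration step and a 10-step recording stride;
the step size keeps the stiffest restraint force (k = 10 acting through up
to ~6 aligned pairs) well inside the Euler stability bound.

## Numerical choices and edge cases

* Pair detection uses a strict `>` on occupancy (the half-occupied boundary
  case is excluded) and detection requires ≥ 2 frames.
* Superposition requires ≥ 3 non-collinear selection atoms (second singular
  value > 1e-8 of the first); ligand RMSD superposes on protein heavy atoms
  first and never refits on the ligand, measuring displacement in the
  receptor frame.
* `cv_value` of an empty CV is 0; scheduling a center for an empty CV is a
  protocol error; a protocol losing all active pairs stops with reason
  `no_active_pairs`.
* TS selection ties break toward the smaller window id; windows with zero
  decided shots are excluded with a warning.
* PCA components use a deterministic full SVD; projections are compared to
  oracles up to component sign.
* RFI vectors are renormalized defensively against all-zero importance
  (degenerate single-feature trees).
* Seeds: all generators are deterministic per seed; replica r of an
  ensemble uses `base_seed + r`.

## Known limitations

* The toy propagators are overdamped and isotropic; there is no inertial
  dynamics, hydrodynamics, or solvent structure.
* The colvars parser reads only the dialect this package writes.
* The labeling thresholds and linear-combination weights of the downhill
  score are declared choices (equal weights, terminal 10% mean) — real
  studies should calibrate them against their bound/unbound reference
  structures.
* Frame-level accuracy treats frames of one simulation as exchangeable
  samples; simulation-level majority voting is available through
  `predict` but is not the reported accuracy.
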