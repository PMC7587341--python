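# Methods

This note records the models behind each module, the parameters that
matter, what the synthetic fixtures do and do not emulate, and the design
choices made where the design was genuinely open. No empirical claim is
made here that the test suite or `scripts/acceptance.py` does not itself
compute.

## Structures, superposition, RMSD

Structures are parallel per-atom arrays (id, name, element, residue,
chain, coordinates in Å, occupancy, B-factor). PDB I/O is delegated to
biotite; when a residue carries alternate locations, only the
highest-occupancy alternate is kept (`altloc="occupancy"`), the standard
preparation policy. Waters are recognised by residue name
(`HOH`/`WAT`/`TIP3`, configurable). Trajectories are a topology plus a
frame stack with a constant atom count; multi-model PDB and multi-frame
XYZ are the native formats (the XYZ reader/writer is ~30 lines and local,
since the installed trajectory libraries require a separate topology
object for XYZ).

Rigid superposition is the Kabsch algorithm via SVD with optional
weights; the proper-rotation branch is enforced with the determinant
correction, and collinear or coincident point sets are rejected (rank
check at tolerance 1e-8). RMSD is the plain root-mean-square deviation
with positional correspondence and no refitting. Element masses come from
biotite's table with a small built-in fallback.

## Hydration-site mapping

The analysis grid is fixed in space, so trajectories must be pre-aligned
on the protein (`align_trajectory` superposes every frame on a reference
frame through a fixed selection). Waters are wrapped into the primary
periodic box before cell assignment when box lengths are present. Cell
assignment is half-open floor binning: a coordinate exactly on a boundary
belongs to the higher-index cell.

* **Cell edge** — default 1.5 Å. Any value below 2.8/√3 ≈ 1.62 Å
  guarantees at most one water oxygen per cell, since two oxygens cannot
  approach closer than the ~2.8 Å O–O contact distance.
* **Stationarity** — a water counts as stationary in frame *t* when its
  RMSF over a centred window (truncated at the trajectory edges) is below
  1.4 Å. The window length is a free parameter of the method; the default
  corresponds to 1 ns of frames (derived from the trajectory's frame
  interval, forced odd, at least 3) and is reported in the map metadata.
  Whether the published grid-mapping tools average per residence event or
  per fixed window is not documented anywhere we could verify, so the
  window definition is parameterised rather than guessed.
* **Occupancies** — %Oall(cell) = 100 × (frames with any water oxygen in
  the cell)/n_frames; %O_RMSF counts only frames where the occupying
  water is stationary, hence %O_RMSF ≤ %Oall cell-for-cell by
  construction. An explicit frame-range argument restricts the analysis
  span (useful when only the tail of a simulation is equilibrated).
* **Sites** — cells with %O_RMSF strictly above 25 (threshold
  configurable), exported as water-oxygen pseudo-atoms with %O_RMSF in
  the B-factor column so viewers colour by occupancy. The crystal
  comparison considers only waters with B-factor strictly below 25 and
  flags a water matched when its nearest site lies within the distance
  cutoff.

A consequence of the fixed-window RMSF worth knowing: windows that span a
residence boundary (the water arrives or leaves) are inflated by the
transition itself, so the first/last frames of a residence event may not
count as stationary even for a perfectly ordered site.

## Conserved crystallographic waters

The ensemble is superposed on a reference through atoms matched by
(chain, residue id, atom name); the default selection is all Cα atoms —
the fitting-atom choice is exposed because reasonable alternatives
(binding-site Cα only) exist. Pooled water oxygens are single-linkage
clustered at a hard cutoff (default 2.4 Å, a typical inter-water
clustering scale; the consensus tools in this space do not publish a
canonical value). Each structure contributes at most one water per
cluster — the member nearest the cluster centroid; displaced waters are
re-clustered among themselves until the pool is exhausted. Clusters with
conservation ≥ `min_conservation` (default 1.0, i.e. present in every
structure) and, optionally, mean B-factor ≤ `b_max` are reported with the
member centroid as representative, sorted by conservation descending,
then mean B ascending, then position (deterministic ties).

*Known limitation*: single linkage chains. When a spurious water happens
to sit between two genuine sites (closer than the cutoff to both), the
two sites merge in the first pass and the keep-nearest rule can split
their members inconsistently across structures, losing one site. At the
fixture densities used here (planted sites ≥ 5 Å apart, 20 random waters
per structure) this affects roughly one ensemble in ten; the acceptance
script reports the measured recovery rate rather than hiding it.

## Supervised dynamics

The controller implements recognition-event supervision: dynamics
proceeds in steps of `step_duration` (default 300 ps) recorded at
`n_checkpoints` equally spaced checkpoints; the ordinary-least-squares
slope of the ligand–site centre-of-mass distance against time decides the
step's fate. Accepted (slope strictly below the threshold, default 0, or
final distance already below the binding distance): the new coordinates
commit and the rejection counter resets. Rejected: the segment is
discarded, the previous coordinates are restored and a fresh seed is
drawn — identical seeds would loop forever in a deterministic backend,
and the original method specifies only a restart from the previous
coordinates. The run ends *bound* when the distance drops below 5 Å
(supervision is then switched off and a classical extension, default
25 ns, is appended and recorded at the same checkpoint spacing) or
*failed* after 30 consecutive rejections. The slope criterion is our
operationalisation of "distance likely to shorten"; the checkpoint count
and threshold are config fields, not claimed canonical.

The closed-form OLS slope is used deliberately instead of a polynomial
fit: it returns exactly zero for constant distances, so the strict accept
inequality behaves correctly at the boundary.

Crucially, supervision never applies a force. Accepted-segment
coordinates are bit-identical to what the raw propagator produces for the
same (state, seed) pairs — `replay_accepted_segments` verifies this, and
the per-event seed log makes any committed trajectory replayable.

Distance is measured between the ligand centre of mass and a user-defined
site centre (the site-centre convention; the original formulation used
the whole-protein centre of mass — both are supported through the
propagator's `distance` hook, and the site centre is the natural choice
when the binding site is defined from a reference ligand's centre of
mass).

**Toy propagator.** An overdamped Langevin point ligand in an isotropic
Gaussian well, U(x) = −A·exp(−|x−x₀|²/2σ²), optional rugged cosine
perturbation, update x ← x − (∇U/γ)Δt + √(2kTΔt/γ)·η. Units are Å, ps
and kcal/mol; kT/γ is the diffusion constant in Å²/ps. It reproduces the
two limits the controller tests need — pure gradient descent at kT = 0
and free diffusion (MSD = 6·(kT/γ)·t) at A = 0 — and nothing more: no
solvent structure, no internal ligand degrees of freedom, no force field.
Passing tests on this backend validate the *controller*, not any claim
about real molecular systems.

**Funnel preset** (`fixtures.FUNNEL_PRESET`): A = 5 kcal/mol, σ = 3 Å,
γ = 1, kT = 0.6, dt = 0.05 ps, start 30 Å, paired with 5 ps supervision
steps, 5 checkpoints and a 400-step attempted budget (2 ns). The geometry
does the work: a freely diffusing particle started at 30 Å reaches a ~5 Å
capture radius with probability bounded by ~5/30 even in unlimited time,
so plain dynamics within the budget binds rarely (< 0.2, estimated over
50 seeds by brute-force simulation before the preset was frozen), while
the supervision ratchet — keep inward segments, retry outward ones —
binds essentially always. The preset is documented, not tuned per run.

## Pose selection

Features are flattened ligand heavy-atom coordinates after protein
superposition onto a common reference; no internal-coordinate
featurisation (the quantity being clustered is the ligand's *position*).
Denoising runs OPTICS with `min_samples` at the sklearn default scale
(5) — tying it to the cluster-size floor makes the xi extraction absorb
trailing outliers — then flags as noise: xi-labelled outliers, residual
clusters smaller than `min_cluster_size` (default 20), points whose
reachability exceeds the `reachability_quantile` (default 0.99) of the
finite reachabilities, and points whose core distance exceeds that same
threshold (an absolute density floor; xi alone is purely relative and
will call a uniform scatter one cluster). If everything is flagged the
operation fails with an explicit no-dense-region error rather than
returning an empty ensemble.

K-means (k-means++ init, 10 restarts, fixed seed) partitions the retained
sets; k defaults to 3, matching the three poses a docking protocol
typically returns, and is reduced with a warning when fewer sets exist.
Each cluster's representative is its **medoid** — the member nearest the
k-means centre — never the centre itself, so representatives are always
physically realised geometries; the alternative reading ("centroid" as
the k-means mean) is deliberately not used. Ranking applies a pluggable
scorer (lower = better) with ties broken by cluster population; the
shipped contact scorer counts ligand/protein heavy-atom pairs within
4 Å as −1 each and penalises sub-2 Å clashes at +10 each. It is a
structural stand-in for end-point binding-energy rescoring (MM/GBSA-class
methods need a force field and a solvation model, outside this package's
scope); the ranking contract, not the energy model, is what the pipeline
preserves.

## Evaluation

`pose_rmsd` superposes the predicted complex onto the reference through a
binding-site selection — default: reference Cα atoms within 8 Å of the
ligand — then computes ligand heavy-atom RMSD with atoms matched by name
and no refitting on the ligand, making the metric invariant under global
rigid motion of the prediction. No ligand-symmetry correction is applied
by default (symmetry-aware RMSD silently changes numbers); an explicit
name map enables manual equivalences. Success curves report, per RMSD
threshold t (default grid 0–6 Å, step 0.1), the fraction of complexes
whose best pose among the top-N ranks has RMSD ≤ t; top-1 uses the rank-1
pose only. Normalisation is per complex (minimum over the top-N poses),
with the per-pose alternative left to the caller by filtering ranks. The
correctness call is strict: a complex counts correct only when its rank-1
RMSD is strictly below 2 Å.

## Synthetic fixtures

All generators are pure functions of (arguments, seed): regeneration is
bit-identical, and each returns a JSON-serialisable truth record
sufficient to score the downstream analysis. The protein stand-in is a
20-residue polyalanine helix with schematic N/CA/C/O/CB geometry — enough
to exercise name-based selections, superposition and contact scoring
realistically, with no downloads.

* *Water trajectories*: tethered waters are Gaussian jitter (sd 0.3 Å by
  default) around fixed points placed near canonical-grid cell centres
  (uniform ±0.25 Å), so the planted spread stays inside one cell; bulk
  waters random-walk at 1 Å per axis per frame and wrap in the periodic
  box. Planted points closer than the 2.8 Å O–O contact distance are a
  generation error. Defaults: 500 frames at 20 ps/frame, 3 tethered + 50
  bulk in a 24 Å box (tests use 200-frame, 18 Å variants for speed; the
  truth record always carries the exact parameters used).
* *Crystal ensembles*: 11 structures, 4 conserved waters (jitter 0.3 Å,
  B ∈ [5, 20]) plus 20 random waters (B ∈ [30, 80]) each, the whole
  structure under a random rigid transform per crystal so alignment is
  actually exercised; a missing-rate option drops conserved waters for
  partial-conservation studies.
* *Funnel systems*: the preset above, with the start direction drawn per
  seed on the 30 Å sphere.
* *Pose ensembles*: a fixed random ligand template (8 atoms) translated
  to k = 3 centres 8 Å apart with per-atom Gaussian jitter (σ = 0.5 Å,
  separation/σ = 16), plus 5% noise poses whose atoms are uniform in the
  bounding box — dense nowhere in the 24-dimensional feature space, so
  planted noise is unambiguous.

What the fixtures do **not** emulate: hydrogen-bond geometry, water
exchange kinetics, ligand flexibility, force-field energetics, crystal
packing. Green tests therefore demonstrate the correctness of the
algorithms under controlled conditions, not predictive accuracy on real
protein–fragment systems.

## Problem sizes and numerical choices

The shipped test suite and acceptance script run everything at desk
scale, chosen so the full validation completes in a few minutes on one
CPU: 200-frame water trajectories (50 seeds), 11-structure ensembles
(20–50 seeds), 20 supervised + 20 unsupervised funnel runs, 50 pose
fixtures, a 5-complex end-to-end pipeline. Degenerate inputs have defined
behaviour throughout: empty water sets warn and return empty results,
all-identical pose sets cluster with a warning, fewer sets than k reduces
k, scorer failures drop the pose with a warning, and contract violations
(mismatched point counts, collinear superposition targets, invalid
windows, non-positive time steps) raise typed errors. Ties are broken
deterministically everywhere (stable sorts; conservation/B-factor/position
ordering for waters; population for equal pose scores), and all
randomness flows through explicit integer seeds kept below 2³¹.
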