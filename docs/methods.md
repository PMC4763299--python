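# Methods

This note documents the models, estimators, numerical choices and known
limitations of `statescan`, in the spirit of a package methods appendix.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ensemble representation

A trajectory is a shared topology (atom names, residues, chains, elements,
PDB v3 conventions) plus a dense `(frames, atoms, 3)` coordinate array in
Å.  Multi-model PDB is the only trajectory format; parsing and writing go
through biotite, with three deliberate policies: ATOM and HETATM are both
first-class (waters and Mg²⁺ are kept unless a selection excludes them),
alternate locations keep the first altloc only so topology is
deterministic, and models with inconsistent atom counts are rejected
before parsing.  Residue numbering is untouched PDB numbering — "residue
60" always means `residue_seq` 60 — and nucleotide phosphates use the
PA/PB/PG, O1B…O3G naming, because every diagnostic monitor is defined in
those names.

Selections are a small boolean mini-language (`name`, `resname`, `chain`,
`resseq` with ranges, `hetero`, `water`, `protein`, and/or/not with
parentheses).  They resolve against the topology only, so a selection is
one ordered index list for all frames of a trajectory.

## Superposition and fluctuation metrics

Superposition is the Kabsch closed form via SVD with reflection
correction (smallest singular direction flipped when needed), so the
returned matrix is always a proper rotation.  Fit sets must contain at
least three non-collinear atoms.

RMSD series superpose each frame on a *fit* selection and measure over a
possibly different *measure* selection; region-restricted RMSD (global Cα
fit, switch-region measurement) is how local plasticity is quantified
without letting the mobile region bias the frame alignment.  RMSD is
geometric (unweighted) over the selected atoms.

RMSF uses the iteratively re-aligned ensemble mean as reference: align all
frames to the current mean on the fit selection, recompute the mean,
repeat until the RMS shift of the mean is below 1e-4 Å (at most 10
iterations — in practice two or three).  Per-atom RMSF is
√⟨|r(t) − ⟨r⟩|²⟩; residues average their selected atoms.  The mean
structure, not a crystal reference, is the standard fluctuation
definition; for iid isotropic noise of width σ per coordinate it converges
to σ√3, which the tests verify at 2000 frames within 5%.

## Cross-correlation

The DCCM uses the same iterated-mean alignment, then the uniform time
average for ⟨·⟩.  One global rigid transform applied to every frame
therefore leaves the map unchanged.  Atoms with (numerically) zero
displacement variance — threshold 1e-12 Å², i.e. strictly static atoms —
produce NaN rows/columns with a warning rather than silent zeros: zero
would assert "uncorrelated", which is false information.  Output is
clipped to [−1, 1] against rounding, the diagonal forced to exactly 1.

## PCA

Frames (optionally strided; the stride helper converts from ps when the
frame interval is known, mirroring sparse snapshot sampling) are aligned
to a fixed reference structure — by design the supplied reference, not the
ensemble mean, unlike RMSF/DCCM — on an alignment selection that defaults
to the analysis selection.  The 3N×3N covariance uses the uniform average
(1/F), so the sample variance (ddof 0) of training projections equals the
eigenvalue exactly.  Full symmetric eigendecomposition (`eigh`) is used;
3N stays in the hundreds at this package's scale, so no truncated solver
is warranted.  Tiny negative eigenvalues are clipped to zero.  Eigenvector
sign is fixed by making each mode's largest-magnitude component positive,
which makes the decomposition — and every projection — deterministic.
A variance-free ensemble is rejected at fit time.

How many PCs delimit conformational states is left to the caller: the
module reports projections; state calls belong to the d1/d2 classifier.

## Clustering

Snapshot dissimilarity is the minimum (superposed) pairwise Cα RMSD,
computed in closed form from the reflection-corrected singular values of
per-pair cross-covariances, evaluated in row blocks (batched 3×3 SVDs) so
5000-frame matrices stay tractable.  Clustering is standard average
linkage (UPGMA) on the full frame-frame matrix — scipy's agglomeration —
cut at the height threshold, i.e. merging stops when the minimal
inter-cluster average distance exceeds the threshold.  The
"distance-to-average" reading of the threshold is deliberately *not* the
clustering criterion: cluster averages (computed after aligning members
to the first member and once re-aligning to the provisional mean —
averaging unaligned coordinates would mix rotation into the shape
average) are used only to pick each cluster's representative, the member
frame with minimal superposed RMSD to that average, ties to the lowest
frame index.  Labels are dense, numbered by first frame appearance, so
results are reproducible and invariant (up to relabeling) under frame
permutation.

## State classifier

The diagnostic is two internal distances — no superposition: d1 from the
switch-II anchor Cα (residue 60) to the nucleotide Pβ, d2 from the
switch-I anchor Cα (residue 35) to Pβ.  Default intervals: *active*
d1 ∈ [5.8, 8.0) Å, *inactive substate 3* d1 ∈ [8.0, 10.0) Å, otherwise
*unassigned*.  Intervals are half-open so the shared 8.0 Å boundary
assigns unambiguously.  A d2 gate ([6.0, 8.0) Å, a GAP-complex-context
value) exists but is off by default, because the operative discrimination
is carried by d1 while d2 differs only weakly between the two states this
classifier names; inactive substates defined by switch-I uncoupling are
expressible through the same configuration but ship without numeric
defaults.  Unassigned frames are always reported, never dropped, so frame
counts are conserved.  Occupancies carry binomial standard errors
√(p(1−p)/n).

Distance densities use 0.1 Å bins on [4, 14) Å by default (≥ 20 bins per
2.2 Å-wide state interval); out-of-range values are excluded from the
density but tallied and logged, so the in-range density integrates to 1.

## Solvent accessibility and contacts

SASA is Shrake–Rupley with a deterministic golden-spiral point lattice
(default 960 points) on each probe-expanded sphere (probe 1.4 Å; Bondi-
style element radii with a 1.7 Å fallback).  Occluders are the union of
target and context atoms minus the atom itself, so a multi-atom ligand
self-occludes and an empty context yields the isolated-group SASA.  The
default context for nucleotide exposure is the protein only — solvent
must not occlude solvent accessibility.  Quadrature error at 960 points
is verified under 0.5% against a 3840-point evaluation and under 1%
against the closed-form sphere and two-sphere-cap cases.

Hydrogen bonds are heavy-atom donor–acceptor distances (3.5 Å default,
no angle term): snapshots may lack hydrogens, and any angle criterion
would silently depend on reconstructed protons.  Salt bridges are charged
N–O pairs within 4.0 Å (community convention).  A water bridges two sites
when both legs are within the H-bond cutoff.  The catalytic report
aggregates Q61 carbonyl–Pγ distance, minimum arginine NH1/NH2 distances
to α- and γ-phosphate oxygens, the amide–carbonyl–Pγ angle, and contact
occupancies.  The three-atom angle is stated without a vertex in common
usage; the implementation takes the middle-listed atom (the carbonyl
oxygen) as vertex, and all three atoms are explicit configuration so any
other convention is one override away.  A histidine-61 variant is pure
configuration (ND1/NE2 selections) — no code change.

## Synthetic two-state generator

The generator emulates the statistical structure of a two-state GTPase
ensemble, not its physics.  The base fold lays 70 Cα atoms along a
constant-speed spherical spiral (radius 11 Å, 3.8 Å steps) with backbone
N/C/O placed along local tangents; the switch-II (residues 59–67) and
switch-I (32–38) segments are pulled toward an interior pocket point with
a cosine-ramped window (full displacement inside the segment, 3-residue
decay outside) so the chain stays continuous, placing the diagnostic
anchors at exactly d1 = 6.8 Å and d2 = 6.5 Å from the pseudo-nucleotide
Pβ.  The ligand (PA/PB/PG plus α/β/γ oxygens; the GDP variant simply
lacks the γ group), an Mg²⁺, a chain-B arginine-finger residue pre-placed
for salt bridges, and waters (one bridging the Q61 carbonyl and a
γ-oxygen, the rest on an outer shell) complete the system.

The two basins differ only in switch placement.  Closed is the base;
open moves switch II rigidly so its anchor sits exactly 9.0 Å from Pβ —
combining radial retraction with a 4 Å lateral swing, the generator's
rendering of the large switch-II rearrangement that distinguishes the
open conformer — and retracts switch I by 3 Å from the nucleotide.  With
the default 0.3 Å per-coordinate noise this puts the inter-basin Cα RMSD
(≈ 2 Å) well above the 1.5 Å clustering threshold and the intra-basin
spread (≈ 0.7 Å) well below it, which is the regime the two-state
construction is meant to provide; it also guarantees, by construction,
that open-state nucleotide SASA exceeds closed-state SASA.  d1 means sit
inside the two classifier intervals with ±3σ√2 ≈ ±1.3 Å spread, so
boundary leakage is at the percent level — visible in recovery scores,
never dominant.

State switching is a stationary two-state Markov chain; the helper builds
the row-stochastic matrix from a target closed-state occupancy and a
mixing rate (default 0.2, i.e. per-frame autocorrelation 0.8; burn-in is
unnecessary because the initial state is drawn from the stationary
distribution).  Noise is iid isotropic Gaussian per atom within a state —
deliberately, so RMSF and DCCM have analytic expectations and coherent
motion enters only through state switching.  A single seeded generator
stream drives everything; identical seeds give bitwise-identical
trajectories and PDB files.

What the generator does *not* emulate: bonded structure and sterics,
anisotropic or collective thermal motion, solvent dynamics, and any
force-field energetics.  Passing recovery tests therefore demonstrates
the estimators' correctness and calibration on a known two-state process,
not performance on real MD output.

## Problem sizes

The recovery study uses 5000-frame ensembles (20 seeds across closed-state
occupancies 0.3/0.5/0.9) for the classifier, with clustering and PCA on
every 10th frame — 500 snapshots, matching the spirit of sparse snapshot
analysis — and exposure measured on 15 frames per state per seed at 960
quadrature points.  These sizes make the whole acceptance study a
minutes-scale, single-CPU computation while keeping sampling error far
below every acceptance margin.

## Known limitations

- Binary trajectory formats (DCD/XTC/NetCDF) and topology/parameter files
  are out of scope; convert to multi-model PDB first.
- The H-bond detector's distance-only criterion over-counts relative to
  angle-aware detectors on hydrogen-bearing structures.
- Average-linkage clustering materializes the full pairwise matrix
  (O(F²)); stride first for very long trajectories.
- The classifier is a fixed-interval rule by design; it does not estimate
  modes from the data (no mixture fitting), so miscalibrated intervals
  show up as systematic unassigned mass — inspect the d1 histogram.
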