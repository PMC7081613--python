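# Methods

This note documents the models, numerical choices and limitations of the
`wormid` pipeline in one place.  Units are micrometres throughout; the
corrected coordinate frame is x = anterior–posterior (anterior negative),
y = dorsal–ventral (dorsal positive), z = left–right.

## Posture correction

Each animal's nucleus cloud is corrected in four stages.

**PCA alignment.**  The cloud is centred and rotated into its
principal-component frame; the first component (largest variance) is the
AP axis.  Axis signs are fixed deterministically (largest-magnitude
component positive, right-handed frame) so the result is reproducible.
Clouds of fewer than 4 cells, or with a vanishing third singular value
(collinear/coplanar), are rejected.

**Quadratic straightening.**  Body bend is modelled as two independent
least-squares quadratics, PC2(x) and PC3(x).  Each cell is shifted by the
curve value at its own AP coordinate — a rigid per-slice shift, so
cross-sections (the DV–LR plane) are never rescaled or deformed.  No
arc-length reparameterization is applied; for bends up to ~10% sagitta-
to-length the residual after straightening is below 1 μm per cell (the
regime asserted in the tests).  Stronger bends leave a nonrigid residual
that the later landmark alignment cannot remove (it is a similarity
transform); this is the main accuracy limit of the correction.

**Roll and origin.**  Cells are projected to the DV–LR plane; cells below
the median radius are excluded (the dense core carries no direction
information) and a von Mises kernel density (κ = 100, i.e. kernel sd
≈ 0.1 rad) over the remaining cell angles is minimized — first on a
512-point grid, then refined by bounded scalar optimization.  The
minimizing direction is dorsal and is rotated to +y.  A smooth density
with optimizer refinement is used instead of a histogram argmin because
the argmin is only bin-resolution accurate: the full pipeline is required
to be idempotent to 1e-6 μm, and a rotation-equivariant smooth estimate
achieves that while a binned one cannot.  If the angular density is flat
(relative relief < 1e-3), a warning is emitted and no roll is applied.
The AP origin is the mode of a Gaussian kernel density along x
(bandwidth 5 μm), refined the same way.  Anterior is the side holding
more cells within ±40 μm of the mode; when the cloud must be flipped,
x and z are negated together so the transform remains a proper rotation
and chirality (left/right) is preserved.

**Fine alignment.**  When reference positions of named landmark cells
(e.g. dye-stained neurons) are available, a 7-parameter similarity
transform (rotation, translation, isotropic scale; Umeyama's closed form)
is fitted on the shared names and applied to all cells.  Fewer than
3 shared landmarks: the sample is returned unchanged with a warning.

## Positional statistics

Per-cell distributions are plain sample means and covariances
(denominator n−1); covariance is withheld for single observations and
flagged unreliable for counts ≤ 3.  The naive mixture assignment
evaluates an equal-prior Gaussian mixture over all components with a
covariance and names each cell by the maximum-density component
(singular covariances regularized by +1e-6 μm² on the diagonal; exact
ties resolve to the lexicographically smaller name).

Relative-position variation of a pair is V(X,Y) = det cov(X−Y) over
co-observing animals; pairs with n ≤ 3 are skipped.  Determinants are
clamped at zero — near-singular difference covariances can produce tiny
negative determinants by roundoff, and V is nonnegative by construction.
The permutation test flags a pair "less varying" iff the observed V is no
larger than V under every evaluated permutation of X's animal order:
all n! permutations (identity included — harmless under ≤) for n ≤ 10,
otherwise up to 1e7 permutations drawn uniformly with replacement from
the symmetric group (seeded).  Permutations are evaluated in vectorized
batches.

## Landmark-panel optimization

The positive ratio p_X = n_X/m is the fraction of tested animals in
which a promoter labels cell X; stability s is the mean of p_X over
cells with p_X > 0.  The checkerboard metric M sums, over unordered cell
pairs with different channel-label vectors, an isotropic trivariate
Gaussian density of their distance with σ = 9.6 μm per axis.  The
normalization constant is kept (it scales M globally; rankings are
unaffected).  Sparseness of one promoter is M with binary
expressed/not-expressed labels.

Panels for two distinguishable channels are enumerated as ordered
promoter pairs (n(n−1)) plus singleton-plus-pair triples with the
singleton in channel 1 (n·C(n−1,2)); since M is invariant under swapping
the two channels, the mirrored triple arrangement is redundant and this
convention enumerates exactly 20,825 assignments for 35 promoters.  For
ranking, a cell counts as positive for a channel when the maximum p_X
over the channel's promoters reaches a threshold (default 0.5,
configurable), and cells are scored at their reference mean positions.
Ties in M break by the lexicographic panel key.

## Atlas synthesis

The displacement flow between two animals is the Gaussian-kernel-weighted
average of the displacements of their shared cells, with diagonal kernel
Σ = diag(σ²) and σ = 9.6 μm per axis by default.  Weights are computed
in log space (the diagonal normalization constant cancels) and always
sum to one; if every kernel underflows at an evaluation point (total
weight < 1e-300), the nearest shared cell's displacement is used with a
warning.

Assembly: a random order of animals is drawn; the first animal seeds the
atlas with its named cells unchanged and is rejected (order resampled)
if it carries fewer than 60 annotations (configurable — scaled-down
cohorts in the tests use 40).  Each later animal contributes its
not-yet-present names mapped through the flow computed from the names it
shares with the *current* atlas; once placed, a name never moves.
Animals sharing fewer than half of their annotated cells are deferred
and retried in passes until a pass makes no progress; never-mergeable
animals are dropped with a warning.  Names still missing can be filled
from a reference position table after a similarity alignment on shared
names; filled names are recorded separately.  Defaults are 3000
generated atlases and 500 voting rounds; tests and examples scale these
to tens to keep runtimes in seconds, which the error-rate comparisons
tolerate because every contrast is computed within the same pool.

`validate_atlases` compares the atlas population against the data
population per name (distance of mean positions; ellipsoid-volume ratio
√(det cov_atlas / det cov_data)) and per pair (ratio of relative-position
variations, flagged when the data co-observation count is below 10).
`tune_sigma` grid-searches the kernel width against a surrogate
objective — mean per-name mean-position distance plus mean |log volume
ratio| — with ties resolved to the smallest σ.  The surrogate is weakly
informative for wide kernels on strongly jittered cohorts (the objective
flattens above σ ≈ 10 μm), so σ should be treated as an empirical
setting; the default 9.6 μm is always available without tuning.

## Annotation

The matching cost between target cells and atlas names is
w_distance·(Euclidean distance) + w_landmark·(per-channel Hamming
distance of binarized landmark bits), defaults w_distance = 1,
w_landmark = 20 (one fully mismatched 2-channel fingerprint costs 40,
dominating any plausible positional distance).  Human corrections make a
fixed cell's row and its name's column infinite except at their
intersection; fixing two cells to one name is an error.  The assignment
is solved with `scipy.optimize.linear_sum_assignment`; rectangular
matrices leave the surplus side unmatched, and when no complete matching
of the smaller side avoids the infinities, infinite entries are replaced
by a large finite penalty and the forbidden assignments are dropped from
the result (maximal feasible matching).  Rows with no finite entry raise,
listing the blocking cells.

Voting draws n_rounds atlases uniformly without replacement from the
pool (with replacement when the pool is smaller) and ranks candidate
names per cell by vote count, ties broken by lower mean position cost of
the supporting rounds, then lexicographically.  Cells are estimated
independently, so duplicate names across cells are possible;
`resolve_unique` removes duplicates by a second assignment on the cost
(n_rounds − votes).  The rank-R error rate is 1 − N_correct/N_annotated
over cells with a ground-truth name; excluded (non-neuronal) cells never
enter.

Cross-validation splits animals into k seeded folds, builds atlases from
training animals only and scores held-out animals with at least a
configurable number of named cells (default 30) against their own
annotations.  Sequential correction repeatedly fixes one randomly chosen
wrong rank-1 cell and re-votes; the voting atlas subset is held fixed
across iterations so successive estimates differ only through the added
constraints.  Each fixed cell is itself corrected, so the correct count
never falls below the number of corrections and the loop terminates at
zero error; the *mean* gain per correction exceeds one on cohort
averages, while single trajectories fluctuate around it because a new
constraint reshuffles the global matching.

## Synthetic data

The generator emulates the statistical structure of a head-neuron
position dataset.  The ground-truth map packs ~200 named cells (minimum
centre spacing 1.5 μm, rejection sampling) into a 60×30×30 μm head
ellipsoid, densest mid-head (a lateral-ganglion-like cluster) with a
uniform anterior tail — the asymmetry that makes the anterior-direction
heuristic well posed — and an empty 50° dorsal wedge so a sparsest
direction exists.  Per animal: iid Gaussian jitter (default sd 1.35 μm
per axis, set from the scale of measured shortest ellipsoid axes of real
corrected data, ≈ 2.7 μm = 2σ), optional correlated pairs sharing a
common displacement, binomial cell dropout (default detection rate
0.97), partial annotation (one cell-specific promoter per animal, each
of its names kept with the promoter's positive ratio, plus an
always-named dye-like subset, default 18% of cells), landmark channel
bits copied from a ground-truth bit per cell (flip noise default 0), a
random quadratic bend (|a| ≤ 0.005 μm⁻¹, i.e. ≤ 10% sagitta-to-length)
and a uniformly random rigid placement.

What the generator does **not** emulate: organ-placement covariation
(e.g. pharynx position shifting whole cell groups), anisotropic or
position-dependent variation, detection artifacts (merged/split nuclei),
annotation errors, and realistic promoter expression structure (subsets
are random rather than lineage-determined).  Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under the stated variation model, not the error rates to expect on real
microscopy data.

## Problem sizes and determinism

Tests and the acceptance script run scaled-down study conditions chosen
as the package's own defaults for fast, deterministic verification:
80-cell maps, cohorts of 8–24 animals, 6–40 atlases and ≤ 40 voting
rounds, with the seed-annotation floor lowered to 40 accordingly.  All
randomness flows through `numpy.random.default_rng` seeds; fixed seeds
reproduce atlas sets, folds, votes and correction curves bit-for-bit.
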