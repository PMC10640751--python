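# Methods

This note documents the algorithms, parameter choices and numerical
conventions behind `plantcloud`, and what the synthetic test bed does and
does not establish about real data.

## Data model

A plant cloud is an `(N, 3)` coordinate array (units follow the scan,
typically mm) with optional per-point labels: a semantic class in
`[0, C)` (e.g. stem system vs leaves, per species) and an instance id
with `-1` meaning "no instance". Instances are only meaningful for leaf
classes; the stem system is fully connected and carries no instances.
`normalize_cloud` maps a cloud to zero centroid and unit maximum radius,
which makes distance-parameterised settings (voxel edges, SBF thresholds)
transferable across acquisitions; it is idempotent and leaves labels
untouched.

Interchange formats are labeled-XYZ text (`x y z [sem [ins]]`, sem before
ins, chosen as the simplest lossless convention), PLY (ASCII and binary
little-endian, coordinates stored float32, labels as int32 properties
`sem`/`ins`, with `label`/`instance` accepted on read), and HDF5 batches
(`data` of shape `B × n × 3` float32, `sem`/`ins` of shape `B × n`),
the layout point-level networks consume. The PLY support is a minimal
vertex-only codec written here; it intentionally covers exactly the
dialects the pipeline produces and reads.

## Down-sampling strategies

**FPS.** Standard greedy max–min selection: the first point is the given
start index or seed-chosen uniformly at random; each later point
maximises its minimum distance to the already-selected set, maintained by
the incremental nearest-selected-distance update (one vectorised distance
pass per selected point, `O(Mn)` total). Argmax ties break to the lowest
index, making runs bit-reproducible. An alternative reading of FPS as
"minimise the sum of distances" circulates in the literature; it is
inconsistent with the `O(Mn)` greedy structure and with common usage, so
the max–min rule is implemented.

**RS.** Sequential (one-pass) random sampling: with `m` points left to
take out of `N'` unvisited, the skip count `S` has CDF
`F(s) = 1 − A(N'−m, s+1)/A(N', s+1)` (falling factorials). One uniform
variate `V` is drawn per *selected point*, and `s` is incremented from 0
until `A(N'−m, s+1) ≤ A(N', s+1)·V`; the permutation ratio is updated
multiplicatively by `(N'−m−s)/(N'−s)` factors, so no factorials are ever
formed. Drawing a fresh variate at every increment of `s` — a formulation
that also circulates — does *not* produce uniform subsets (at `N=3, m=1`
it gives skip probabilities 1/3, 4/9, 2/9); the one-draw-per-selection
form is used and is validated against an exhaustive enumeration oracle by
chi-square at `N=6, n=3`. Output indices are strictly increasing, so RS
also preserves acquisition order.

**UVS / VFPS.** Both build a half-open axis-aligned voxel grid
(`cell = floor((p − origin)/l)` per axis; origin defaults to the
per-axis minimum). UVS keeps, per occupied voxel, the real member point
nearest the voxel's geometric centre (ties to the lowest index); VFPS
emits the gravity centroid of the members, a synthetic point that by
convexity lies inside its cell. Both then run seeded FPS on the voxel
stage's output to reach the exact target `n`; fewer occupied voxels than
`n` is an error pointing at `auto_voxel_size`. VFPS output has no source
indices; labels are transferred by per-voxel majority vote with ties
broken to the smallest label id — a centroid may genuinely straddle
organs, and majority vote is the least surprising convention.

**SBF.** The edge/internal split used by 3DEPS is a k-NN
centroid-displacement filter: for each point take its `k` nearest
neighbours, compute the displacement `d` of the neighbourhood centroid
from the point and the mean neighbour distance `r̄`, and flag the point
as edge iff `d/r̄ > τ`. For an interior point of a locally symmetric
sampling the centroid shift cancels (`d/r̄ ≈ 0`); at the end of a
regularly spaced segment all neighbours lie to one side and
`d/r̄ = 1 > 0.5`. Defaults `k = 20`, `τ = 0.5`, both exposed. This is a
deliberately simple, testable boundary operator; other boundary
detectors (e.g. normal-discontinuity or angle-gap criteria) would slot
into the same interface, and the downstream 3DEPS bookkeeping is
agnostic to the filter's internals.

**3DEPS.** Split by SBF into edge set B and internal set C; the edge
target is `n_e = round(ratio·n)` (half-away-from-zero), internal target
`n − n_e`. If a part is smaller than its target the whole part is taken
and the deficit spills to the other part. Each part is reduced by FPS
with seeds derived from the base seed via `SeedSequence`, and the parts
are concatenated (edges first). Useful ratios are 0.1–0.5; beyond that
the interior becomes so sparse that organ bodies lose support.

**Helpers.** `auto_voxel_size` bisects a single scale factor on the
bounding-box extents (optionally forced cubic) until the occupied-voxel
count lands in `[n_target, 2·n_target]`; it is deterministic, capped at
60 iterations, and fails loudly for degenerate clouds with fewer unique
points than the target. `rs_then_fps` composes RS down to an
intermediate size (default 10⁶; skipped when the cloud is already
smaller) with FPS to the final count, with index bookkeeping back into
the original cloud — the practical recipe for very dense scans where
plain FPS is too slow.

All strategies take an explicit integer seed, derive any internal
randomness deterministically from it, and return exactly `n` points with
carried labels; index-returning strategies return unique, valid indices.

## Segmentation metrics

Semantic metrics come from per-class point counts: Precision
= TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R), IoU = TP/(TP+FP+FN);
per class, F1 = 2·IoU/(1+IoU) holds identically and is asserted as an
internal consistency check. The summary is the unweighted (macro) mean
over classes; classes with no points on either side are excluded from
the mean rather than scored 0, and a micro-averaged variant is available
behind a flag. Within a class, an empty denominator scores 0.

Instance metrics treat ground truth and prediction as partitions of
point-index sets, each instance tagged with a semantic class (majority
vote of its points when instances arrive unclassed). Per instance-bearing
class: every ground-truth instance contributes its best IoU against the
predicted instances of that class (0 if nothing overlaps); mCov averages
these uniformly and mWCov weights by the instance's share of the class's
points, so mWCov = mCov exactly when all instances are equal-sized.
mPrec/mRec count predicted instances matched to a ground-truth instance
at IoU > 0.5, divided by the number of predicted (resp. ground-truth)
instances, then averaged over classes; a class with no predictions
contributes precision 0. Because the threshold exceeds 0.5, a predicted
instance can match at most one ground-truth instance, so no explicit
assignment (Hungarian) step is needed — this set-theoretic fact is
asserted at run time. The small-cluster filter discards predicted
instances below 1% of the mean predicted-instance size, the mean taken
before any removal; it is applied before metric computation when used,
mirroring its place in inference pipelines.

## Rank scoring

Given a strategies × metrics table in %, each column is ranked descending
(all supported metrics are higher-is-better) and the top three positions
receive 3/2/1 points for Precision, Recall, mPrec and mRec — metrics that
do not individually summarise quality — and 6/4/2 for the comprehensive
F1, IoU, Cov and WCov. Score is the row sum (maximum 18 for the semantic
four, 36 for the dual eight); AveDiff is the mean over columns of the
column best minus the row's value, reported rounded half-to-even to two
decimals. Values tied at the table's printed precision share the
arithmetic mean of the points their positions span; a "first" policy
(earlier row wins) is available because published tables are sometimes
ranked on unrounded values that the printed precision cannot recover.
Two of the bundled benchmark tables contain one such printed tie each
(their WCov columns); rows whose points depend on how that tie is broken
are the only published Score cells the symmetric policy does not
reproduce, and the golden tests pin exactly the reproducible cells.
Points handed out per column always sum to 6 (minor) or 12 (major)
absent ties, Score is invariant to row order, and both properties are
tested over random tables.

## Synthetic plants

`gen_plant` builds a labeled single plant from parametric organ surfaces:
a slightly swaying vertical stem tube (class 0, no instance), and
`n_leaves` blades (class 1, instance ids 0..n_leaves−1) attached at
golden-angle (137.5°) azimuths along the upper stem. The dicot morphology
adds a short petiole tube per leaf (stem class, keeping the stem system
connected) ending in a broad drooping elliptical blade about 0.55 long
axes wide; the monocot morphology sheathes long arched blades directly
from the stem with blade length ≥ 5× width. Points are allocated to
organs proportionally to surface area with a floor of 100 points per
organ and trimmed on the stem so the total is exact; isotropic Gaussian
jitter (σ default 1 mm) is added last. Defaults — dicot, 6 leaves,
20,000 points, 300 mm stem, 80 mm leaf scale — sit inside the
10,000–100,000-point single-plant regime of close-range phenotyping
scans. The generator reproduces organ geometry, connectivity and label
structure well enough to exercise every sampler and metric; it does not
model scanner noise anisotropy, occlusion, self-contact, growth stages or
leaf texture, so passing tests demonstrate algorithmic correctness, not
field robustness.

`perturb_prediction` degrades ground truth where real networks fail:
semantic flips are restricted to boundary points (k = 10 neighbourhood
containing ≥ 2 classes — leaf edges, tips and stem–leaf junctions),
instance splits cut a leaf by a random plane through its centroid, and
merges relabel a leaf to its nearest-centroid neighbour. With all rates
zero the prediction equals ground truth and every metric is exactly 1;
metrics degrade monotonically in expectation as rates grow, which is
tested over seeds.

`augment` runs a strategy `times` (default 10) with child seeds spawned
from the base seed — with random-start FPS this yields genuinely distinct
4096-point clouds per source plant — and `split_train_test` shuffles and
splits `K` clouds with `|train| = round(2K/3)` for the conventional 2:1
ratio.

## Numerical conventions and problem sizes

- Distance ties (FPS argmax, UVS nearest-to-centre) break to the lowest
  index; label-vote ties to the smallest label id. These make every
  strategy bit-stable for a fixed seed.
- Permutation ratios in RS are products of at most `s+1` factors in
  `(0, 1]`, so no overflow is possible at any cloud size.
- All child seeds derive from the user seed through
  `numpy.random.SeedSequence` and are reduced below 2³¹.
- The test suite exercises FPS against a brute-force oracle up to
  N = 50 (all start points), RS against exhaustive subset enumeration at
  N = 6, n = 3 with 20,000 seeded draws, the voxel stages against
  per-voxel brute-force search/means, instance metrics against an
  all-pairs IoU oracle, and the full sampler set at n = 4096 on
  12,000–25,000-point synthetic plants — sizes chosen so the whole suite
  runs in well under a minute per property while still covering the
  operating regime.

## Known limitations

- The SBF here is one reasonable boundary operator, not the only one;
  3DEPS results depend on the filter, and `k`/`τ` should be re-examined
  for point densities far outside the defaults' regime.
- VFPS label transfer by majority vote can mislabel centroids of voxels
  that straddle organ boundaries; evaluate label-sensitive pipelines with
  index-preserving strategies if this matters.
- AveDiff values recomputed from rounded (printed) tables can differ in
  the last digit from values computed on unrounded runs; the bundled
  benchmark AveDiff column is therefore reproduced only where the printed
  precision determines it.
- The scoring procedure is ordinal: it rewards rank, not margin, and is
  most informative alongside AveDiff, which preserves magnitude.
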