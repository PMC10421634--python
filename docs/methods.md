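# Methods

This note documents the models, numerical choices and limitations of
`ethokit`. Nothing here reports an empirical result; every number a
test or `scripts/acceptance.py` asserts is computed at run time.

## The behavioral model

Behavior is modeled as a hierarchy of timescales. At the bottom are
**postures** — recurring configurations of the body, each held for a
fraction of a second. Postures chain into **behavioral modules**
(actions such as walking or climbing): sets of postures with high
mutual transition probability. Modules themselves relate through a
tree — some actions share postures or follow each other
preferentially — giving a two-or-more-level **hierarchy**. The
analysis makes only one dynamical assumption: that between-posture
transitions are informative at the level of a first-order process on
posture *runs* (maximal constant-label stretches). Dwell durations are
deliberately factored out: transition lags count run changes, not
frames, so a slow and a fast performance of the same action yield the
same transition structure.

## Synthetic data generator

The generator (`ethokit.simulate`) is the package's test bed and
defines the conditions every recovery property is measured under.

* **Skeleton**: 15 landmarks (head/trunk, arms with elbows, legs,
  tail), a tree of 14 bones whose adjacent-bone pairs give exactly 19
  joint-angle triplets (six each at the degree-4 neck and hip, one at
  head, shoulders, elbows and knees). Reference bone lengths follow
  adult rhesus proportions; the arena is a 2.45 × 2.45 × 2.75 m cage.
* **Posture templates** are sampled as per-landmark Gaussian
  perturbations (sd 0.06 m) of the reference stance and frozen per
  repertoire; candidates are rejected until all pairwise distances in
  the 19-dimensional joint-angle space exceed `min_separation`
  (default 1.0 rad). Sampling poses rather than angle vectors
  guarantees each template is geometrically realizable, so rendered
  frames reproduce template angles exactly (round-trip < 1e-6 rad at
  zero noise); an inverse-kinematics solve for 19 coupled angles on a
  degree-4 tree would be over-constrained.
* **Dynamics**: a row-stochastic, zero-diagonal Markov matrix over
  postures. From a posture in module *m*, transition mass splits
  `within_module_prob` (default 0.9) to the other postures of *m*,
  optionally `within_super_prob` (default 0.07) to sibling modules of
  the same super-module, remainder to everything else. Dwell times are
  geometric with mean `dwell_mean_frames` = 18 frames (0.6 s at
  30 Hz) — memoryless, matching the first-order run-level analysis;
  the true dwell distribution of real animals is not known to be
  geometric, and nothing downstream depends on that shape.
* **Rendering**: each run places its (subject-scaled, randomly yawed)
  template on a center-of-mass path integrating the posture's
  horizontal velocity tendency (0–0.25 m/s) with reflection at the
  cage walls; run boundaries are blended linearly over 3 frames;
  observation noise is isotropic Gaussian, default sd 1 cm
  (typical multi-camera triangulation error). Batch corruption adds a
  constant per-session offset, dropout runs (frames marked missing)
  and outlier frames (displaced outside the cage, or collapsed to a
  point).

What the generator does **not** emulate: continuous within-posture
kinematics (frames within a run differ only by noise and COM motion),
muscle/skeletal dynamics, occlusion structure correlated with pose,
non-stationary repertoires, or multi-animal interaction. Passing
recovery tests on this data shows the pipeline's inference machinery is
correct under its own assumptions — not that real macaque behavior
satisfies those assumptions.

## Preprocessing

Order per session: QC → interpolation → normalization.

* QC invalidates frames with any landmark outside the cage box or mean
  bone length < 10 cm (pose collapse).
* Gaps of ≤ 10 frames (0.33 s) with valid data on both sides are
  filled per coordinate with shape-preserving piecewise cubics (PCHIP);
  monotone cubics avoid the overshoot a natural spline can produce in
  short gaps, and reproduce linear motion exactly. Boundary gaps are
  never filled.
* Normalization translates the neck to the origin, scales the spine
  (neck–hip) to length 1, and applies the unique proper rotation taking
  the spine to −Z and the spine-orthogonalized shoulder axis to +X.
  The canonical axes are a convention — any fixed frame works — but
  must be explicit for reproducibility. Frames with zero spine length
  or shoulders parallel to the spine are invalidated with a logged
  reason. Invalid frames are dropped from feature rows but keep their
  frame indices, so transition lags stay in frame units.

## Features and embedding

23 features per frame: the 19 joint angles (computed on normalized
coordinates, hence invariant to position, size and heading), the
center-of-mass speed and the three per-axis speeds (computed on raw
arena coordinates, since normalization removes translation; centered
finite differences × fps, smoothed with a 5-frame moving average; COM =
mean of all 15 landmarks). Each of the three feature groups (angles /
COM speed / axis speeds) is min–max scaled to [0, 1] per subject as a
group, preserving within-group geometry. PCA keeps the smallest
leading set of components reaching 95% explained variance; UMAP
(Euclidean, `min_dist` = 0.001, `n_neighbors` = 20, fixed seed) embeds
the scores in 2-D — one global embedding over all sessions, so posture
labels share a single space.

Density is a binned Gaussian KDE: a 200 × 200 histogram over the data
range (+5% margin) smoothed with a per-dimension Silverman bandwidth
(σ·n^(−1/6)), normalized to integrate to 1. Watershed runs on the
inverted density, seeded at regional maxima. Two suppression rules
remove spurious modes: peaks below 1e-6 of the global maximum
(numerical speckle) and peaks below the density ~3 isolated samples
would generate under the bandwidth; after labeling, basins supported by
fewer than max(5, 0.2%) of points are merged into their deepest
neighboring basin. Rationale: a posture is a *recurring* pose pattern;
a basin holding a handful of stray frames is sampling noise, and
leaving such micro-basins in place fragments the transition graph.
Every embedded point receives exactly one label (basins partition the
grid).

## Transition graphs, Paris, modularity, Dasgupta, AMI

* `M(T)` is column-stochastic over run postures; at T = 1 the diagonal
  is structurally zero (runs change posture). Lags are run-counted.
  Zero columns (postures never observed as sources) are flagged, not
  filled. Session boundaries contribute no transitions.
* **Paris** is implemented natively (no suitable graph-hierarchy
  library is assumed present): agglomerative merging of the pair
  minimizing the node-pair sampling distance
  d(a,b) = p(a)p(b)/p(a,b) on the symmetrized weights, with cluster
  weight and linkage updated additively. The distance is reducible, so
  greedy merging yields non-decreasing heights (asserted in tests).
  Disconnected components are clustered separately and joined at twice
  the maximum finite height, with a warning. Ties break toward the
  lowest cluster index, making the algorithm deterministic.
* **Modularity** is directed weighted Newman modularity,
  Q = (1/m)·Σ_ij [A_ij − k_i^out·k_j^in/m]·δ(c_i,c_j); the transition
  matrix is genuinely directed, and the single-module partition scores
  exactly 0. A `directed=False` switch symmetrizes first, for
  sensitivity checks. The dendrogram cut is chosen by evaluating Q at
  51 equally spaced heights in [0.4, 1.4]; because Paris heights are
  data-scale dependent, the range auto-extends (with a warning) when
  the tree's heights fall outside it. Ties prefer the coarser
  partition.
* **Dasgupta score** = 1 − cost/(n·total weight) with
  cost = Σ_pairs w_ij·|leaves under lca(i,j)|, on symmetrized weights,
  self-loops excluded. **AMI** uses the permutation (hypergeometric)
  expectation and arithmetic-mean normalization; dict inputs are
  compared over the shared posture universe. Both are cross-checked in
  the test suite against brute-force enumerations (explicit LCA,
  explicit EMI sums) to 1e-12.

## Alignment

The MNN correction searches K = 100 Euclidean neighbors both ways;
mutual pairs are samples inside each other's neighborhoods. The raw
correction per sample is the weighted mean of (sample − neighbor)
differences; weights default to a Gaussian kernel
w ∝ exp(−d²/σ²) with σ = the median mutual-pair distance, so far
(poorly matching) neighbors are down-weighted — literal
proportional-to-distance weighting would up-weight the worst matches,
and both it and inverse-distance weighting remain available as
documented switches. Corrections are smoothed in time with a centered
15th-order running median (shrinking windows at the boundaries);
samples with no mutual pairs get no raw vector and are filled by
temporal interpolation of the filtered corrections. Alignment operates
on the 23-dimensional normalized features, immediately before PCA and
embedding; multi-session studies align every session to the largest
one.

The method recovers a constant batch offset when the feature
distribution is *atomic at the offset scale* — clusters tighter than
the offset, separated by more than it — which is exactly the posture
structure the features have. Two caveats, measurable with the
generator: offsets along high-variance feature dimensions (the
yaw-dependent axis speeds) are partially absorbed by the neighborhoods
and under-recovered; and when a cluster holds many more than K
samples, neighbor selection inside the cluster biases the correction
along the offset by ~1.25σ_cluster (K-truncation selection). The
alignment recovery benchmark therefore uses run-ordered samples from
49 tight posture clusters (within-cluster sd 0.02 in normalized
units, cluster size ≈ K) — the regime the correction is designed for
and the posture cardinality typical of full-scale recordings.

## Timescale statistics

* Modularity and stability (consecutive-lag AMI) curves are fit with
  trust-region nonlinear least squares to a·e^{bT} + c, b constrained
  to [−10, −1e-6], initialized from a log-linear regression on
  (value − min). Flat or non-convergent curves are flagged degenerate
  and report a missing (not infinite) half-life.
* The shuffle null permutes **run-level** posture labels (preserving
  run count and label frequencies) and recomputes the metric through
  the full graph → Paris → best-cut chain; frame-level shuffling is
  available as a switch but would destroy dwell structure the
  statistic never sees. p uses the add-one convention
  p = (1 + #{null ≥ obs})/(1 + n), so 100 permutations bound p at
  1/101.
* Session comparisons: type-II two-way ANOVA (subject + task, no
  interaction — sessions are treated as independent units, a stated
  simplification), pairwise-session AMI with per-cell permutation
  p-values corrected by Benjamini–Hochberg within the family, and
  unpaired t-tests on group values after subtracting nuisance-factor
  means ("partialled").

## Problem sizes and determinism

Recovery benchmarks run at desk scale, chosen to keep the statistics
meaningful: one 20k-frame session (~11 min of behavior, ~1100 runs)
for posture/module recovery; 100k-frame label sequences (~5500 runs)
for hierarchy and null calibration; 5000 samples for alignment; 100
replicates for half-life accuracy; 20 paired replicates for the
mixing-speed comparison. All generators and the pipeline are
deterministic given their seeds; pipeline stages draw from named
substreams of a master seed, and UMAP runs single-threaded with a
fixed `random_state`.

## Known limitations

* Transition counts at 20k frames are sparse (~8 per posture pair), so
  module recovery on a single session can occasionally misplace one
  posture (frame-level module AMI ≈ 0.8 rather than ≈ 0.95).
* Blend frames at run boundaries (~15% of frames at the default dwell)
  are intrinsically ambiguous and bound frame-level label agreement
  away from 1.
* The [0.4, 1.4] default cut range suits probability-scale transition
  graphs of a few dozen nodes; other weight scales rely on the
  auto-extension.
* The exponential decay model is descriptive; no mechanistic claim is
  made about why organization decays with lag.
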