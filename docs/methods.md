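# Methods

This note records the models, conventions and design choices behind
`knnbench`, in the order a user meets them: distance measures,
classifier and evaluation protocol, score aggregation and ranking,
profile clustering, and the synthetic data generators.

## Distance measures

All twelve measures operate on equal-length real vectors and are
implemented as pure, broadcasting functions (`metrics` module).  The
conventions where the definitions leave room:

* **0/0 terms** in Canberra and Clark (both coordinates zero) contribute
  0, so `d(0, 0) = 0` — the standard convention.
* **Hamming** compares stored values exactly (no tolerance), i.e. it is
  the indicator count of differing coordinates.  It is only informative
  for nominal or discretised numeric data; on continuous features every
  coordinate differs and the distance is constantly equal to the number
  of features.
* **Bhattacharyya**, $-\ln\sum_i\sqrt{x_i y_i}$, is a distance between
  probability distributions.  The plain function evaluates the formula
  as printed, on any vectors with $x_i y_i \ge 0$; on unnormalised input
  its self-distance is $-\ln\sum_i x_i$ (possibly negative), and two
  vectors with disjoint support return `+inf` — a sentinel rather than
  an error, so nearest-neighbour ranking still works (the point is
  simply maximally far).  The registry-wrapped metric simplex-projects
  both arguments first.  This is deliberate: on unnormalised features
  with small coefficient of variation, $\sum_i\sqrt{x_i y_i}\approx
  \langle\sqrt{x},\sqrt{y}\rangle$ is dominated by $\|\sqrt{y}\|$, so
  the induced neighbour ordering is nearly the same for every query and
  kNN accuracy pins at chance.  Restricting the measure to its actual
  domain (the simplex) makes it a usable benchmark participant; the raw
  behaviour remains available through the plain function.
* **Fisher** is likewise defined only on the probability simplex; the
  registry wrapper projects raw features with `simplex_project`
  (min-shift if any coordinate is negative, then sum-normalise).  The
  geodesic is evaluated through the chord,
  $2\arcsin(\|\sqrt{x}-\sqrt{y}\|/2)$, which is mathematically identical
  to $\arccos\langle\sqrt{x},\sqrt{y}\rangle$ but well-conditioned near
  0, so identical inputs give exactly 0 rather than
  $O(\sqrt{\varepsilon})$.  The arcsin argument is clipped to $[0,1]$ to
  absorb floating-point overshoot.
* **Sobolev** uses the unnormalised DFT with frequencies
  $\omega_j = 2\pi j/N$ indexed $j = 0..N-1$ and weight
  $(1+\omega_j)^k$, degree $k=1$ by default.  Two dialects are exposed:
  `full` (default) sums the complete spectrum and is a true metric whose
  $k=0$ limit equals $\sqrt{N}\times$ Euclidean by Parseval's identity;
  `literal` drops the $j=0$ (DC) coefficient, making the measure blind
  to constant offsets — it exists for fidelity studies of the truncated
  summation convention.  No negative-frequency symmetrisation is
  applied, so the upper half of the spectrum is weighted more heavily
  than its conjugate-symmetric mirror; this is a property of the
  definition, not a bug, and is shared by both dialects.
* **Flags.** Each registry entry carries `is_true_metric` (triangle
  inequality holds on its intended domain; false for Bray–Curtis,
  Clark, Minkowski with $p<1$ and the `literal` Sobolev dialect) and
  `requires_nonnegative` (Bhattacharyya, Bray–Curtis, Soergel — the
  domains on which their stated ranges/axioms hold).

## Classifier and evaluation protocol

The classifier is deliberately the plain lazy learner: exhaustive
distance computation, majority vote among the $k$ nearest training
rows.  Distance ties at the $k$-th rank are broken by training-row
index (stable sort); vote ties by the `nearest_sum` policy (the tied
class whose neighbours have the smallest summed distance wins; any
remaining tie and the alternative `label_order` policy pick the
alphabetically first label).  No distance weighting, tree acceleration
or feature scaling — features are used as given.

Because the source benchmarks report no split scheme, the default
protocol is the field norm: 10 repetitions of a seeded stratified 70/30
train/test split, neighbourhood grid $k = 1..20$ ($1..11$ for the small
lung-shaped preset, whose 22-row training partitions cannot support
more), scores averaged over repetitions.  Stratified $k$-fold is
available as an alternative scheme.  Stratification requires at least
two members per class and every class present in both partitions,
otherwise the protocol raises naming the offending class.  Per-class
precision/recall/$F_1$ are macro-averaged by default (micro available);
a class never predicted contributes precision 0 with a logged warning.
Accuracy is the overall fraction correct (for a single positive-class
tally, $(\mathrm{TP}+\mathrm{TN})/\mathrm{total}$).  The distance
matrix of each split is computed once and reused across the whole $k$
grid.

## Scoring, ranking, consensus

The benchmark's final score for (metric, measure, dataset) is the
maximum over the $k$ grid.  Metrics are ranked per (dataset × measure)
with descending score; tied scores share fractional (average) ranks by
default, with `min` and `ordinal` policies exposed because published
summary rankings of this kind are often inconsistent with any single
tie convention.  The ranking granularity is likewise configurable:
per best-over-$k$ column (default) or per (dataset × measure × $k$)
slice.

Two consensus orders are produced.  The *mean rank* is the arithmetic
average of a metric's ranks over all columns.  The *cross-entropy Monte
Carlo* consensus minimises the (optionally weighted) sum of Kendall
distances to the input orders: an $m\times m$ position-probability
matrix, initialised uniform, is sampled for `sample_size` candidate
orders per iteration (default $200m$); the elite
$\lceil\rho\cdot\text{sample\_size}\rceil$ candidates ($\rho = 0.1$)
re-fit the matrix with exponential smoothing 0.7; the search stops when
the best objective has not improved for 7 iterations (or after 100).
The input lists — and, in the CLI pipeline, the mean-rank order — are
evaluated as candidates up front, so the returned objective never
exceeds theirs.  Hyperparameters beyond $\rho$ are unreported in the
source benchmarks; the defaults above converge reliably at $m = 12$ and
are config-exposed.  On five-item problems the search recovers the
exhaustive-enumeration optimum in every tested instance.

## Clustering of performance profiles

Each metric's profile is its vector of best-over-$k$ scores across all
(dataset × measure) columns.  Profiles are clustered by $k$-means
(squared Euclidean, $k$-means++ initialisation, 50 restarts, lowest
inertia kept), on raw scores by default with a standardisation flag.
Note that published partitions of such profiles are not necessarily the
minimum-inertia solution: on the packaged reference matrix the widely
cited 3-cluster structure is a Voronoi-stable local optimum whose
inertia (0.336 raw) exceeds the global optimum found by multi-restart
$k$-means (0.148, which merges the two probability-simplex metrics into
the main cluster and isolates Hamming).  A single-start Lloyd run can
land in the former; a correct multi-restart implementation cannot.  The
mean-rank structure, by contrast, is robust: the packaged matrix always
places Fisher, Bhattacharyya and Hamming in the three worst positions.
A 2-D PCA projection (centered, top two components) is provided for
plotting only.

## Synthetic data generators

The generators emulate the *shapes* of four classic cancer benchmarks
(3-class 64×64 image slices; a 699×9 cytology table; a 32×55 ordinal
panel; a 97×9 continuous clinical table), not their distributions,
about which nothing is assumed beyond type.  Common construction:
balanced classes (±1), class means at a positive baseline separated by
`separation` × `noise_sd` along random orthonormal directions
(pairwise-equidistant), i.i.d. Gaussian noise, deterministic per seed.

* `gaussian_float` records features at a finite measurement resolution,
  default one noise-SD per step, emulating ordinal laboratory scores
  (cytology grades are integers stored as floats).  Discretisation is
  what gives Hamming a signal; `resolution=0` produces genuinely
  continuous features, on which Hamming degenerates — exactly the
  behaviour seen on real continuous clinical tables, and the
  `prostate_like` preset uses it.  The baseline ($8\sigma$) keeps
  features positive so the probability-style measures are defined.
* `integer_sparse` rounds and clips to a small integer range (default
  0–3), emulating multivariate ordinal survey panels.
* `image_like` builds per-class smooth templates (low-pass-filtered
  random fields, orthonormalised), adds pixel noise, rounds to integer
  intensities in [0, 255] and flattens row-major.

Preset separations are fixed once at values giving the difficulty
ordering of the real benchmarks (hard 3-class images 1.5, easy cytology
6, hard small panel 2, intermediate continuous table 4); the
image preset is scaled to 300 instances by default (the original 3064
available by flag) to keep a 12-metric × 20-$k$ sweep interactive.

What passing tests on these generators show — and what they do not: the
pipeline's correctness, determinism and calibration (at 6σ separation
every metric classifies nearly perfectly; at 0σ every metric sits at
chance) are demonstrated on data with Gaussian noise, exact class
balance and homogeneous feature scales.  Real biomedical tables have
skewed, heteroscedastic, correlated features and label noise; relative
metric rankings measured here do not transfer to such data, which is
precisely why the toolkit exists — to re-measure them on reference data
resembling one's own.

A note on sampling variance: a single 200-sample dataset carries
dataset-level noise of several accuracy points (repeated splits of the
same draw are highly correlated), so calibration quantities in the
acceptance script are averaged over three independent replicate
datasets.

## Numerical and degenerate-input conventions

Zero denominators raise (`bray_curtis`, `soergel` on all-zero input;
`simplex_project` on constant-minimum vectors) except where a
convention exists (Canberra/Clark 0/0 terms).  Negative products raise
in Bhattacharyya.  NaN scores cannot be ranked.  Score tensors must be
complete over each experiment's own $k$ grid (grids may differ between
datasets); missing cells are reported explicitly.  All stochastic
components (splits, generators, CE search, $k$-means) are seeded, and
the CLI writes plain TSVs so reruns are byte-identical.

## Known limitations

* The brute-force classifier is $O(n_\text{train})$ per query by
  design; for large image data use the scaled presets.
* The `literal` Sobolev dialect is a pseudometric (DC-blind) and is not
  included in the default benchmark set.
* Weighted rank aggregation supports per-list weights, but no
  significance testing of rank differences is provided.
* The CSV loader accepts numeric features only; missing values are a
  parse error, not imputed.
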