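# Methods

## Problem and pipeline

The package addresses binary classification of single white-blood-cell
microscope crops into healthy lymphocytes versus leukemic blasts, with the
emphasis on *wrapper feature selection*: rather than classifying on a full
descriptor bank, a feature subset is chosen by directly minimizing

```
fitness(mask) = 1 - ACC(mask)
```

where `ACC(mask)` is the stratified cross-validated accuracy of a
k-nearest-neighbour classifier restricted to the masked feature columns.
The full flow is

```
images -> descriptors -> 85/15 stratified split -> selection (training rows)
       -> linear SVM / KNN / decision tree -> confusion metrics
       -> two-way ANOVA + Tukey HSD over the accuracy grid
```

Selection and standardization are fitted on training rows only by default;
the `paper_faithful` / `pooled` modes reproduce the common but leaky
practice of pooling train and test rows into one matrix before selection,
and exist purely so that the two protocols can be compared.

## Synthetic blood smears

Real single-cell leukemia benchmarks require registration to download, so
the package ships a generator that emulates their structure: one cell per
square crop over a light background, H&E-like staining shared by both
classes, and a class difference carried entirely by nuclear morphology.
Each cell is a disk whose contour radius is modulated by a low-order random
Fourier series (harmonics 2–8, coefficient SD 1/k, scaled by
`boundary_irregularity`); the nucleus is a second, rougher perturbed disk
inside it. Chromatin is a Gaussian-filtered noise field added inside the
nucleus (`texture_grain`); stain variation is a per-image colour shift
(`color_jitter_sd`) and sensor noise a per-pixel Gaussian
(`pixel_noise_sd`). Pixels are clipped to [0, 1] and quantized to the 8-bit
grid at render time, so in-memory arrays, written PNGs and re-read PNGs are
bit-identical.

Default conditions: 130 healthy + 130 blast crops of 96 px (balanced, the
standard benchmark size), healthy nucleus/cell radius fraction 0.52 (SD
0.05), blast 0.82, blast contours four times more irregular
(0.16 vs 0.04) and chromatin three times coarser (0.10 vs 0.03). A single
`separability` knob in [0, 1] linearly interpolates the blast geometry
toward the healthy one; at 0 the class-conditional distributions are
identical (labels carry no information), and at 1 the default geometries
are calibrated so descriptor-based classifiers reach essentially perfect
held-out accuracy. Per-sample random streams derive from
`(dataset seed, sample index)`, so enlarging a dataset never reshuffles
existing samples.

What the generator does **not** emulate: multi-cell fields, touching or
overlapping cells, focus and illumination gradients, staining artefacts,
segmentation failures, and any within-class morphological subtypes.
Passing tests therefore demonstrate that the selection and evaluation
machinery behaves correctly on data whose class structure is known by
construction — not that the descriptor bank is sufficient for clinical
images.

## Descriptor bank

Images are segmented by a two-stage Otsu threshold on inverse luminance
(largest connected component, hole-filled; nucleus by re-thresholding
within the cell). Three descriptor families, 40 features total:

- **colour (30)** — per-channel mean, population SD, skewness and excess
  kurtosis over the cell region in RGB and HSV (24), plus nucleus-region
  channel means (6). Population (divide-by-n) moments throughout; skewness
  and kurtosis of a constant region are defined as 0.
- **texture (4)** — grey-level co-occurrence contrast, correlation, energy
  and homogeneity on the min–max-quantized cell region (8 levels, offsets
  (0,1) and (1,0), symmetric, normalized to sum 1), averaged over offsets.
  Only pixel pairs with both ends inside the mask are counted, which is why
  the matrix is accumulated directly rather than through a rectangular-image
  routine. "Energy" is the angular second moment `sum(P^2)`; correlation of
  a zero-variance region is 0.
- **shape (6)** — cell area, perimeter, circularity `4*pi*A/P^2`, solidity,
  nucleus/cell area ratio, nucleus circularity. An empty nucleus mask
  yields zeros with a warning rather than an error.

A deep-embedding adapter with the identical output contract (one pooled
penultimate-layer row per sample) is defined for pretrained CNN backbones;
it requires locally cached weights and is never exercised by the default
build. Downstream code is agnostic to which source produced the rows.

## Selectors

All three searches optimize the same memoized fitness; the empty mask is
assigned fitness 1.0 (worst) so the search space stays closed, and all
best-so-far updates are strict (ties keep the incumbent), which makes the
per-iteration trace non-increasing and byte-reproducible from the seeds.

- **Binary PSO** — Kennedy–Eberhart velocity rule
  `v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)`, clamped to
  `±v_max`, with sigmoid transfer: bit j becomes 1 iff
  `sigmoid(v_j) > u_j` for fresh uniform `u_j`. Defaults: 25 particles,
  50 iterations, w = 0.7, c1 = c2 = 1.5, v_max = 4 — standard binary-PSO
  practice.
- **Subset ACO** — per-feature pheromone `tau_j` (init 1.0) and heuristic
  `eta_j` (Fisher score rescaled to (0, 1]); each ant includes feature j
  independently with probability `tau^a eta^b / (1 + tau^a eta^b)`.
  After each iteration pheromone evaporates by `rho = 0.2` and the
  iteration-best ant deposits `q (1 - fitness)` on its features. The
  iteration-best ant is first refined by a first-improvement single-bit-flip
  hill climb. This local-search coupling is the standard cure for pheromone
  stagnation: without it the plain construction repeatedly converged a few
  bit-flips short of the verified optimum on small instances, and bounded
  (Max–Min) pheromone was found too sensitive to its bound constants to be
  a dependable alternative.
- **Binary GWO** — wolves move toward the average of the alpha/beta/delta
  estimates with exploration coefficient `a` decaying linearly 2 -> 0;
  continuous positions are binarized by the same sigmoid-vs-uniform rule.
  The leader hierarchy is updated by strict cascade, so
  `f(alpha) <= f(beta) <= f(delta)` at every iteration.
- **Exhaustive oracle** — evaluates every non-empty mask (guarded at
  d <= 20), ties broken by fewer selected features then lexicographic mask
  order. It exists to verify the metaheuristics, never to stand in for them.

The fitness evaluator uses stratified 5-fold cross-validation with k = 1 on
training rows; leave-one-out is used when the fold count equals the sample
count. Folds are fixed once per search from the fitness seed, so fitness is
a pure function of the mask.

## Evaluation layer

The 85/15 split draws `floor(0.85 * n_c)` training samples per class by
seeded shuffle (110 + 110 train, 20 + 20 test at the default 260). The
positive class is the blast class, so sensitivity is the blast-detection
rate. Metrics are kept as exact fractions and rounded to one decimal only
for reporting; zero-denominator ratios are reported as not-available,
never 0. With balanced classes, accuracy is exactly the mean of
sensitivity and specificity — the internal-consistency identity the test
suite asserts on published-style confusion tables.

The two-way ANOVA is the closed-form balanced fixed-effects decomposition
with interaction (first array axis = "Columns" factor, e.g. classifier;
second = "Rows" factor, e.g. selector), restricted to balanced designs with
>= 2 replicates per cell; it is cross-checked in the tests against both an
explicit design-matrix least-squares projection and statsmodels. Tukey HSD
uses the studentized range distribution for simultaneous intervals
(`diff ± q_{0.05;k,df} sqrt(MSW/n)`) and p-values, equal group sizes only;
the test oracle integrates the studentized-range density by direct double
quadrature.

## Numerical and design choices

- Degenerate inputs: zero-variance images are a segmentation error; a
  constant region yields well-defined (zero) higher moments; an all-equal
  ANOVA reports F as not-available; identical Tukey groups give p ~ 1.
- Sub-seeds: every stage derives its seed as `crc32(global_seed:stage)`
  (below 2^31), so stages re-run in isolation reproduce the pipeline run.
- Stage wall-times are persisted to a separate `timings.json`; the main
  `report.json` contains only deterministic content and is byte-stable
  across runs with one seed.
- Problem sizes in the test suite and acceptance script (d = 6 oracle
  tables at n = 60, 100 + 100 image calibration runs, three replicates per
  ANOVA cell) were chosen as the smallest sizes at which the respective
  properties are statistically meaningful.
- The replicated selector x classifier grid for ANOVA/Tukey is generated at
  separability 0.4: at full separability every cell saturates at 100% and
  there is no variance to decompose.

## Known limitations

- The synthetic generator's realism gap (above) means accuracy figures on
  it say nothing quantitative about clinical imagery.
- The ACO heuristic uses univariate Fisher scores, which can misrank
  features whose value is purely interactive; the wrapper fitness, not the
  heuristic, has the final word.
- Tukey is implemented for equal group sizes only (no Tukey–Kramer), and
  the ANOVA for balanced designs only, matching the balanced accuracy grids
  it is applied to.
- A single train/test split is used end-to-end (matching the protocol the
  pipeline models); outer k-fold evaluation is out of scope.
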