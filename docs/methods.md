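# Methods

## Problem setting

A whole-slide image is decomposed into non-overlapping square tiles
(default 256×256 px; trailing partial tiles are dropped). Each tile
carries a composition vector on the K-simplex: the fraction of each of K
cell/tissue clusters among its contents. Compositions can come from
pixel-level label maps (`build_grid_from_label_map`), from per-tile
tables produced by any upstream pipeline (cell calling, deep embeddings
+ clustering), or from the synthetic generator. Slide-level composition
`b` is the unweighted mean of the valid tiles' compositions — i.e. the
fraction of tiles per cluster, with every tile weighted equally
regardless of how many labeled pixels or cells it holds.

Background exclusion follows the standard white-slide rule for 8-bit
H&E tiles: a tile is background iff the fraction of pixels with all
three RGB channels strictly above 210 strictly exceeds 0.70. Stain
channels for SSIM evaluation are contrast-normalized by a percentile
min-max rescale (defaults: 70th to 99.99th percentile mapped to [0, 1]).

## ROI selection

Candidate ROIs are all grid-aligned square windows of a given side at a
given stride. The default stride equals the side, which makes the
candidate set a partition of the grid: candidates are pairwise
non-overlapping, and pooling all of them reproduces `b` exactly (a
conservation identity used as a test invariant). The conventional ROI
sizes of 1000 / 1500 / 2000 / 2500 px map to sides of 4 / 6 / 8 / 10
tiles at 256-px tiles (`round(px / tile_size)`); tile-aligned windows
keep the columns of `A` exact. Each column of `A` is the mean
composition of the window's valid tiles; `E_j` is its Shannon entropy
(natural log by default; base configurable).

**Sparse matching** (`select_l1`): minimize the number of ROIs whose
weighted pooled composition matches `b`. Exact equality `Ax = b` is
generically infeasible with finitely many candidates, so it is relaxed
to the elementwise slack `|Ax − b| ≤ ε` (default ε = 1e-3). If the
program is infeasible the slack is doubled — each retry recorded in the
result status and the log — up to ε = 0.25, after which the solver
raises with the closest achievable deviation. Two modes are provided and
the result reports which ran:

* `milp` (default): binary selection indicators `z` with continuous
  weights `y ≤ z`, `Σy = 1`, `|Ay − b| ≤ ε`, minimizing `Σz` — the exact
  minimum-cardinality program, solved by HiGHS branch-and-bound.
* `lp`: the continuous relaxation `min Σx` over the same slack set.

**Entropy-regularized matching** (`select_entropy`): the quadratic
program `min ‖Ax − b‖² − λ·Eᵀx` over the box-constrained simplex
(`0 ≤ x ≤ 1`, `Σx = 1`), default λ = 1. The sign convention maximizes
entropy (heterogeneous tissue); `entropy_sign=-1` flips the regularizer
for workflows that want homogeneous regions. The program is solved by
accelerated projected gradient (FISTA) with exact Euclidean simplex
projection and a step size from the largest eigenvalue of `2AᵀA`;
convergence is declared when the relative objective change falls below
1e-14 (at most 2000 iterations). For the problem sizes the package
targets (tens to a few thousand candidates) this is fast and accurate to
well below the support cutoff.

**Support and refinement.** Selected ROIs are the candidates with weight
above 0.01, the cutoff that guarantees every reported ROI contributes
meaningfully. The fractional weights are a relaxation of the quantity
users actually consume — a discrete ROI set, scored with each chosen
window used in full (equal pooling). `select_entropy` therefore finishes
with a refinement pass: it exhaustively evaluates the equal-pooled
discrete objective over all subsets of the (small) thresholded support
and returns the best subset. The continuous solve screens candidates;
the exhaustive pass picks the deliverable. Refinement is skipped (with
the plain thresholded support returned) when the screened set exceeds 16
candidates. Both the continuous objective and the discrete
`support_objective` are reported.

**Random baseline** (`random_selection`): 1,000 draws of k pairwise
non-overlapping windows, sampled uniformly without replacement with
bounded rejection of overlapping draws, scored per draw by the three
metrics below. With the default stride (= side) every draw is accepted
immediately.

**Exhaustive oracle** (`brute_force_select`): enumerates every support
up to a size cap (combinatorial budget 10⁶). For the entropy objective
each support is scored by the equal-pooled discrete objective; for the
sparse objective supports are scanned in increasing cardinality and each
is checked for ε-feasibility with its own optimal weights (a small LP),
so the returned value is the true minimum cardinality. It exists for
testing and small problems only.

**Non-overlap.** Selected ROI windows are non-overlapping by
construction at the default stride. At finer strides the convex solvers
report overlap but do not forbid it (the weights are fractional); the
random baseline always enforces it.

## Evaluation metrics

Given the combined composition `R` of the selected ROIs (tiles pooled
once, so duplicated windows collapse) and the slide composition `W`:

* `MSE = (1/n) Σᵢ (Rᵢ − Wᵢ)²` over the n clusters;
* `JSD`: base-2 Jensen–Shannon divergence, bounded by 1, with the
  convention that terms with a zero numerator contribute 0. This
  convention can understate divergence for empty classes, so an exact
  mixture-KL formulation (`exact=True`) is also provided and serves as
  the independent oracle in tests;
* mean ROI entropy `(1/m) Σᵢ H(rᵢ)` with `H(r) = −Σ r log r`
  (nonnegative Shannon entropy; natural log by default, base 2
  available — JSD is always base 2, entropy base is the caller's
  choice).

MSE punishes single outlying clusters; JSD saturates and drops empty
classes. Reporting both covers each one's blind spot.

## Clustering and agreement

Tiles are clustered by k-means (k-means++ initialization, 10 restarts,
fixed seed default 0) on compositions or on any per-tile embedding. The
cluster count is chosen at the knee of the within-cluster
sum-of-squares curve, defined as the maximum second difference of
**log**-inertia — the sharpest relative bend, insensitive to the
absolute inertia scale (the raw-inertia second difference peaks too
early whenever the first splits remove most of the variance). The full
curve is returned so a caller can deliberately pick a smaller k within
the elbow; a knee weaker than 0.25 in log-inertia is flagged as
low-confidence. The reference configuration uses K = 7 clusters.

Agreement between labelings:

* **Purity** `(1/N) Σ_pred max_truth |c ∩ t|` — fraction of items whose
  predicted cluster's majority truth class they share; splitting a
  predicted cluster can only keep or raise it.
* **NMI** `MI(U,V) / mean(H(U), H(V))` with the arithmetic mean
  (geometric available). Conventions: two single-class labelings → 1;
  single-class against multi-class → 0. Cross-checked against
  scikit-learn's contingency-table implementation at 1e-10.
* **Spearman cluster pairing**: the full correlation matrix between
  predicted and truth cluster mean profiles, plus a one-to-one
  assignment maximizing total correlation (Hungarian algorithm; a
  greedy variant is exposed for comparison). Constant profiles yield
  undefined correlations, reported as NaN and excluded.
* **CCA** between two paired feature spaces, computed through
  orthonormal SVD bases of both views (the numerically stable
  formulation). Composition inputs are always rank-deficient — the
  simplex constraint removes one dimension — so rank-deficient views are
  restricted to their principal subspace with a warning rather than
  failing. Two components by default; statsmodels' canonical-correlation
  routine is the independent oracle in tests.

## Virtual-stain evaluation

For a virtual/real stain pair from adjacent sections: mean SSIM over an
11-px sliding window (odd window required; scikit-image backend,
cross-checked against an independent term-by-term implementation), Dice
overlap `2|A∩B|/(|A|+|B|)` of the two sections' nuclear masks (both
empty → 1, trivial agreement), and the Dice-compensated SSIM
`SSIM / Dice`. The compensation corrects for physical section-to-section
content drift: if only 80% of nuclei coincide between sections, a
perfect virtual stain cannot exceed SSIM ≈ 0.8. Compensated values above
1 are possible and reported as-is; Dice = 0 leaves the quantity
undefined (NaN with a warning). Marker positivity is the fraction of
cells with mean intensity strictly above a caller-supplied gate
(per-marker gates are acquisition-specific and are never guessed), and
real-vs-virtual positivity ratios are compared by Pearson correlation
with a two-sided p-value.

## Synthetic data

The generator emulates the spatial structure the selection problem
feeds on: a 2-D tissue of spatially contiguous regions of K clusters.
Per cluster, an independent Gaussian white-noise field is smoothed
(length-scale `smoothness_px`, computed on a coarse lattice and
nearest-neighbour upsampled when the field is smooth below the working
resolution); the pixel label is the argmax across clusters after adding
per-cluster offsets, tuned by a damped monotone fixed-point search so
realized global proportions land within ±0.02 of the target (a Potts
model would give similar geometry at far higher cost). Defaults mirror
the reference configuration: a 40×40 grid of 256-px tiles, K = 7
clusters, equal target proportions, smoothness 1024 px (a handful of
large blobs per slide). Tile compositions are pixel-true by default;
finite `dirichlet_conc` resamples each tile from a Dirichlet centered on
the pixel-true composition to emulate noisy cell-type calling.

Paired embeddings are a fixed random linear map of composition plus
Gaussian noise — at zero noise the first K−1 canonical correlations
against compositions are exactly 1, giving a sharp recovery target.
Nuclear mask pairs are disk fields with random pixel-flip perturbation,
bisected to hit a target Dice within ±0.05.

What the generator does **not** emulate: real H&E/CyCIF pixel texture,
stain variation, segmentation errors correlated with tissue type,
imaging artifacts, or annotation ambiguity. Passing tests therefore
demonstrate the correctness and the comparative behavior of the
algorithms (optimized selection beats random sampling on representative
coverage and heterogeneity), not their absolute performance on clinical
material.

## Problem sizes and numerical choices

* Reference slide: 40×40 tiles, K = 7, side-4 ROIs → M = 100
  non-overlapping candidates; solver-vs-oracle checks run on 12×12-tile
  slides (M = 9 candidates) where exhaustive enumeration over all
  supports is cheap. These sizes exercise every code path while keeping
  the full suite fast.
* Annotation ties (equal pixel counts) break to the lowest id;
  tile-level annotation requires at least one annotated pixel, otherwise
  the tile is excluded from annotation analyses (and partially annotated
  tiles enter with full weight).
* All stochastic operations take explicit integer seeds (default 0) and
  are bit-reproducible; k-means determinism is up to cluster-id
  permutation, which the agreement metrics are invariant to.
* Composition sums are validated to 1e-4 on input tables (accumulated
  rounding from upstream pipelines) but maintained to 1e-9 internally.

## Known limitations

* The entropy refinement pass guarantees the best discrete subset *of
  the screened candidates*; in pathological geometries the global
  discrete optimum can involve a candidate whose fractional weight fell
  below the 0.01 cutoff.
* The continuous LP mode of sparse matching can return fractional
  supports larger than the true minimum cardinality; the default MILP
  mode is exact but slower on very large candidate sets.
* Weighted per-cluster interest scores and co-localization objectives
  are out of scope, as is everything upstream of the per-tile
  composition/embedding contract (stain normalization algorithms,
  registration, nuclear segmentation, color deconvolution) and the
  training of any encoder.
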