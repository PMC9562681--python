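# Methods

## Persistent homology of spot point clouds

Each spot's cell centroids are treated as a finite metric space under the
Euclidean distance, filtered by the Vietoris–Rips rule: an edge (u, v)
enters at scale t = d(u, v), a triangle at its longest edge. The scale is
the full *distance*, not the disk radius; narratives in which growing disks
touch at t = d/2 differ only by a global factor of two, and the downstream
Pearson correlations are invariant to positive rescaling of features, so
the convention cannot change which genes are called topology-associated (a
property the test suite asserts directly).

**H0.** Kruskal's algorithm over edges sorted by (length, vertex pair):
every union of two components is an H0 death, so the finite deaths are
exactly the Euclidean minimum-spanning-tree edge lengths. Uncapped, one
essential class survives; with a scale cap, components alive at the cap are
reported as bars (0, cap) and counted essential, mirroring H1.

**H1.** Z/2 column reduction of the anti-transposed boundary matrix
(persistent cohomology): edge columns holding their cofacet triangles are
processed in decreasing filtration order. Two ingredients make this fast
enough for 200-cell patches in well under a second:

- *clearing* — edges already paired as H0 deaths (MST edges) are skipped;
  reducing them is what makes the plain algorithm blow up, since their
  columns cancel all the way to zero through the whole registry;
- most remaining columns pivot immediately on a cofacet triangle whose
  longest edge is the column's own edge, requiring no column additions.

Triangles are keyed by (rank of longest edge, remaining vertex), a linear
extension of the filtration; any such extension yields the same barcode, so
this differs from a plain lexicographic tie-break only in which of several
simultaneous simplices is named in a pairing. The inner loop is
numba-compiled; columns are sorted integer arrays merged by symmetric
difference.

Classes alive at the maximum scale get death clamped to that scale and are
counted essential, keeping all coordinates finite for vectorization. The
default cap is the patch diagonal (350·√2 px), beyond which no pair of
in-patch points can interact. Zero-persistence bars are discarded
everywhere.

**Oracle.** `naive_reduction_oracle` builds the full simplex list ordered
by (filtration, dimension, lexicographic vertices) and performs the
textbook left-to-right dense reduction with no optimizations, refusing
clouds above 15 points. The optimized routines are required to reproduce
its bar multisets exactly on hundreds of random instances; H0 deaths are
additionally cross-checked against scipy's independent MST.

## Persistence images

A diagram is mapped to a fixed grid over (birth, persistence): each bar
(b, d) contributes a bivariate Gaussian at (b, p = d − b) with bandwidth σ,
weighted linearly by p and integrated cellwise as a product of normal CDF
differences — so a bar's total mass over the plane is exactly p, and the
linear weight vanishes at the diagonal, the standard stability-preserving
choice. Defaults: 35 birth bins × 20 persistence bins = 700 features per
dimension (1400 per spot, H0 block then H1 block, names `H0_ITF001` …
`H1_ITF700`); both ranges [0, patch diagonal]; σ = one persistence-bin
width (≈ 24.7 px under the defaults — narrow enough to resolve ring-scale
features, wide enough that neighboring cells share information). The grid
is fixed per run so features are comparable across spots. Bins far from any
bar are constant zero across a slide and are dropped (and recorded) before
correlation.

## Synthetic slides

The generator emulates a Visium-like slide at a testable scale: spots on a
hex-like grid with pitch exactly one patch size (so patches tile without
overlap, and any smaller pitch is a hard error), each spot drawing a point
pattern from a mixture of uniform Poisson (40 or 90 points), Matérn-style
clusters (4 parents, radius 25 px), and 1–3 planted rings (radius 55 px,
thickness 10 px, 20% uniform background). Point counts of 40–115 per spot
sit in the range where per-spot persistence takes milliseconds.

Two per-spot summaries carry the ground truth: the planted ring count (an
H1 quantity) and the mean nearest-neighbor distance (an H0 quantity). Gene
g draws counts from a negative binomial with log-mean
α_g + Σ_s β_{g,s}·z_s, where z_s is the slide-standardized summary;
variance is μ + μ²/θ with dispersion θ. Defaults: α_g ~ N(log 3, 0.8)
(clearing the 25%-zero filter for well-expressed genes while letting weak
genes fail it, as in real data), θ = 2 (moderate UMI-like overdispersion),
β = 1.5 for the 30 coupled genes of the 300-gene panel, 400 spots. These
are the study conditions used by the analysis scripts, the acceptance
script, and the recovery tests.

What the generator does *not* emulate: H&E color and stain variation,
cell-type mixtures, segmentation errors, spatial autocorrelation between
neighboring spots, or library-size variation. Passing recovery tests
therefore show that the pipeline detects topology–expression coupling when
it exists and is calibrated under its own noise model — not that any
particular real-tissue association is true.

## TAG analysis

Gene selection keeps genes with at most 25% zero reads, ranked by variance
of log1p counts (the same scale as the downstream transform; ties broken by
gene id), truncated to the top 150. All retained genes are organized into
TAG clusters — "correlating well" is reported per gene as max |PCC| rather
than imposed as a hard threshold.

Both axes of the genes×ITFs correlation matrix are clustered with k-means
(10 restarts, fixed seed) on correlation profiles — rows for genes, columns
for ITFs — not on raw expression. k is chosen per axis by the elbow rule
operationalized as the maximizer of the second difference of the
within-cluster sum of squares over interior k in 2…12; when the curve has
no interior point the baseline of 10 clusters (clipped to the range) is
used, and exact ties resolve toward the smaller k. Cluster ids are
relabeled 1…k by first appearance so outputs are stable. Each ITF cluster
is assigned its most-similar TAG cluster by the mean correlation over the
block; ties go to the lower cluster id.

## Enrichment

Over-representation of a query of n genes against a term with K members in
a universe of N genes is the upper-tail hypergeometric probability
P(X ≥ k) (scipy's survival function; the test suite checks it against the
exhaustive combinatorial sum for all N ≤ 25). The universe is all genes
passing the zero-fraction filter *before* the top-150 truncation — the
least biased background available locally. Holm's step-down adjustment is
applied within each cluster's term family and controls the family-wise
error at α = 0.05; type-I behavior is verified on label-shuffled nulls.
External enrichment services and ontology-graph propagation are out of
scope; the synthetic GMT (planted term plus random decoys) exercises the
machinery.

## Prediction

One regressor per gene, leave-one-out over spots: the model never sees the
held-out spot's expression (a sentinel test injects an outlier and asserts
the held-out prediction is unchanged). Features and counts are
log1p-transformed. Learners sit behind a fit/predict registry — LightGBM
(default), XGBoost, and AdaBoost — all single-threaded and seeded, so a
fixed seed gives byte-identical outputs end to end. Accuracy is the Pearson
correlation between held-out predictions and truth, reported as undefined
(never silently 0) when either side is constant; learner comparisons use
the mean per-gene PCC difference with a paired two-sided t-test. The
default subsets mirror the analysis design — 19 genes with the highest
max |PCC|, then the 12 ITFs with the highest mean |PCC| against them — and
the analysis driver runs LOOCV on 150 spots, which keeps the 19-gene
two-learner comparison to a few minutes on one core.

## Numerical and degenerate-input choices

- Duplicate points yield zero-persistence H0 bars, discarded like all
  zero-persistence bars; empty clouds yield empty diagrams, which vectorize
  to zero vectors rather than errors.
- Zero-variance genes or ITFs are dropped from the correlation matrix and
  listed, so the matrix never contains NaN.
- Correlations are clipped into [−1, 1] against floating-point overshoot.
- The pipeline seed expands by fixed offsets per stage (simulate +0,
  cluster +1, predict +2), so stages are individually reproducible; the run
  manifest records config and output checksums and lets completed stages be
  skipped on re-run.

## Known limitations

- Only Rips filtrations in dimensions 0/1 on 2-D clouds; no alpha/Čech
  complexes, no H2+, no approximate sparse filtrations (clouds are capped
  at 2^21 points by the triangle-key packing, far above any patch).
- Nucleus detection is a global threshold on a hematoxylin-like
  optical-density channel plus connected components — adequate for rendered
  fixtures, not for real stain variation or touching nuclei.
- The elbow rule is a heuristic; on correlation matrices without block
  structure the chosen k is essentially arbitrary (the baseline fallback
  exists for exactly that case).
- Persistence-image features are grid-quantized; features of very small
  spatial scale relative to the bin width blur together.
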