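# Methods

## Normalization model

A Ct value is a log2-scale measurement: each PCR cycle doubles the product,
so differences in Ct are log2 fold changes with the sign reversed (lower Ct
= more transcript). For gene *g* with pooled median Ct *m_g* over all cells
with a successful reaction — pooled across both experimental groups, so
cross-group comparisons share one reference — expression is

    expr[c, g] = clip(m_g − Ct[c, g], −B, +B),        B = 5 by default.

The bound caps the representable range at ±5 cycles, i.e. 32-fold in linear
units. Reactions that failed to amplify carry no information beyond "below
detection"; they are excluded from the median (so non-expressers do not
define the center) and assigned the floor −B. Clipping is applied after
centering, with the closed interval kept (values exactly at ±B are valid).
Even-length medians are the midpoint of the two central values. A per-group
pooling mode exists (`per_group=True`) for designs where a shared reference
is inappropriate.

Degenerate input: a gene with no successful reaction anywhere is retained
at the floor with a warning rather than dropped, so the gene panel stays
aligned across matrices.

## Clustering

Cells are partitioned by k-means on the normalized matrix, minimizing the
within-cluster sum of squared Euclidean distances (WCSS). The
implementation is Lloyd's algorithm with k-means++ seeding, taking the best
of `n_init = 50` restarts; given a seed and input order the fit is
deterministic, and more restarts can only lower the returned WCSS. Empty
clusters are re-seeded from the point farthest from its centroid.
Non-expressers enter at the floor −B: a cell failing a cluster's markers is
thereby distant from that cluster in those coordinates, which is the
desired treatment of presence/absence structure. Assignment ties at exactly
equal centroid distance resolve to the lowest cluster index.

Hierarchical clustergrams use complete linkage on Euclidean distances
(scipy's implementation), which guarantees monotone merge heights. Heatmap
row order (`subgroup_order`) places each k-means cluster as a contiguous
block, ordered internally by its complete-linkage leaf order, with blocks
sequenced by a dendrogram over the centroids.

The number of clusters is chosen by mean silhouette width over a candidate
range, with per-k WCSS and silhouette returned for audit and a gap-style
alternative deliberately out of scope. On a 96-gene panel the mean
silhouette of even well-separated subpopulations is deflated by the
noise dimensions (observed maxima near 0.08 at the correct k on default
synthetic data), so the `no_structure` flag — raised when no candidate k
reaches 0.25 — is conservative: it reliably fires on homogeneous data
(observed maxima below 0.02) but can also fire on structured data. The
flag annotates the diagnostics table; it never vetoes the selected k.

## Differential testing

Per-gene comparisons use the two-sample Kolmogorov–Smirnov test:
D = sup_t |ECDF_x(t) − ECDF_y(t)|, with the asymptotic Kolmogorov
distribution at effective sample size sqrt(nm/(n+m)) supplying the p-value.
The ECDF definition handles the heavy ties at the expression floor without
any continuity correction. p-values are clamped to the smallest positive
float where the asymptotic survival function underflows, keeping them in
(0, 1]. Family-wise error is controlled by Bonferroni with multiplicity
equal to the number of genes in the comparison family (configurable to
genes × clusters for callers treating all cluster-vs-rest runs as one
family), at a strict p < 0.05. Direction is the sign of the focal-minus-
reference median; the focal group is the lexicographically first label
unless named explicitly, so relabeling groups flips directions but not
statistics. FDR procedures are intentionally absent.

Calibration, recomputed by the test suite: the uncorrected test at nominal
0.05 rejects in [0.03, 0.07] of 2000 null draws (n = 30 vs 30), and
Bonferroni over 96 null genes holds the family-wise error at or below 0.05
across 1000 simulated panels (within binomial sampling slack).

## Cross-group cluster matching

Groups are clustered independently and their clusters matched one-to-one
in centroid space by exact minimum-cost assignment (Hungarian algorithm)
on Euclidean centroid distances, mirroring a per-group clustering design;
joint re-clustering is a different analysis and is not what the matcher
models. Matched pairs farther apart than `max_dist` are broken. The default
`max_dist` is the 95th percentile of the first model's member-to-centroid
distances: scale-aware, since a genuine counterpart should lie no farther
from a cluster's centroid than that cluster's own peripheral members.
Calls per first-group cluster: *absent* if unmatched or the counterpart's
abundance is strictly below a 2% minority floor; *depleted* if the
abundance ratio falls below 0.5 or the counterpart sits exactly at the
floor (tie rule); otherwise *present*. The thresholds are explicit,
configurable stand-ins for what is usually judged visually from heatmaps.

## Image quantification

The blue (DAPI) channel is binarized with an automated image-specific
threshold — Otsu's method, the standard instantiation of auto-binarization,
pluggable via `dapi_method` — and nuclei are counted as 8-connected
components strictly larger than 15 pixels. Red and green stain channels are
binarized at a fixed 0.30 threshold on unit-scaled intensity (8/16-bit
inputs are rescaled to [0, 1] first), held constant across images of the
same stain so areas are comparable; pixels strictly above threshold count.
Stain area divided by nucleus count gives area-per-cell; with zero nuclei
the quotient is reported missing with a warning. Touching nuclei are not
watershed-split. A flat blue channel yields zero nuclei by construction.

## Morphometry

Caliper tumor volume is the standard half-ellipsoid-style formula
V = 0.5·L·W·H (cm → cm³) and density D = M/V (g/cm³); dimensions are
validated non-negative and volume must be positive for density. Wound
series reduce to fraction-open (area relative to day 0) with the closure
day defined as the first day at or below an epsilon that defaults to
exactly zero (configurable for traced-area noise). qRT-PCR relative
expression is 2^−ΔCt against a reference gene, with an optional calibrator
delta for the ΔΔCt form.

## Synthetic data

The generator emulates the sorted-cell array design the pipeline targets:
384 cells in four 96-well plates (two plates per group, sequential fill, no
batch effects), a 96-gene panel, and four latent subpopulations. Each
subpopulation owns an 8-gene marker block whose mean Ct is 4 cycles below
the 25-cycle background — a 16-fold planted effect, comparable to the ±5
dynamic range after clipping — with Gaussian cycle noise of sd 1.0 and
independent per-reaction dropout of 0.15, a mid-range failed-amplification
rate for panels mixing robust and marginal assays. Group mixing proportions
default to 0.30/0.25/0.25/0.20 in the first group and 0.45/0/0.10/0.45 in
the second: one subpopulation absent, one depleted below the 0.5 ratio, two
preserved — the qualitative structure the cross-group matcher exists to
detect. All values are configurable; a one-cluster `null_spec` and an
`identical_groups_spec` provide negative controls.

What the generator does not model: plate/batch effects, doublets,
cluster-correlated dropout gradients, gene–gene correlation within a cell
beyond cluster membership, and amplification efficiency differences between
assays. Passing tests therefore demonstrate correctness of the algorithms
under the assumed mixture-of-Gaussians-with-dropout model, not robustness
to those real-data artifacts.

## Problem sizes and determinism

Simulation-based checks use 100 generator seeds for cluster recovery and
absence detection, 2000 null draws for type-I calibration, and 1000
96-gene panels for the family-wise error check; brute-force oracles run at
n ≤ 10 (exhaustive k-means partitions, O(n³) linkage, permutation
assignment). Every stochastic path is seeded: the generator, k-means
restarts, and property-test data. Identical seeds give bit-identical
outputs.

## Known limitations

- The silhouette criterion inherits its high-dimensional deflation (above);
  for panels much larger than the cell count a variance-filtered or
  distance-based selector would be preferable.
- Asymptotic K–S p-values are conservative at very small samples; a
  permutation alternative is a natural extension (small samples currently
  trigger a warning below n = 5).
- Cluster matching assumes the normalization placed both groups on one
  scale (enforced by requiring a shared gene panel and bound); it does not
  model partial cluster splits or merges across groups.
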