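# Methods

## The model

`spatialcomm` treats a tissue image as a marked point pattern: cell *i* has a
centroid (x, y) in µm (for IMC, 1 pixel = 1 µm), a categorical cell type from
a declared palette, and non-negative per-marker mean intensities. All spatial
reasoning happens on two neighborhood constructions:

* **Radius neighborhoods.** Cells a and b are neighbors when their centroid
  distance is ≤ `radius_px` (default 15, inclusive boundary) and they share
  an image. The radius equals roughly one cell diameter, so neighbors are
  cells "up to one cell away", and neighborhood *size* carries local-density
  information. This is a centroid approximation of the
  boundary-to-boundary neighbor relation that segmentation pipelines
  (CellProfiler "Measure Object Neighbors") produce from masks; masks are
  out of scope here, and the radius is configurable to compensate for the
  missing cell-body extent.
* **kNN windows.** Each cell's window is its `window_k` = 10 nearest cells
  *including itself* (ties broken by (distance, cell_id) so the construction
  is deterministic; windows truncate in images smaller than k). "10 including
  the center" was chosen over "center + 10" as the reading of the
  fixed-size-window workflow; the parameter is configurable.

The per-cell feature for community detection is the neighbor-type proportion
vector `p_i(X) = (# neighbors of type X) / (# neighbors)`, range 0–1, summing
to 1 for every cell with at least one neighbor. The center cell is excluded
from its own denominator in the radius route (the neighbor relation is
between distinct objects) and included in the window route. Isolated cells
keep an all-zero profile, are flagged, and are retained: they cluster into
their own low-diversity communities rather than being dropped.

## Community detection

**Graph route (default).** A kNN graph (euclidean, parameter `knn_k`) is
built on the profile vectors, edges are reweighted by the Jaccard overlap of
the endpoints' kNN sets, and the graph is partitioned by Louvain modularity
optimization — the PhenoGraph recipe. Louvain (igraph `community_multilevel`)
is the default to mirror the R implementation this analysis style grew out
of; Leiden (`leidenalg`) is available via `method="leiden"`. Runs are
deterministic for a fixed seed, and community ids are canonicalized to 1..K
by descending size.

Modularity optimization *over-partitions* dense structure by design (a
single tight blob can split into several fine communities), which is why the
workflow pairs it with **agglomeration**: average-linkage hierarchical
clustering (euclidean) of the community composition profiles, cut at
`target_n`. "Composition" here is the distribution of member cells' *own*
types — the quantity composition bar charts show — not the mean neighbor
profile; both are stored on the labeling. Low-diversity, near-duplicate
communities (e.g. minor variants of tumor-dominated neighborhoods) merge
first; the merge order is recorded as a tree. The linkage and metric are
package choices (the upstream analyses do not state theirs); both live in
one place (`communities.agglomerate`) if a different linkage is wanted.

`knn_k` is a resolution knob. The conventional k = 250 applies to datasets
of 10⁵ cells and more; at the ~5×10³-cell scale of the synthetic studies the
package holds k near 1 % of the cells (k ≈ 50), and the cross-parameter
stability check uses k = 40 vs 80. Stability is assessed by Pearson
correlation of matched community composition profiles across runs
(`match_communities`, greedy assignment by descending correlation with ties
broken by community size).

**Window route.** Mini-batch k-means (fixed `random_state`, `n_init=10`) on
raw window cell-type *count* vectors (counts, not proportions, mirroring the
tissue-core workflow); each cell inherits its window's cluster. Communities
are profiled as z-scores of cell-type proportions across communities
(sample sd, ddof = 1; zero-variance cell types get z = 0 with a warning).

## Permutation enrichment

For focal type F in community C of image I, the observed statistic per
neighbor type T is the mean number of T-neighbors per focal cell, computed on
the fixed radius graph restricted to C's cells. The null shuffles cell-type
labels `n_perm` = 1000 times while keeping positions, edges, and community
membership fixed; by default the permutation pool is the (image × community)
stratum ("separated by community"), with a whole-image pool available
(`within="image"`). Either all labels are shuffled (default) or the focal
cells' labels are held fixed (`permute="nonfocal"`); which variant the
original analyses used is not documented, so both exist and the default is
stated here. Summaries:

* `log2FC = log2((obs + ε)/(null_mean + ε))` with ε = 1, so zero counts are
  defined and shrunk toward the null;
* one-sided p-values with add-one correction,
  `p = (1 + #{perm ≥ obs}) / (n_perm + 1)` — never exactly 0, bounded below
  by 1/(n_perm+1);
* `significant ⇔ min(p_enrich, p_deplete) ≤ alpha` (default 0.01).

The permutation pool is traversed in cell_id order and each image draws its
own RNG stream from (seed, image id), so results are invariant to the row
order of the input and to which other images share the table.

**Conditional analysis.** Focal cells are stratified by the presence of ≥ 1
conditioning-type cell (e.g. T_reg) in their radius neighborhood; the test
then runs per stratum with the conditioning cells' labels held fixed under
the null. Holding them fixed is essential: the stratum definition is
position-based, and letting conditioning labels move would dissolve the very
structure being conditioned on.

**Interaction counts.** The marker-conditioned variant counts
marker-positive neighbors of a target type (intensity strictly > 0.5 by
default) per focal cell and normalizes by the marker-positive prevalence of
the target type, per image by default (`per="group"` pools the prevalence
over a treatment arm). Zero prevalence flags the record undefined rather
than dividing by zero.

## Spatial statistics

* **Distances:** per source cell, the euclidean nearest target in the same
  image (kd-tree), dropped and flagged beyond `max_dist_px` = 800;
  self-matches are excluded when a cell satisfies both predicates. Two-class
  comparisons use the Mann–Whitney rank-sum test (the upstream analyses
  report significance tiers without naming a test; rank-sum is the
  distribution-free default for skewed distance data). Distances are also
  reported log2(x+1)-scaled for display.
* **Cross-sections:** positions are projected on the first principal axis of
  the tumor cells' coordinates (configurable to x/y), centered on the tumor
  centroid; community member counts are histogrammed in signed-position
  bins, out-of-range cells landing in the edge bins so rows sum to community
  sizes. Note the projection geometry: an annular community peaks near
  ±tumor radius but is nonzero at position 0 (chords of the ring).
* **Correlations:** Pearson r and two-sided p per cell-type pair across
  units (ROIs or communities), zero-variance types masked, display order
  from average-linkage clustering of 1 − r; significance tiers */**/*** at
  0.05/0.01/0.001. Community-level correlation is the higher-powered
  alternative to per-ROI correlation for detecting localized co-occurrence.
* **Density:** community member count divided by tissue area in mm². Tissue
  area defaults to the convex hull of the image's cells (the source of
  "total tissue area" in upstream work is unstated; known ROI areas can be
  passed in). Presence is boundary-inclusive at ≥ 25 cells/mm². A community
  *set* is present when the summed density of its members reaches the
  threshold; co-occurrence is the fraction of images where both sets are
  present.
* **Covariate association:** Spearman rho between per-image community
  density and a numeric covariate (≥ 4 pairs; constant inputs flagged). This
  deliberately replaces mixed-effects modelling, which is out of scope.

## Synthetic tissue: what it emulates, and what it does not

One ROI is a 920 × 920 µm field with a circular tumor (radius 240 µm), an
interface ring (width 100 µm), and normal tissue outside. Background cells
are homogeneous Poisson per region at 0.0075 / 0.0055 / 0.0045 cells/µm²
(tumor / interface / normal) — 4500–7500 cells/mm², i.e. confluent segmented
tissue in which almost every cell has neighbors within one cell diameter.
Region mixtures use a 14-type palette: a tumor-cell-dominated core, an
M1-macrophage-lined interface, and epithelium/endothelium-rich normal
tissue. Hubs — T/DC aggregates (100 cells, radius 35 µm, CD8/CD4/T_reg/DC
mix) and myeloid aggregates — are placed mid-interface as truncated Gaussian
blobs; all T/DC hubs plant one community. The default ROI carries ~5,000
cells and exactly 5 planted communities.

Markers are log-normal per cell with additive log-mean shifts by cell type,
hub membership, planted community, and treatment group. The defaults encode
a hub activation phenotype (CXCL9 on hub DCs, PD-1 on hub T cells, CD86 on
hub DCs, Ki67/cleaved caspase-3 on hub tumor cells), so marker-conditioned
analyses have planted effects. `treg_conditional_spec` plants the
conditional contrast: T_reg-containing hubs displace their DCs to the hub
rim (suppressed CD8–DC adjacency), T_reg-free hubs keep DCs in the core.
Group effects can scale hub sizes, drop hubs or T_regs, displace hub types,
and shift marker means per arm.

What the generator does **not** emulate: cell shapes and masks (so the
boundary-distance neighbor rule is approximated by centroid distance),
segmentation errors and cell-typing noise, spatial marker gradients beyond
the hub/community structure, holes and folds in tissue, multiple or
irregular tumors (the geometry is one disk + ring, though multiple specs can
be composed), and between-patient heterogeneity. Passing tests therefore
demonstrate correctness of the *method* under a faithful-but-idealized
tissue model, not performance on real IMC images.

## Numerical and reproducibility choices

* Every stochastic step takes an explicit seed; per-image and per-stage
  seeds are spawned from the master seed, so any stage is independently
  reproducible and two runs with the same config produce byte-identical
  artifacts (checked by SHA-256 digest in the run manifest).
* log2 scaling uses a +1 pseudocount (configurable); the marker high/low cut
  (default 0.5) applies to the stored, unscaled intensity with a strict `>`.
* kNN ties break on (distance, cell_id); permutation pools are traversed in
  cell_id order; community ids sort by descending size — all so that equal
  inputs give equal outputs regardless of row order.
* p-value comparisons use a 1e-12 tolerance so ties between observed and
  permuted statistics (which are rationals with a common denominator) count
  as "at least as extreme".
* Degenerate inputs: empty images yield empty adjacency; all-identical
  profiles yield one community; images without focal cells are skipped with
  a warning; zero-variance types are masked (correlation) or zeroed
  (z-scores); zero marker prevalence flags the interaction count undefined.

## Problem sizes used in tests

The test suite and the acceptance script run on simulated data sized for a
single CPU: ~5,000-cell ROIs for community recovery and stability, a
~15,000-cell 3-image cohort for the profile invariant, 40 × 400-cell images
(560 tests) for type-I error, a 12-cell toy image (2,970 distinct label
arrangements) for exact-enumeration agreement at 10,000 permutations, and
5-image cohorts for the conditional contrast. These sizes are the package's
reference study conditions; all scale linearly upward with cell count except
the Louvain step, whose kNN-graph construction dominates at ≥10⁵ cells.

## Known limitations

* Centroid-based neighborhoods undercount neighbors of large or elongated
  cells relative to mask-based detection.
* Modularity optimization's resolution is controlled only indirectly
  (through `knn_k` and agglomeration); the number of fine communities is
  not a stable quantity across parameter choices — compositions are (that
  is the stability property actually tested).
* The permutation null conditions on positions and the community partition;
  it does not test against spatial point-process alternatives
  (pair-correlation structure, inhomogeneity within a community).
* Convex-hull tissue area overestimates density denominators for concave or
  fragmented tissue.
* Cross-image inference is left to the caller: enrichment results are
  per-image, and no multiple-testing correction is applied by default (the
  per-image significance convention is kept deliberately); an optional
  Benjamini–Hochberg helper (`adjust_pvalues`) adds FDR-adjusted columns for
  callers who want them.
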