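# spatialcomm

Spatial cellular-community analysis for multiplexed tissue imaging
(imaging mass cytometry and similar segmented single-cell data).

Multiplexed imaging yields one row per segmented cell — centroid, cell type,
marker intensities — but single-cell statistics discard how cells are
*arranged*. `spatialcomm` groups cells not by their own phenotype but by the
**cell-type composition of their local neighborhood**, recovering recurring
spatial patterns ("communities") of the tumor microenvironment such as
T cell/dendritic cell activation hubs at the tumor interface, and then asks
targeted questions of those communities: which cell pairs are enriched around
a focal cell type, how that changes when regulatory T cells are present, how
far marker-defined cell classes sit from each other, and how community
density behaves across images.

## What it computes

For each cell *i* with neighborhood *N(i)* (all cells within radius
*r* = 15 µm, about one cell diameter):

```
p_i(X) = |{ j ∈ N(i) : type(j) = X }| / |N(i)|,   X ∈ palette
```

* **Communities (graph route)** — PhenoGraph-style clustering of the
  profile vectors `p_i`: k-nearest-neighbor graph, edges weighted by shared
  kNN (Jaccard) overlap, Louvain modularity optimization (Leiden optional);
  fine communities are agglomerated to a target count by average-linkage
  hierarchical clustering of community composition profiles.
* **Communities (window route)** — mini-batch k-means on the cell-type
  counts of each cell's 10-nearest-neighbor window, with z-score community
  profiles (the workflow used for large tissue-core cohorts).
* **Neighborhood enrichment** — for focal cells of one type inside one
  community, the mean per-focal-cell count of each neighbor type is compared
  with a null that permutes cell-type labels within the (image × community)
  stratum: `log2FC = log2((obs + 1)/(null + 1))`, one-sided p-values with
  add-one correction, significance at `min(p) ≤ 0.01`. A conditional mode
  splits focal cells by the presence of a conditioning type (e.g. T_regs) in
  their neighborhood, holding the conditioning cells fixed under the null.
* **Spatial statistics** — capped nearest-neighbor distances between
  marker-defined classes with rank-sum comparison; cross-section community
  profiles through the tumor center; per-ROI/per-community cell-type Pearson
  correlation; hierarchical ROI clustering; community density (cells/mm²)
  with presence calls at ≥ 25 cells/mm² and co-occurrence; Spearman
  association of density with a per-image covariate.
* **Synthetic tissue** — a generator planting all of the above: Poisson
  tissue regions (tumor core / interface ring / normal), hub communities,
  log-normal marker models with community- and treatment-linked shifts, and
  full per-cell ground truth.

## Worked example

```python
import warnings
from sklearn.metrics import adjusted_rand_score
import spatialcomm as sc

table, truth = sc.generate_tissue(sc.default_tissue_spec(seed=1))
graph = sc.build_neighbor_graph(table, radius_px=15.0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    profiles = sc.neighborhood_profiles(table, graph)

fine = sc.cluster_profiles(profiles, knn_k=50, seed=1, cells=table)
final, tree = sc.agglomerate(fine, target_n=5)
print(fine.n_communities, adjusted_rand_score(truth.planted, final.labels))
```

prints `24 0.840…`: Louvain finds 24 fine communities in the ~5,100-cell
tissue; agglomerating them to 5 recovers the planted structure (tumor core,
interface ring, normal tissue, T/DC hub, myeloid hub) with adjusted Rand
index 0.840. The recovered composition matrix makes the communities
recognizable — e.g. community 2 is 80 % tumor cells and community 5 carries
the T/DC hub mix (17 % CD4, 18 % CD8, 12 % T_reg, 16 % DC subsets).

The conditional enrichment analysis (`examples/03_conditional_enrichment.py`)
shows the planted T_reg effect: around CD8 T cells *with* a T_reg neighbor,
dendritic cells are significantly depleted (log2FC −2.46), while in the
*without* stratum DC contact is at or above its null (log2FC +0.08); CXCL9-high
dendritic cells sit a median 4.6 µm from their nearest PD-1⁺ CD8 T cell
versus 75.7 µm for CXCL9-low DCs (rank-sum p ≈ 2 × 10⁻⁷⁵,
`examples/04_distances_density.py`).

Each script in `examples/` is a short narrative: simulation ground truth,
community detection, conditional enrichment, distances/density, and the
window/k-means variant. The same stages are scriptable from a shell:

```bash
spatialcomm run --seed 7 --n-images 4 --out-dir run/
```

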