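"""Spatial community detection on neighborhood features.

Cells are grouped not by their own phenotype but by the composition of their
local neighborhood. Two detectors are provided:

* :func:`cluster_profiles` — a PhenoGraph-style procedure on radius-
  neighborhood proportion vectors: k-nearest-neighbor graph (euclidean),
  edges reweighted by shared-neighbor (Jaccard) overlap, then Louvain
  modularity optimization (Leiden optional). Fine communities are merged to a
  target count with :func:`agglomerate` (average-linkage hierarchical
  clustering of community composition profiles); low-diversity near-duplicate
  communities merge first.
* :func:`window_kmeans` — mini-batch k-means on fixed-size kNN-window
  cell-type count vectors, the workflow used for large human tissue-core
  panels, with :func:`zscore_profile` for the community × cell-type z-score
  heatmap.

Community ids are canonicalized to 1..K by descending cell count so repeated
runs with the same seed are directly comparable.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.cluster import MiniBatchKMeans
from sklearn.neighbors import NearestNeighbors

from .io_model import CellTable, Palette, ParameterError
from .neighborhoods import KnnWindows, NeighborhoodProfiles


@dataclass
class CommunityLabeling:
    """Per-cell community assignment plus per-community profiles.

    Two composition summaries are kept: ``cell_type_composition`` (the
    distribution of member cells' *own* types — what composition bar charts
    show, and the feature used for agglomeration and cross-run matching) and
    ``neighbor_composition`` (the mean neighborhood profile of members).
    """

    labels: np.ndarray                       # community id per cell (1..K)
    sizes: pd.Series                         # id -> member count
    cell_type_composition: pd.DataFrame | None = None   # id × palette
    neighbor_composition: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    @property
    def community_ids(self) -> list[int]:
        return list(self.sizes.index)

    def composition(self) -> pd.DataFrame:
        comp = (self.cell_type_composition
                if self.cell_type_composition is not None
                else self.neighbor_composition)
        if comp is None:
            raise ParameterError("labeling carries no composition profile")
        return comp

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.labels == community)


@dataclass
class MergeTree:
    """Recorded agglomeration: (id_a, id_b, merged_id, distance) per merge."""

    merges: list[tuple[int, int, int, float]]
    mapping: dict[int, int]                  # original id -> final id

    def to_records(self) -> list[dict]:
        return [{"a": a, "b": b, "merged": m, "distance": d}
                for a, b, m, d in self.merges]


@dataclass
class CommunityMatch:
    """Cross-labeling composition similarity and greedy best-match pairs."""

    similarity: pd.DataFrame                 # a-id × b-id Pearson r
    assignment: dict[int, int]               # a-id -> b-id
    matched_correlation: pd.Series           # a-id -> r of its match


def _canonicalize(raw: np.ndarray) -> np.ndarray:
    """Relabel to 1..K by descending community size (ties by old id)."""
    ids, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((ids, -counts))
    mapping = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    return np.vectorize(mapping.__getitem__)(raw)


def _cell_type_composition(labels: np.ndarray, cells: CellTable
                           ) -> pd.DataFrame:
    codes = cells.type_codes
    ids = np.unique(labels)
    rows = []
    for cid in ids:
        counts = np.bincount(codes[labels == cid],
                             minlength=cells.palette.n_types)
        rows.append(counts / counts.sum())
    return pd.DataFrame(rows, index=pd.Index(ids, name="community"),
                        columns=list(cells.palette))


def _neighbor_composition(labels: np.ndarray, profiles: np.ndarray,
                          palette: Palette | None) -> pd.DataFrame:
    ids = np.unique(labels)
    rows = [profiles[labels == cid].mean(axis=0) for cid in ids]
    cols = list(palette) if palette is not None \
        else [f"f{j}" for j in range(profiles.shape[1])]
    return pd.DataFrame(rows, index=pd.Index(ids, name="community"),
                        columns=cols)


def make_labeling(labels: np.ndarray, cells: CellTable | None = None,
                  profiles: NeighborhoodProfiles | np.ndarray | None = None,
                  params: dict | None = None) -> CommunityLabeling:
    """Package raw (already canonical) labels with composition profiles."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    sizes = pd.Series(counts, index=pd.Index(ids, name="community"),
                      name="size")
    ctc = _cell_type_composition(labels, cells) if cells is not None else None
    nbc = None
    if profiles is not None:
        mat = profiles.proportions if isinstance(
            profiles, NeighborhoodProfiles) else np.asarray(profiles)
        pal = (profiles.palette if isinstance(profiles, NeighborhoodProfiles)
               else (cells.palette if cells is not None else None))
        nbc = _neighbor_composition(labels, mat, pal)
    return CommunityLabeling(labels=labels, sizes=sizes,
                             cell_type_composition=ctc,
                             neighbor_composition=nbc,
                             params=params or {})


# ---------------------------------------------------------------------------
# graph-based detection

def _jaccard_knn_graph(mat: np.ndarray, knn_k: int) -> ig.Graph:
    n = len(mat)
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(mat)
    _, idx = nn.kneighbors(mat)
    idx = idx[:, 1:]                       # drop self
    rows = np.repeat(np.arange(n), knn_k)
    a = sp.csr_matrix((np.ones(n * knn_k, dtype=np.float64),
                       (rows, idx.ravel())), shape=(n, n))
    inter = (a @ a.T).tocsr()
    sym = ((a + a.T) > 0).tocoo()
    mask = sym.row < sym.col
    ei, ej = sym.row[mask], sym.col[mask]
    shared = np.asarray(inter[ei, ej]).ravel()
    weights = shared / (2.0 * knn_k - shared)
    keep = weights > 0
    edges = np.column_stack([ei[keep], ej[keep]])
    g = ig.Graph(n=n, edges=edges.tolist())
    g.es["weight"] = weights[keep].tolist()
    return g


def cluster_profiles(profiles: NeighborhoodProfiles | np.ndarray,
                     knn_k: int, seed: int,
                     cells: CellTable | None = None,
                     method: str = "louvain") -> CommunityLabeling:
    """PhenoGraph-style community detection on neighborhood profiles.

    Builds a euclidean kNN graph on the profile vectors, reweights edges by
    the Jaccard overlap of the endpoints' kNN sets, and partitions the graph
    by Louvain modularity optimization (``method="leiden"`` switches to the
    Leiden refinement). The run is deterministic for a fixed seed.

    Pass the cell table via ``cells`` to also record the member-cell-type
    composition needed by :func:`agglomerate` and :func:`match_communities`.
    """
    mat = profiles.proportions if isinstance(profiles, NeighborhoodProfiles) \
        else np.asarray(profiles, dtype=float)
    n = len(mat)
    if knn_k >= n:
        raise ParameterError(f"knn_k={knn_k} must be < n_cells={n}")
    if knn_k < 1:
        raise ParameterError("knn_k must be >= 1")
    params = {"knn_k": knn_k, "seed": seed, "method": method}
    if np.ptp(mat, axis=0).max() == 0:     # no structure at all
        return make_labeling(np.ones(n, dtype=int), cells, profiles, params)
    g = _jaccard_knn_graph(mat, knn_k)
    if method == "louvain":
        state = _pyrandom.getstate()
        try:
            _pyrandom.seed(seed)
            part = g.community_multilevel(weights="weight")
        finally:
            _pyrandom.setstate(state)
        raw = np.asarray(part.membership)
    elif method == "leiden":
        import leidenalg
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, weights="weight",
            seed=seed)
        raw = np.asarray(part.membership)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return make_labeling(_canonicalize(raw), cells, profiles, params)


# ---------------------------------------------------------------------------
# agglomeration

def agglomerate(labeling: CommunityLabeling, target_n: int
                ) -> tuple[CommunityLabeling, MergeTree]:
    """Merge communities down to ``target_n`` by composition similarity.

    Average-linkage hierarchical clustering on euclidean distance between
    community composition profiles, cut at ``target_n`` clusters. Communities
    with (near-)identical composition — typically the low-diversity ones —
    merge first. Merged communities are relabeled 1..target_n by descending
    size; the merge order is returned as a :class:`MergeTree`.
    """
    comp = labeling.composition()
    k = labeling.n_communities
    if target_n < 1:
        raise ParameterError("target_n must be >= 1")
    if target_n >= k:
        raise ParameterError(f"target_n={target_n} must be < current "
                             f"community count {k}")
    ids = np.asarray(comp.index)
    z = linkage(comp.to_numpy(), method="average", metric="euclidean")
    cut = cut_tree(z, n_clusters=target_n).ravel()

    # record the first (k - target_n) merges in linkage order
    merges: list[tuple[int, int, int, float]] = []
    node_repr: dict[int, int] = {i: int(ids[i]) for i in range(k)}
    for step in range(k - target_n):
        a, b, dist, _ = z[step]
        ra, rb = node_repr[int(a)], node_repr[int(b)]
        node_repr[k + step] = min(ra, rb)
        merges.append((ra, rb, min(ra, rb), float(dist)))

    new_raw = np.empty_like(labeling.labels)
    group_of = {int(ids[i]): int(cut[i]) for i in range(k)}
    for cid, grp in group_of.items():
        new_raw[labeling.labels == cid] = grp + 1
    new_labels = _canonicalize(new_raw)

    # final mapping old -> new, and merged compositions (size-weighted)
    mapping = {}
    for cid in ids:
        sel = labeling.labels == cid
        mapping[int(cid)] = int(new_labels[sel][0]) if sel.any() else -1
    sizes = labeling.sizes

    def _merge_comp(old: pd.DataFrame | None) -> pd.DataFrame | None:
        if old is None:
            return None
        w = sizes.reindex(old.index).to_numpy(dtype=float)
        new_ids = sorted(set(mapping.values()) - {-1})
        rows = []
        for nid in new_ids:
            members = [i for i in old.index if mapping[int(i)] == nid]
            ww = w[[list(old.index).index(i) for i in members]]
            block = old.loc[members].to_numpy()
            rows.append((block * ww[:, None]).sum(axis=0) / ww.sum())
        return pd.DataFrame(rows, index=pd.Index(new_ids, name="community"),
                            columns=old.columns)

    ids_new, counts_new = np.unique(new_labels, return_counts=True)
    new = CommunityLabeling(
        labels=new_labels,
        sizes=pd.Series(counts_new, index=pd.Index(ids_new, name="community"),
                        name="size"),
        cell_type_composition=_merge_comp(labeling.cell_type_composition),
        neighbor_composition=_merge_comp(labeling.neighbor_composition),
        params={**labeling.params, "agglomerated_to": target_n})
    return new, MergeTree(merges=merges, mapping=mapping)


# ---------------------------------------------------------------------------
# cross-run matching and summaries

def match_communities(a: CommunityLabeling, b: CommunityLabeling
                      ) -> CommunityMatch:
    """Pearson-correlation matching of community composition profiles.

    Computes the full a × b correlation matrix of composition profiles, then
    pairs communities greedily by descending correlation (ties broken by
    community size). Used to check that runs with different graph parameters
    find the same communities.
    """
    ca, cb = a.composition(), b.composition()
    if list(ca.columns) != list(cb.columns):
        raise ParameterError("labelings use different palettes")
    am, bm = ca.to_numpy(), cb.to_numpy()
    with np.errstate(invalid="ignore"):
        full = np.corrcoef(am, bm)
    r = np.nan_to_num(full[:len(am), len(am):], nan=0.0)
    sim = pd.DataFrame(r, index=ca.index, columns=cb.index)
    pairs = [(float(r[i, j]), float(a.sizes.iloc[i]), i, j)
             for i in range(len(am)) for j in range(len(bm))]
    pairs.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    assignment: dict[int, int] = {}
    corr: dict[int, float] = {}
    for val, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ai, bj = int(ca.index[i]), int(cb.index[j])
        assignment[ai] = bj
        corr[ai] = val
        if len(used_a) == min(len(am), len(bm)):
            break
    return CommunityMatch(similarity=sim, assignment=assignment,
                          matched_correlation=pd.Series(corr).sort_index())


def rank_by_cell_type(labeling: CommunityLabeling, cells: CellTable,
                      cell_type: str, top_n: int = 5
                      ) -> tuple[pd.Series, float]:
    """Top communities by member count of one cell type, plus coverage.

    Returns the ``top_n`` community ids ranked by how many cells of
    ``cell_type`` they contain, and the fraction of all such cells those
    communities hold (e.g. "the top five CD8 T cell communities contain 75%
    of all CD8 T cells").
    """
    cells.palette.index(cell_type)
    is_type = (cells.df["cell_type"] == cell_type).to_numpy()
    total = int(is_type.sum())
    if total == 0:
        warnings.warn(f"no cells of type {cell_type!r} present", stacklevel=2)
        return pd.Series(dtype=int), float("nan")
    counts = pd.Series(labeling.labels[is_type]).value_counts()
    counts = counts.sort_values(ascending=False)
    top = counts.iloc[:top_n]
    return top, float(top.sum() / total)


# ---------------------------------------------------------------------------
# window/k-means variant

def window_kmeans(windows: KnnWindows, n_clusters: int, seed: int,
                  cells: CellTable | None = None) -> CommunityLabeling:
    """Mini-batch k-means on kNN-window composition count vectors.

    Each cell is assigned the cluster of its window; features are the raw
    window cell-type counts. Deterministic for a fixed seed.
    """
    n = len(windows.counts)
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ParameterError("n_clusters exceeds the number of cells")
    km = MiniBatchKMeans(n_clusters=n_clusters, random_state=seed,
                         n_init=10, batch_size=1024)
    raw = km.fit_predict(windows.counts.astype(float))
    labels = _canonicalize(raw)
    lab = make_labeling(labels, cells,
                        params={"n_clusters": n_clusters, "seed": seed,
                                "window_k": windows.window_k})
    if lab.cell_type_composition is None:
        # fall back to window-based composition when no table was given
        sizes = windows.counts.sum(axis=1, keepdims=True)
        props = windows.counts / np.maximum(sizes, 1)
        lab.neighbor_composition = _neighbor_composition(
            labels, props, windows.palette)
    return lab


def zscore_profile(labeling: CommunityLabeling) -> pd.DataFrame:
    """Community × cell-type z-scores of composition proportions.

    Each cell type's proportion is standardized across communities (mean 0,
    sample sd 1), the representation used for community heatmaps. Cell types
    with zero variance across communities get z = 0 with a warning.
    """
    comp = labeling.composition()
    if len(comp) < 2:
        raise ParameterError("zscore_profile needs >= 2 communities")
    mat = comp.to_numpy(dtype=float)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance cell type(s) "
                      f"{list(comp.columns[zero])}: z set to 0", stacklevel=2)
    z = np.zeros_like(mat)
    np.divide(mat - mu, sd, where=~zero, out=z)
    return pd.DataFrame(z, index=comp.index, columns=comp.columns)
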