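"""Neighbor graphs and neighborhood composition features.

Two neighborhood definitions are supported, mirroring the two community
workflows used for mouse and human IMC panels:

* a fixed-radius graph (default 15 µm = 15 px, about one cell diameter, so
  neighbors are cells "up to one cell away"); neighborhood sizes then reflect
  local density. Boundary-to-boundary distance from segmentation masks is
  approximated by centroid-to-centroid distance at the same radius.
* k-nearest-neighbor *windows* (default 10 cells including the center), the
  fixed-size variant used with mini-batch k-means community detection.

The per-cell feature for community detection is the proportion of each
palette cell type among a cell's neighbors:

    proportion(X) = (# neighbors of type X) / (# neighbors),   range 0–1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .io_model import CellTable, Palette, ParameterError


@dataclass
class NeighborGraph:
    """Symmetric radius adjacency over a cell table's row order.

    ``matrix`` is an n×n boolean CSR with no diagonal; edges only connect
    cells of the same image.
    """

    matrix: sp.csr_matrix
    radius: float
    image_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def neighbors_of(self, i: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[i]:
                                   self.matrix.indptr[i + 1]]


def build_neighbor_graph(cells: CellTable, radius_px: float = 15.0
                         ) -> NeighborGraph:
    """Adjacency: (a, b) neighbors iff same image and ‖a − b‖ ≤ radius_px.

    The boundary case is inclusive (distance exactly equal to the radius
    counts as a neighbor). Empty images simply contribute no edges.
    """
    if radius_px <= 0:
        raise ParameterError("radius_px must be > 0")
    n = cells.n_cells
    coords = cells.coords
    image_ids = cells.df["image_id"].to_numpy()
    rows, cols = [], []
    for img in cells.images:
        idx = cells.image_rows(img)
        if len(idx) < 2:
            continue
        tree = cKDTree(coords[idx])
        pairs = tree.query_pairs(r=radius_px, output_type="ndarray")
        if len(pairs):
            a, b = idx[pairs[:, 0]], idx[pairs[:, 1]]
            rows.extend([a, b])
            cols.extend([b, a])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        m = sp.csr_matrix((np.ones(len(r), dtype=np.int8), (r, c)),
                          shape=(n, n))
    else:
        m = sp.csr_matrix((n, n), dtype=np.int8)
    m.sum_duplicates()
    m.data[:] = 1
    return NeighborGraph(matrix=m, radius=float(radius_px),
                         image_ids=image_ids)


@dataclass
class NeighborhoodProfiles:
    """Per-cell neighbor-type proportion vectors.

    Rows of ``proportions`` sum to 1 for every cell with at least one
    neighbor; isolated cells carry the all-zero vector and are flagged in
    ``isolated``.
    """

    proportions: np.ndarray          # n_cells × n_types, rows sum to 1 or 0
    counts: np.ndarray               # raw neighbor-type counts
    neighborhood_size: np.ndarray    # per-cell neighbor count
    isolated: np.ndarray             # bool mask
    palette: Palette

    def as_frame(self, cells: CellTable) -> pd.DataFrame:
        out = pd.DataFrame(self.proportions, columns=list(self.palette))
        out.insert(0, "cell_id", cells.df["cell_id"].to_numpy())
        out.insert(1, "image_id", cells.df["image_id"].to_numpy())
        out["neighborhood_size"] = self.neighborhood_size
        return out


def _one_hot(codes: np.ndarray, n_types: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix((np.ones(n, dtype=np.float64),
                          (np.arange(n), codes)), shape=(n, n_types))


def neighborhood_profiles(cells: CellTable, graph: NeighborGraph,
                          include_center: bool = False
                          ) -> NeighborhoodProfiles:
    """Neighbor cell-type proportions per cell (the clustering feature).

    The center cell is excluded from its own denominator by default (the
    neighbor relation holds between distinct cells); pass
    ``include_center=True`` for window-style compositions. Isolated cells get
    an all-zero profile and are flagged rather than dropped, so they survive
    into clustering as their own low-diversity group.
    """
    if graph.n_cells != cells.n_cells:
        raise ParameterError("graph was built on a different table")
    codes = cells.type_codes
    onehot = _one_hot(codes, cells.palette.n_types)
    adj = graph.matrix.astype(np.float64)
    if include_center:
        adj = adj + sp.identity(cells.n_cells, format="csr")
    counts = np.asarray((adj @ onehot).todense())
    sizes = counts.sum(axis=1)
    isolated = sizes == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated cell(s) received "
                      "all-zero profiles", stacklevel=2)
    props = np.divide(counts, sizes[:, None], where=sizes[:, None] > 0,
                      out=np.zeros_like(counts))
    return NeighborhoodProfiles(
        proportions=props, counts=counts,
        neighborhood_size=sizes.astype(np.int64),
        isolated=isolated, palette=cells.palette)


@dataclass
class KnnWindows:
    """Fixed-size nearest-neighbor windows around every cell.

    ``indices`` gives, per cell, the global row indices of its window
    (center first); ``counts`` are the window cell-type count vectors used as
    k-means features. Windows truncate in images smaller than ``window_k``.
    """

    indices: list[np.ndarray]
    counts: np.ndarray               # n_cells × n_types integer counts
    window_sizes: np.ndarray
    window_k: int
    palette: Palette


def knn_windows(cells: CellTable, window_k: int = 10) -> KnnWindows:
    """The ``window_k`` nearest cells (center included) around every cell.

    Distances are euclidean within the image; ties are broken by cell_id
    order, so the result is deterministic. The center cell is at distance 0
    and is always part of its own window.
    """
    if window_k < 1:
        raise ParameterError("window_k must be >= 1")
    n = cells.n_cells
    coords = cells.coords
    codes = cells.type_codes
    n_types = cells.palette.n_types
    indices: list[np.ndarray | None] = [None] * n
    counts = np.zeros((n, n_types), dtype=np.int64)
    sizes = np.zeros(n, dtype=np.int64)
    cell_ids = cells.df["cell_id"].to_numpy()
    for img in cells.images:
        idx = cells.image_rows(img)
        # pre-sort by cell_id so a stable distance sort breaks ties by id
        idx = idx[np.argsort(cell_ids[idx], kind="stable")]
        pts = coords[idx]
        k = min(window_k, len(idx))
        chunk = max(1, int(2e7) // max(len(idx), 1))
        for start in range(0, len(idx), chunk):
            block = pts[start:start + chunk]
            d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            order = np.argsort(d2, axis=1, kind="stable")[:, :k]
            for li, row in enumerate(order):
                gi = idx[start + li]
                win = idx[row]
                indices[gi] = win
                counts[gi] = np.bincount(codes[win], minlength=n_types)
                sizes[gi] = k
    return KnnWindows(indices=indices, counts=counts, window_sizes=sizes,
                      window_k=window_k, palette=cells.palette)
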