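"""Distance, density, correlation, and tissue-architecture statistics.

Complements the community detectors with the descriptive spatial statistics
of the workflow: capped nearest-neighbor distances between marker-defined
cell classes (e.g. CXCL9-high vs -low dendritic cells to PD-1⁺ CD8 T cells,
within 800 px), cross-section community profiles through the tumor center,
per-unit cell-type Pearson correlations, hierarchical ROI clustering,
community density with presence calling (≥ 25 cells/mm²) and co-occurrence,
and Spearman association between community density and a per-image covariate
(e.g. tumor mutational burden).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial import ConvexHull, cKDTree

from .communities import CommunityLabeling
from .io_model import CellTable, ParameterError, log2_scale


@dataclass(frozen=True)
class CellPredicate:
    """Selects cells by type and/or a marker intensity cut.

    ``side=">"`` keeps cells with intensity strictly above the threshold
    ("high"/positive), ``side="<="`` the complement ("low"/negative).
    """

    cell_type: str | tuple[str, ...] | None = None
    marker: str | None = None
    threshold: float | None = None
    side: str = ">"

    def mask(self, cells: CellTable) -> np.ndarray:
        m = np.ones(cells.n_cells, dtype=bool)
        if self.cell_type is not None:
            types = (self.cell_type,) if isinstance(self.cell_type, str) \
                else tuple(self.cell_type)
            m &= cells.df["cell_type"].isin(types).to_numpy()
        if self.marker is not None:
            if self.marker not in cells.markers:
                raise ParameterError(f"marker {self.marker!r} not in table")
            v = cells.df[self.marker].to_numpy(dtype=float)
            if self.side == ">":
                m &= v > self.threshold
            elif self.side == "<=":
                m &= v <= self.threshold
            else:
                raise ParameterError(f"unknown side {self.side!r}")
        return m


def min_distance(cells: CellTable, source: CellPredicate,
                 target: CellPredicate, max_dist_px: float = 800.0,
                 labeling: CommunityLabeling | None = None,
                 community: int | None = None) -> pd.DataFrame:
    """Nearest-target distance per source cell, capped at ``max_dist_px``.

    Distances are euclidean within the image (kd-tree search); sources whose
    nearest target lies beyond the cap — or that sit in an image with no
    targets — are flagged ``target_found=False`` and carry no distance.
    ``log2_distance`` applies the package's log2(x+1) display scale.
    Optionally restricted to the cells of one community.
    """
    scope = np.ones(cells.n_cells, dtype=bool)
    if community is not None:
        if labeling is None:
            raise ParameterError("community restriction requires a labeling")
        scope = labeling.labels == community
    src = source.mask(cells) & scope
    tgt = target.mask(cells) & scope
    coords = cells.coords
    records = []
    for img in cells.images:
        img_mask = (cells.df["image_id"] == img).to_numpy()
        s_idx = np.flatnonzero(src & img_mask)
        t_idx = np.flatnonzero(tgt & img_mask)
        if len(s_idx) == 0:
            continue
        if len(t_idx) == 0:
            for i in s_idx:
                records.append({"cell_id": cells.df["cell_id"].iloc[i],
                                "image_id": img, "distance": np.nan,
                                "log2_distance": np.nan,
                                "target_found": False})
            continue
        tree = cKDTree(coords[t_idx])
        d, j = tree.query(coords[s_idx], k=1,
                          distance_upper_bound=max_dist_px)
        # a source that is itself a target would match at distance 0;
        # exclude self-matches by querying two neighbors for those cells
        self_match = np.isin(s_idx, t_idx)
        if self_match.any():
            d2, j2 = tree.query(coords[s_idx], k=2,
                                distance_upper_bound=max_dist_px)
            d = np.where(self_match, d2[:, 1], d)
        found = np.isfinite(d) & (d <= max_dist_px)
        for i, di, ok in zip(s_idx, d, found):
            records.append({"cell_id": cells.df["cell_id"].iloc[i],
                            "image_id": img,
                            "distance": float(di) if ok else np.nan,
                            "log2_distance": float(log2_scale(di))
                            if ok else np.nan,
                            "target_found": bool(ok)})
    return pd.DataFrame.from_records(records)


def distance_comparison(cells: CellTable, source_a: CellPredicate,
                        source_b: CellPredicate, target: CellPredicate,
                        max_dist_px: float = 800.0,
                        alternative: str = "less", **kwargs
                        ) -> tuple[pd.DataFrame, float, float]:
    """Rank-sum comparison of nearest-target distances between two classes.

    Returns the pooled distance records (with a ``source_class`` column of
    ``"a"``/``"b"``) and the Mann–Whitney U statistic and p-value testing
    whether class-a distances are stochastically ``alternative`` (default
    "less", i.e. class a sits closer to the targets) than class-b distances.
    """
    rec_a = min_distance(cells, source_a, target, max_dist_px, **kwargs)
    rec_b = min_distance(cells, source_b, target, max_dist_px, **kwargs)
    rec_a["source_class"] = "a"
    rec_b["source_class"] = "b"
    records = pd.concat([rec_a, rec_b], ignore_index=True)
    da = rec_a.loc[rec_a["target_found"], "distance"].to_numpy()
    db = rec_b.loc[rec_b["target_found"], "distance"].to_numpy()
    if len(da) == 0 or len(db) == 0:
        return records, np.nan, np.nan
    stat, p = stats.mannwhitneyu(da, db, alternative=alternative)
    return records, float(stat), float(p)


def cross_section_profile(cells: CellTable, labeling: CommunityLabeling,
                          axis: str = "auto", n_bins: int = 40,
                          tumor_type: str = "Tumor") -> pd.DataFrame:
    """Community cell counts along a cross-section through the tumor center.

    Per image, positions are projected on the chosen axis (``"auto"`` = first
    principal axis of the tumor cells' coordinates; ``"x"``/``"y"`` force an
    axis) and centered so 0 is the tumor centroid; counts are pooled over
    images into shared signed-position bins. Cells beyond the bin range are
    counted in the edge bins, so each community's row sums to its size.
    Falls back to the all-cell centroid (with a warning) when an image has no
    tumor cells.
    """
    coords = cells.coords
    is_tumor = (cells.df["cell_type"] == tumor_type).to_numpy()
    pos = np.empty(cells.n_cells)
    for img in cells.images:
        img_mask = (cells.df["image_id"] == img).to_numpy()
        tum = coords[img_mask & is_tumor]
        if len(tum) == 0:
            warnings.warn(f"image {img!r} has no {tumor_type!r} cells; "
                          "using all-cell centroid", stacklevel=2)
            tum = coords[img_mask]
        center = tum.mean(axis=0)
        rel = coords[img_mask] - center
        if axis == "x":
            u = np.array([1.0, 0.0])
        elif axis == "y":
            u = np.array([0.0, 1.0])
        elif axis == "auto":
            c = tum - center
            # first principal axis of the tumor cloud
            _, _, vt = np.linalg.svd(c - c.mean(axis=0), full_matrices=False)
            u = vt[0]
        else:
            raise ParameterError(f"unknown axis {axis!r}")
        pos[img_mask] = rel @ u
    lim = np.abs(pos).max() or 1.0
    edges = np.linspace(-lim, lim, n_bins + 1)
    binned = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    ids = labeling.community_ids
    out = np.zeros((len(ids), n_bins), dtype=int)
    for k, cid in enumerate(ids):
        out[k] = np.bincount(binned[labeling.labels == cid],
                             minlength=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(out, index=pd.Index(ids, name="community"),
                        columns=pd.Index(np.round(centers, 3),
                                         name="position"))


@dataclass
class CorrelationResult:
    """Pairwise Pearson r, p-values, significance tiers, and display order."""

    r: pd.DataFrame
    p: pd.DataFrame
    tiers: pd.DataFrame          # "", "*", "**", "***"
    order: list[str]             # hierarchical-clustering leaf order


def pairwise_correlation(compositions: pd.DataFrame) -> CorrelationResult:
    """Cell-type pair Pearson correlation across analysis units.

    ``compositions`` is a unit × cell-type proportion matrix where a unit is
    an ROI or a community; the correlation of a cell-type pair across
    communities measures co-occurrence at neighborhood scale, which is the
    higher-powered alternative to per-ROI correlation. Zero-variance cell
    types are masked (NaN). Significance tiers: * p<0.05, ** p<0.01,
    *** p<0.001. The leaf order from average-linkage clustering of (1 − r)
    is returned for display.
    """
    if len(compositions) < 3:
        raise ParameterError("pairwise_correlation needs >= 3 units")
    cols = list(compositions.columns)
    mat = compositions.to_numpy(dtype=float)
    nz = mat.std(axis=0) > 0
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if nz[i] and nz[j]:
                ri, pi = stats.pearsonr(mat[:, i], mat[:, j])
                r[i, j] = r[j, i] = ri
                p[i, j] = p[j, i] = pi
    tiers = np.full((k, k), "", dtype=object)
    tiers[p < 0.05] = "*"
    tiers[p < 0.01] = "**"
    tiers[p < 0.001] = "***"
    rr = pd.DataFrame(r, index=cols, columns=cols)
    active = [c for c, ok in zip(cols, nz) if ok]
    if len(active) > 2:
        sub = rr.loc[active, active].to_numpy()
        d = 1.0 - sub[np.triu_indices(len(active), k=1)]
        order_idx = leaves_list(linkage(d, method="average"))
        order = [active[i] for i in order_idx]
    else:
        order = active
    order += [c for c in cols if c not in order]
    return CorrelationResult(
        r=rr, p=pd.DataFrame(p, index=cols, columns=cols),
        tiers=pd.DataFrame(tiers, index=cols, columns=cols), order=order)


def unit_composition(cells: CellTable, by: str = "image_id") -> pd.DataFrame:
    """Cell-type proportion matrix per unit (ROI by default)."""
    tab = pd.crosstab(cells.df[by], cells.df["cell_type"])
    tab = tab.reindex(columns=list(cells.palette), fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0)


def community_proportions(cells: CellTable, labeling: CommunityLabeling
                          ) -> pd.DataFrame:
    """Per-ROI community frequency matrix (rows sum to 1)."""
    tab = pd.crosstab(cells.df["image_id"], pd.Series(labeling.labels,
                                                      name="community"))
    return tab.div(tab.sum(axis=1), axis=0)


def cluster_rois(proportions: pd.DataFrame
                 ) -> tuple[list, list, np.ndarray, np.ndarray]:
    """Hierarchically cluster ROIs and communities by frequency profiles.

    Average-linkage on euclidean distance along both axes of the ROI ×
    community proportion matrix; returns (roi leaf order, column leaf order,
    row linkage, column linkage). Treatment arms with distinct community
    frequencies separate into the top-level branches.
    """
    if len(proportions) < 2:
        raise ParameterError("cluster_rois needs >= 2 ROIs")
    z_rows = linkage(proportions.to_numpy(), method="average",
                     metric="euclidean")
    row_order = [proportions.index[i] for i in leaves_list(z_rows)]
    if proportions.shape[1] >= 2:
        z_cols = linkage(proportions.to_numpy().T, method="average",
                         metric="euclidean")
        col_order = [proportions.columns[i] for i in leaves_list(z_cols)]
    else:
        z_cols = np.empty((0, 4))
        col_order = list(proportions.columns)
    return row_order, col_order, z_rows, z_cols


def tissue_area_mm2(cells: CellTable) -> pd.Series:
    """Convex-hull area of each image's cells, in mm² (coordinates in µm)."""
    out = {}
    for img in cells.images:
        pts = cells.coords[cells.image_rows(img)]
        if len(pts) < 3:
            raise ParameterError(f"image {img!r} has < 3 cells; no hull area")
        out[img] = ConvexHull(pts).volume / 1e6
    return pd.Series(out, name="area_mm2")


def community_density(cells: CellTable, labeling: CommunityLabeling,
                      areas_mm2: pd.Series | None = None,
                      density_threshold: float = 25.0) -> pd.DataFrame:
    """Cells/mm² per (image, community) with inclusive presence calling.

    density = member count / tissue area; a community is *present* in an
    image when its density is **at least** the threshold (boundary
    inclusive). Tissue area defaults to the image's convex hull; pass
    ``areas_mm2`` to use known ROI areas instead.
    """
    areas = tissue_area_mm2(cells) if areas_mm2 is None else areas_mm2
    if (areas <= 0).any():
        raise ParameterError("tissue areas must be > 0")
    records = []
    for img in cells.images:
        rows = cells.image_rows(img)
        area = float(areas[img])
        labs = labeling.labels[rows]
        for cid in labeling.community_ids:
            count = int((labs == cid).sum())
            density = count / area
            records.append({"image_id": img, "community": cid,
                            "count": count, "area_mm2": area,
                            "density": density,
                            "present": density >= density_threshold})
    return pd.DataFrame.from_records(records)


def co_occurrence(density: pd.DataFrame, set_a: Sequence | int,
                  set_b: Sequence | int, density_threshold: float = 25.0
                  ) -> float:
    """Fraction of images where both community sets are present.

    A *set* of communities is present in an image when the summed density of
    its members is at least the threshold (single ids are treated as
    one-element sets).
    """
    def present(ids):
        ids = [ids] if np.isscalar(ids) else list(ids)
        sub = density[density["community"].isin(ids)]
        tot = sub.groupby("image_id")["density"].sum()
        return tot >= density_threshold

    pa, pb = present(set_a), present(set_b)
    both = (pa & pb).reindex(density["image_id"].unique(), fill_value=False)
    return float(both.mean())


def covariate_correlation(densities: pd.Series, covariate: pd.Series,
                          ) -> tuple[float, float]:
    """Spearman correlation between per-image community density and a
    covariate (e.g. tumor mutational burden). Needs ≥ 4 paired observations;
    constant inputs are flagged by returning NaN with a warning.
    """
    joined = pd.concat([densities.rename("d"), covariate.rename("c")],
                       axis=1).dropna()
    if len(joined) < 4:
        raise ParameterError("covariate_correlation needs >= 4 pairs")
    if joined["d"].nunique() == 1 or joined["c"].nunique() == 1:
        warnings.warn("constant input: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(joined["d"], joined["c"])
    return float(rho), float(p)
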