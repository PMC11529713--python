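"""Permutation-based neighborhood enrichment around focal cells.

For each image, the observed statistic per neighbor type is the mean number
of neighbors of that type per focal cell (e.g. per CD8⁺ T cell), computed on
the fixed radius neighbor graph. The null distribution shuffles cell-type
labels while keeping every position and every edge fixed; by default labels
are permuted only within the (image × community) stratum, matching an
analysis that is "separated by community". Enrichment is summarized as

    log2FC = log2((observed + eps) / (null mean + eps)),   eps = 1,

with one-sided permutation p-values using the add-one correction
p = (1 + #{perm ≥ obs}) / (n_perm + 1), so p is never exactly 0 and lies in
[1/(n_perm+1), 1]. A result is significant when min(p_enrich, p_deplete) ≤
alpha (default 0.01).

The conditional analysis splits focal cells of a community by the presence
of a conditioning cell type (e.g. T_regs) in their radius neighborhood and
runs the same test per stratum, holding the conditioning cells' labels fixed
during permutation so that the strata do not dissolve under the null.
"""

from __future__ import annotations

import warnings
import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .communities import CommunityLabeling
from .io_model import CellTable, ParameterError
from .neighborhoods import NeighborGraph


def _community_edges(graph: NeighborGraph, rows: np.ndarray,
                     comm_mask_local: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge list (both orientations), local indices, comm × comm."""
    sub = graph.matrix[rows][:, rows].tocoo()
    keep = comm_mask_local[sub.row] & comm_mask_local[sub.col]
    return sub.row[keep], sub.col[keep]


def _stat(lab, ei, ej, focal_code, focal_ok, n_types):
    focal = (lab == focal_code) & focal_ok
    nf = int(focal.sum())
    if nf == 0:
        return None, 0
    sel = focal[ei]
    counts = np.bincount(lab[ej[sel]], minlength=n_types).astype(float)
    return counts / nf, nf


def permutation_enrichment(cells: CellTable, graph: NeighborGraph,
                           labeling: CommunityLabeling, focal_type: str,
                           community: int, n_perm: int = 1000, seed: int = 0,
                           *, permute: str = "all",
                           within: str = "community", alpha: float = 0.01,
                           eps: float = 1.0,
                           hold_types: Sequence[str] = (),
                           focal_stratum: np.ndarray | None = None,
                           images: Sequence[str] | None = None
                           ) -> pd.DataFrame:
    """Neighborhood enrichment for focal cells of one community, per image.

    Parameters
    ----------
    permute
        ``"all"`` shuffles every eligible label; ``"nonfocal"`` keeps the
        focal-type cells' labels fixed and shuffles the rest.
    within
        ``"community"`` (default) permutes labels only among the community's
        cells; ``"image"`` draws the null from the whole image's labels.
        Observed statistics are always restricted to the community subgraph.
    hold_types
        Cell types whose labels are never shuffled (used by the conditional
        analysis to preserve the conditioning structure).
    focal_stratum
        Optional per-cell stratum labels (aligned with the table); when
        given, the test runs separately for each non-null stratum, with the
        focal set restricted to that stratum.

    Returns one row per (image, stratum, neighbor type).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values are coarse",
                      stacklevel=2)
    if permute not in ("all", "nonfocal"):
        raise ParameterError(f"unknown permute mode {permute!r}")
    if within not in ("community", "image"):
        raise ParameterError(f"unknown within mode {within!r}")
    palette = cells.palette
    f_code = palette.index(focal_type)
    hold_codes = {palette.index(t) for t in hold_types}
    codes = cells.type_codes
    strata: list = [None]
    if focal_stratum is not None:
        focal_stratum = np.asarray(focal_stratum, dtype=object)
        strata = sorted({s for s in focal_stratum if s is not None},
                        key=str)

    records = []
    for img in (images if images is not None else cells.images):
        # per-image stream derived from (seed, image id): independent of row
        # order and of which other images are in the table
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, zlib.crc32(str(img).encode()))))
        rows = cells.image_rows(img)
        lab = codes[rows]
        comm_mask = labeling.labels[rows] == community
        if not comm_mask.any():
            continue
        ei, ej = _community_edges(graph, rows, comm_mask)

        pool = np.flatnonzero(
            (comm_mask if within == "community" else np.ones_like(comm_mask))
            & ~np.isin(lab, list(hold_codes) or [-1])
            & (lab != f_code if permute == "nonfocal" else True))
        # canonical pool order (by cell_id) so results do not depend on the
        # row order of the input table
        ids = cells.df["cell_id"].to_numpy()[rows]
        pool = pool[np.argsort(ids[pool], kind="stable")]

        for stratum in strata:
            if stratum is None:
                focal_ok = comm_mask
            else:
                focal_ok = comm_mask & (focal_stratum[rows] == stratum)
            obs, nf = _stat(lab, ei, ej, f_code, focal_ok, palette.n_types)
            if obs is None:
                warnings.warn(f"image {img!r}: no focal {focal_type!r} cells"
                              + (f" in stratum {stratum!r}" if stratum else
                                 "") + "; skipped", stacklevel=2)
                continue
            null = np.empty((n_perm, palette.n_types))
            valid = np.zeros(n_perm, dtype=bool)
            lab_perm = lab.copy()
            for p in range(n_perm):
                lab_perm[pool] = lab[pool][rng.permutation(len(pool))]
                st, nfp = _stat(lab_perm, ei, ej, f_code, focal_ok,
                                palette.n_types)
                if st is not None:
                    null[p] = st
                    valid[p] = True
            nv = int(valid.sum())
            null_v = null[valid]
            null_mean = null_v.mean(axis=0) if nv else np.full(
                palette.n_types, np.nan)
            tol = 1e-12
            p_enr = (1 + (null_v >= obs - tol).sum(axis=0)) / (nv + 1)
            p_dep = (1 + (null_v <= obs + tol).sum(axis=0)) / (nv + 1)
            log2fc = np.log2((obs + eps) / (null_mean + eps))
            for t, tname in enumerate(palette):
                records.append({
                    "image_id": img, "community": community,
                    "stratum": stratum if stratum is not None else "all",
                    "focal_type": focal_type, "neighbor_type": tname,
                    "observed": obs[t], "null_mean": null_mean[t],
                    "log2fc": log2fc[t],
                    "p_enrich": p_enr[t], "p_deplete": p_dep[t],
                    "significant": min(p_enr[t], p_dep[t]) <= alpha,
                    "n_focal": nf, "n_perm_used": nv,
                })
    return pd.DataFrame.from_records(records)


def adjust_pvalues(results: pd.DataFrame, alpha: float = 0.01
                   ) -> pd.DataFrame:
    """Optional Benjamini–Hochberg correction across neighbor types.

    Enrichment is reported with per-image, per-type significance by default
    (no multiplicity correction); this helper adds BH-adjusted columns
    (``p_enrich_adj``, ``p_deplete_adj``, ``significant_adj``) within each
    (image, community, stratum) block for callers who want FDR control.
    """
    from scipy.stats import false_discovery_control

    out = results.copy()
    for col in ("p_enrich", "p_deplete"):
        out[col + "_adj"] = np.nan
        for _, idx in out.groupby(["image_id", "community",
                                   "stratum"]).groups.items():
            out.loc[idx, col + "_adj"] = false_discovery_control(
                out.loc[idx, col].to_numpy(), method="bh")
    out["significant_adj"] = out[["p_enrich_adj",
                                  "p_deplete_adj"]].min(axis=1) <= alpha
    return out


def conditional_split(cells: CellTable, graph: NeighborGraph,
                      labeling: CommunityLabeling, community: int,
                      conditioning_type: str) -> np.ndarray:
    """Stratify a community's cells by conditioning-type presence.

    A cell is in the ``"with"`` stratum iff at least one cell of
    ``conditioning_type`` lies in its radius neighborhood, ``"without"``
    otherwise; cells outside the community get ``None``. The stratum is a
    property of positions, so it is invariant under the label-permutation
    null when the conditioning cells are held fixed.
    """
    c_code = cells.palette.index(conditioning_type)
    is_cond = (cells.type_codes == c_code).astype(np.float64)
    n_cond_nb = graph.matrix.astype(np.float64) @ is_cond
    out = np.full(cells.n_cells, None, dtype=object)
    in_comm = labeling.labels == community
    out[in_comm & (n_cond_nb >= 1)] = "with"
    out[in_comm & (n_cond_nb < 1)] = "without"
    return out


def conditional_enrichment(cells: CellTable, graph: NeighborGraph,
                           labeling: CommunityLabeling, focal_type: str,
                           community: int, conditioning_type: str,
                           n_perm: int = 1000, seed: int = 0,
                           **kwargs) -> pd.DataFrame:
    """Enrichment per (with / without conditioning-type) stratum.

    Runs :func:`permutation_enrichment` with focal cells split by
    :func:`conditional_split` and the conditioning cells' labels held fixed
    during permutation.
    """
    stratum = conditional_split(cells, graph, labeling, community,
                                conditioning_type)
    return permutation_enrichment(
        cells, graph, labeling, focal_type, community, n_perm=n_perm,
        seed=seed, hold_types=(conditioning_type,), focal_stratum=stratum,
        **kwargs)


def interaction_count(cells: CellTable, graph: NeighborGraph,
                      focal_type: str, target_type: str, target_marker: str,
                      expr_threshold: float = 0.5, per: str = "image",
                      labeling: CommunityLabeling | None = None,
                      community: int | None = None) -> pd.DataFrame:
    """Normalized marker-positive neighbor counts per focal cell.

    Counts, per image, how often a marker-positive cell of ``target_type``
    (intensity strictly above ``expr_threshold``) appears in the radius
    neighborhood of a ``focal_type`` cell, averaged over focal cells; the
    relative count divides by the marker-positive fraction of ``target_type``
    cells (the prevalence of the qualifying state), computed per image
    (``per="image"``) or pooled per treatment group (``per="group"``).
    Optionally restricted to one community. Images with zero qualifying
    prevalence are flagged ``defined=False``.
    """
    if target_marker not in cells.markers:
        raise ParameterError(f"marker {target_marker!r} not in table")
    if per not in ("image", "group"):
        raise ParameterError(f"unknown per mode {per!r}")
    df = cells.df
    codes = cells.type_codes
    f_code = cells.palette.index(focal_type)
    t_code = cells.palette.index(target_type)
    marker = df[target_marker].to_numpy(dtype=float)
    qualifying = ((codes == t_code) & (marker > expr_threshold)).astype(float)
    n_qual_nb = np.asarray(graph.matrix.astype(np.float64) @ qualifying)
    in_scope = np.ones(cells.n_cells, dtype=bool)
    if community is not None:
        if labeling is None:
            raise ParameterError("community restriction requires a labeling")
        in_scope = labeling.labels == community

    groups = df["group"].to_numpy() if "group" in df.columns \
        else np.full(cells.n_cells, "all")
    records = []
    for img in cells.images:
        img_mask = (df["image_id"] == img).to_numpy()
        group = groups[img_mask][0]
        focal = img_mask & in_scope & (codes == f_code)
        if not focal.any():
            continue
        mean_count = float(n_qual_nb[focal].mean())
        if per == "image":
            denom_mask = img_mask & (codes == t_code)
        else:
            denom_mask = (groups == group) & (codes == t_code)
        n_target = int(denom_mask.sum())
        prevalence = float(qualifying[denom_mask].sum() / n_target) \
            if n_target else 0.0
        defined = prevalence > 0
        records.append({
            "image_id": img, "group": group, "focal_type": focal_type,
            "target_type": target_type, "target_marker": target_marker,
            "n_focal": int(focal.sum()), "mean_count": mean_count,
            "normalizer": prevalence,
            "relative_count": mean_count / prevalence if defined else np.nan,
            "defined": defined,
        })
    return pd.DataFrame.from_records(records)
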