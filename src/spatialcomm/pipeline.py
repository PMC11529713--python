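"""End-to-end orchestration: simulate → neighbors → communities → enrich → stats.

Each stage reads the previous stage's CSV artifacts from the output directory
(or in-memory results when run in one call), so stages can also be executed
independently through the CLI. A :class:`RunManifest` records the config, the
seed, a SHA-256 digest of every output file and per-stage timings; identical
config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .communities import agglomerate, cluster_profiles, rank_by_cell_type
from .enrichment import conditional_enrichment
from .io_model import AnalysisConfig, CellTable, read_cell_table
from .neighborhoods import build_neighbor_graph, neighborhood_profiles
from .spatial_stats import (cluster_rois, community_density,
                            community_proportions, cross_section_profile,
                            pairwise_correlation)
from .synthetic_tissue import (DEFAULT_PALETTE, TissueSpec, default_tissue_spec,
                               generate_cohort)

log = logging.getLogger("spatialcomm")

ALL_STAGES = ("simulate", "neighbors", "communities", "enrich", "stats")


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[str]
    files: dict[str, str]          # relative path -> sha256
    timings: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing input {path.name!r} "
            f"(run the producing stage first)")
    return path


def scaled_knn_k(config: AnalysisConfig, n_cells: int) -> int:
    """Graph-building k capped at ~1% of the cells.

    The configured default (k=250) is meant for full-size datasets of 10⁵
    cells and more; on desk-scale simulations the same absolute k would span
    several planted communities, so k is held near a constant neighborhood
    *fraction* instead.
    """
    return max(15, min(config.knn_k, n_cells // 100))


def run_pipeline(config: AnalysisConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = ALL_STAGES,
                 spec: TissueSpec | None = None, n_images: int = 4,
                 group_effects: dict | None = None,
                 target_n: int = 5, focal_type: str = "CD8_T",
                 conditioning_type: str = "Treg") -> RunManifest:
    """Run the pipeline stages in order, writing artifacts under ``out_dir``.

    Stages not listed are skipped; a later stage loads its inputs from the
    files earlier runs left in ``out_dir`` and fails with the missing file's
    name otherwise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    files: dict[str, str] = {}
    palette = (spec or default_tissue_spec()).palette
    cells: CellTable | None = None
    profiles = None
    graph = None
    labeling = None

    def _track(*paths: Path) -> None:
        for p in paths:
            files[p.name] = _sha256(p)

    if "simulate" in stages:
        t0 = time.perf_counter()
        base = spec if spec is not None else default_tissue_spec(config.seed)
        cohort = generate_cohort(base, n_images, group_effects,
                                 seed=config.seed)
        cells_df = pd.concat([t.df for t, _ in cohort], ignore_index=True)
        truth_df = pd.concat([g.df for _, g in cohort], ignore_index=True)
        cells = CellTable(cells_df, base.palette)
        p1, p2 = out / "cells.csv", out / "truth.csv"
        _write_csv(cells_df, p1)
        _write_csv(truth_df, p2)
        _track(p1, p2)
        timings["simulate"] = time.perf_counter() - t0
        log.info("simulate: %d cells over %d images", cells.n_cells, n_images)

    if "neighbors" in stages:
        t0 = time.perf_counter()
        if cells is None:
            cells = read_cell_table(_require(out / "cells.csv", "neighbors"),
                                    palette)
        graph = build_neighbor_graph(cells, config.radius_px)
        profiles = neighborhood_profiles(cells, graph)
        pf = profiles.as_frame(cells)
        p1 = out / "profiles.csv"
        _write_csv(pf, p1)
        coo = graph.matrix.tocoo()
        mask = coo.row < coo.col
        edges = pd.DataFrame({
            "cell_a": cells.df["cell_id"].to_numpy()[coo.row[mask]],
            "cell_b": cells.df["cell_id"].to_numpy()[coo.col[mask]],
            "image_id": cells.df["image_id"].to_numpy()[coo.row[mask]]})
        p2 = out / "edges.csv"
        _write_csv(edges, p2)
        _track(p1, p2)
        timings["neighbors"] = time.perf_counter() - t0
        log.info("neighbors: %d edges at radius %.1f", len(edges),
                 config.radius_px)

    if "communities" in stages:
        t0 = time.perf_counter()
        if cells is None or profiles is None:
            raise FileNotFoundError(
                "stage 'communities' needs in-memory profiles; run the "
                "'neighbors' stage in the same call or use the CLI "
                "'communities' command on profiles.csv")
        k = scaled_knn_k(config, cells.n_cells)
        fine = cluster_profiles(profiles, knn_k=k, seed=config.seed,
                                cells=cells)
        labeling = fine
        merge_records = []
        if fine.n_communities > target_n:
            labeling, tree = agglomerate(fine, target_n)
            merge_records = tree.to_records()
        p1 = out / "labels.csv"
        _write_csv(pd.DataFrame({
            "cell_id": cells.df["cell_id"], "image_id": cells.df["image_id"],
            "community": labeling.labels}), p1)
        p2 = out / "composition.csv"
        labeling.composition().to_csv(p2)
        p3 = out / "merge_tree.json"
        p3.write_text(json.dumps({"initial": fine.n_communities,
                                  "target": labeling.n_communities,
                                  "merges": merge_records}, indent=2))
        _track(p1, p2, p3)
        timings["communities"] = time.perf_counter() - t0
        log.info("communities: %d fine -> %d final", fine.n_communities,
                 labeling.n_communities)

    if "enrich" in stages:
        t0 = time.perf_counter()
        if cells is None or graph is None or labeling is None:
            raise FileNotFoundError(
                "stage 'enrich' needs cells.csv, edges and labels from "
                "earlier stages run in the same call")
        top, _ = rank_by_cell_type(labeling, cells, focal_type, top_n=1)
        community = int(top.index[0])
        enr = conditional_enrichment(
            cells, graph, labeling, focal_type, community,
            conditioning_type, n_perm=config.n_perm, seed=config.seed,
            alpha=config.alpha)
        p1 = out / "enrichment.csv"
        _write_csv(enr, p1)
        _track(p1)
        timings["enrich"] = time.perf_counter() - t0
        log.info("enrich: community %d, %d result rows", community, len(enr))

    if "stats" in stages:
        t0 = time.perf_counter()
        if cells is None or labeling is None:
            raise FileNotFoundError(
                "stage 'stats' needs cells and labels from earlier stages")
        dens = community_density(cells, labeling,
                                 density_threshold=config.density_threshold)
        p1 = out / "density.csv"
        _write_csv(dens, p1)
        comp = labeling.composition()
        paths = [p1]
        if len(comp) >= 3:
            corr = pairwise_correlation(comp)
            p2 = out / "correlations.csv"
            corr.r.to_csv(p2)
            paths.append(p2)
        props = community_proportions(cells, labeling)
        if len(props) >= 2:
            row_order, col_order, _, _ = cluster_rois(props)
            p3 = out / "roi_clustering.json"
            p3.write_text(json.dumps({"roi_order": list(map(str, row_order)),
                                      "community_order":
                                      [int(c) for c in col_order]}, indent=2))
            paths.append(p3)
        xsec = cross_section_profile(cells, labeling)
        p4 = out / "cross_section.csv"
        xsec.to_csv(p4)
        paths.append(p4)
        _track(*paths)
        timings["stats"] = time.perf_counter() - t0
        log.info("stats: density/correlation/cross-section written")

    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           version=__version__, stages=list(stages),
                           files=files, timings=timings)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
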