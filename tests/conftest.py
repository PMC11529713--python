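"""Shared fixtures: hand-built micro tables and one session-scoped tissue."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import spatialcomm as sc
from spatialcomm.io_model import CellTable, Palette


@pytest.fixture(scope="session")
def palette() -> Palette:
    return sc.DEFAULT_PALETTE


def build_table(positions, types, palette=None, image_id="img0",
                markers=None, group="vehicle") -> CellTable:
    """Construct a small validated cell table from raw arrays."""
    palette = palette or sc.DEFAULT_PALETTE
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    df = pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(n)],
        "image_id": image_id,
        "x": positions[:, 0], "y": positions[:, 1],
        "cell_type": list(types),
        "group": group,
    })
    for name, vals in (markers or {}).items():
        df[name] = np.asarray(vals, dtype=float)
    return CellTable(df, palette)


@pytest.fixture()
def make_table():
    return build_table


@pytest.fixture(scope="session")
def tissue():
    """One reference ROI (~5,000 cells) with its graph and profiles."""
    table, truth = sc.generate_tissue(sc.default_tissue_spec(seed=1))
    graph = sc.build_neighbor_graph(table, 15.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = sc.neighborhood_profiles(table, graph)
    return table, truth, graph, profiles


@pytest.fixture(scope="session")
def communities5(tissue):
    """Fine Louvain communities of the reference ROI, agglomerated to 5."""
    table, truth, graph, profiles = tissue
    fine = sc.cluster_profiles(profiles, knn_k=50, seed=1, cells=table)
    agg, tree = sc.agglomerate(fine, 5)
    return fine, agg, tree
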