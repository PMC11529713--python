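"""Cell-table data model, CSV I/O, validation, and run configuration.

The universal input of every analysis stage is a *cell table*: one row per
segmented cell carrying its image (ROI) identifier, centroid coordinates in
micrometres (for imaging mass cytometry 1 pixel = 1 µm, so pixel and µm
thresholds coincide), a cell-type label drawn from a declared palette, optional
tissue-domain and treatment-group labels, and per-marker mean intensities.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Columns with fixed meaning; every other numeric column is a marker.
RESERVED_COLUMNS = ("cell_id", "image_id", "x", "y", "cell_type", "domain", "group")
REQUIRED_COLUMNS = ("cell_id", "image_id", "x", "y", "cell_type")


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed value."""


class ValidationError(ValueError):
    """A table violates a cell-table invariant."""


class ParameterError(ValueError):
    """An operation received an out-of-range parameter."""


class SpecError(ValueError):
    """A synthetic-tissue or effect specification is inconsistent."""


@dataclass(frozen=True)
class Palette:
    """Ordered universe of cell-type labels (the "X" of the proportion feature)."""

    cell_types: tuple[str, ...]

    def __init__(self, cell_types: Iterable[str]):
        object.__setattr__(self, "cell_types", tuple(cell_types))
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValidationError("palette labels must be unique")
        if len(self.cell_types) < 2:
            raise ValidationError("a palette needs at least 2 cell types")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def index(self, label: str) -> int:
        try:
            return self.cell_types.index(label)
        except ValueError:
            raise KeyError(f"cell type {label!r} not in palette") from None

    def codes(self, labels: Sequence[str]) -> np.ndarray:
        """Integer codes of ``labels`` in palette order; unknown label raises."""
        cat = pd.Categorical(labels, categories=self.cell_types)
        codes = np.asarray(cat.codes)
        if (codes < 0).any():
            bad = sorted(set(np.asarray(labels)[codes < 0]))
            raise ValidationError(f"cell types not in palette: {bad}")
        return codes

    def __iter__(self):
        return iter(self.cell_types)

    def __len__(self) -> int:
        return self.n_types


@dataclass
class AnalysisConfig:
    """Run parameters shared across the pipeline stages.

    Defaults follow the analysis conventions for IMC data: a 15 px (=µm)
    neighbor radius (about one cell diameter, so neighbors are cells "up to
    one cell away"), k=250 graph-building input for community detection on
    full-size datasets, 1000 label permutations with significance at p ≤ 0.01,
    an 800 px cap on nearest-neighbor distances, a 0.5 marker intensity cut
    for high/low splits, 25 cells/mm² community-presence threshold, and
    10-cell nearest-neighbor windows for the k-means community variant.
    """

    radius_px: float = 15.0
    knn_k: int = 250
    n_perm: int = 1000
    alpha: float = 0.01
    max_dist_px: float = 800.0
    expr_threshold: float = 0.5
    density_threshold: float = 25.0
    window_k: int = 10
    seed: int = 0
    log2_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("radius_px", "n_perm", "max_dist_px", "expr_threshold",
                     "density_threshold", "window_k", "knn_k"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.log2_pseudocount < 0:
            raise ParameterError("log2_pseudocount must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class CellTable:
    """Validated per-cell records for one or more images.

    ``df`` holds one row per cell with the reserved columns plus marker
    columns; ``palette`` declares the cell-type universe. Row order is the
    canonical cell order used by neighbor graphs and labelings built from
    this table.
    """

    df: pd.DataFrame
    palette: Palette

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> list[str]:
        out = []
        for col in self.df.columns:
            if col in RESERVED_COLUMNS:
                continue
            if pd.api.types.is_numeric_dtype(self.df[col]):
                out.append(col)
        return out

    @property
    def images(self) -> list[str]:
        return list(pd.unique(self.df["image_id"]))

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def type_codes(self) -> np.ndarray:
        return self.palette.codes(self.df["cell_type"].to_numpy())

    def image_rows(self, image_id: str) -> np.ndarray:
        return np.flatnonzero((self.df["image_id"] == image_id).to_numpy())

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        for col in ("x", "y"):
            vals = df[col]
            if not pd.api.types.is_numeric_dtype(vals):
                coerced = pd.to_numeric(vals, errors="coerce")
                bad = int(np.flatnonzero(coerced.isna() & vals.notna())[0]) \
                    if (coerced.isna() & vals.notna()).any() else None
                raise SchemaError(
                    f"non-numeric coordinate in column {col!r}"
                    + (f" at row {bad}" if bad is not None else ""))
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite coordinate in column {col!r}")
        if df.duplicated(subset=["cell_id", "image_id"]).any():
            raise ValidationError("(cell_id, image_id) pairs must be unique")
        self.palette.codes(df["cell_type"].to_numpy())
        for m in self.markers:
            v = df[m].to_numpy(dtype=float)
            if np.nanmin(v) < 0 if len(v) else False:
                raise ValidationError(f"marker {m!r} has negative intensities")

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(self.df.loc[np.asarray(mask)].reset_index(drop=True),
                         self.palette)


def read_cell_table(path: str | Path, palette: Palette) -> CellTable:
    """Read a UTF-8 CSV cell table and validate it against ``palette``.

    Marker columns are auto-detected as every numeric column whose name is
    not reserved. Raises :class:`SchemaError` when a required column is
    missing or a coordinate fails to parse (the message names the column and
    the first offending row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={c: str for c in
                                  ("cell_id", "image_id", "cell_type",
                                   "domain", "group")})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric coordinate in column {col!r} at row "
                f"{int(np.flatnonzero(bad)[0])}")
        df[col] = coerced
    return CellTable(df, palette)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table as UTF-8 CSV (floats at full precision)."""
    table.df.to_csv(path, index=False)


def log2_scale(values, pseudocount: float = 1.0) -> np.ndarray:
    """log2(value + pseudocount), elementwise, for non-negative intensities.

    With the default pseudocount of 1 the transform maps 0 to 0 and is the
    conventional variance-stabilizing display scale for mean marker
    intensities.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValidationError("log2_scale requires non-negative input")
    return np.log2(v + pseudocount)
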