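"""Synthetic multiplexed-imaging tissue with planted spatial communities.

Emulates the architecture of an imaging-mass-cytometry ROI through a lung
tumor: a circular tumor core, an annular tumor–normal interface, and
surrounding normal tissue, each with its own cell density and cell-type
mixture, plus planted multi-cell-type "hub" aggregates (e.g. T cell +
dendritic cell clusters on the tumor boundary). Marker intensities are drawn
from log-normal distributions whose log-mean can shift with cell type, hub
membership, planted community and treatment group, so marker-conditioned
analyses (PD-1⁺ selection, CXCL9 high/low splits, treatment contrasts) have
known ground truth.

Cell positions are homogeneous Poisson within each region; hub cells are
isotropic Gaussian blobs truncated to the hub radius (optionally with chosen
cell types displaced to the hub rim, which suppresses their adjacency to the
hub core). Every draw flows from one `numpy` Generator seeded by the spec, so
identical spec + seed reproduces the table byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import CellTable, Palette, SpecError

#: 14-type palette of a T-cell-oriented IMC panel.
DEFAULT_PALETTE = Palette([
    "Tumor", "Epithelium", "Endothelium", "Fibroblast",
    "Macrophage_M1", "Macrophage_M2", "Neutrophil",
    "B_cell", "NK", "CD4_T", "CD8_T", "Treg", "DC", "CD103_DC",
])

DEFAULT_MARKERS = ("PD1", "PDL1", "CD86", "CXCL9", "Ki67", "cCasp3", "LAG3")

REGIONS = ("tumor", "interface", "normal")

#: Region mixtures follow the architecture of a treated lung tumor: a
#: tumor-cell-dominated core, a type-1-macrophage-lined interface ring, and
#: epithelium/endothelium-rich normal tissue.
DEFAULT_COMPOSITION = {
    "tumor": {"Tumor": 0.85, "Macrophage_M2": 0.06, "Neutrophil": 0.03,
              "CD8_T": 0.02, "Fibroblast": 0.02, "Treg": 0.02},
    "interface": {"Macrophage_M1": 0.40, "Fibroblast": 0.16, "Tumor": 0.12,
                  "Macrophage_M2": 0.08, "CD8_T": 0.05, "CD4_T": 0.05,
                  "Neutrophil": 0.04, "DC": 0.04, "CD103_DC": 0.02,
                  "Treg": 0.04},
    "normal": {"Epithelium": 0.44, "Endothelium": 0.20, "Fibroblast": 0.12,
               "B_cell": 0.10, "CD4_T": 0.05, "CD8_T": 0.04, "NK": 0.05},
}

#: cells per µm² — 4500–7500 cells/mm², i.e. confluent segmented tissue where
#: nearly every cell has neighbors within one cell diameter (15 µm).
DEFAULT_DENSITY = {"tumor": 0.0075, "interface": 0.0055, "normal": 0.0045}


@dataclass(frozen=True)
class HubSpec:
    """A planted cell aggregate.

    ``community`` is the ground-truth community id shared by all cells of the
    hub (several hubs may plant the same community). ``center=None`` places
    the hub on the tumor boundary at a seeded random angle. Types listed in
    ``rim_types`` are placed on an annulus just outside the hub body instead
    of in its Gaussian core, which suppresses (without abolishing) their
    radius-neighborhood adjacency to core cells.
    """

    community: str
    composition: Mapping[str, float]
    n_cells: int = 80
    radius: float = 30.0
    center: tuple[float, float] | None = None
    rim_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise SpecError("hub n_cells must be >= 1")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"hub composition sums to {total}, not 1")


@dataclass(frozen=True)
class MarkerShift:
    """Additive shift of a marker's log-mean for a matching stratum."""

    marker: str
    dmu: float
    cell_type: str | None = None
    community: str | None = None   # matches the planted community id
    group: str | None = None
    hub_only: bool = False         # restrict to cells inside any hub


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal intensity model: log X ~ Normal(mu_base + Σ shifts, sigma)."""

    base: Mapping[str, tuple[float, float]]
    shifts: tuple[MarkerShift, ...] = ()

    def mu_sigma(self, marker: str) -> tuple[float, float]:
        return self.base[marker]


def default_marker_model() -> MarkerModel:
    """Baseline-low markers with hub-associated activation shifts.

    The shifts encode the activation phenotype of a T-cell/DC hub: high
    CXCL9 on hub dendritic cells, PD-1 on hub T cells, CD86 on hub DCs, and
    elevated Ki67 / cleaved caspase-3 on hub-adjacent tumor cells.
    """
    base = {m: (-2.0, 0.8) for m in DEFAULT_MARKERS}
    shifts = (
        MarkerShift("CXCL9", 2.5, cell_type="DC", hub_only=True),
        MarkerShift("CXCL9", 2.5, cell_type="CD103_DC", hub_only=True),
        MarkerShift("PD1", 2.0, cell_type="CD8_T", hub_only=True),
        MarkerShift("PD1", 2.0, cell_type="CD4_T", hub_only=True),
        MarkerShift("PD1", 1.5, cell_type="Treg", hub_only=True),
        MarkerShift("CD86", 1.5, cell_type="DC", hub_only=True),
        MarkerShift("Ki67", 1.0, cell_type="Tumor", hub_only=True),
        MarkerShift("cCasp3", 1.5, cell_type="Tumor", hub_only=True),
        MarkerShift("LAG3", 1.0, cell_type="CD8_T", hub_only=True),
    )
    return MarkerModel(base=base, shifts=shifts)


@dataclass(frozen=True)
class TissueSpec:
    """Full description of one synthetic ROI."""

    field_size: tuple[float, float] = (920.0, 920.0)
    tumor_center: tuple[float, float] | None = None  # default: field center
    tumor_radius: float = 240.0
    interface_width: float = 100.0
    density_per_region: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY))
    composition_per_region: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {r: dict(c) for r, c in
                                 DEFAULT_COMPOSITION.items()})
    hubs: tuple[HubSpec, ...] = ()
    marker_model: MarkerModel = field(default_factory=default_marker_model)
    palette: Palette = DEFAULT_PALETTE
    group: str = "vehicle"
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size
        cx, cy = self.center
        r_out = self.tumor_radius + self.interface_width
        if not (r_out <= cx <= w - r_out and r_out <= cy <= h - r_out):
            raise SpecError("tumor + interface ring does not fit in the field")
        for region in REGIONS:
            if self.density_per_region.get(region, 0) <= 0:
                raise SpecError(f"density for region {region!r} must be > 0")
            comp = self.composition_per_region[region]
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise SpecError(f"composition for region {region!r} "
                                "does not sum to 1")
            for t in comp:
                self.palette.index(t)
        for hub in self.hubs:
            c = hub.center
            if c is not None and not (0 <= c[0] <= w and 0 <= c[1] <= h):
                raise SpecError(f"hub {hub.community!r} center outside field")

    @property
    def center(self) -> tuple[float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return (self.field_size[0] / 2.0, self.field_size[1] / 2.0)

    def region_area(self, region: str) -> float:
        r, w = self.tumor_radius, self.interface_width
        if region == "tumor":
            return math.pi * r * r
        if region == "interface":
            return math.pi * ((r + w) ** 2 - r * r)
        if region == "normal":
            return self.field_size[0] * self.field_size[1] \
                - math.pi * (r + w) ** 2
        raise KeyError(region)


@dataclass
class GroundTruth:
    """Planted labels, row-aligned with the generated cell table."""

    df: pd.DataFrame  # cell_id, image_id, region, planted_community

    @property
    def planted(self) -> np.ndarray:
        return self.df["planted_community"].to_numpy()

    @property
    def region(self) -> np.ndarray:
        return self.df["region"].to_numpy()


# ---------------------------------------------------------------------------
# position sampling

def _sample_disk(rng, n, center, radius):
    u = rng.uniform(0.0, 1.0, n)
    theta = rng.uniform(0.0, 2 * math.pi, n)
    rr = radius * np.sqrt(u)
    return np.column_stack([center[0] + rr * np.cos(theta),
                            center[1] + rr * np.sin(theta)])


def _sample_annulus(rng, n, center, r_in, r_out):
    u = rng.uniform(0.0, 1.0, n)
    theta = rng.uniform(0.0, 2 * math.pi, n)
    rr = np.sqrt(u * (r_out ** 2 - r_in ** 2) + r_in ** 2)
    return np.column_stack([center[0] + rr * np.cos(theta),
                            center[1] + rr * np.sin(theta)])


def _sample_normal_region(rng, n, spec: TissueSpec):
    """Uniform points in the field outside the interface ring (rejection)."""
    w, h = spec.field_size
    cx, cy = spec.center
    r_out = spec.tumor_radius + spec.interface_width
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(64, int(1.6 * (n - len(out)) /
                        max(spec.region_area("normal") / (w * h), 1e-6)))
        pts = rng.uniform([0, 0], [w, h], size=(m, 2))
        keep = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 > r_out ** 2
        out = np.vstack([out, pts[keep]])
    return out[:n]


def _sample_hub_positions(rng, hub: HubSpec, center, is_rim: np.ndarray):
    n = len(is_rim)
    pos = np.empty((n, 2))
    n_core = int((~is_rim).sum())
    # Gaussian core truncated to 0.6 * radius (resampling the overflow)
    sigma, rmax = hub.radius / 2.5, 0.6 * hub.radius
    core = np.empty((0, 2))
    while len(core) < n_core:
        cand = rng.normal(0.0, sigma, size=(max(32, 2 * (n_core - len(core))), 2))
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= rmax ** 2]
        core = np.vstack([core, cand])
    pos[~is_rim] = center + core[:n_core]
    n_rim = int(is_rim.sum())
    if n_rim:
        rr = rng.uniform(hub.radius, 1.4 * hub.radius, n_rim)
        th = rng.uniform(0.0, 2 * math.pi, n_rim)
        pos[is_rim] = center + np.column_stack([rr * np.cos(th),
                                                rr * np.sin(th)])
    return pos


def _composition_arrays(comp: Mapping[str, float], palette: Palette):
    types = list(comp)
    probs = np.array([comp[t] for t in types], dtype=float)
    return types, probs / probs.sum()


# ---------------------------------------------------------------------------
# marker sampling

def _sample_markers(rng, model: MarkerModel, cell_type, planted, group,
                    in_hub) -> dict[str, np.ndarray]:
    n = len(cell_type)
    cell_type = np.asarray(cell_type)
    planted = np.asarray(planted)
    in_hub = np.asarray(in_hub)
    out: dict[str, np.ndarray] = {}
    for marker, (mu0, sigma) in model.base.items():
        mu = np.full(n, mu0, dtype=float)
        for s in model.shifts:
            if s.marker != marker:
                continue
            if s.group is not None and s.group != group:
                continue
            mask = np.ones(n, dtype=bool)
            if s.cell_type is not None:
                mask &= cell_type == s.cell_type
            if s.community is not None:
                mask &= planted == s.community
            if s.hub_only:
                mask &= in_hub
            mu[mask] += s.dmu
        out[marker] = rng.lognormal(mean=mu, sigma=sigma)
    return out


# ---------------------------------------------------------------------------
# generators

def generate_tissue(spec: TissueSpec, image_id: str = "img_000",
                    rng: np.random.Generator | None = None,
                    ) -> tuple[CellTable, GroundTruth]:
    """Generate one ROI: (cell table, ground truth), reproducible from seed.

    Background cells per region: count ~ Poisson(density × area), positions
    uniform in the region, types i.i.d. from the region composition. Planted
    community ids are ``bg_<region>`` for background cells and the hub's
    ``community`` for hub cells.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cx, cy = spec.center
    r, w = spec.tumor_radius, spec.interface_width

    xs, types, regions, planted, in_hub = [], [], [], [], []

    for region in REGIONS:
        lam = spec.density_per_region[region] * spec.region_area(region)
        n = int(rng.poisson(lam))
        if region == "tumor":
            pos = _sample_disk(rng, n, (cx, cy), r)
        elif region == "interface":
            pos = _sample_annulus(rng, n, (cx, cy), r, r + w)
        else:
            pos = _sample_normal_region(rng, n, spec)
        tnames, probs = _composition_arrays(
            spec.composition_per_region[region], spec.palette)
        tt = rng.choice(len(tnames), size=n, p=probs)
        xs.append(pos)
        types.extend(tnames[i] for i in tt)
        regions.extend([region] * n)
        planted.extend([f"bg_{region}"] * n)
        in_hub.extend([False] * n)

    for hub in spec.hubs:
        if hub.center is None:
            # default placement: mid-interface annulus around the tumor
            theta = rng.uniform(0.0, 2 * math.pi)
            rpos = r + w / 2.0
            center = np.array([cx + rpos * math.cos(theta),
                               cy + rpos * math.sin(theta)])
        else:
            center = np.asarray(hub.center, dtype=float)
        tnames, probs = _composition_arrays(hub.composition, spec.palette)
        tt = rng.choice(len(tnames), size=hub.n_cells, p=probs)
        hub_types = np.array([tnames[i] for i in tt])
        is_rim = np.isin(hub_types, hub.rim_types)
        pos = _sample_hub_positions(rng, hub, center, is_rim)
        np.clip(pos[:, 0], 0.0, spec.field_size[0], out=pos[:, 0])
        np.clip(pos[:, 1], 0.0, spec.field_size[1], out=pos[:, 1])
        d = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
        reg = np.where(d <= r, "tumor",
                       np.where(d <= r + w, "interface", "normal"))
        xs.append(pos)
        types.extend(hub_types)
        regions.extend(reg)
        planted.extend([hub.community] * hub.n_cells)
        in_hub.extend([True] * hub.n_cells)

    pos = np.vstack(xs) if xs else np.empty((0, 2))
    n = len(pos)
    markers = _sample_markers(rng, spec.marker_model, types, planted,
                              spec.group, in_hub)
    df = pd.DataFrame({
        "cell_id": [f"c{i:06d}" for i in range(n)],
        "image_id": image_id,
        "x": pos[:, 0], "y": pos[:, 1],
        "cell_type": types,
        "domain": regions,
        "group": spec.group,
        **markers,
    })
    truth = GroundTruth(pd.DataFrame({
        "cell_id": df["cell_id"], "image_id": image_id,
        "region": regions, "planted_community": planted,
    }))
    return CellTable(df, spec.palette), truth


_EFFECT_KEYS = {"hub_count_scale", "hub_keep_prob", "marker_shifts",
                "drop_treg_from_hubs", "rim_types"}


def _apply_effects(spec: TissueSpec, effects: Mapping, group: str,
                   rng: np.random.Generator) -> TissueSpec:
    unknown = set(effects) - _EFFECT_KEYS
    if unknown:
        raise SpecError(f"unknown group effect key(s): {sorted(unknown)}")
    hubs = list(spec.hubs)
    if "hub_keep_prob" in effects:
        p = float(effects["hub_keep_prob"])
        hubs = [h for h in hubs if rng.uniform() < p]
    if "hub_count_scale" in effects:
        s = float(effects["hub_count_scale"])
        hubs = [replace(h, n_cells=max(1, int(round(h.n_cells * s))))
                for h in hubs]
    if effects.get("drop_treg_from_hubs"):
        new = []
        for h in hubs:
            comp = {t: p for t, p in h.composition.items() if t != "Treg"}
            total = sum(comp.values())
            new.append(replace(h, composition={t: p / total
                                               for t, p in comp.items()}))
        hubs = new
    if "rim_types" in effects:
        hubs = [replace(h, rim_types=tuple(effects["rim_types"]))
                for h in hubs]
    model = spec.marker_model
    if "marker_shifts" in effects:
        extra = tuple(MarkerShift(**d) if isinstance(d, dict) else d
                      for d in effects["marker_shifts"])
        model = MarkerModel(model.base, model.shifts + extra)
    return replace(spec, hubs=tuple(hubs), marker_model=model, group=group)


def generate_cohort(base_spec: TissueSpec, n_images: int,
                    group_effects: Mapping[str, Mapping] | None = None,
                    seed: int | None = None,
                    ) -> list[tuple[CellTable, GroundTruth]]:
    """Generate an image cohort, optionally split into treatment arms.

    ``group_effects`` maps group label → effect dict; images are split evenly
    (in order) across the groups. Recognized effect keys: ``hub_count_scale``
    (scales hub sizes), ``hub_keep_prob`` (random hub dropout),
    ``drop_treg_from_hubs``, ``rim_types`` (displace the listed cell types to
    every hub's rim), ``marker_shifts`` (extra :class:`MarkerShift` entries,
    given as dataclasses or kwargs dicts). Unknown keys raise ``SpecError``.

    Per-image seeds are spawned from the master seed, so each image is
    independently reproducible.
    """
    if n_images < 1:
        raise SpecError("n_images must be >= 1")
    master = base_spec.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n_images)
    groups = list(group_effects) if group_effects else [base_spec.group]
    per_group = math.ceil(n_images / len(groups))
    out = []
    for i, child in enumerate(children):
        group = groups[min(i // per_group, len(groups) - 1)]
        rng = np.random.default_rng(child)
        spec_i = base_spec
        if group_effects and group_effects.get(group):
            spec_i = _apply_effects(base_spec, group_effects[group], group, rng)
        else:
            spec_i = replace(base_spec, group=group)
        table, truth = generate_tissue(spec_i, image_id=f"img_{i:03d}", rng=rng)
        out.append((table, truth))
    return out


# ---------------------------------------------------------------------------
# canned study conditions

def tdc_hub(n_cells: int = 100, radius: float = 35.0,
            with_treg: bool = True,
            rim_types: tuple[str, ...] = ()) -> HubSpec:
    """A T cell/dendritic cell aggregate, the hallmark interface community."""
    if with_treg:
        comp = {"DC": 0.18, "CD103_DC": 0.10, "CD8_T": 0.24, "CD4_T": 0.20,
                "Treg": 0.16, "Tumor": 0.12}
    else:
        comp = {"DC": 0.22, "CD103_DC": 0.12, "CD8_T": 0.28, "CD4_T": 0.24,
                "Tumor": 0.14}
    return HubSpec(community="hub_TDC", composition=comp, n_cells=n_cells,
                   radius=radius, rim_types=rim_types)


def myeloid_hub(n_cells: int = 100, radius: float = 35.0) -> HubSpec:
    """A macrophage/neutrophil aggregate, a second planted community."""
    comp = {"Macrophage_M2": 0.44, "Neutrophil": 0.24, "Macrophage_M1": 0.16,
            "Tumor": 0.16}
    return HubSpec(community="hub_myeloid", composition=comp,
                   n_cells=n_cells, radius=radius)


def default_tissue_spec(seed: int = 0) -> TissueSpec:
    """The reference ROI: 3 regions + 5 planted communities (~5,000 cells).

    Ground-truth communities: bg_tumor, bg_interface, bg_normal, hub_TDC
    (3 hubs), hub_myeloid (2 hubs).
    """
    hubs = tuple([tdc_hub() for _ in range(3)] + [myeloid_hub()
                                                  for _ in range(2)])
    return TissueSpec(hubs=hubs, seed=seed)


def treg_conditional_spec(seed: int = 0) -> TissueSpec:
    """Study conditions for the T_reg conditional-enrichment analysis.

    Half of the T/DC hubs contain T_regs and have their dendritic cells
    displaced to the hub rim (suppressed CD8–DC adjacency where T_regs are
    present); the other half are T_reg-free with DCs intermixed in the core.
    All hubs plant the same ``hub_TDC`` community, so the with/without-T_reg
    contrast happens *within* one community, as in a conditional enrichment
    analysis.
    """
    hubs = tuple(
        [tdc_hub(with_treg=True, rim_types=("DC", "CD103_DC"))
         for _ in range(3)]
        + [tdc_hub(with_treg=False) for _ in range(3)])
    return TissueSpec(hubs=hubs, seed=seed)
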