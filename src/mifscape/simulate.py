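"""Synthetic tumor-microenvironment generator.

Produces cell tables in the canonical format with known ground truth:
tumor cells as a Poisson scatter inside non-overlapping circular nests
(epithelial compartment), immune cells as a Poisson scatter over the whole
ROI window thinned by a *mixing* rule (1 — immune cells uniform everywhere;
0 — immune cells excluded from nests plus an exclusion margin), and marker
flags drawn independently per cell from configured co-expression
frequencies.  One global seed; per-ROI substreams are spawned from a
``numpy.random.SeedSequence`` so ROIs are independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_ROI_HEIGHT,
    DEFAULT_ROI_WIDTH,
    MARKERS,
    ROI,
    table_columns,
    validate_cell_table,
)
from .errors import ConfigurationError, ParameterError

#: Default per-lineage marker co-expression frequencies.  Chosen so that the
#: simulated phenotype densities fall inside the published cohort's min–max
#: ranges; they are documentation defaults, not fitted values.
DEFAULT_COEXPRESSION: dict[str, dict[str, float]] = {
    "tumor": {"KI67": 0.10},
    "t_cell": {"CD8": 0.35, "PD-1": 0.12, "PD-L1": 0.10,
               "KI67": 0.08, "Foxp3": 0.08},
    "macrophage": {"PD-L1": 0.15, "KI67": 0.08},
}

_LINEAGE_MARKER = {"tumor": "panCK", "t_cell": "CD3", "macrophage": "CD68"}


@dataclass
class SimulationConfig:
    window: tuple[float, float] = (DEFAULT_ROI_WIDTH, DEFAULT_ROI_HEIGHT)
    n_cases: int = 1
    rois_per_case: int = 10
    n_nests: int = 6
    nest_radius: float = 80.0
    tumor_intensity: float = 3000.0  # cells/mm² inside nests
    immune_intensity: dict[str, float] = field(
        default_factory=lambda: {"t_cell": 500.0, "macrophage": 150.0})
    mixing: float = 1.0
    exclusion_margin: float = 100.0
    marker_coexpression_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COEXPRESSION.items()})
    pdl1_tumor_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mixing <= 1:
            raise ConfigurationError("mixing must lie in [0, 1]")
        if self.tumor_intensity < 0 or any(v < 0 for v in
                                           self.immune_intensity.values()):
            raise ConfigurationError("intensities must be >= 0")
        if self.nest_radius <= 0 or self.n_nests < 0:
            raise ConfigurationError("invalid nest geometry")

    @property
    def window_area_mm2(self) -> float:
        return self.window[0] * self.window[1] / 1e6


@dataclass
class GroundTruth:
    """Generative truth shipped alongside every simulated table; never
    consumed by the analysis stages."""

    roi_labels: dict[str, str]  # roi_id -> "mixed" | "unmixed"
    intensities: dict[str, float]
    cell_lineage: pd.DataFrame  # cell_id, lineage
    nest_centers: dict[str, np.ndarray]


def _place_nests(rng: np.random.Generator, cfg: SimulationConfig,
                 max_tries: int = 2000) -> np.ndarray:
    w, h = cfg.window
    r = cfg.nest_radius
    if cfg.n_nests == 0:
        return np.empty((0, 2))
    if 2 * r > min(w, h):
        raise ConfigurationError("nest_radius too large for the window")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < cfg.n_nests:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                f"could not place {cfg.n_nests} non-overlapping nests of "
                f"radius {r} in a {w} x {h} window")
        c = rng.uniform([r, r], [w - r, h - r])
        if all(np.hypot(*(c - o)) >= 2 * r for o in centers):
            centers.append(c)
    return np.asarray(centers)


def _in_nest(points: np.ndarray, centers: np.ndarray, radius: float) -> np.ndarray:
    if len(points) == 0 or len(centers) == 0:
        return np.zeros(len(points), dtype=bool)
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return (d2 <= radius ** 2).any(axis=1)


def _uniform_in_discs(rng: np.random.Generator, n: int,
                      centers: np.ndarray, radius: float) -> np.ndarray:
    which = rng.integers(0, len(centers), n)
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = radius * np.sqrt(rng.uniform(0, 1, n))
    return centers[which] + np.c_[rad * np.cos(theta), rad * np.sin(theta)]


def _draw_flags(rng: np.random.Generator, n: int, lineage: str,
                cfg: SimulationConfig) -> dict[str, np.ndarray]:
    flags = {m: np.zeros(n, dtype=np.int8) for m in MARKERS}
    flags[_LINEAGE_MARKER[lineage]][:] = 1
    probs = dict(cfg.marker_coexpression_probs.get(lineage, {}))
    if lineage == "tumor":
        probs.setdefault("PD-L1", cfg.pdl1_tumor_fraction)
    for marker, p in sorted(probs.items()):
        flags[marker] = (rng.uniform(0, 1, n) < p).astype(np.int8)
    flags[_LINEAGE_MARKER[lineage]][:] = 1  # co-expression never clears lineage
    return flags


def _simulate_roi(rng: np.random.Generator, cfg: SimulationConfig,
                  case_id: str, roi_id: str) -> tuple[pd.DataFrame, np.ndarray]:
    w, h = cfg.window
    centers = _place_nests(rng, cfg)
    nest_area_mm2 = cfg.n_nests * np.pi * cfg.nest_radius ** 2 / 1e6
    frames = []
    # tumor cells inside nests
    n_tumor = rng.poisson(cfg.tumor_intensity * nest_area_mm2)
    if n_tumor and len(centers):
        xy = _uniform_in_discs(rng, n_tumor, centers, cfg.nest_radius)
        np.clip(xy, [0, 0], [w, h], out=xy)
        frames.append(("tumor", xy))
    # immune cells over the window, thinned inside the exclusion zone
    excl_radius = cfg.nest_radius + cfg.exclusion_margin
    for lineage in sorted(cfg.immune_intensity):
        n = rng.poisson(cfg.immune_intensity[lineage] * cfg.window_area_mm2)
        if n == 0:
            continue
        xy = rng.uniform([0, 0], [w, h], (n, 2))
        if cfg.mixing < 1 and len(centers):
            in_zone = _in_nest(xy, centers, excl_radius)
            keep = ~in_zone | (rng.uniform(0, 1, n) < cfg.mixing)
            xy = xy[keep]
        if len(xy):
            frames.append((lineage, xy))
    rows = []
    for lineage, xy in frames:
        n = len(xy)
        flags = _draw_flags(rng, n, lineage, cfg)
        inside = _in_nest(xy, centers, cfg.nest_radius)
        df = pd.DataFrame({
            "case_id": case_id, "roi_id": roi_id,
            "x": xy[:, 0], "y": xy[:, 1],
            "compartment": np.where(inside, "epithelial", "stroma"),
            "_lineage": lineage,
        })
        for m in MARKERS:
            df[m] = flags[m]
        rows.append(df)
    if rows:
        cells = pd.concat(rows, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["case_id", "roi_id", "x", "y",
                                      "compartment", "_lineage", *MARKERS])
    cells.insert(0, "cell_id",
                 [f"{roi_id}_c{i:06d}" for i in range(len(cells))])
    return cells, centers


def simulate_landscape(cfg: SimulationConfig,
                       ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate ``n_cases × rois_per_case`` ROIs; deterministic under seed."""
    streams = np.random.SeedSequence(cfg.seed).spawn(
        cfg.n_cases * cfg.rois_per_case)
    label = "mixed" if cfg.mixing >= 0.5 else "unmixed"
    pieces, roi_labels, nest_centers = [], {}, {}
    k = 0
    for ci in range(cfg.n_cases):
        case_id = f"case{ci + 1:02d}"
        for ri in range(cfg.rois_per_case):
            roi_id = f"{case_id}_roi{ri + 1:02d}"
            rng = np.random.default_rng(streams[k]); k += 1
            cells, centers = _simulate_roi(rng, cfg, case_id, roi_id)
            pieces.append(cells)
            roi_labels[roi_id] = label
            nest_centers[roi_id] = centers
    cells = pd.concat(pieces, ignore_index=True)
    lineage = cells[["cell_id", "_lineage"]].rename(
        columns={"_lineage": "lineage"})
    cells = cells.drop(columns="_lineage")[table_columns(MARKERS)]
    cells = validate_cell_table(cells)
    intensities = {"tumor_in_nest": cfg.tumor_intensity,
                   **{k: v for k, v in cfg.immune_intensity.items()}}
    return cells, GroundTruth(roi_labels, intensities, lineage, nest_centers)


def rois_for(cells: pd.DataFrame,
             window: tuple[float, float] = (DEFAULT_ROI_WIDTH,
                                            DEFAULT_ROI_HEIGHT),
             ) -> dict[str, ROI]:
    """ROI objects (default window) for every ROI in a cell table."""
    out = {}
    for roi_id, g in cells.groupby("roi_id"):
        out[str(roi_id)] = ROI(str(roi_id), str(g["case_id"].iloc[0]),
                               width=window[0], height=window[1])
    return out


def simulate_mixed(seed: int = 0, **overrides) -> tuple[pd.DataFrame, GroundTruth]:
    """Preset: immune cells uniform through the tumor nests (mixing = 1).

    Tumor intensity is raised so nest purity clears the 85% QC rule, and both
    cell types comfortably exceed 200 cells per ROI.
    """
    cfg = SimulationConfig(seed=seed, mixing=1.0, tumor_intensity=6000.0,
                           rois_per_case=overrides.pop("rois_per_case", 3),
                           **overrides)
    return simulate_landscape(cfg)


def simulate_unmixed(seed: int = 0, **overrides) -> tuple[pd.DataFrame, GroundTruth]:
    """Preset: immune cells excluded from nests by a 100 µm margin."""
    cfg = SimulationConfig(seed=seed, mixing=0.0, exclusion_margin=100.0,
                           tumor_intensity=6000.0,
                           rois_per_case=overrides.pop("rois_per_case", 3),
                           **overrides)
    return simulate_landscape(cfg)


PRESETS = {"mixed_demo": simulate_mixed, "unmixed_demo": simulate_unmixed}


def tma_base_percentages(n_cores: int = 36, seed: int = 0,
                         max_percent: float = 60.0) -> pd.DataFrame:
    """Synthetic per-core marker percentages for the TMA consistency demo."""
    rng = np.random.default_rng(seed)
    data = {m: rng.uniform(0.0, max_percent, n_cores) for m in MARKERS}
    return pd.DataFrame(data, index=[f"core{i + 1:02d}" for i in range(n_cores)])


def simulate_tma_timepoints(base: pd.DataFrame, n_timepoints: int = 3,
                            noise_sd: float = 1.0, seed: int = 0,
                            ) -> dict[int, pd.DataFrame]:
    """Replicate 'staining runs': time point 1 is the base percentages,
    later time points add independent Gaussian noise truncated to [0, 100]."""
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = {1: base.copy()}
    for t in range(2, n_timepoints + 1):
        noisy = base + rng.normal(0.0, noise_sd, base.shape)
        out[t] = noisy.clip(0.0, 100.0)
    return out


def plant_pdl1_gradient(cells: pd.DataFrame, effect: float,
                        fraction: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Move a seeded fraction of T cells ``effect`` µm toward their nearest
    PD-L1+ malignant cell (clamped at the target), per ROI.

    Guarantees the PD-L1+ reference stratum's nearest-T-cell distances shrink
    relative to the unshifted table; ``effect = 0`` is the identity.
    """
    pdl1_tumor = (cells["panCK"] == 1) & (cells["PD-L1"] == 1)
    if not pdl1_tumor.any():
        raise ParameterError("no PD-L1+ malignant cells to shift toward")
    if effect < 0:
        raise ParameterError("effect must be >= 0")
    out = cells.copy()
    if effect == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, g in cells.groupby("roi_id", sort=True):
        anchors = g.loc[pdl1_tumor.loc[g.index], ["x", "y"]].to_numpy(float)
        tcells = g.index[g["CD3"] == 1]
        if len(anchors) == 0 or len(tcells) == 0:
            continue
        chosen = tcells[rng.uniform(0, 1, len(tcells)) < fraction]
        xy = out.loc[chosen, ["x", "y"]].to_numpy(float)
        d = np.sqrt(((xy[:, None, :] - anchors[None, :, :]) ** 2).sum(-1))
        nearest = anchors[d.argmin(axis=1)]
        vec = nearest - xy
        dist = np.maximum(np.hypot(vec[:, 0], vec[:, 1]), 1e-12)
        step = np.minimum(effect, dist)
        out.loc[chosen, ["x", "y"]] = xy + vec / dist[:, None] * step[:, None]
    return out
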