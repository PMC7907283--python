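"""Coordinate-based merging of per-marker calls and co-expression phenotyping.

Per-marker single-cell analyses are merged onto the DAPI spine by X/Y
coordinates (nearest spine cell within a tolerance).  Phenotypes are named
boolean co-expression rules: a cell matches a rule iff every
required-positive marker flag is set and every required-negative flag is
clear.  The shipped default registry contains the 26 density-table rows of
the study panel — 4 panCK-lineage, 18 CD3-lineage (the Foxp3 rows carry an
explicit CD8 requirement-negative) and 4 CD68-lineage — which are nested,
not mutually exclusive: a CD3+CD8+PD-1+ cell also matches CD3+CD8+ and CD3+.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datamodel import (
    LINEAGE_MARKERS,
    LINEAGE_OF_MARKER,
    MARKERS,
    table_columns,
    validate_cell_table,
)
from .errors import ConfigurationError, ParameterError
from .io import MarkerPointSets


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named boolean co-expression rule."""

    name: str
    require_positive: frozenset[str]
    require_negative: frozenset[str] = frozenset()
    lineage: str = "t_cell"

    def __post_init__(self) -> None:
        object.__setattr__(self, "require_positive", frozenset(self.require_positive))
        object.__setattr__(self, "require_negative", frozenset(self.require_negative))
        overlap = self.require_positive & self.require_negative
        if overlap:
            raise ConfigurationError(
                f"phenotype {self.name!r}: markers both required positive and "
                f"negative: {sorted(overlap)}"
            )

    def validate_against_panel(self, markers: Sequence[str]) -> None:
        unknown = (self.require_positive | self.require_negative) - set(markers)
        if unknown:
            raise ConfigurationError(
                f"phenotype {self.name!r} references unknown marker(s): "
                f"{sorted(unknown)}"
            )

    def matches(self, flags: Mapping[str, bool]) -> bool:
        return (all(flags.get(m, False) for m in self.require_positive)
                and not any(flags.get(m, False) for m in self.require_negative))


def _defn(name: str, pos: Iterable[str], neg: Iterable[str], lineage: str):
    return PhenotypeDefinition(name, frozenset(pos), frozenset(neg), lineage)


def default_registry() -> list[PhenotypeDefinition]:
    """The 26 phenotype rows of the study's density table."""
    out: list[PhenotypeDefinition] = []
    # tumor lineage
    for extra in ([], ["PD-L1"], ["KI67"], ["KI67", "PD-L1"]):
        name = "panCK+" + "".join(m + "+" for m in extra)
        out.append(_defn(name, ["panCK"] + extra, [], "tumor"))
    # T-cell lineage
    cd3_rows: list[tuple[list[str], list[str]]] = [
        ([], []),
        (["PD-L1"], []),
        (["PD-1"], []),
        (["PD-1", "PD-L1"], []),
        (["KI67"], []),
        (["KI67", "PD-L1"], []),
        (["KI67", "PD-1"], []),
        (["KI67", "PD-1", "PD-L1"], []),
        (["Foxp3"], ["CD8"]),
        (["Foxp3", "PD-L1"], ["CD8"]),
        (["Foxp3", "PD-1"], ["CD8"]),
        (["CD8"], []),
        (["CD8", "PD-L1"], []),
        (["CD8", "PD-1"], []),
        (["CD8", "PD-1", "PD-L1"], []),
        (["CD8", "KI67"], []),
        (["CD8", "KI67", "PD-L1"], []),
        (["CD8", "KI67", "PD-1"], []),
    ]
    for extra, neg in cd3_rows:
        name = "CD3+" + "".join(m + "+" for m in extra)
        if "Foxp3" in extra:
            # Foxp3 rows interpose the explicit CD8- right after Foxp3+
            name = "CD3+Foxp3+CD8-" + "".join(
                m + "+" for m in extra if m != "Foxp3")
        out.append(_defn(name, ["CD3"] + extra, neg, "t_cell"))
    # macrophage lineage
    for extra in ([], ["KI67"], ["KI67", "PD-L1"], ["PD-L1"]):
        name = "CD68+" + "".join(m + "+" for m in extra)
        out.append(_defn(name, ["CD68"] + extra, [], "macrophage"))
    return out


def registry_to_frame(registry: Iterable[PhenotypeDefinition]) -> pd.DataFrame:
    rows = [{"name": d.name,
             "require_positive": "+".join(sorted(d.require_positive)),
             "require_negative": "+".join(sorted(d.require_negative)),
             "lineage": d.lineage} for d in registry]
    return pd.DataFrame(rows)


def registry_from_config(entries: Iterable[Mapping]) -> list[PhenotypeDefinition]:
    return [_defn(e["name"], e.get("positives", []), e.get("negatives", []),
                  e.get("lineage", "t_cell")) for e in entries]


@dataclass
class MergeReport:
    """Book-keeping of the coordinate join, per marker."""

    matched: dict[str, int] = field(default_factory=dict)
    unmatched: dict[str, int] = field(default_factory=dict)

    @property
    def unmatched_count(self) -> int:
        return sum(self.unmatched.values())


def _assign_events(spine_xy: np.ndarray, spine_ids: np.ndarray,
                   ev_xy: np.ndarray, tolerance: float) -> np.ndarray:
    """Indices into the spine (or -1) for each event; one-to-nearest within
    tolerance, ties broken by smallest cell_id."""
    tree = cKDTree(spine_xy)
    out = np.full(len(ev_xy), -1, dtype=np.int64)
    neighbours = tree.query_ball_point(ev_xy, tolerance + 1e-12)
    for i, cand in enumerate(neighbours):
        if not cand:
            continue
        cand = np.asarray(cand)
        d = np.hypot(*(spine_xy[cand] - ev_xy[i]).T)
        keep = cand[np.abs(d - d.min()) <= 1e-9]
        if len(keep) > 1:  # coordinate tie: deterministic by cell_id
            keep = keep[np.argsort(spine_ids[keep], kind="stable")]
        out[i] = keep[0]
    return out


def merge_marker_calls(point_sets: MarkerPointSets, tolerance: float = 0.5,
                       markers: Sequence[str] = MARKERS,
                       ) -> tuple[pd.DataFrame, MergeReport]:
    """Merge per-marker positive events onto the DAPI spine by coordinates.

    Every spine cell appears exactly once in the output regardless of the
    marker-event counts; each marker event sets the flag of its nearest
    spine cell within ``tolerance`` µm or is dropped and counted.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    if not point_sets.spine:
        raise ParameterError("spine is empty")
    report = MergeReport()
    pieces = []
    for roi_id in point_sets.roi_ids:
        spine = point_sets.spine[roi_id].copy()
        spine_xy = spine[["x", "y"]].to_numpy(float)
        spine_ids = spine["cell_id"].to_numpy()
        for m in markers:
            spine[m] = np.int8(0)
        for marker, per_roi in point_sets.events.items():
            ev = per_roi.get(roi_id)
            if ev is None or len(ev) == 0:
                continue
            idx = _assign_events(spine_xy, spine_ids,
                                 ev[["x", "y"]].to_numpy(float), tolerance)
            hit = idx[idx >= 0]
            col = spine.columns.get_loc(marker)
            spine.iloc[np.unique(hit), col] = np.int8(1)
            report.matched[marker] = report.matched.get(marker, 0) + int(len(hit))
            report.unmatched[marker] = (report.unmatched.get(marker, 0)
                                        + int((idx < 0).sum()))
        pieces.append(spine)
    cells = pd.concat(pieces, ignore_index=True)
    if "compartment" not in cells.columns:
        cells["compartment"] = "unassigned"
    cells = cells[table_columns(markers)]
    return validate_cell_table(cells, markers), report


@dataclass
class PhenotypeCalls:
    """Result of phenotype calling over a cell table.

    ``membership`` is a boolean DataFrame indexed like the cell table with
    one column per phenotype name; ``lineage`` is a per-cell Series over
    {tumor, t_cell, macrophage, other}; ``multi_lineage_ids`` lists cells
    positive for more than one lineage marker (resolved by priority).
    """

    membership: pd.DataFrame
    lineage: pd.Series
    multi_lineage_ids: list[str]

    def matched_names(self, cell_index) -> set[str]:
        row = self.membership.loc[cell_index]
        return set(row.index[row])


def call_phenotypes(cells: pd.DataFrame,
                    registry: Sequence[PhenotypeDefinition] | None = None,
                    lineage_priority: Sequence[str] = LINEAGE_MARKERS,
                    markers: Sequence[str] = MARKERS) -> PhenotypeCalls:
    """Evaluate every registry rule against every cell's marker flags."""
    registry = list(registry) if registry is not None else default_registry()
    if sorted(lineage_priority) != sorted(LINEAGE_MARKERS):
        raise ConfigurationError(
            f"lineage_priority must order {LINEAGE_MARKERS}, got {lineage_priority}"
        )
    for d in registry:
        d.validate_against_panel(markers)
    membership = pd.DataFrame(index=cells.index)
    for d in registry:
        mask = pd.Series(True, index=cells.index)
        for m in d.require_positive:
            mask &= cells[m] == 1
        for m in d.require_negative:
            mask &= cells[m] == 0
        membership[d.name] = mask
    lineage = pd.Series("other", index=cells.index, dtype=object)
    n_lineage_pos = sum((cells[m] == 1).astype(int) for m in LINEAGE_MARKERS)
    for m in reversed(list(lineage_priority)):  # highest priority wins last
        lineage[cells[m] == 1] = LINEAGE_OF_MARKER[m]
    multi = cells.loc[n_lineage_pos > 1, "cell_id"].tolist() if len(cells) else []
    return PhenotypeCalls(membership, lineage, multi)


@dataclass(frozen=True)
class PDL1Status:
    status: str  # "positive" | "negative" | "not_evaluable"
    fraction: float | None
    n_malignant: int
    n_pdl1: int


def classify_case_pdl1(cells: pd.DataFrame,
                       cutoff: float = 0.01) -> PDL1Status:
    """Case-level PD-L1 call: positive iff the PD-L1+ fraction of panCK+
    cells strictly exceeds ``cutoff``."""
    malignant = cells[cells["panCK"] == 1]
    n = len(malignant)
    if n == 0:
        return PDL1Status("not_evaluable", None, 0, 0)
    n_pos = int((malignant["PD-L1"] == 1).sum())
    frac = n_pos / n
    return PDL1Status("positive" if frac > cutoff else "negative",
                      frac, n, n_pos)
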