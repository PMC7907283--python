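"""Core data model: panel, cell records, ROI geometry and panel configuration.

The canonical in-memory representation of a cell table is a pandas
``DataFrame`` with the columns ``cell_id, case_id, roi_id, x, y,
compartment`` followed by one 0/1 column per panel marker.  Coordinates are
always stored in micrometres (µm), origin at the ROI top-left corner, y
increasing downward.  :class:`CellRecord` is the row-level view used for
validation and round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, IntegrityError

#: The 8-marker panel, in panel order.
MARKERS: tuple[str, ...] = (
    "panCK", "PD-L1", "PD-1", "CD3", "CD8", "Foxp3", "KI67", "CD68",
)

#: Lineage-defining markers in default priority order (highest first).
LINEAGE_MARKERS: tuple[str, ...] = ("panCK", "CD3", "CD68")

#: Marker -> lineage name.
LINEAGE_OF_MARKER: dict[str, str] = {
    "panCK": "tumor",
    "CD3": "t_cell",
    "CD68": "macrophage",
}

COMPARTMENTS: tuple[str, ...] = ("epithelial", "stroma", "unassigned")

#: Default ROI window in µm (20x field).
DEFAULT_ROI_WIDTH = 931.0
DEFAULT_ROI_HEIGHT = 698.0

#: Fixed non-marker columns of a cell table, in order.
BASE_COLUMNS: tuple[str, ...] = (
    "cell_id", "case_id", "roi_id", "x", "y", "compartment",
)


@dataclass(frozen=True)
class CellRecord:
    """One segmented, nucleated (DAPI+) cell event."""

    cell_id: str
    case_id: str
    roi_id: str
    x: float
    y: float
    compartment: str = "unassigned"
    marker_flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise IntegrityError(
                f"cell {self.cell_id!r}: negative coordinate ({self.x}, {self.y})"
            )
        if self.compartment not in COMPARTMENTS:
            raise IntegrityError(
                f"cell {self.cell_id!r}: unknown compartment {self.compartment!r}"
            )

    def flag(self, marker: str) -> bool:
        return bool(self.marker_flags.get(marker, False))


@dataclass
class ROI:
    """An axis-aligned rectangular region of interest."""

    roi_id: str
    case_id: str
    width: float = DEFAULT_ROI_WIDTH
    height: float = DEFAULT_ROI_HEIGHT
    compartment_areas: dict[str, float] | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise IntegrityError(
                f"ROI {self.roi_id!r}: non-positive window {self.width} x {self.height}"
            )
        if self.compartment_areas is not None:
            total = sum(self.compartment_areas.values())
            if total > self.area_mm2 + 1e-6:
                raise IntegrityError(
                    f"ROI {self.roi_id!r}: compartment areas sum to {total:.6f} mm2 "
                    f"> ROI area {self.area_mm2:.6f} mm2"
                )

    @property
    def area_mm2(self) -> float:
        """ROI area in mm² (width × height / 10⁶)."""
        return self.width * self.height / 1e6

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.height


@dataclass
class PanelConfig:
    """Panel and pipeline thresholds.

    ``merge_tolerance`` is the coordinate-join radius in µm used when
    per-marker tables are merged onto the nucleated-cell spine;
    ``roi_tumor_fraction_min`` is the minimal fraction of panCK+ cells in the
    epithelial compartment for an ROI to pass QC; ``pdl1_case_cutoff`` is the
    strict lower bound on the PD-L1+ fraction of malignant cells for a case
    to be called PD-L1 positive.
    """

    marker_names: tuple[str, ...] = MARKERS
    pixel_size: float = 0.5
    coordinate_units: str = "micron"
    merge_tolerance: float = 0.5
    pdl1_case_cutoff: float = 0.01
    roi_tumor_fraction_min: float = 0.85
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.marker_names = tuple(self.marker_names)
        if self.coordinate_units not in ("micron", "pixel"):
            raise ConfigurationError(
                f"coordinate_units must be 'micron' or 'pixel', got "
                f"{self.coordinate_units!r}"
            )
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.merge_tolerance < 0:
            raise ConfigurationError("merge_tolerance must be >= 0")
        for name, v in (
            ("pdl1_case_cutoff", self.pdl1_case_cutoff),
            ("roi_tumor_fraction_min", self.roi_tumor_fraction_min),
        ):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown panel config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("panel", doc))

    def with_overrides(self, **kw) -> "PanelConfig":
        return replace(self, **kw)


def table_columns(markers: Sequence[str] = MARKERS) -> list[str]:
    """Column order of the canonical cell-table format."""
    return list(BASE_COLUMNS) + list(markers)


def empty_cell_table(markers: Sequence[str] = MARKERS) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in BASE_COLUMNS})
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    for m in markers:
        df[m] = pd.Series(dtype=np.int8)
    return df


def validate_cell_table(df: pd.DataFrame,
                        markers: Sequence[str] = MARKERS) -> pd.DataFrame:
    """Validate a cell table against the data-model invariants.

    Raises :class:`FormatError` for missing columns, :class:`IntegrityError`
    for duplicate cell ids, negative coordinates, bad compartments or
    non-binary marker flags.  Returns the table with normalised dtypes.
    """
    missing = [c for c in table_columns(markers) if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing required column(s): {missing}")
    df = df.copy()
    for col in ("cell_id", "case_id", "roi_id", "compartment"):
        df[col] = df[col].astype(str)
    if len(df) == 0:
        return df
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate cell_id values: {sorted(set(dup))[:5]}")
    for col in ("x", "y"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, "cell_id"].iloc[0]
            raise IntegrityError(f"negative {col} coordinate for cell {bad!r}")
    bad_comp = set(df["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise IntegrityError(f"unknown compartment label(s): {sorted(bad_comp)}")
    for m in markers:
        vals = pd.to_numeric(df[m], errors="raise")
        if not vals.isin((0, 1)).all():
            raise IntegrityError(f"marker column {m!r} contains non-0/1 values")
        df[m] = vals.astype(np.int8)
    return df


def records_to_table(records: Iterable[CellRecord],
                     markers: Sequence[str] = MARKERS) -> pd.DataFrame:
    rows = []
    for r in records:
        extra = set(r.marker_flags) - set(markers)
        if extra:
            raise IntegrityError(
                f"cell {r.cell_id!r}: markers not in panel: {sorted(extra)}"
            )
        row = {
            "cell_id": r.cell_id, "case_id": r.case_id, "roi_id": r.roi_id,
            "x": r.x, "y": r.y, "compartment": r.compartment,
        }
        for m in markers:
            row[m] = int(bool(r.marker_flags.get(m, False)))
        rows.append(row)
    if not rows:
        return empty_cell_table(markers)
    return validate_cell_table(pd.DataFrame(rows, columns=table_columns(markers)),
                               markers)


def table_to_records(df: pd.DataFrame,
                     markers: Sequence[str] = MARKERS) -> list[CellRecord]:
    df = validate_cell_table(df, markers)
    out = []
    for d in df.to_dict("records"):
        out.append(CellRecord(
            cell_id=d["cell_id"], case_id=d["case_id"], roi_id=d["roi_id"],
            x=float(d["x"]), y=float(d["y"]), compartment=d["compartment"],
            marker_flags={m: bool(d[m]) for m in markers},
        ))
    return out
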