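"""Reading and writing cell tables, per-marker event tables and run outputs.

All on-disk tables are comma-delimited UTF-8 text with a header row.  Cell
tables use the canonical column layout of :mod:`mifscape.datamodel`; marker
event tables carry ``cell_id, case_id, roi_id, x, y`` (the DAPI table — the
spine of all nucleated cells — additionally carries ``compartment``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    MARKERS,
    PanelConfig,
    empty_cell_table,
    table_columns,
    validate_cell_table,
)
from .errors import ConfigurationError, FormatError, IntegrityError

#: Reserved name of the all-nucleated-cells table in a marker-table set.
DAPI = "DAPI"

_FLOAT_FMT = "%.10g"


def _to_micron(df: pd.DataFrame, config: PanelConfig) -> pd.DataFrame:
    if config.coordinate_units == "pixel":
        df = df.copy()
        df["x"] = df["x"] * config.pixel_size
        df["y"] = df["y"] * config.pixel_size
    return df


def read_cell_table(path, config: PanelConfig | None = None) -> pd.DataFrame:
    """Read a consolidated cell table, converting coordinates to µm.

    Raises :class:`FormatError` naming the missing column or the offending
    line for non-numeric coordinates, and :class:`IntegrityError` for
    duplicate cell ids.
    """
    config = config or PanelConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "case_id": str,
                                  "roi_id": str, "compartment": str})
    missing = [c for c in table_columns(config.marker_names) if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {missing}")
    if len(df) == 0:
        return empty_cell_table(config.marker_names)
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path.name}: non-numeric {col!r} coordinate at line {line}"
            )
        df[col] = vals
    df = _to_micron(df, config)
    return validate_cell_table(df, config.marker_names)


def write_cell_table(df: pd.DataFrame, path,
                     markers=MARKERS) -> None:
    """Write a cell table in the canonical CSV dialect (coordinates in µm)."""
    df = validate_cell_table(df, markers)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class MarkerPointSets:
    """Per-marker positive-event point sets keyed by ROI, plus the DAPI spine.

    ``spine[roi_id]`` is a DataFrame of all nucleated cells in that ROI;
    ``events[marker][roi_id]`` holds the marker-positive events.
    """

    spine: dict[str, pd.DataFrame]
    events: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)

    @property
    def roi_ids(self) -> list[str]:
        return sorted(self.spine)


_EVENT_COLS = ("cell_id", "case_id", "roi_id", "x", "y")


def _read_event_table(path, config: PanelConfig, need_compartment: bool) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "case_id": str,
                                  "roi_id": str})
    required = list(_EVENT_COLS) + (["compartment"] if need_compartment else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s): {missing}")
    for col in ("x", "y"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if not need_compartment and "compartment" not in df.columns:
        df["compartment"] = "unassigned"
    df["compartment"] = df["compartment"].astype(str)
    return _to_micron(df, config)


def read_marker_tables(paths: Mapping[str, object],
                       config: PanelConfig | None = None) -> MarkerPointSets:
    """Load pre-merge per-marker event tables.

    ``paths`` maps marker name (or ``"DAPI"``) to a file path.  The DAPI
    table is mandatory — it defines cell identity — and every marker table
    must only reference ROIs present in it.
    """
    config = config or PanelConfig()
    if DAPI not in paths:
        raise ConfigurationError(
            "a DAPI (all nucleated cells) table is required as the spine"
        )
    unknown = set(paths) - set(config.marker_names) - {DAPI}
    if unknown:
        raise ConfigurationError(
            f"marker table(s) not in panel: {sorted(unknown)}"
        )
    spine_df = _read_event_table(paths[DAPI], config, need_compartment=True)
    if spine_df["cell_id"].duplicated().any():
        raise IntegrityError("DAPI table contains duplicate cell_id values")
    spine = {rid: g.reset_index(drop=True) for rid, g in spine_df.groupby("roi_id")}
    events: dict[str, dict[str, pd.DataFrame]] = {}
    unmatched_rois: dict[str, list[str]] = {}
    for marker, p in paths.items():
        if marker == DAPI:
            continue
        df = _read_event_table(p, config, need_compartment=False)
        extra = sorted(set(df["roi_id"]) - set(spine))
        if extra:
            unmatched_rois[marker] = extra
        events[marker] = {rid: g.reset_index(drop=True)
                          for rid, g in df.groupby("roi_id")}
    if unmatched_rois:
        detail = "; ".join(f"{m}: {r}" for m, r in sorted(unmatched_rois.items()))
        raise IntegrityError(
            f"marker tables reference ROIs absent from the DAPI spine ({detail})"
        )
    return MarkerPointSets(spine=spine, events=events)


def write_outputs(results: Mapping[str, object], out_dir) -> dict[str, Path]:
    """Write the run's tables plus a machine-readable summary.

    ``results`` maps logical names (``density``, ``proximity``, ``gcurves``,
    ``pattern_calls``, ``qc``, ...) to DataFrames, and optionally ``summary``
    to a JSON-serialisable mapping.  Re-running with identical inputs yields
    byte-identical files.
    """
    if results is None:
        raise ValueError("results must not be None")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    written: dict[str, Path] = {}
    for name, obj in results.items():
        if name == "summary":
            continue
        if not isinstance(obj, pd.DataFrame):
            raise TypeError(f"result {name!r} is not a DataFrame")
        p = out_dir / f"{name}.csv"
        obj.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written[name] = p
    summary = dict(results.get("summary", {}))
    summary.setdefault("tables", sorted(written))
    p = out_dir / "run_summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written["summary"] = p
    return written
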