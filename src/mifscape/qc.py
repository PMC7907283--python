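"""ROI-level quality control."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import PanelConfig


@dataclass
class ROIQCReport:
    roi_id: str
    n_cells: int
    compartment_counts: dict[str, int]
    panck_fraction: float | None  # among epithelial cells; None if none
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags


def qc_roi(cells: pd.DataFrame, config: PanelConfig | None = None) -> ROIQCReport:
    """Check the malignant-cell content of one ROI's epithelial compartment.

    The ROI is flagged ``low_tumor_fraction`` when fewer than
    ``config.roi_tumor_fraction_min`` of its epithelial-compartment cells are
    panCK+, and ``no_epithelial_compartment`` when there are no epithelial
    cells at all.  QC never raises; it always returns a report.
    """
    config = config or PanelConfig()
    roi_ids = cells["roi_id"].unique()
    roi_id = str(roi_ids[0]) if len(roi_ids) else "<empty>"
    counts = cells["compartment"].value_counts().to_dict()
    counts = {str(k): int(v) for k, v in counts.items()}
    epi = cells[cells["compartment"] == "epithelial"]
    flags: list[str] = []
    if len(roi_ids) > 1:
        flags.append("multiple_roi_ids")
    if len(epi) == 0:
        return ROIQCReport(roi_id, len(cells), counts, None,
                           flags + ["no_epithelial_compartment"])
    frac = float(epi["panCK"].sum()) / len(epi)
    if frac < config.roi_tumor_fraction_min:
        flags.append("low_tumor_fraction")
    return ROIQCReport(roi_id, len(cells), counts, frac, flags)


def qc_all_rois(cells: pd.DataFrame,
                config: PanelConfig | None = None) -> pd.DataFrame:
    """Run :func:`qc_roi` per ROI; returns one row per ROI."""
    rows = []
    for rid, g in cells.groupby("roi_id", sort=True):
        rep = qc_roi(g, config)
        rows.append({
            "roi_id": rid,
            "case_id": g["case_id"].iloc[0],
            "n_cells": rep.n_cells,
            "n_epithelial": rep.compartment_counts.get("epithelial", 0),
            "n_stroma": rep.compartment_counts.get("stroma", 0),
            "panck_fraction": rep.panck_fraction,
            "flags": ";".join(rep.flags),
            "passed": rep.passed,
        })
    return pd.DataFrame(rows)
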