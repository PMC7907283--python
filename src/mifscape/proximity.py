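"""Malignant-cell-to-immune-cell distance analysis.

Distances are euclidean, in µm, and are only ever computed between cells of
the same ROI (ROIs are disjoint physical fields); per-case statistics pool
each reference cell's nearest-neighbour distance across the case's ROIs
before taking the median.  A phenotype is labelled *close* when its median
distance from malignant cells is less than or equal to the overall median
radius, *far* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .phenotyping import PhenotypeCalls

#: Reference strata of the proximity matrix.
STRATA = ("panCK+", "panCK+PD-L1-", "panCK+PD-L1+")

#: Above this many target points, nearest-neighbour queries switch from the
#: dense distance matrix to a k-d tree (results are identical).
_KDTREE_THRESHOLD = 2000


def distance_matrix(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    """Pairwise euclidean distance matrix, |from| × |to|."""
    from_pts = np.atleast_2d(np.asarray(from_pts, float))
    to_pts = np.atleast_2d(np.asarray(to_pts, float))
    if from_pts.size == 0 or to_pts.size == 0:
        raise ParameterError("distance_matrix: empty point set is not evaluable")
    return cdist(from_pts, to_pts)


def nn_distances(ref_pts: np.ndarray, tgt_pts: np.ndarray) -> np.ndarray:
    """Distance from each reference point to its nearest target point."""
    ref_pts = np.atleast_2d(np.asarray(ref_pts, float))
    tgt_pts = np.atleast_2d(np.asarray(tgt_pts, float))
    if ref_pts.size == 0 or tgt_pts.size == 0:
        raise ParameterError("nn_distances: empty point set is not evaluable")
    if max(len(ref_pts), len(tgt_pts)) > _KDTREE_THRESHOLD:
        d, _ = cKDTree(tgt_pts).query(ref_pts)
        return np.asarray(d, float)
    return distance_matrix(ref_pts, tgt_pts).min(axis=1)


def _points(cells: pd.DataFrame, mask: pd.Series) -> np.ndarray:
    return cells.loc[mask, ["x", "y"]].to_numpy(float)


def pooled_nn_distances(cells: pd.DataFrame, ref_mask: pd.Series,
                        tgt_mask: pd.Series) -> np.ndarray:
    """Reference-cell NN distances pooled over ROIs (within-ROI pairs only).

    ROIs lacking reference or target cells contribute nothing.
    """
    chunks = []
    for _, g in cells.groupby("roi_id", sort=True):
        ref = _points(g, ref_mask.loc[g.index])
        tgt = _points(g, tgt_mask.loc[g.index])
        if len(ref) == 0 or len(tgt) == 0:
            continue
        chunks.append(nn_distances(ref, tgt))
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def median_nn_distance(cells: pd.DataFrame, ref_mask: pd.Series,
                       tgt_mask: pd.Series, mode: str = "nearest") -> float:
    """Median distance from reference cells to a target phenotype.

    ``mode="nearest"`` (default): median over reference cells of the
    nearest-target distance.  ``mode="allpairs"``: median of the full
    reference × target distance matrix.  Returns NaN ("not evaluable") when
    either side is empty in every ROI.
    """
    if mode not in ("nearest", "allpairs"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "nearest":
        d = pooled_nn_distances(cells, ref_mask, tgt_mask)
        return float(np.median(d)) if len(d) else float("nan")
    chunks = []
    for _, g in cells.groupby("roi_id", sort=True):
        ref = _points(g, ref_mask.loc[g.index])
        tgt = _points(g, tgt_mask.loc[g.index])
        if len(ref) == 0 or len(tgt) == 0:
            continue
        chunks.append(distance_matrix(ref, tgt).ravel())
    if not chunks:
        return float("nan")
    return float(np.median(np.concatenate(chunks)))


def overall_radius(summary: pd.DataFrame, stratum: str = "panCK+") -> float:
    """Median over the (case × phenotype) grid of median distances for one
    reference stratum — the cohort's close/far radius."""
    vals = summary.loc[(summary["stratum"] == stratum)
                       & summary["median_distance"].notna(), "median_distance"]
    if len(vals) == 0:
        raise ParameterError("no evaluable median distances for the stratum")
    return float(np.median(vals.to_numpy(float)))


def classify_proximity(median_distance: float, radius: float) -> str:
    """close iff distance ≤ radius (equal counts as close)."""
    if not (np.isfinite(median_distance) and np.isfinite(radius)):
        raise ParameterError("distance and radius must be finite")
    return "close" if median_distance <= radius else "far"


@dataclass
class ProximitySummary:
    """Per (case, reference stratum, target phenotype) median distances with
    the overall radius and close/far labels."""

    table: pd.DataFrame  # case_id, stratum, phenotype, median_distance, label
    overall_radius_um: float
    stratum_medians: dict[str, float]  # per-stratum overall median distance


def _stratum_masks(cells: pd.DataFrame) -> dict[str, pd.Series]:
    panck = cells["panCK"] == 1
    return {
        "panCK+": panck,
        "panCK+PD-L1-": panck & (cells["PD-L1"] == 0),
        "panCK+PD-L1+": panck & (cells["PD-L1"] == 1),
    }


def stratified_proximity(cells: pd.DataFrame, calls: PhenotypeCalls,
                         phenotypes: Sequence[str] | None = None,
                         mode: str = "nearest") -> ProximitySummary:
    """Median NN distances from the three malignant-cell strata to each
    target phenotype, per case, plus the overall close/far radius.

    The panCK+ stratum is the union of the two PD-L1 strata; empty strata
    yield NaN ("not evaluable") entries.
    """
    if not (cells["panCK"] == 1).any():
        raise ParameterError("no panCK+ cells: proximity not evaluable")
    if phenotypes is None:
        phenotypes = [c for c in calls.membership.columns
                      if not c.startswith("panCK")]
    rows = []
    for case_id, g in cells.groupby("case_id", sort=True):
        sub_calls = calls.membership.loc[g.index]
        masks = _stratum_masks(g)
        for stratum, ref_mask in masks.items():
            for ph in phenotypes:
                tgt_mask = sub_calls[ph]
                med = median_nn_distance(g, ref_mask, tgt_mask, mode=mode)
                rows.append({"case_id": case_id, "stratum": stratum,
                             "phenotype": ph, "median_distance": med})
    table = pd.DataFrame(rows)
    radius = overall_radius(table, "panCK+")
    table["label"] = [
        classify_proximity(d, radius) if np.isfinite(d) else "not_evaluable"
        for d in table["median_distance"]
    ]
    stratum_medians = {}
    for s in STRATA:
        vals = table.loc[(table["stratum"] == s)
                         & table["median_distance"].notna(), "median_distance"]
        stratum_medians[s] = (float(np.median(vals.to_numpy(float)))
                              if len(vals) else float("nan"))
    return ProximitySummary(table, radius, stratum_medians)


def proximity_matrix(summary: ProximitySummary) -> pd.DataFrame:
    """Heat-map-ready wide layout: phenotype rows × the three stratum columns
    of cohort-median distances."""
    t = summary.table
    agg = (t.groupby(["phenotype", "stratum"])["median_distance"]
           .median().unstack("stratum"))
    return agg.reindex(columns=list(STRATA))


def count_within_radius(ref_pts: np.ndarray, tgt_pts: np.ndarray,
                        radii: Sequence[float]) -> np.ndarray:
    """Number of target cells whose nearest reference cell lies within each
    radius of an increasing sweep."""
    radii = np.asarray(radii, float)
    if len(radii) == 0 or (radii < 0).any() or (np.diff(radii) <= 0).any():
        raise ParameterError("radii must be non-negative and strictly increasing")
    tgt_pts = np.atleast_2d(np.asarray(tgt_pts, float))
    if tgt_pts.size == 0:
        return np.zeros(len(radii), dtype=int)
    d = nn_distances(tgt_pts, ref_pts)
    return (d[:, None] <= radii[None, :]).sum(axis=0)
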