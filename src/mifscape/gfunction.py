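"""Nearest-neighbour G function versus theoretical Poisson, and the
mixed/unmixed landscape classification.

The empirical cross-type G function is the CDF of nearest-target distances
over reference points, uncorrected for edge effects by default (a
reduced-sample border correction is available behind a flag).  The
theoretical curve is the G function of a homogeneous Poisson process at the
intensity of the observed target pattern, ``1 − exp(−λπr²)``.  Their
difference, in percentage points of G, drives the landscape call: *mixed*
when the deviation stays within ``[lower, upper]`` over the whole radius
grid, *unmixed* when it exceeds ``upper`` anywhere, *indeterminate*
otherwise (the source rule defines no branch for deviations below the lower
bound only).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .phenotyping import PhenotypeCalls
from .proximity import nn_distances

#: Default radius grid: 0–200 µm in 1 µm steps.
DEFAULT_R_GRID = np.arange(0.0, 201.0, 1.0)

#: Default deviation thresholds, percentage points of G.
DEFAULT_LOWER = -10.0
DEFAULT_UPPER = 10.0


def _check_grid(r_grid: np.ndarray) -> np.ndarray:
    r_grid = np.asarray(r_grid, float)
    if r_grid.ndim != 1 or len(r_grid) == 0 or (np.diff(r_grid) < 0).any():
        raise ParameterError("r_grid must be a non-empty ordered 1-D array")
    if (r_grid < 0).any():
        raise ParameterError("r_grid must be non-negative")
    return r_grid


def empirical_g(ref_pts: np.ndarray, tgt_pts: np.ndarray,
                r_grid: np.ndarray = DEFAULT_R_GRID, *,
                exclude_self: bool = False,
                border_correction: bool = False,
                window: tuple[float, float] | None = None) -> np.ndarray:
    """Empirical nearest-neighbour G function on ``r_grid``.

    ``g(r)`` = fraction of reference points whose nearest target lies within
    distance r.  With ``exclude_self`` the two patterns are taken to be the
    same set and zero-distance self matches are excluded.  With
    ``border_correction`` (reduced-sample estimator) only reference points
    farther than r from the window boundary enter the estimate at radius r;
    ``window`` = (width, height) is then required.
    """
    r_grid = _check_grid(r_grid)
    ref_pts = np.atleast_2d(np.asarray(ref_pts, float))
    tgt_pts = np.atleast_2d(np.asarray(tgt_pts, float))
    if ref_pts.size == 0 or tgt_pts.size == 0:
        raise ParameterError("empirical_g: empty pattern is not evaluable")
    if exclude_self:
        if len(tgt_pts) < 2:
            raise ParameterError("self G needs >= 2 points")
        from scipy.spatial import cKDTree
        d, _ = cKDTree(tgt_pts).query(ref_pts, k=2)
        nn = d[:, 1]
    else:
        nn = nn_distances(ref_pts, tgt_pts)
    hit = nn[:, None] <= r_grid[None, :]
    if not border_correction:
        return hit.mean(axis=0)
    if window is None:
        raise ParameterError("border correction requires the window size")
    w, h = window
    b = np.minimum.reduce([ref_pts[:, 0], w - ref_pts[:, 0],
                           ref_pts[:, 1], h - ref_pts[:, 1]])
    usable = b[:, None] > r_grid[None, :]
    num = (hit & usable).sum(axis=0)
    den = usable.sum(axis=0)
    g = hit.mean(axis=0)  # fall back to uncorrected where nothing is usable
    ok = den > 0
    g[ok] = num[ok] / den[ok]
    return g


def poisson_g(intensity_lambda: float,
              r_grid: np.ndarray = DEFAULT_R_GRID) -> np.ndarray:
    """Theoretical Poisson (CSR) G function: 1 − exp(−λπr²)."""
    if intensity_lambda < 0:
        raise ParameterError("intensity must be >= 0")
    r_grid = _check_grid(r_grid)
    return 1.0 - np.exp(-intensity_lambda * np.pi * r_grid ** 2)


def deviation_curve(g_emp: np.ndarray, g_pois: np.ndarray) -> np.ndarray:
    """Deviation in percentage points of G: 100 × (g_emp − g_pois)."""
    g_emp = np.asarray(g_emp, float)
    g_pois = np.asarray(g_pois, float)
    if g_emp.shape != g_pois.shape:
        raise ParameterError("curves must share the same radius grid")
    return 100.0 * (g_emp - g_pois)


@dataclass
class GCurve:
    """Empirical and theoretical G on a shared grid, with their deviation."""

    r_grid: np.ndarray
    g_emp: np.ndarray
    g_pois: np.ndarray
    intensity_lambda: float
    n_reference: int
    n_target: int
    roi_id: str = ""
    case_id: str = ""

    @property
    def deviation(self) -> np.ndarray:
        return deviation_curve(self.g_emp, self.g_pois)

    def to_frame(self, phenotype: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "roi_id": self.roi_id, "case_id": self.case_id,
            "phenotype": phenotype, "r": self.r_grid,
            "g_emp": self.g_emp, "g_pois": self.g_pois,
            "deviation": self.deviation,
        })


def compute_gcurve(ref_pts: np.ndarray, tgt_pts: np.ndarray,
                   window: tuple[float, float],
                   r_grid: np.ndarray = DEFAULT_R_GRID, *,
                   border_correction: bool = False,
                   roi_id: str = "", case_id: str = "") -> GCurve:
    """Empirical vs intensity-matched Poisson G for one ROI.

    λ is the observed target intensity: target count ÷ window area (µm⁻²).
    """
    r_grid = _check_grid(r_grid)
    tgt_pts = np.atleast_2d(np.asarray(tgt_pts, float))
    lam = len(tgt_pts) / (window[0] * window[1])
    g_emp = empirical_g(ref_pts, tgt_pts, r_grid,
                        border_correction=border_correction, window=window)
    return GCurve(r_grid, g_emp, poisson_g(lam, r_grid), lam,
                  int(np.atleast_2d(ref_pts).shape[0]), len(tgt_pts),
                  roi_id=roi_id, case_id=case_id)


@dataclass
class PatternCall:
    """Mixed/unmixed/indeterminate landscape call."""

    scope: str  # "roi" | "case"
    label: str  # "mixed" | "unmixed" | "indeterminate" | "not_evaluable"
    max_deviation: float = float("nan")
    min_deviation: float = float("nan")
    votes: dict[str, int] = field(default_factory=dict)


def classify_pattern(deviation: np.ndarray,
                     lower: float = DEFAULT_LOWER,
                     upper: float = DEFAULT_UPPER, *,
                     invert_polarity: bool = False) -> PatternCall:
    """Classify one ROI's deviation curve.

    mixed — the whole curve lies in [lower, upper]; unmixed — the curve
    exceeds ``upper`` somewhere; indeterminate — the curve only drops below
    ``lower``.  ``invert_polarity`` negates the curve first (for the reading
    where segregation shows up as a deficit rather than an excess of G).
    """
    if lower > upper:
        raise ParameterError("lower threshold must not exceed upper")
    dev = np.asarray(deviation, float)
    if invert_polarity:
        dev = -dev
    lo, hi = float(dev.min()), float(dev.max())
    if lo >= lower and hi <= upper:
        label = "mixed"
    elif hi > upper:
        label = "unmixed"
    else:
        label = "indeterminate"
    return PatternCall("roi", label, max_deviation=hi, min_deviation=lo)


def aggregate_patterns(roi_calls: Sequence[PatternCall]) -> PatternCall:
    """Case-level call: plurality vote over ROI labels, ties indeterminate."""
    if not roi_calls:
        raise ParameterError("need >= 1 ROI call")
    votes = Counter(c.label for c in roi_calls if c.label != "not_evaluable")
    if not votes:
        return PatternCall("case", "not_evaluable")
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        label = "indeterminate"
    else:
        label = top[0][0]
    finite = [c for c in roi_calls if np.isfinite(c.max_deviation)]
    return PatternCall(
        "case", label,
        max_deviation=max((c.max_deviation for c in finite), default=float("nan")),
        min_deviation=min((c.min_deviation for c in finite), default=float("nan")),
        votes=dict(votes),
    )


def cohort_tally(case_calls: Mapping[str, PatternCall]) -> dict[str, int]:
    return dict(Counter(c.label for c in case_calls.values()))


def phenotype_pattern_profile(cells: pd.DataFrame, calls: PhenotypeCalls,
                              window: tuple[float, float],
                              phenotypes: Sequence[str] = ("CD3+",),
                              r_grid: np.ndarray = DEFAULT_R_GRID, *,
                              lower: float = DEFAULT_LOWER,
                              upper: float = DEFAULT_UPPER,
                              invert_polarity: bool = False,
                              border_correction: bool = False,
                              keep_curves: bool = False,
                              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-ROI and per-case pattern calls for each target phenotype.

    Reference = panCK+ cells; target = the phenotype's cells; ROIs lacking
    either side are reported ``not_evaluable``.  Returns (per-ROI table,
    per-case table, long-format G-curve table — empty unless
    ``keep_curves``).
    """
    roi_rows, gcurves = [], []
    for (case_id, roi_id), g in cells.groupby(["case_id", "roi_id"], sort=True):
        ref = g.loc[g["panCK"] == 1, ["x", "y"]].to_numpy(float)
        sub = calls.membership.loc[g.index]
        for ph in phenotypes:
            tgt = g.loc[sub[ph], ["x", "y"]].to_numpy(float)
            if len(ref) == 0 or len(tgt) == 0:
                roi_rows.append({"case_id": case_id, "roi_id": roi_id,
                                 "phenotype": ph, "label": "not_evaluable",
                                 "max_deviation": np.nan,
                                 "min_deviation": np.nan})
                continue
            curve = compute_gcurve(ref, tgt, window, r_grid,
                                   border_correction=border_correction,
                                   roi_id=str(roi_id), case_id=str(case_id))
            if keep_curves:
                gcurves.append(curve.to_frame(ph))
            call = classify_pattern(curve.deviation, lower, upper,
                                    invert_polarity=invert_polarity)
            roi_rows.append({"case_id": case_id, "roi_id": roi_id,
                             "phenotype": ph, "label": call.label,
                             "max_deviation": call.max_deviation,
                             "min_deviation": call.min_deviation})
    per_roi = pd.DataFrame(roi_rows)
    case_rows = []
    for (case_id, ph), g in per_roi.groupby(["case_id", "phenotype"], sort=True):
        calls_list = [PatternCall("roi", r.label, r.max_deviation, r.min_deviation)
                      for r in g.itertuples()]
        agg = aggregate_patterns(calls_list)
        case_rows.append({"case_id": case_id, "phenotype": ph,
                          "label": agg.label,
                          "n_roi": len(g),
                          **{f"votes_{k}": v for k, v in sorted(agg.votes.items())}})
    per_case = pd.DataFrame(case_rows)
    curve_df = (pd.concat(gcurves, ignore_index=True) if gcurves
                else pd.DataFrame(columns=["roi_id", "case_id", "phenotype",
                                           "r", "g_emp", "g_pois", "deviation"]))
    return per_roi, per_case, curve_df
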