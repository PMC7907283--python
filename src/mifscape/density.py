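"""Compartmentalized cell densities, cohort summaries, group comparisons and
tissue-microarray staining-consistency QC.

Densities are cells/mm² computed per ROI against the compartment area, then
averaged (unweighted) over a case's ROIs.  When the input does not carry
measured tissue-category areas, a compartment's area is estimated as
ROI area × (compartment cell count / total cell count).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MARKERS, ROI
from .errors import ParameterError
from .phenotyping import PhenotypeCalls, PhenotypeDefinition, default_registry

COMPARTMENT_LEVELS = ("epithelial", "stroma", "combined")


def compartment_area_mm2(roi: ROI, cells: pd.DataFrame, compartment: str) -> float:
    """Area in mm² of one compartment of an ROI.

    Uses the ROI's measured ``compartment_areas`` when available, otherwise
    apportions the ROI area by cell-count fraction.  ``combined`` is the sum
    of the epithelial and stroma areas.
    """
    if compartment == "combined":
        return (compartment_area_mm2(roi, cells, "epithelial")
                + compartment_area_mm2(roi, cells, "stroma"))
    if roi.compartment_areas is not None and compartment in roi.compartment_areas:
        return float(roi.compartment_areas[compartment])
    total = len(cells)
    if total == 0:
        return 0.0
    frac = (cells["compartment"] == compartment).sum() / total
    return roi.area_mm2 * float(frac)


def _phenotype_mask(cells: pd.DataFrame, phenotype,
                    calls: PhenotypeCalls | None) -> pd.Series:
    if isinstance(phenotype, PhenotypeDefinition):
        mask = pd.Series(True, index=cells.index)
        for m in phenotype.require_positive:
            mask &= cells[m] == 1
        for m in phenotype.require_negative:
            mask &= cells[m] == 0
        return mask
    if calls is None:
        raise ParameterError(
            "phenotype given by name requires PhenotypeCalls membership")
    return calls.membership[phenotype]


def compute_density(cells: pd.DataFrame, phenotype,
                    compartment: str, rois: Mapping[str, ROI],
                    calls: PhenotypeCalls | None = None,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-ROI densities (cells/mm²) and the per-case unweighted mean.

    ``phenotype`` is a :class:`PhenotypeDefinition` or a phenotype name
    resolved through ``calls``.  ROIs whose compartment area is zero or
    unknown are excluded with a warning rather than reported as zero.
    """
    if compartment not in COMPARTMENT_LEVELS:
        raise ParameterError(f"unknown compartment {compartment!r}")
    mask = _phenotype_mask(cells, phenotype, calls)
    rows = []
    for roi_id, g in cells.groupby("roi_id", sort=True):
        roi = rois[str(roi_id)]
        area = compartment_area_mm2(roi, g, compartment)
        if compartment == "combined":
            in_comp = g["compartment"].isin(("epithelial", "stroma"))
        else:
            in_comp = g["compartment"] == compartment
        count = int((mask.loc[g.index] & in_comp).sum())
        if area <= 0:
            warnings.warn(
                f"ROI {roi_id}: zero {compartment} area, excluded from density",
                stacklevel=2)
            continue
        rows.append({"roi_id": roi_id, "case_id": g["case_id"].iloc[0],
                     "count": count, "area_mm2": area,
                     "density": count / area})
    per_roi = pd.DataFrame(rows, columns=["roi_id", "case_id", "count",
                                          "area_mm2", "density"])
    per_case = (per_roi.groupby("case_id")["density"].mean()
                if len(per_roi) else pd.Series(dtype=float))
    return per_roi, per_case


def density_table(cells: pd.DataFrame, rois: Mapping[str, ROI],
                  registry: Sequence[PhenotypeDefinition] | None = None,
                  calls: PhenotypeCalls | None = None) -> pd.DataFrame:
    """Long-format density table: one row per (case, phenotype, compartment)."""
    registry = list(registry) if registry is not None else default_registry()
    rows = []
    for d in registry:
        for comp in COMPARTMENT_LEVELS:
            _, per_case = compute_density(cells, d, comp, rois, calls)
            for case_id, val in per_case.items():
                rows.append({"case_id": case_id, "phenotype": d.name,
                             "compartment": comp, "density": float(val)})
    return pd.DataFrame(rows, columns=["case_id", "phenotype",
                                       "compartment", "density"])


def summarize_cohort(per_case: pd.DataFrame) -> pd.DataFrame:
    """Median/min/max over cases per (phenotype, compartment).

    The median of an even number of cases is the mean of the two central
    values.
    """
    if len(per_case) == 0:
        raise ParameterError("cohort summary requires at least one case")
    g = per_case.groupby(["phenotype", "compartment"])["density"]
    out = g.agg(median="median", min="min", max="max", n_cases="count")
    return out.reset_index()


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    pvalue: float
    method: str
    note: str = ""


def compare_compartments(epithelial: Sequence[float],
                         stroma: Sequence[float]) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) of per-case densities.

    Exact null when both samples are small (n ≤ 12) and untied; normal
    approximation with tie correction otherwise.  Fully degenerate data
    (every value identical) returns p = 1 with a note.
    """
    x = np.asarray(epithelial, float)
    y = np.asarray(stroma, float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("need >= 2 cases per compartment")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return ComparisonResult(np.nan, 1.0, "wilcoxon-rank-sum",
                                "degenerate data: all values identical")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            "wilcoxon-rank-sum", f"null={method}")


def kruskal_groups(*groups: Sequence[float]) -> ComparisonResult:
    """Kruskal–Wallis test across >2 groups of continuous values."""
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if all(np.all(a == arrays[0][0]) for a in arrays):
        return ComparisonResult(np.nan, 1.0, "kruskal-wallis",
                                "degenerate data: all values identical")
    stat, p = stats.kruskal(*arrays)
    return ComparisonResult(float(stat), float(p), "kruskal-wallis")


def categorical_test(table: np.ndarray) -> ComparisonResult:
    """Chi-square test of a contingency table; Fisher exact for 2×2 tables
    with small expected counts."""
    table = np.asarray(table)
    if table.shape == (2, 2):
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            stat, p = stats.fisher_exact(table)
            return ComparisonResult(float(stat), float(p), "fisher-exact")
    res = stats.chi2_contingency(table)
    return ComparisonResult(float(res.statistic), float(res.pvalue), "chi-square")


def marker_percentages(cells: pd.DataFrame,
                       markers: Sequence[str] = MARKERS) -> dict[str, float]:
    """Percent of DAPI+ (i.e. all) cells positive for each marker, for one
    TMA core.  Empty core -> ParameterError ("not evaluable")."""
    if len(cells) == 0:
        raise ParameterError("empty core: marker percentages not evaluable")
    n = len(cells)
    return {m: 100.0 * float((cells[m] == 1).sum()) / n for m in markers}


def consistency_correlation(percent_tables: Mapping[int, pd.DataFrame],
                            alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of per-core marker percentages across time points.

    ``percent_tables`` maps time-point label -> DataFrame (cores × markers)
    of percentages; all time points must share the same core index.  Returns
    one row per (marker, time-point pair) with rho, raw p, Bonferroni-
    adjusted p (family = all marker × pair tests) and a significance flag at
    adjusted p < ``alpha``.  Constant vectors yield rho = NaN, flagged
    ``undefined``.
    """
    tps = sorted(percent_tables)
    if len(tps) < 2:
        raise ParameterError("need >= 2 time points")
    first = percent_tables[tps[0]]
    for t in tps[1:]:
        if not first.index.equals(percent_tables[t].index):
            raise ParameterError("time points must share the same core set")
    if len(first) < 3:
        raise ParameterError("need >= 3 cores")
    markers = list(first.columns)
    rows = []
    for m in markers:
        for a, b in itertools.combinations(tps, 2):
            va = percent_tables[a][m].to_numpy(float)
            vb = percent_tables[b][m].to_numpy(float)
            if np.all(va == va[0]) or np.all(vb == vb[0]):
                rows.append({"marker": m, "pair": f"{a}-{b}", "rho": np.nan,
                             "pvalue": np.nan, "note": "undefined: constant vector"})
                continue
            rho, p = stats.spearmanr(va, vb)
            rows.append({"marker": m, "pair": f"{a}-{b}", "rho": float(rho),
                         "pvalue": float(p), "note": ""})
    out = pd.DataFrame(rows)
    n_tests = int(out["pvalue"].notna().sum())
    out["pvalue_bonferroni"] = np.minimum(1.0, out["pvalue"] * n_tests)
    out["significant"] = out["pvalue_bonferroni"] < alpha
    out.loc[out["pvalue"].isna(), "significant"] = False
    return out
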