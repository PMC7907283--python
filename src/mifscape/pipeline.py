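"""End-to-end orchestration: load or simulate cells, then phenotype →
QC → density → spatial proximity → landscape patterns → outputs."""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import density as density_mod
from . import gfunction, proximity, qc, simulate
from .datamodel import DEFAULT_ROI_HEIGHT, DEFAULT_ROI_WIDTH, PanelConfig
from .errors import ConfigurationError
from .io import read_cell_table, write_outputs
from .phenotyping import call_phenotypes, classify_case_pdl1, default_registry

log = logging.getLogger("mifscape")


def load_run_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("run config must be a mapping")
    return doc


def _get_cells(cfg: Mapping, panel: PanelConfig, seed: int | None):
    inp = cfg.get("input", {})
    if "cell_table" in inp:
        return read_cell_table(inp["cell_table"], panel), None
    preset = inp.get("preset")
    if preset is None:
        raise ConfigurationError(
            "run config needs input.cell_table or input.preset")
    if preset not in simulate.PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {sorted(simulate.PRESETS)}")
    overrides = dict(cfg.get("simulation", {}))
    use_seed = seed if seed is not None else overrides.pop("seed", panel.random_seed)
    overrides.pop("seed", None)
    cells, truth = simulate.PRESETS[preset](seed=use_seed, **overrides)
    return cells, truth


def run_pipeline(config: Mapping | str | Path, seed: int | None = None,
                 out_dir=None) -> dict:
    """Execute the full analysis described by a run config.

    ``config`` is a mapping (or path to a YAML file) with optional blocks
    ``panel``, ``input`` (``cell_table`` path or ``preset`` name),
    ``simulation`` (preset overrides), ``analysis`` and ``output``.
    Returns the results dict that :func:`mifscape.io.write_outputs` consumes.
    """
    if isinstance(config, (str, Path)):
        config = load_run_config(config)
    panel = PanelConfig.from_dict(config.get("panel", {}))
    analysis = dict(config.get("analysis", {}))
    window = tuple(analysis.get("window", (DEFAULT_ROI_WIDTH, DEFAULT_ROI_HEIGHT)))

    timings: dict[str, float] = {}

    def stage(name):
        t0 = time.perf_counter()

        def done(n_records=None):
            timings[name] = round(time.perf_counter() - t0, 4)
            log.info("stage %-10s %8.3fs  records=%s", name, timings[name],
                     n_records)
        return done

    done = stage("load")
    cells, truth = _get_cells(config, panel, seed)
    done(len(cells))

    done = stage("phenotype")
    registry = default_registry()
    calls = call_phenotypes(cells, registry)
    pdl1 = {case: classify_case_pdl1(g, panel.pdl1_case_cutoff)
            for case, g in cells.groupby("case_id", sort=True)}
    done(len(cells))

    done = stage("qc")
    qc_table = qc.qc_all_rois(cells, panel)
    done(len(qc_table))

    done = stage("density")
    rois = simulate.rois_for(cells, window)
    dens = density_mod.density_table(cells, rois, registry, calls)
    summary = density_mod.summarize_cohort(dens)
    done(len(dens))

    done = stage("spatial")
    prox = proximity.stratified_proximity(cells, calls)
    done(len(prox.table))

    done = stage("patterns")
    target_phenotypes = analysis.get("pattern_phenotypes", ["CD3+"])
    per_roi, per_case, gcurves = gfunction.phenotype_pattern_profile(
        cells, calls, window, target_phenotypes,
        lower=analysis.get("lower", gfunction.DEFAULT_LOWER),
        upper=analysis.get("upper", gfunction.DEFAULT_UPPER),
        invert_polarity=analysis.get("invert_polarity", False),
        keep_curves=True)
    done(len(per_roi))

    results = {
        "density": dens,
        "density_summary": summary,
        "proximity": prox.table,
        "gcurves": gcurves,
        "pattern_calls": per_roi,
        "pattern_calls_case": per_case,
        "qc": qc_table,
        "summary": {
            "n_cells": int(len(cells)),
            "n_cases": int(cells["case_id"].nunique()),
            "n_rois": int(cells["roi_id"].nunique()),
            "overall_radius_um": prox.overall_radius_um,
            "stratum_median_um": prox.stratum_medians,
            "pdl1_status": {k: v.status for k, v in pdl1.items()},
            "pattern_tally": per_case["label"].value_counts().to_dict(),
            "timings_s": timings,
        },
    }
    out = out_dir or config.get("output", {}).get("out_dir")
    if out is not None:
        write_outputs(results, out)
    return results
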