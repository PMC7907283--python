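import os

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mifscape.datamodel import (
    MARKERS,
    CellRecord,
    PanelConfig,
    ROI,
    table_to_records,
    validate_cell_table,
)
from mifscape.errors import (
    ConfigurationError,
    FormatError,
    IntegrityError,
)
from mifscape.io import read_cell_table, read_marker_tables, write_cell_table, write_outputs
from mifscape.qc import qc_roi
from conftest import make_cells


class TestCellRecord:
    def test_negative_coordinate_rejected(self):
        with pytest.raises(IntegrityError):
            CellRecord("c1", "case01", "roi01", -1.0, 5.0)

    def test_unknown_compartment_rejected(self):
        with pytest.raises(IntegrityError):
            CellRecord("c1", "case01", "roi01", 1.0, 5.0, compartment="lumen")

    def test_flag_defaults_false(self):
        r = CellRecord("c1", "case01", "roi01", 1.0, 2.0,
                       marker_flags={"CD3": True})
        assert r.flag("CD3") and not r.flag("CD8")


class TestROI:
    def test_default_area(self):
        roi = ROI("r1", "case01")
        assert roi.area_mm2 == pytest.approx(931 * 698 / 1e6)

    def test_compartment_areas_must_fit(self):
        with pytest.raises(IntegrityError):
            ROI("r1", "case01", compartment_areas={"epithelial": 0.5,
                                                   "stroma": 0.2})

    def test_nonpositive_window_rejected(self):
        with pytest.raises(IntegrityError):
            ROI("r1", "case01", width=0.0)


class TestPanelConfig:
    def test_defaults(self):
        cfg = PanelConfig()
        assert cfg.marker_names == MARKERS
        assert cfg.pixel_size == 0.5
        assert cfg.roi_tumor_fraction_min == 0.85

    def test_bad_units(self):
        with pytest.raises(ConfigurationError):
            PanelConfig(coordinate_units="furlong")

    def test_negative_tolerance(self):
        with pytest.raises(ConfigurationError):
            PanelConfig(merge_tolerance=-1)


class TestReadWriteCellTable:
    def test_empty_table_header_only(self, tmp_path, panel):
        p = tmp_path / "empty.csv"
        p.write_text(",".join(["cell_id", "case_id", "roi_id", "x", "y",
                               "compartment", *MARKERS]) + "\n")
        df = read_cell_table(p, panel)
        assert len(df) == 0

    def test_round_trip_three_rows(self, tmp_path, panel):
        cells = make_cells([
            {"x": 1.25, "y": 2.5, "pos": ["CD3", "CD8"]},
            {"x": 10.0, "y": 0.0, "pos": ["panCK"], "compartment": "epithelial"},
            {"x": 930.9, "y": 697.0, "pos": []},
        ])
        p = tmp_path / "cells.csv"
        write_cell_table(cells, p)
        back = read_cell_table(p, panel)
        assert table_to_records(back) == table_to_records(cells)

    def test_pixel_units_converted(self, tmp_path):
        cells = make_cells([{"x": 100.0, "y": 40.0, "pos": []}])
        p = tmp_path / "cells.csv"
        write_cell_table(cells, p)
        df = read_cell_table(p, PanelConfig(coordinate_units="pixel"))
        assert df["x"].iloc[0] == pytest.approx(50.0)
        assert df["y"].iloc[0] == pytest.approx(20.0)

    def test_missing_column_named(self, tmp_path, panel):
        cells = make_cells([{"x": 1, "y": 2}]).drop(columns=["CD8"])
        p = tmp_path / "cells.csv"
        cells.to_csv(p, index=False)
        with pytest.raises(FormatError, match="CD8"):
            read_cell_table(p, panel)

    def test_non_numeric_coordinate_reports_line(self, tmp_path, panel):
        cells = make_cells([{"x": 1, "y": 2}, {"x": 3, "y": 4}])
        cells["x"] = cells["x"].astype(object)
        cells.loc[1, "x"] = "oops"
        p = tmp_path / "cells.csv"
        cells.to_csv(p, index=False)
        with pytest.raises(FormatError, match="line 3"):
            read_cell_table(p, panel)

    def test_duplicate_cell_id(self, tmp_path, panel):
        cells = make_cells([{"cell_id": "dup", "x": 1, "y": 2},
                            {"cell_id": "dup", "x": 3, "y": 4}])
        p = tmp_path / "cells.csv"
        cells.to_csv(p, index=False)
        with pytest.raises(IntegrityError, match="dup"):
            read_cell_table(p, panel)

    def test_missing_file(self, panel, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_cell_table(tmp_path / "nope.csv", panel)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(0, 931, allow_nan=False, width=32),
        st.floats(0, 698, allow_nan=False, width=32),
        st.integers(0, 255)),
        min_size=1, max_size=20))
    def test_round_trip_property(self, rows):
        cells = make_cells([
            {"cell_id": f"c{i}", "x": x, "y": y,
             "pos": [m for b, m in zip(bin(flags)[2:].zfill(8)[::-1], MARKERS)
                     if b == "1"]}
            for i, (x, y, flags) in enumerate(rows)])
        import io as _io
        buf = _io.StringIO()
        cells.to_csv(buf, index=False, float_format="%.10g")
        buf.seek(0)
        back = validate_cell_table(pd.read_csv(buf, dtype={
            "cell_id": str, "case_id": str, "roi_id": str, "compartment": str}))
        assert np.allclose(back[["x", "y"]], cells[["x", "y"]], atol=1e-6)
        assert (back[list(MARKERS)].to_numpy()
                == cells[list(MARKERS)].to_numpy()).all()

    def test_pixel_and_micron_inputs_agree(self, tmp_path):
        # same geometry written in px (at 0.5 µm/px) and in µm
        xs, ys = [10.0, 400.5, 931.0], [5.25, 0.0, 698.0]
        micron = make_cells([{"cell_id": f"m{i}", "x": x, "y": y}
                             for i, (x, y) in enumerate(zip(xs, ys))])
        pixel = make_cells([{"cell_id": f"m{i}", "x": 2 * x, "y": 2 * y}
                            for i, (x, y) in enumerate(zip(xs, ys))])
        p1, p2 = tmp_path / "um.csv", tmp_path / "px.csv"
        micron.to_csv(p1, index=False)
        pixel.to_csv(p2, index=False)
        a = read_cell_table(p1, PanelConfig())
        b = read_cell_table(p2, PanelConfig(coordinate_units="pixel"))
        assert np.allclose(a[["x", "y"]], b[["x", "y"]], atol=1e-6)


def _write_event_table(path, rows, compartment=False):
    cols = ["cell_id", "case_id", "roi_id", "x", "y"]
    if compartment:
        cols.append("compartment")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


class TestReadMarkerTables:
    def test_dapi_only(self, tmp_path, panel):
        p = tmp_path / "dapi.csv"
        _write_event_table(p, [(f"c{i}", "case01", "roi01", i, i, "stroma")
                               for i in range(5)], compartment=True)
        sets = read_marker_tables({"DAPI": p}, panel)
        assert len(sets.spine["roi01"]) == 5
        assert sets.events == {}

    def test_dapi_plus_cd3(self, tmp_path, panel):
        d, c = tmp_path / "dapi.csv", tmp_path / "cd3.csv"
        _write_event_table(d, [(f"c{i}", "case01", "roi01", i, i, "stroma")
                               for i in range(4)], compartment=True)
        _write_event_table(c, [("e0", "case01", "roi01", 0, 0),
                               ("e1", "case01", "roi01", 1, 1)])
        sets = read_marker_tables({"DAPI": d, "CD3": c}, panel)
        assert len(sets.spine["roi01"]) == 4
        assert len(sets.events["CD3"]["roi01"]) == 2

    def test_missing_dapi(self, tmp_path, panel):
        c = tmp_path / "cd3.csv"
        _write_event_table(c, [("e0", "case01", "roi01", 0, 0)])
        with pytest.raises(ConfigurationError, match="DAPI"):
            read_marker_tables({"CD3": c}, panel)

    def test_marker_not_in_panel(self, tmp_path, panel):
        d = tmp_path / "dapi.csv"
        _write_event_table(d, [("c0", "case01", "roi01", 0, 0, "stroma")],
                           compartment=True)
        with pytest.raises(ConfigurationError, match="CD163"):
            read_marker_tables({"DAPI": d, "CD163": d}, panel)

    def test_disjoint_rois_listed(self, tmp_path, panel):
        d, c = tmp_path / "dapi.csv", tmp_path / "cd3.csv"
        _write_event_table(d, [("c0", "case01", "roiA", 0, 0, "stroma")],
                           compartment=True)
        _write_event_table(c, [("e0", "case01", "roiB", 0, 0),
                               ("e1", "case01", "roiC", 1, 1)])
        with pytest.raises(IntegrityError) as exc:
            read_marker_tables({"DAPI": d, "CD3": c}, panel)
        assert "roiB" in str(exc.value) and "roiC" in str(exc.value)


class TestQCROI:
    def _roi(self, n_pos, n_neg):
        rows = [{"x": i, "y": 0, "compartment": "epithelial",
                 "pos": ["panCK"]} for i in range(n_pos)]
        rows += [{"x": i, "y": 10, "compartment": "epithelial"}
                 for i in range(n_neg)]
        return make_cells(rows)

    def test_pass_at_90_percent(self, panel):
        rep = qc_roi(self._roi(90, 10), panel)
        assert rep.passed
        assert rep.panck_fraction == pytest.approx(0.90)

    def test_flag_at_80_percent(self, panel):
        rep = qc_roi(self._roi(80, 20), panel)
        assert not rep.passed
        assert "low_tumor_fraction" in rep.flags

    def test_no_epithelial_compartment(self, panel):
        cells = make_cells([{"x": 1, "y": 1, "compartment": "stroma"}])
        rep = qc_roi(cells, panel)
        assert rep.panck_fraction is None
        assert "no_epithelial_compartment" in rep.flags

    def test_qc_monotone_in_threshold(self, panel):
        cells = self._roi(80, 20)
        strict = qc_roi(cells, PanelConfig(roi_tumor_fraction_min=0.85))
        lax = qc_roi(cells, PanelConfig(roi_tumor_fraction_min=0.5))
        assert not strict.passed and lax.passed


class TestWriteOutputs:
    def _results(self):
        return {
            "density": pd.DataFrame({"phenotype": ["CD3+"], "density": [1.5]}),
            "proximity": pd.DataFrame({"phenotype": ["CD3+"], "d": [10.0]}),
            "gcurves": pd.DataFrame({"r": [0.0, 1.0], "g_emp": [0, 1]}),
            "pattern_calls": pd.DataFrame({"roi_id": ["r1"],
                                           "label": ["mixed"]}),
            "summary": {"n_cells": 2},
        }

    def test_four_tables_plus_summary(self, tmp_path):
        written = write_outputs(self._results(), tmp_path / "out")
        assert sorted(written) == ["density", "gcurves", "pattern_calls",
                                   "proximity", "summary"]
        for p in written.values():
            assert p.exists()

    def test_determinism_byte_identical(self, tmp_path):
        w1 = write_outputs(self._results(), tmp_path / "a")
        w2 = write_outputs(self._results(), tmp_path / "b")
        for k in w1:
            assert w1[k].read_bytes() == w2[k].read_bytes()

    def test_unwritable_path_raises(self, tmp_path):
        blocker = tmp_path / "blocker"
        blocker.write_text("")  # out_dir collides with an existing file
        with pytest.raises(OSError):
            write_outputs(self._results(), blocker)

    @pytest.mark.skipif(os.geteuid() == 0, reason="root ignores permissions")
    def test_readonly_dir_raises(self, tmp_path):
        ro = tmp_path / "ro"
        ro.mkdir()
        os.chmod(ro, 0o500)
        try:
            with pytest.raises(OSError):
                write_outputs(self._results(), ro)
        finally:
            os.chmod(ro, 0o700)


class TestRunPipeline:
    def test_mixed_demo_completes(self, tmp_path):
        from mifscape.pipeline import run_pipeline
        res = run_pipeline({"input": {"preset": "mixed_demo"},
                            "simulation": {"rois_per_case": 1}},
                           seed=7, out_dir=tmp_path / "out")
        assert len(res["pattern_calls"]) > 0
        assert (tmp_path / "out" / "run_summary.json").exists()

    def test_missing_input_and_preset(self):
        from mifscape.pipeline import run_pipeline
        with pytest.raises(ConfigurationError):
            run_pipeline({"input": {}})

    def test_rerun_same_seed_identical_calls(self):
        from mifscape.pipeline import run_pipeline
        cfg = {"input": {"preset": "unmixed_demo"},
               "simulation": {"rois_per_case": 1}}
        a = run_pipeline(cfg, seed=3)
        b = run_pipeline(cfg, seed=3)
        pd.testing.assert_frame_equal(a["pattern_calls"], b["pattern_calls"])
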