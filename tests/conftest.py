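import numpy as np
import pandas as pd
import pytest

from mifscape.datamodel import MARKERS, PanelConfig, table_columns


def make_cells(rows, markers=MARKERS):
    """Build a cell table from compact row dicts.

    Each row: dict with x, y and optional cell_id/case_id/roi_id/compartment
    plus a 'pos' list of positive markers.
    """
    out = []
    for i, r in enumerate(rows):
        rec = {
            "cell_id": r.get("cell_id", f"c{i:04d}"),
            "case_id": r.get("case_id", "case01"),
            "roi_id": r.get("roi_id", "roi01"),
            "x": float(r["x"]),
            "y": float(r["y"]),
            "compartment": r.get("compartment", "stroma"),
        }
        pos = set(r.get("pos", []))
        for m in markers:
            rec[m] = int(m in pos)
        out.append(rec)
    return pd.DataFrame(out, columns=table_columns(markers))


@pytest.fixture
def cells_factory():
    return make_cells


@pytest.fixture
def panel():
    return PanelConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
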