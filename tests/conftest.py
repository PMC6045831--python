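"""Shared fixtures: small scans, simple segmentations, a default study."""

from __future__ import annotations

import numpy as np
import pytest

from onhrel.bscan import BScan
from onhrel.pipeline import StudyConfig, run_study
from onhrel.segmentation import BoundarySegment, ControlPoint, ScanSegmentation
from onhrel.synthetic import generate_study


def make_segment(label: str, cols, rows) -> BoundarySegment:
    return BoundarySegment(
        label=label,
        points=tuple(ControlPoint(col=float(c), row=float(r)) for c, r in zip(cols, rows)),
    )


def make_segmentation(
    scan: BScan,
    ilm_row,
    bm_row,
    gap_cols: tuple[float, float] | None = None,
    n_pts: int = 13,
    rater_id: str = "r1",
    session_id: str = "1",
) -> ScanSegmentation:
    """Build a segmentation whose boundaries follow callables or constants.

    ``ilm_row`` / ``bm_row`` are either constants or callables of the
    column index returning a row.  The BM gap spans ``gap_cols``
    (defaults to the middle third of the scan).
    """
    c_max = scan.n_cols - 1
    if gap_cols is None:
        gap_cols = (c_max / 3.0, 2 * c_max / 3.0)

    def rows_for(fn, cols):
        if callable(fn):
            return [fn(c) for c in cols]
        return [fn] * len(cols)

    ilm_cols = np.linspace(0, c_max, n_pts)
    left_cols = np.linspace(0, gap_cols[0], max(3, n_pts // 3))
    right_cols = np.linspace(gap_cols[1], c_max, max(3, n_pts // 3))
    return ScanSegmentation(
        scan_id=scan.scan_id,
        rater_id=rater_id,
        session_id=session_id,
        ilm=make_segment("ILM", ilm_cols, rows_for(ilm_row, ilm_cols)),
        bm_left=make_segment("BM_left", left_cols, rows_for(bm_row, left_cols)),
        bm_right=make_segment("BM_right", right_cols, rows_for(bm_row, right_cols)),
    )


@pytest.fixture
def small_scan() -> BScan:
    """An 80 x 120 scan with non-square pixels (axial 4, lateral 10 um/px)."""
    return BScan(
        scan_id="scanA",
        subject_id="subj01",
        eye="OD",
        device="devA",
        protocol="radial",
        pixels=np.zeros((80, 120), dtype=np.uint8),
        axial_scale=4.0,
        lateral_scale=10.0,
    )


@pytest.fixture
def wide_scan() -> BScan:
    """A scan wide enough for the full 5.7 mm area window (600 cols x 10 um)."""
    return BScan(
        scan_id="scanW",
        subject_id="subj01",
        eye="OD",
        device="devA",
        protocol="radial",
        pixels=np.zeros((200, 600), dtype=np.uint8),
        axial_scale=4.0,
        lateral_scale=10.0,
    )


@pytest.fixture(scope="session")
def default_study_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    return generate_study(out, seed=0)


@pytest.fixture(scope="session")
def default_report(default_study_manifest):
    return run_study(StudyConfig(manifest=default_study_manifest))
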