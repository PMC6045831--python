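"""Control-point boundary model and curve-fit interpolation.

Semi-manual OCT segmentation is represented as ordered control points
placed by a rater along each anatomical boundary: the inner limiting
membrane (ILM) and the temporal and nasal wings of Bruch's membrane
(BM).  A shape-preserving piecewise-cubic (monotone Hermite / PCHIP)
interpolant connects the control points.  PCHIP is used because a
rater-adjusted anatomical boundary must pass through every placed point
without ringing between sparse points; an unconstrained cubic spline can
overshoot badly where control points are far apart.

Boundaries are single-valued curves in the lateral coordinate: control
point columns are strictly increasing, and two points at the same column
are an error, never a silent merge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .bscan import BScan

__all__ = [
    "ControlPoint",
    "BoundarySegment",
    "ScanSegmentation",
    "SampledBoundary",
    "fit_boundary",
    "resample_boundary",
    "edit_control_point",
    "save_segmentation",
    "load_segmentation",
    "SEGMENT_LABELS",
]

SEGMENT_LABELS = ("ILM", "BM_left", "BM_right")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ControlPoint:
    """A rater-placed point in pixel coordinates (fractional allowed)."""

    col: float
    row: float


@dataclass(frozen=True)
class BoundarySegment:
    """One boundary's ordered control points.

    ``label`` is one of :data:`SEGMENT_LABELS`.  Columns are strictly
    increasing so the boundary is a single-valued curve of the lateral
    coordinate.
    """

    label: str
    points: tuple[ControlPoint, ...]

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"label must be one of {SEGMENT_LABELS}, got {self.label!r}")
        pts = tuple(self.points)
        if len(pts) < 2:
            raise ValueError(f"{self.label}: a boundary needs >= 2 control points")
        cols = np.array([p.col for p in pts], dtype=float)
        if not np.all(np.diff(cols) > 0):
            raise ValueError(
                f"{self.label}: control point columns must be strictly increasing"
            )
        object.__setattr__(self, "points", pts)

    @property
    def cols(self) -> np.ndarray:
        return np.array([p.col for p in self.points], dtype=float)

    @property
    def rows(self) -> np.ndarray:
        return np.array([p.row for p in self.points], dtype=float)

    @property
    def min_col(self) -> float:
        return self.points[0].col

    @property
    def max_col(self) -> float:
        return self.points[-1].col


@dataclass(frozen=True)
class ScanSegmentation:
    """One rater's single-session delineation of ILM and BM on one scan.

    The two BM wings must not overlap laterally; the gap between their
    medial endpoints is the shadowed sub-nerve region that is later
    bridged with a straight line.  The ILM's lateral support must cover
    the union of both BM supports so the area integrand is defined
    everywhere the BM is.
    """

    scan_id: str
    rater_id: str
    session_id: str
    ilm: BoundarySegment
    bm_left: BoundarySegment
    bm_right: BoundarySegment

    def __post_init__(self) -> None:
        if self.ilm.label != "ILM":
            raise ValueError(f"ilm segment must be labelled ILM, got {self.ilm.label!r}")
        if self.bm_left.label != "BM_left" or self.bm_right.label != "BM_right":
            raise ValueError("bm segments must be labelled BM_left / BM_right")
        if not self.bm_left.max_col < self.bm_right.min_col:
            raise ValueError(
                "BM wings overlap: left wing ends at col "
                f"{self.bm_left.max_col}, right wing starts at {self.bm_right.min_col}"
            )
        lo = min(self.bm_left.min_col, self.bm_right.min_col)
        hi = max(self.bm_left.max_col, self.bm_right.max_col)
        if self.ilm.min_col > lo or self.ilm.max_col < hi:
            raise ValueError(
                "ILM lateral support must cover the union of the BM supports: "
                f"ILM [{self.ilm.min_col}, {self.ilm.max_col}] vs BM [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class SampledBoundary:
    """A boundary resampled on a uniform lateral grid, both axes in um."""

    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
            raise ValueError("xs and ys must be equal-length 1-D arrays with >= 2 samples")
        steps = np.diff(xs)
        if not np.all(steps > 0):
            raise ValueError("xs must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("xs must be a uniform grid")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    @property
    def step(self) -> float:
        return float(self.xs[1] - self.xs[0])


def _interpolator(segment: BoundarySegment) -> PchipInterpolator:
    return PchipInterpolator(segment.cols, segment.rows, extrapolate=False)


def fit_boundary(segment: BoundarySegment, xs: Sequence[float] | np.ndarray) -> np.ndarray:
    """Evaluate the fitted boundary curve at lateral pixel positions ``xs``.

    The curve is a monotone piecewise-cubic Hermite interpolant through
    the control points.  It reproduces every control point exactly
    (values at control abscissae are snapped to the control ordinates,
    making the interpolation property bit-exact), is continuous and
    single-valued, and between consecutive control points with monotone
    ordinates never leaves the range spanned by those two ordinates.

    Raises
    ------
    ValueError
        If any abscissa lies outside the control-point span.
    """
    xs = np.asarray(xs, dtype=float)
    cols = segment.cols
    if xs.size and (xs.min() < cols[0] or xs.max() > cols[-1]):
        raise ValueError(
            f"{segment.label}: abscissae outside control span "
            f"[{cols[0]}, {cols[-1]}]: [{xs.min()}, {xs.max()}]"
        )
    ys = _interpolator(segment)(xs)
    # exact reproduction of control points, independent of cubic round-off
    rows = segment.rows
    idx = np.searchsorted(cols, xs)
    idx = np.clip(idx, 0, cols.size - 1)
    hit = cols[idx] == xs
    ys[hit] = rows[idx[hit]]
    return ys


def resample_boundary(segment: BoundarySegment, scan: BScan, step: float) -> SampledBoundary:
    """Resample a fitted boundary on a uniform micrometre grid.

    The grid starts at the segment's left support edge and advances by
    ``step`` um while remaining inside the support; ordinates are
    converted to depth in um via the scan's axial scale.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    x0_um = segment.min_col * scan.lateral_scale
    x1_um = segment.max_col * scan.lateral_scale
    width = x1_um - x0_um
    if step > width:
        raise ValueError(f"step {step} um exceeds lateral support width {width} um")
    n = int(np.floor(width / step + 1e-9)) + 1
    xs_um = x0_um + step * np.arange(n)
    rows = fit_boundary(segment, xs_um / scan.lateral_scale)
    return SampledBoundary(xs=xs_um, ys=rows * scan.axial_scale)


def edit_control_point(
    seg: BoundarySegment,
    action: str,
    point: ControlPoint | None = None,
    index: int | None = None,
) -> BoundarySegment:
    """Return a new segment with one control point added, removed or moved.

    ``add`` requires ``point``; ``remove`` requires ``index``; ``move``
    requires both (the point at ``index`` is replaced).  Any edit that
    would break the strict column ordering or leave fewer than two
    points raises, mirroring what a segmentation tool must forbid.
    """
    pts = list(seg.points)
    if action == "add":
        if point is None:
            raise ValueError("add requires a point")
        pts.append(point)
        pts.sort(key=lambda p: p.col)
    elif action == "remove":
        if index is None:
            raise ValueError("remove requires an index")
        if len(pts) - 1 < 2:
            raise ValueError("removal would leave fewer than 2 control points")
        del pts[index]
    elif action == "move":
        if point is None or index is None:
            raise ValueError("move requires an index and a point")
        pts[index] = point
        pts.sort(key=lambda p: p.col)
    else:
        raise ValueError(f"unknown action {action!r}")
    return replace(seg, points=tuple(pts))


def _segment_to_json(seg: BoundarySegment) -> dict:
    return {"label": seg.label, "points": [[p.col, p.row] for p in seg.points]}


def _segment_from_json(obj: dict) -> BoundarySegment:
    pts = tuple(ControlPoint(col=float(c), row=float(r)) for c, r in obj["points"])
    return BoundarySegment(label=obj["label"], points=pts)


def save_segmentation(seg: ScanSegmentation, path: Path | str) -> None:
    """Serialize a segmentation to versioned JSON (deterministic bytes)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "scan_id": seg.scan_id,
        "rater_id": seg.rater_id,
        "session_id": seg.session_id,
        "segments": [
            _segment_to_json(seg.ilm),
            _segment_to_json(seg.bm_left),
            _segment_to_json(seg.bm_right),
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ": "), indent=1) + "\n")


def load_segmentation(path: Path | str) -> ScanSegmentation:
    """Load a segmentation JSON file, validating all structural invariants."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported segmentation schema version {doc.get('schema_version')!r}"
        )
    by_label = {}
    for obj in doc["segments"]:
        if obj["label"] in by_label:
            raise ValueError(f"duplicate segment label {obj['label']!r}")
        by_label[obj["label"]] = _segment_from_json(obj)
    missing = [lab for lab in SEGMENT_LABELS if lab not in by_label]
    if missing:
        raise ValueError(f"segmentation file missing segments: {missing}")
    return ScanSegmentation(
        scan_id=str(doc["scan_id"]),
        rater_id=str(doc["rater_id"]),
        session_id=str(doc["session_id"]),
        ilm=by_label["ILM"],
        bm_left=by_label["BM_left"],
        bm_right=by_label["BM_right"],
    )
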