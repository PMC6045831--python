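"""End-to-end reliability study orchestration.

Given a manifest of B-scans and segmentations (real, converted, or
synthetic), the pipeline computes per-segmentation cross-sectional
areas, pairwise axial segmentation differences, limits of agreement with
outlier flags, ICC blocks per comparison type, and Bland-Altman
summaries, and writes them as plot-ready CSV/JSON tables.

Manifest CSV schema (one row per segmentation)::

    scan_id, subject_id, eye_id, eye, device, protocol, rater_id,
    session_id, quality, scan_path, seg_path

Paths are relative to the manifest's directory.  Rows with ``quality``
other than ``"pass"`` are excluded (with a log record): quality
exclusion is data-driven, since the vendor signal indices behind it are
not computed here.  Summaries are always stratified by scan protocol;
scans acquired with different protocols are never compared, and
inter-device comparisons are computed for the radial protocol only,
because line-scan positioning varies too much between devices for the
same cross-section to be measured.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bscan import BScan, read_bscan
from .metrics import (
    DEFAULT_HALF_WIDTH_MM,
    DEFAULT_STEP_UM,
    cross_sectional_area,
    segmentation_difference,
)
from .reliability import (
    LoaSummary,
    MeasurementTable,
    bland_altman,
    flag_outliers,
    icc_two_way_random,
    limits_of_agreement,
)
from .segmentation import ScanSegmentation, load_segmentation

__all__ = ["StudyConfig", "StudyReport", "run_study", "validate_manifest", "write_report"]

logger = logging.getLogger("onhrel.pipeline")

MANIFEST_COLUMNS = (
    "scan_id",
    "subject_id",
    "eye_id",
    "eye",
    "device",
    "protocol",
    "rater_id",
    "session_id",
    "quality",
    "scan_path",
    "seg_path",
)

COMPARISONS = ("intra_rater", "inter_rater", "inter_device")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one reliability-study run."""

    manifest: Path
    half_width_mm: float = DEFAULT_HALF_WIDTH_MM
    step_um: float = DEFAULT_STEP_UM
    out_dir: Path | None = None
    raters: tuple[str, ...] | None = None  # restrict the comparison plan
    devices: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.half_width_mm <= 0:
            raise ValueError("half_width_mm must be positive")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        object.__setattr__(self, "manifest", Path(self.manifest))
        if self.out_dir is not None:
            object.__setattr__(self, "out_dir", Path(self.out_dir))


@dataclass
class StudyReport:
    """All summary surfaces of one study run."""

    areas: pd.DataFrame
    differences: pd.DataFrame
    area_differences: pd.DataFrame
    loa: pd.DataFrame
    icc: dict
    bland_altman: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def max_area_diff(self, comparison: str) -> float:
        """Maximum absolute area difference (mm^2) for a comparison type."""
        sub = self.area_differences[self.area_differences["comparison"] == comparison]
        if sub.empty:
            raise ValueError(f"no area differences for comparison {comparison!r}")
        return float(sub["abs_area_diff_mm2"].max())

    def icc_values(self, comparison: str) -> list[float]:
        """All defined per-stratum ICC values for a comparison type."""
        out = []
        for block in self.icc.get(comparison, []):
            if block.get("icc") is not None:
                out.append(block["icc"])
        return out


def validate_manifest(path: Path | str) -> list[str]:
    """Check a manifest for missing files, duplicate keys, quality flags."""
    path = Path(path)
    df = pd.read_csv(path)
    issues: list[str] = []
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        return [f"manifest missing columns: {missing_cols}"]
    root = path.parent
    for col in ("scan_path", "seg_path"):
        for p in df[col].unique():
            if not (root / p).exists():
                issues.append(f"missing file: {p}")
    keys = df[["scan_id", "rater_id", "session_id"]].astype(str).agg("|".join, axis=1)
    for dup in sorted(keys[keys.duplicated()].unique()):
        issues.append(f"duplicate key: {dup}")
    for _, row in df[df["quality"] != "pass"].iterrows():
        issues.append(
            f"quality-flagged scan: {row['scan_id']} ({row['rater_id']} s{row['session_id']}): "
            f"{row['quality']}"
        )
    return issues


def _load_inputs(
    df: pd.DataFrame, root: Path
) -> tuple[dict[str, BScan], dict[tuple[str, str, str], ScanSegmentation]]:
    scans: dict[str, BScan] = {}
    segs: dict[tuple[str, str, str], ScanSegmentation] = {}
    for _, row in df.iterrows():
        sid = row["scan_id"]
        if sid not in scans:
            scans[sid] = read_bscan(root / row["scan_path"])
        key = (sid, str(row["rater_id"]), str(row["session_id"]))
        segs[key] = load_segmentation(root / row["seg_path"])
    return scans, segs


def _icc_block(
    long: pd.DataFrame, value_col: str, subject_col: str, measurer_col: str
) -> dict:
    """Pivot a long frame to a table and compute ICC(A,1).

    Subjects with any missing cell (e.g. a quality-excluded segmentation)
    are dropped: complete-case analysis, with the count noted.
    """
    wide = long.pivot_table(index=subject_col, columns=measurer_col, values=value_col)
    complete = wide.dropna()
    note = ""
    if len(complete) < len(wide):
        note = f"dropped {len(wide) - len(complete)} incomplete subject(s); "
    if len(complete) < 2:
        return {
            "icc": None,
            "n": len(complete),
            "k": wide.shape[1],
            "note": note + "fewer than 2 complete subjects",
        }
    table = MeasurementTable(
        subjects=tuple(str(s) for s in complete.index),
        measurers=tuple(str(m) for m in complete.columns),
        values=complete.to_numpy(),
    )
    try:
        return {"icc": icc_two_way_random(table), "n": table.n, "k": table.k, "note": note}
    except ValueError as exc:  # zero-variance stratum: undefined, reported as such
        return {"icc": None, "n": table.n, "k": table.k, "note": note + str(exc)}


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full reliability analysis described by ``config``.

    Deterministic given fixed inputs.  Raises on missing files or
    incomplete measurement tables; excluded (quality-flagged) scans are
    logged and reported in the returned :class:`StudyReport`.
    """
    df = pd.read_csv(config.manifest)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    df["session_id"] = df["session_id"].astype(str)
    df["rater_id"] = df["rater_id"].astype(str)

    excluded = []
    bad = df["quality"] != "pass"
    for _, row in df[bad].iterrows():
        msg = f"excluded scan {row['scan_id']} ({row['rater_id']} s{row['session_id']}): quality={row['quality']}"
        logger.info(msg)
        excluded.append(msg)
    df = df[~bad].copy()
    if config.raters is not None:
        df = df[df["rater_id"].isin(config.raters)]
    if config.devices is not None:
        df = df[df["device"].isin(config.devices)]
    if df.empty:
        raise ValueError("no usable manifest rows after exclusions and plan filtering")

    scans, segs = _load_inputs(df, config.manifest.parent)

    # ------------------------------------------------------------------ areas
    area_rows = []
    for _, row in df.iterrows():
        key = (row["scan_id"], row["rater_id"], row["session_id"])
        res = cross_sectional_area(
            segs[key], scans[row["scan_id"]],
            half_width=config.half_width_mm, step=config.step_um,
        )
        area_rows.append(
            {
                "scan_id": row["scan_id"],
                "eye_id": row["eye_id"],
                "device": row["device"],
                "protocol": row["protocol"],
                "rater_id": row["rater_id"],
                "session_id": row["session_id"],
                "area_mm2": res.area,
            }
        )
    areas = pd.DataFrame(area_rows)

    # ------------------------------------------- pairwise segmentation diffs
    scan_meta = df.drop_duplicates("scan_id").set_index("scan_id")
    diff_rows = []
    for scan_id, group in df.groupby("scan_id"):
        scan = scans[scan_id]
        # intra-rater: session pairs within each rater
        for rater_id, g in group.groupby("rater_id"):
            sess = sorted(g["session_id"].unique())
            for s1, s2 in itertools.combinations(sess, 2):
                for label in ("ILM", "BM"):
                    d = segmentation_difference(
                        segs[(scan_id, rater_id, s1)], segs[(scan_id, rater_id, s2)],
                        label, scan, step=config.step_um, comparison="intra_rater",
                    )
                    diff_rows.append(
                        {
                            "scan_id": scan_id,
                            "protocol": scan_meta.loc[scan_id, "protocol"],
                            "comparison": "intra_rater",
                            "segment_label": label,
                            "a": f"{rater_id}/s{s1}",
                            "b": f"{rater_id}/s{s2}",
                            "mean_abs_diff_um": d.mean_abs_diff_um,
                            "mean_abs_diff_px": d.mean_abs_diff_px,
                        }
                    )
        # inter-rater: rater pairs at first session (raters whose first-session
        # segmentation survived quality exclusion)
        raters_here = sorted(group.loc[group["session_id"] == "1", "rater_id"].unique())
        for r1, r2 in itertools.combinations(raters_here, 2):
            for label in ("ILM", "BM"):
                d = segmentation_difference(
                    segs[(scan_id, r1, "1")], segs[(scan_id, r2, "1")],
                    label, scan, step=config.step_um, comparison="inter_rater",
                )
                diff_rows.append(
                    {
                        "scan_id": scan_id,
                        "protocol": scan_meta.loc[scan_id, "protocol"],
                        "comparison": "inter_rater",
                        "segment_label": label,
                        "a": r1,
                        "b": r2,
                        "mean_abs_diff_um": d.mean_abs_diff_um,
                        "mean_abs_diff_px": d.mean_abs_diff_px,
                    }
                )
    differences = pd.DataFrame(diff_rows)

    # ------------------------------------------------------ area differences
    adiff_rows = []
    base = areas.copy()
    # intra-rater: session pairs on the same scan
    for (scan_id, rater_id), g in base.groupby(["scan_id", "rater_id"]):
        g = g.sort_values("session_id")
        for (_, a), (_, b) in itertools.combinations(g.iterrows(), 2):
            adiff_rows.append(
                {
                    "comparison": "intra_rater",
                    "protocol": a["protocol"],
                    "eye_id": a["eye_id"],
                    "stratum": a["device"],
                    "a": f"{rater_id}/s{a['session_id']}",
                    "b": f"{rater_id}/s{b['session_id']}",
                    "area_a_mm2": a["area_mm2"],
                    "area_b_mm2": b["area_mm2"],
                    "area_diff_mm2": a["area_mm2"] - b["area_mm2"],
                    "abs_area_diff_mm2": abs(a["area_mm2"] - b["area_mm2"]),
                }
            )
    s1 = base[base["session_id"] == "1"]
    # inter-rater: rater pairs on the same scan (first session)
    for scan_id, g in s1.groupby("scan_id"):
        g = g.sort_values("rater_id")
        for (_, a), (_, b) in itertools.combinations(g.iterrows(), 2):
            adiff_rows.append(
                {
                    "comparison": "inter_rater",
                    "protocol": a["protocol"],
                    "eye_id": a["eye_id"],
                    "stratum": a["device"],
                    "a": a["rater_id"],
                    "b": b["rater_id"],
                    "area_a_mm2": a["area_mm2"],
                    "area_b_mm2": b["area_mm2"],
                    "area_diff_mm2": a["area_mm2"] - b["area_mm2"],
                    "abs_area_diff_mm2": abs(a["area_mm2"] - b["area_mm2"]),
                }
            )
    # inter-device: device pairs for the same eye and rater, radial protocol only
    radial = s1[s1["protocol"] == "radial"]
    for (eye_id, rater_id), g in radial.groupby(["eye_id", "rater_id"]):
        g = g.sort_values("device")
        for (_, a), (_, b) in itertools.combinations(g.iterrows(), 2):
            adiff_rows.append(
                {
                    "comparison": "inter_device",
                    "protocol": "radial",
                    "eye_id": eye_id,
                    "stratum": rater_id,
                    "a": a["device"],
                    "b": b["device"],
                    "area_a_mm2": a["area_mm2"],
                    "area_b_mm2": b["area_mm2"],
                    "area_diff_mm2": a["area_mm2"] - b["area_mm2"],
                    "abs_area_diff_mm2": abs(a["area_mm2"] - b["area_mm2"]),
                }
            )
    area_differences = pd.DataFrame(adiff_rows)

    # --------------------------------------------------- LoA and outlier flags
    loa_rows = []
    if not differences.empty:
        for (proto, comp, label), g in differences.groupby(
            ["protocol", "comparison", "segment_label"]
        ):
            vals = g["mean_abs_diff_um"].to_numpy()
            if vals.size < 2:
                continue
            loa = limits_of_agreement(vals, unit="um")
            flagged = sorted(g.loc[g["mean_abs_diff_um"] > loa.upper, "scan_id"].unique())
            loa_rows.append(
                {
                    "protocol": proto,
                    "comparison": comp,
                    "segment_label": label,
                    "n": loa.n,
                    "mean_um": loa.mean,
                    "sd_um": loa.sd,
                    "lower_um": loa.lower,
                    "upper_um": loa.upper,
                    "n_outliers": len(flagged),
                    "outlier_scan_ids": ";".join(flagged),
                }
            )
    loa_df = pd.DataFrame(loa_rows)

    # ---------------------------------------------------------------- ICC
    icc: dict[str, list[dict]] = {c: [] for c in COMPARISONS}
    for proto, g in areas.groupby("protocol"):
        # intra-rater: eyes x sessions, per device, for raters with >= 2 sessions
        for (device, rater_id), gg in g.groupby(["device", "rater_id"]):
            if gg["session_id"].nunique() < 2:
                continue
            block = _icc_block(gg, "area_mm2", "eye_id", "session_id")
            block.update(protocol=proto, stratum=f"{device}/{rater_id}")
            icc["intra_rater"].append(block)
        # inter-rater: eyes x raters at first session, per device
        gs1 = g[g["session_id"] == "1"]
        for device, gg in gs1.groupby("device"):
            if gg["rater_id"].nunique() < 2:
                continue
            block = _icc_block(gg, "area_mm2", "eye_id", "rater_id")
            block.update(protocol=proto, stratum=device)
            icc["inter_rater"].append(block)
        # inter-device: eyes x devices per rater, radial only
        if proto == "radial":
            for rater_id, gg in gs1.groupby("rater_id"):
                if gg["device"].nunique() < 2:
                    continue
                block = _icc_block(gg, "area_mm2", "eye_id", "device")
                block.update(protocol=proto, stratum=rater_id)
                icc["inter_device"].append(block)

    # --------------------------------------------------------- Bland-Altman
    ba_rows = []
    if not area_differences.empty:
        for (comp, proto, stratum, a_id, b_id), g in area_differences.groupby(
            ["comparison", "protocol", "stratum", "a", "b"]
        ):
            if len(g) < 2:
                continue
            g = g.sort_values("eye_id")
            ba = bland_altman(
                g["area_a_mm2"].to_numpy(), g["area_b_mm2"].to_numpy(), unit="mm2"
            )
            ba_rows.append(
                {
                    "comparison": comp,
                    "protocol": proto,
                    "stratum": stratum,
                    "a": a_id,
                    "b": b_id,
                    "n": len(g),
                    "bias_mm2": ba.bias,
                    "loa_lower_mm2": ba.loa.lower,
                    "loa_upper_mm2": ba.loa.upper,
                    "ci_bias_lo": ba.ci_bias[0],
                    "ci_bias_hi": ba.ci_bias[1],
                    "ci_loa_lower_lo": ba.ci_lower_loa[0],
                    "ci_loa_lower_hi": ba.ci_lower_loa[1],
                    "ci_loa_upper_lo": ba.ci_upper_loa[0],
                    "ci_loa_upper_hi": ba.ci_upper_loa[1],
                }
            )
    bland_altman_df = pd.DataFrame(ba_rows)

    report = StudyReport(
        areas=areas,
        differences=differences,
        area_differences=area_differences,
        loa=loa_df,
        icc=icc,
        bland_altman=bland_altman_df,
        excluded=excluded,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: StudyReport, out_dir: Path | str) -> None:
    """Write all report tables as CSV/JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.areas.to_csv(out / "areas.csv", index=False, lineterminator="\n")
    report.differences.to_csv(out / "differences.csv", index=False, lineterminator="\n")
    report.area_differences.to_csv(
        out / "area_differences.csv", index=False, lineterminator="\n"
    )
    report.loa.to_csv(out / "loa.csv", index=False, lineterminator="\n")
    report.bland_altman.to_csv(out / "bland_altman.csv", index=False, lineterminator="\n")
    (out / "icc.json").write_text(json.dumps(report.icc, indent=2, sort_keys=True) + "\n")
    if report.excluded:
        (out / "exclusions.log").write_text("\n".join(report.excluded) + "\n")
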