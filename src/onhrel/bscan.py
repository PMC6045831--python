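"""Device-agnostic OCT B-scan container and interchange-format I/O.

A B-scan is a 2-D grayscale intensity grid together with the physical
per-pixel scaling needed to express positions in micrometres.  Scans are
exchanged as an 8- or 16-bit grayscale PNG/TIFF plus a JSON metadata
sidecar carrying identifiers and the axial/lateral scaling factors.
Vendor raw formats are not parsed; conversion to this interchange format
is assumed to happen upstream.

Coordinate convention: 0-based pixel indices; the axial (row) coordinate
increases downward, i.e. deeper into tissue; the lateral (column)
coordinate increases left to right.  The physical origin sits at the
centre of pixel (0, 0).  Only coordinate differences enter downstream
area and difference formulas, so the origin choice is observationally
irrelevant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "BScan",
    "PointUm",
    "read_bscan",
    "write_bscan",
    "pixel_to_um",
    "sidecar_path",
]

_VALID_EYES = frozenset({"OD", "OS"})
_VALID_PROTOCOLS = frozenset({"line", "radial"})

#: JSON sidecar keys, in canonical (sorted) write order.
SIDECAR_KEYS = (
    "axial_scale_um",
    "device",
    "eye",
    "lateral_scale_um",
    "protocol",
    "scan_id",
    "subject_id",
)


@dataclass(frozen=True)
class PointUm:
    """A physical position on a B-scan, in micrometres.

    ``x`` is measured from the left edge of the scan, ``y`` from the top
    of the image (depth; larger values are deeper in tissue).
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"PointUm coordinates must be non-negative, got {self}")


@dataclass(frozen=True)
class BScan:
    """One cross-sectional OCT image with physical scaling metadata.

    Parameters
    ----------
    scan_id, subject_id
        Opaque identifier strings.
    eye
        Laterality tag, ``"OD"`` or ``"OS"``.
    device
        Acquisition device label.
    protocol
        Scan protocol tag, ``"line"`` or ``"radial"``.
    pixels
        2-D intensity grid; rows index axial depth, columns lateral
        position.  Stored as ``uint8`` or ``uint16``.
    axial_scale, lateral_scale
        Micrometres per pixel, axial (rows) and lateral (columns).
        Image-specific: there is no meaningful default, so both are
        required and must be positive.
    """

    scan_id: str
    subject_id: str
    eye: str
    device: str
    protocol: str
    pixels: np.ndarray = field(repr=False)
    axial_scale: float
    lateral_scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(
                f"pixels must be a 2-D grid with >= 2 rows and columns, got shape {px.shape}"
            )
        if px.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"pixels must be uint8 or uint16, got {px.dtype}")
        if not (self.axial_scale > 0 and self.lateral_scale > 0):
            raise ValueError(
                "scaling factors must be positive "
                f"(axial={self.axial_scale}, lateral={self.lateral_scale})"
            )
        if self.eye not in _VALID_EYES:
            raise ValueError(f"eye must be one of {sorted(_VALID_EYES)}, got {self.eye!r}")
        if self.protocol not in _VALID_PROTOCOLS:
            raise ValueError(
                f"protocol must be one of {sorted(_VALID_PROTOCOLS)}, got {self.protocol!r}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def width_um(self) -> float:
        """Lateral physical width, (cols - 1) * lateral_scale."""
        return (self.n_cols - 1) * self.lateral_scale

    @property
    def depth_um(self) -> float:
        """Axial physical depth, (rows - 1) * axial_scale."""
        return (self.n_rows - 1) * self.axial_scale

    @property
    def center_x_um(self) -> float:
        """Lateral midpoint of the scan in micrometres."""
        return self.width_um / 2.0


def sidecar_path(image_path: Path | str) -> Path:
    """Path of the JSON metadata sidecar next to an image file."""
    p = Path(image_path)
    return p.with_suffix(".json")


def pixel_to_um(col: float, row: float, scan: BScan) -> PointUm:
    """Convert pixel indices to physical micrometres using the scan's scales.

    Fractional indices are allowed (sub-pixel positions); indices must
    lie within the image grid.
    """
    if not (0 <= col < scan.n_cols) or not (0 <= row < scan.n_rows):
        raise ValueError(
            f"pixel index (col={col}, row={row}) outside grid "
            f"{scan.n_rows}x{scan.n_cols}"
        )
    return PointUm(x=col * scan.lateral_scale, y=row * scan.axial_scale)


def write_bscan(scan: BScan, path: Path | str) -> None:
    """Write a B-scan as a grayscale image plus JSON sidecar.

    The sidecar is written with sorted keys and fixed separators so two
    writes of the same scan are byte-identical.
    """
    path = Path(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError(f"interchange image must be PNG or TIFF, got {path.suffix!r}")
    Image.fromarray(scan.pixels).save(path)
    meta = {
        "scan_id": scan.scan_id,
        "subject_id": scan.subject_id,
        "eye": scan.eye,
        "device": scan.device,
        "protocol": scan.protocol,
        "axial_scale_um": scan.axial_scale,
        "lateral_scale_um": scan.lateral_scale,
    }
    sidecar_path(path).write_text(
        json.dumps(meta, sort_keys=True, separators=(",", ": "), indent=2) + "\n"
    )


def read_bscan(path: Path | str) -> BScan:
    """Read a B-scan from an image file and its JSON metadata sidecar.

    Missing or invalid scaling metadata is an error, never a default:
    scale factors are image specific and silently assuming one would
    corrupt every micrometre quantity downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sc}")
    meta = json.loads(sc.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sc} missing required keys: {missing}")
    img = Image.open(path)
    px = np.asarray(img)
    if px.dtype == np.int32:  # PIL loads 16-bit PNG as mode I
        px = px.astype(np.uint16)
    axial = float(meta["axial_scale_um"])
    lateral = float(meta["lateral_scale_um"])
    if not (axial > 0 and lateral > 0):
        raise ValueError(
            f"sidecar {sc} declares non-positive scale (axial={axial}, lateral={lateral})"
        )
    return BScan(
        scan_id=str(meta["scan_id"]),
        subject_id=str(meta["subject_id"]),
        eye=str(meta["eye"]),
        device=str(meta["device"]),
        protocol=str(meta["protocol"]),
        pixels=px,
        axial_scale=axial,
        lateral_scale=lateral,
    )
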