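"""DICOM slice input and overlay/report output.

A CT slice is represented as a pair of 2-D matrices: the raw stored pixel
values straight from the DICOM PixelData, and the Hounsfield-unit (HU)
matrix obtained through the modality rescale transform

    hu = raw * RescaleSlope + RescaleIntercept

HU values are kept as floats after rescaling; no re-quantisation is applied,
so threshold comparisons in downstream classification are free of integer
rounding artefacts.

Coordinates are 0-based ``(row, col)`` with row 0 at the top of the image,
matching matrix indexing everywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import pydicom
from PIL import Image, ImageDraw

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import FibrosisResult
    from .segmentation import SnakeResult

log = logging.getLogger(__name__)

__all__ = [
    "CTSlice",
    "DicomFormatError",
    "OverlaySpec",
    "read_dicom_slice",
    "to_hounsfield",
    "write_overlay",
    "write_report_csv",
]

REPORT_COLUMNS = [
    "patient_id",
    "image_id",
    "n_roi_pixels",
    "n_fibrosis_pixels",
    "fibrosis_percent",
]


class DicomFormatError(ValueError):
    """Raised for DICOM files that parse but do not fit the expected dialect."""


@dataclass(frozen=True)
class CTSlice:
    """One CT slice as an HU matrix plus pixel geometry and rescale metadata.

    Attributes
    ----------
    hu : ndarray of float
        Hounsfield-unit matrix, ``raw * rescale_slope + rescale_intercept``.
    raw : ndarray of int
        Stored pixel values as read from the file.
    rescale_slope, rescale_intercept : float
        Modality rescale transform parameters (slope unitless, intercept HU).
    pixel_spacing : (float, float)
        Physical pixel size ``(row_mm, col_mm)``, both strictly positive.
    patient_id, image_id : str
        Identifiers used in reports.
    """

    hu: np.ndarray
    raw: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing: tuple[float, float]
    patient_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        raw = np.asarray(self.raw)
        if hu.ndim != 2 or raw.ndim != 2 or hu.shape != raw.shape:
            raise ValueError("hu and raw must be 2-D matrices of identical shape")
        if min(hu.shape) < 8:
            raise ValueError("slice must be at least 8x8 pixels")
        if not np.issubdtype(raw.dtype, np.integer):
            raise ValueError("raw stored values must be integer-typed")
        rs, cs = self.pixel_spacing
        if not (rs > 0 and cs > 0):
            raise ValueError("pixel_spacing components must be strictly positive")
        expected = raw.astype(float) * self.rescale_slope + self.rescale_intercept
        if not np.allclose(hu, expected, rtol=0.0, atol=1e-9):
            raise ValueError("hu does not equal raw * slope + intercept")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "raw", raw)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape


@dataclass(frozen=True)
class OverlaySpec:
    """Rendering rules for the diagnostic overlay image.

    The initial contour is drawn as a red dashed line, the evolved contour as
    a solid blue line, and classified fibrosis pixels are painted in a third,
    distinct colour on a grayscale soft-tissue-window background
    (centre 40 HU, width 400 HU by default).
    """

    initial_contour_color: tuple[int, int, int] = (255, 0, 0)
    final_contour_color: tuple[int, int, int] = (0, 0, 255)
    fibrosis_mark_color: tuple[int, int, int] = (255, 200, 0)
    window_center: float = 40.0
    window_width: float = 400.0
    dash_on: int = 3  # dashed style: draw 3 segments, skip 3

    def __post_init__(self) -> None:
        colors = {
            self.initial_contour_color,
            self.final_contour_color,
            self.fibrosis_mark_color,
        }
        if len(colors) != 3:
            raise ValueError("overlay colours must be pairwise distinct")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")


def to_hounsfield(raw: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Apply the modality rescale transform element-wise.

    Raises
    ------
    ValueError
        If ``slope`` is zero (the transform would not be invertible).
    """
    if slope == 0:
        raise ValueError("rescale slope must be non-zero")
    return np.asarray(raw, dtype=float) * float(slope) + float(intercept)


def read_dicom_slice(path: str | Path) -> CTSlice:
    """Read a single-frame DICOM CT file into a :class:`CTSlice`.

    Missing RescaleSlope/RescaleIntercept default to 1 and 0 with a logged
    warning.  Multi-frame files and files without pixel data are rejected.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except (pydicom.errors.InvalidDicomError, OSError) as exc:
        raise IOError(f"cannot read DICOM file: {path}") from exc

    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise DicomFormatError(f"multi-frame DICOM not supported: {path}")
    if "PixelData" not in ds:
        raise DicomFormatError(f"DICOM file has no pixel data: {path}")

    raw = np.asarray(ds.pixel_array)
    if raw.ndim != 2:
        raise DicomFormatError(f"expected a single 2-D frame: {path}")

    if "RescaleSlope" in ds:
        slope = float(ds.RescaleSlope)
    else:
        log.warning("%s: RescaleSlope missing, defaulting to 1", path.name)
        slope = 1.0
    if "RescaleIntercept" in ds:
        intercept = float(ds.RescaleIntercept)
    else:
        log.warning("%s: RescaleIntercept missing, defaulting to 0", path.name)
        intercept = 0.0
    if "PixelSpacing" not in ds:
        raise DicomFormatError(f"DICOM file has no PixelSpacing: {path}")
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))

    return CTSlice(
        hu=to_hounsfield(raw, slope, intercept),
        raw=raw,
        rescale_slope=slope,
        rescale_intercept=intercept,
        pixel_spacing=spacing,
        patient_id=str(getattr(ds, "PatientID", "")),
        image_id=str(getattr(ds, "SOPInstanceUID", path.stem)),
    )


def _window_to_gray(hu: np.ndarray, center: float, width: float) -> np.ndarray:
    lo = center - width / 2.0
    scaled = (hu - lo) / width * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def _draw_contour(
    draw: ImageDraw.ImageDraw,
    contour: np.ndarray,
    color: tuple[int, int, int],
    dash_on: int = 0,
) -> None:
    n = len(contour)
    for i in range(n):
        if dash_on and (i // dash_on) % 2 == 1:
            continue
        r0, c0 = contour[i]
        r1, c1 = contour[(i + 1) % n]
        draw.line([(c0, r0), (c1, r1)], fill=color, width=1)


def write_overlay(
    ct: CTSlice,
    snake: "SnakeResult",
    fibrosis: "FibrosisResult",
    spec: OverlaySpec | None = None,
    path: str | Path = "overlay.png",
) -> Path:
    """Write a PNG overlay: windowed grayscale background, both contours, and
    every classified fibrosis pixel painted at its exact (row, col) position.

    Output is fully deterministic: identical inputs produce byte-identical
    files.  Fibrosis marks are painted after the contours so that no fibrosis
    pixel is ever occluded by a contour line.
    """
    spec = spec or OverlaySpec()
    gray = _window_to_gray(ct.hu, spec.window_center, spec.window_width)
    img = Image.fromarray(np.stack([gray] * 3, axis=-1), mode="RGB")

    draw = ImageDraw.Draw(img)
    _draw_contour(draw, snake.final_contour, spec.final_contour_color)
    _draw_contour(draw, snake.initial_contour, spec.initial_contour_color,
                  dash_on=spec.dash_on)

    arr = np.array(img)
    r0, _, c0, _ = fibrosis.roi
    rows, cols = np.nonzero(fibrosis.mask)
    arr[rows + r0, cols + c0] = spec.fibrosis_mark_color

    path = Path(path)
    try:
        Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write overlay image: {path}") from exc
    return path


def write_report_csv(rows: list[dict], path: str | Path) -> Path:
    """Write the per-image report CSV (one row per processed image)."""
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
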