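"""Pixel-level fibrosis classification and optional calcium lesion scoring.

Fibrosis is operationalised as native-CT attenuation in a closed Hounsfield
band, 60-90 HU by default: within the rectangular heart ROI every pixel
whose HU value v satisfies ``hu_low <= v <= hu_high`` is classified as
fibrotic, and the reported quantity is the percentage of ROI pixels so
classified.  The denominator is the full ROI rectangle; an interior-only
mode (denominator restricted to pixels inside the evolved heart contour) is
available behind a flag but is non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CTSlice
from .segmentation import SnakeConfig, SnakeResult, evolve_snake
from .stats import round_half_up

__all__ = [
    "CalciumLesion",
    "FibrosisResult",
    "agatston_score",
    "detect_fibrosis",
    "fibrosis_percentage_for_image",
]


@dataclass(frozen=True)
class FibrosisResult:
    """Classification result over a rectangular ROI.

    ``mask`` has the ROI's dimensions; ``percentage`` is kept at full float
    precision (reporting layers round to 2 decimals).
    """

    mask: np.ndarray
    roi: tuple[int, int, int, int]
    n_roi_pixels: int
    n_fibrosis_pixels: int
    percentage: float
    hu_low: float = 60.0
    hu_high: float = 90.0

    def __post_init__(self) -> None:
        if self.n_fibrosis_pixels != int(self.mask.sum()):
            raise ValueError("n_fibrosis_pixels inconsistent with mask")
        if self.n_fibrosis_pixels > self.n_roi_pixels:
            raise ValueError("more fibrosis pixels than ROI pixels")


@dataclass(frozen=True)
class CalciumLesion:
    """One connected calcium lesion and its Agatston contribution."""

    pixel_count: int
    area_mm2: float
    max_hu: float
    weight: int
    score: float


def detect_fibrosis(
    ct: CTSlice,
    roi: tuple[int, int, int, int],
    hu_low: float = 60.0,
    hu_high: float = 90.0,
    interior_mask: np.ndarray | None = None,
) -> FibrosisResult:
    """Classify every ROI pixel by the closed HU band ``[hu_low, hu_high]``.

    ``roi`` is an inclusive ``(row_min, row_max, col_min, col_max)``
    rectangle inside the slice.  If ``interior_mask`` (an ROI-shaped boolean
    mask, e.g. from :func:`~fibroct.segmentation.contour_interior_mask`) is
    given, both numerator and denominator are restricted to it; this
    interior-only mode is non-canonical and off by default.
    """
    if hu_low > hu_high:
        raise ValueError("hu_low must not exceed hu_high")
    r0, r1, c0, c1 = roi
    nr, nc = ct.shape
    if not (0 <= r0 <= r1 < nr and 0 <= c0 <= c1 < nc):
        raise ValueError(f"ROI {roi} outside slice bounds {ct.shape}")
    window = ct.hu[r0 : r1 + 1, c0 : c1 + 1]
    if window.size == 0:
        raise ValueError("empty ROI")
    mask = (window >= hu_low) & (window <= hu_high)
    if interior_mask is not None:
        if interior_mask.shape != window.shape:
            raise ValueError("interior_mask shape must match the ROI")
        mask &= interior_mask
        n_roi = int(interior_mask.sum())
        if n_roi == 0:
            raise ValueError("interior mask selects no pixels")
    else:
        n_roi = int(window.size)
    n_fib = int(mask.sum())
    return FibrosisResult(
        mask=mask,
        roi=(r0, r1, c0, c1),
        n_roi_pixels=n_roi,
        n_fibrosis_pixels=n_fib,
        percentage=100.0 * n_fib / n_roi,
        hu_low=hu_low,
        hu_high=hu_high,
    )


def fibrosis_percentage_for_image(
    ct: CTSlice,
    snake_config: SnakeConfig,
    hu_low: float = 60.0,
    hu_high: float = 90.0,
) -> float:
    """Full per-image pipeline: snake ROI detection then band classification.

    Returns the fibrosis percentage rounded half-up to 2 decimals, the
    precision used in reports; use :func:`analyze_image` for full precision
    and intermediate results.
    """
    _, fib = analyze_image(ct, snake_config, hu_low=hu_low, hu_high=hu_high)
    return float(round_half_up(fib.percentage, 2))


def analyze_image(
    ct: CTSlice,
    snake_config: SnakeConfig,
    hu_low: float = 60.0,
    hu_high: float = 90.0,
) -> tuple[SnakeResult, FibrosisResult]:
    """Run segmentation and classification, returning both results."""
    snake = evolve_snake(ct.hu, snake_config)
    fib = detect_fibrosis(ct, snake.roi, hu_low=hu_low, hu_high=hu_high)
    return snake, fib


_AGATSTON_WEIGHTS = ((400.0, 4), (300.0, 3), (200.0, 2), (130.0, 1))


def _agatston_weight(max_hu: float) -> int:
    for threshold, weight in _AGATSTON_WEIGHTS:
        if max_hu >= threshold:
            return weight
    raise ValueError("lesion peak below the 130 HU scoring threshold")


def agatston_score(
    ct: CTSlice,
    threshold: float = 130.0,
    min_pixels: int = 4,
    min_area_mm2: float = 1.0,
) -> tuple[list[CalciumLesion], float]:
    """Agatston-style calcium scoring of a slice.

    A lesion is an 8-connected component of pixels at or above ``threshold``
    HU with at least ``min_pixels`` contiguous pixels and an area strictly
    greater than ``min_area_mm2``.  Each lesion scores area times a weight
    set by its peak HU (130-199: 1, 200-299: 2, 300-399: 3, >=400: 4); the
    total is the sum over lesions.  The weight table completes the published
    lesion-definition rule into a computable score.
    """
    above = ct.hu >= threshold
    labels, n_labels = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    pixel_area = ct.pixel_spacing[0] * ct.pixel_spacing[1]

    lesions: list[CalciumLesion] = []
    for lab in range(1, n_labels + 1):
        component = labels == lab
        count = int(component.sum())
        area = count * pixel_area
        if count < min_pixels or area <= min_area_mm2:
            continue
        peak = float(ct.hu[component].max())
        weight = _agatston_weight(peak)
        lesions.append(
            CalciumLesion(
                pixel_count=count,
                area_mm2=area,
                max_hu=peak,
                weight=weight,
                score=area * weight,
            )
        )
    return lesions, float(sum(l.score for l in lesions))
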