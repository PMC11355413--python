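"""Synthetic CT phantoms with known fibrosis ground truth.

A phantom slice emulates the features the pipeline depends on, and nothing
more: a high-attenuation elliptical "heart" (myocardium 40 HU with a
smaller blood-pool ellipse at 45 HU) on a low-attenuation background
(-800 HU), a seeded random subset of heart pixels planted in the 60-90 HU
fibrosis band at a known fraction, optional additive Gaussian HU noise, and
valid DICOM rescale metadata (slope 1, intercept -1024, unsigned 16-bit
storage).  Default tissue values sit just below the fibrosis band on
purpose, to stress the closed-interval boundary of the classifier.

Ground-truth masks are captured *before* noise is added, so the expected
detection error under noise is the analytic normal band-crossing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .io import CTSlice, to_hounsfield

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_replicate_set",
    "write_phantom_dicom",
]

_SLOPE = 1.0
_INTERCEPT = -1024.0
_FIBROSIS_BAND = (60.0, 90.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``fibrosis_fraction`` is the target fraction of heart-ellipse pixels
    planted in the fibrosis band, in [0, 0.5].  ``pixel_spacing`` defaults
    to 0.6 mm, the in-plane detector pitch of the emulated acquisition.
    """

    shape: tuple[int, int] = (256, 256)
    heart_center: tuple[float, float] | None = None
    heart_axes: tuple[float, float] = (60.0, 75.0)
    myocardium_hu: float = 40.0
    blood_hu: float = 45.0
    background_hu: float = -800.0
    fibrosis_hu: float = 75.0
    fibrosis_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    pixel_spacing: tuple[float, float] = (0.6, 0.6)
    patient_id: str = "PHANTOM"
    image_id: str = "phantom-0"

    def __post_init__(self) -> None:
        lo, hi = _FIBROSIS_BAND
        if not (lo <= self.fibrosis_hu <= hi):
            raise ValueError("fibrosis_hu must lie inside the 60-90 HU band")
        for name, hu in (
            ("myocardium_hu", self.myocardium_hu),
            ("blood_hu", self.blood_hu),
            ("background_hu", self.background_hu),
        ):
            if lo <= hu <= hi:
                raise ValueError(f"{name} must lie outside the 60-90 HU band")
        if not (0.0 <= self.fibrosis_fraction <= 0.5):
            raise ValueError("fibrosis_fraction must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        cr, cc = self.center
        ar, ac = self.heart_axes
        nr, nc = self.shape
        if cr - ar < 0 or cr + ar > nr - 1 or cc - ac < 0 or cc + ac > nc - 1:
            raise ValueError("heart ellipse must lie fully inside the image")

    @property
    def center(self) -> tuple[float, float]:
        if self.heart_center is not None:
            return self.heart_center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


@dataclass(frozen=True)
class PhantomTruth:
    """Pre-noise ground truth for one phantom slice."""

    heart_mask: np.ndarray
    fibrosis_mask: np.ndarray
    true_bbox: tuple[int, int, int, int]
    planted_fraction_in_bbox: float
    n_fibrosis_pixels: int

    def __post_init__(self) -> None:
        if (self.fibrosis_mask & ~self.heart_mask).any():
            raise ValueError("fibrosis mask must be a subset of the heart mask")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTSlice, PhantomTruth]:
    """Build one phantom slice and its ground truth.

    The realised fibrosis pixel count is ``round(fraction * heart pixel
    count)``, placed uniformly at random (seeded) over the heart; noise, if
    any, is added after the truth masks are captured.  HU values are encoded
    to integer stored values, so the returned slice carries quantised HU
    (within 0.5 HU of the intended field at zero noise).
    """
    heart = _ellipse_mask(spec.shape, spec.center, spec.heart_axes)
    blood = _ellipse_mask(
        spec.shape, spec.center, (spec.heart_axes[0] * 0.45, spec.heart_axes[1] * 0.45)
    )
    hu = np.full(spec.shape, spec.background_hu, dtype=float)
    hu[heart] = spec.myocardium_hu
    hu[blood & heart] = spec.blood_hu

    n_heart = int(heart.sum())
    n_fib = int(round(spec.fibrosis_fraction * n_heart))
    if n_fib > n_heart:
        raise ValueError("infeasible fibrosis fraction")
    rng = np.random.default_rng(spec.seed)
    fibrosis = np.zeros(spec.shape, dtype=bool)
    if n_fib > 0:
        heart_idx = np.flatnonzero(heart)
        chosen = rng.choice(heart_idx, size=n_fib, replace=False)
        fibrosis.flat[chosen] = True
        hu[fibrosis] = spec.fibrosis_hu

    rows, cols = np.nonzero(heart)
    bbox = (int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))
    bbox_area = (bbox[1] - bbox[0] + 1) * (bbox[3] - bbox[2] + 1)
    truth = PhantomTruth(
        heart_mask=heart,
        fibrosis_mask=fibrosis,
        true_bbox=bbox,
        planted_fraction_in_bbox=n_fib / bbox_area,
        n_fibrosis_pixels=n_fib,
    )

    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    raw = np.clip(np.rint((hu - _INTERCEPT) / _SLOPE), 0, 65535).astype(np.uint16)
    ct = CTSlice(
        hu=to_hounsfield(raw, _SLOPE, _INTERCEPT),
        raw=raw,
        rescale_slope=_SLOPE,
        rescale_intercept=_INTERCEPT,
        pixel_spacing=spec.pixel_spacing,
        patient_id=spec.patient_id,
        image_id=spec.image_id,
    )
    return ct, truth


def generate_replicate_set(
    spec: PhantomSpec,
    n_images: int = 3,
    jitter: float = 0.0,
) -> list[tuple[CTSlice, PhantomTruth]]:
    """Generate ``n_images`` phantoms of the same "patient".

    Each image perturbs the heart centre and axes by uniform offsets in
    ``[-jitter, +jitter]`` pixels, drawn from a stream seeded with
    ``spec.seed + image index`` so regeneration is deterministic.  With
    ``jitter=0`` all images are identical; with ``jitter>0`` the geometry
    (and hence the fibrosis placement over the shifted heart) varies, as
    different slices of one patient would.
    """
    if n_images < 2:
        raise ValueError("n_images must be >= 2")
    out = []
    for i in range(n_images):
        jrng = np.random.default_rng(spec.seed + i)
        dcr, dcc, dar, dac = jrng.uniform(-jitter, jitter, size=4) if jitter > 0 else (
            0.0,
            0.0,
            0.0,
            0.0,
        )
        cr, cc = spec.center
        ar, ac = spec.heart_axes
        sub = replace(
            spec,
            heart_center=(cr + dcr, cc + dcc),
            heart_axes=(max(ar + dar, 4.0), max(ac + dac, 4.0)),
            image_id=f"{spec.image_id}-rep{i + 1}",
        )
        out.append(generate_phantom(sub))
    return out


def write_phantom_dicom(ct: CTSlice, path: str | Path) -> Path:
    """Write a slice as a single-frame uncompressed DICOM CT file.

    All UIDs and dates are derived deterministically from the slice
    identifiers and content, so identical slices yield byte-identical files.
    """
    path = Path(path)
    entropy = [ct.patient_id, ct.image_id, str(int(ct.raw.sum()))]
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=entropy)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=entropy + ["series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[ct.patient_id, "study"])
    ds.Modality = "CT"
    ds.PatientName = ct.patient_id
    ds.PatientID = ct.patient_id
    ds.StudyDate = "20000101"
    ds.ContentDate = "20000101"
    ds.StudyTime = "000000"
    ds.ContentTime = "000000"

    ds.Rows, ds.Columns = ct.raw.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = str(ct.rescale_slope)
    ds.RescaleIntercept = str(ct.rescale_intercept)
    ds.PixelSpacing = [str(ct.pixel_spacing[0]), str(ct.pixel_spacing[1])]
    ds.PixelData = np.ascontiguousarray(ct.raw, dtype=np.uint16).tobytes()

    ds.save_as(path, enforce_file_format=True)
    return path
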