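"""Patient-level orchestration: config handling, per-patient replicate runs,
repeatability runs, and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import yaml

from . import __version__
from .io import CTSlice, read_dicom_slice
from .quantify import analyze_image
from .segmentation import SnakeConfig
from .stats import replicate_stats, round_half_up

__all__ = [
    "build_manifest",
    "load_config",
    "run_patient",
    "run_repeatability",
    "snake_config_for_image",
]

_SNAKE_KEYS = ("sigma", "alpha", "beta", "gamma", "iterations", "n_points",
               "max_px_move")


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON run configuration.

    Layout: an optional global ``snake`` block (sigma, alpha, beta, gamma,
    iterations, n_points) and an optional ``images`` mapping of image_id to
    ``{center: [r, c], axes: [ar, ac]}`` initial-contour parameters.
    """
    if path is None:
        return {}
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config must be a mapping: {path}")
    return cfg


def snake_config_for_image(
    config: dict, image_id: str, **overrides
) -> SnakeConfig:
    """Build a SnakeConfig for one image.

    Precedence: explicit overrides (CLI flags) > per-image config entry >
    global ``snake`` block > package defaults.  Images without a per-image
    entry fall back to the automatic tissue-centroid initialiser at run
    time.
    """
    kwargs: dict = {}
    snake_block = config.get("snake", {})
    for key in _SNAKE_KEYS:
        if key in snake_block:
            kwargs[key] = snake_block[key]
    entry = config.get("images", {}).get(image_id, {})
    if "center" in entry:
        kwargs["init_center"] = tuple(entry["center"])
    if "axes" in entry:
        kwargs["init_axes"] = tuple(entry["axes"])
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return SnakeConfig(**kwargs)


def _load_slices(images: list) -> list[CTSlice]:
    out = []
    for item in images:
        out.append(item if isinstance(item, CTSlice) else read_dicom_slice(item))
    return out


def run_patient(
    images: list,
    config: dict | None = None,
    hu_low: float = 60.0,
    hu_high: float = 90.0,
    **snake_overrides,
) -> dict:
    """Process one patient's replicate images and summarise them.

    ``images`` is a list of DICOM paths or in-memory slices.  Returns a dict
    with one report row per image plus the patient summary (mean, sample SD
    and CV of the per-image fibrosis percentages) when two or more images
    are given.
    """
    if not images:
        raise ValueError("need at least one image per patient")
    config = config or {}
    slices = _load_slices(images)
    rows = []
    for ct in slices:
        cfg = snake_config_for_image(config, ct.image_id, **snake_overrides)
        snake, fib = analyze_image(ct, cfg, hu_low=hu_low, hu_high=hu_high)
        rows.append(
            {
                "patient_id": ct.patient_id,
                "image_id": ct.image_id,
                "n_roi_pixels": fib.n_roi_pixels,
                "n_fibrosis_pixels": fib.n_fibrosis_pixels,
                "fibrosis_percent": round_half_up(fib.percentage, 2),
            }
        )
    percentages = [row["fibrosis_percent"] for row in rows]
    summary = replicate_stats(percentages) if len(percentages) >= 2 else None
    return {
        "patient_id": slices[0].patient_id,
        "images": rows,
        "percentages": percentages,
        "summary": summary,
    }


def run_repeatability(
    image,
    config: dict | None = None,
    n_runs: int = 3,
    iteration_increment: int = 10,
    hu_low: float = 60.0,
    hu_high: float = 90.0,
    **snake_overrides,
) -> dict:
    """Repeat the pipeline on one image with increasing snake iterations.

    Run j uses ``iterations = base + j * iteration_increment`` (j = 0 ..
    n_runs-1), mirroring the published robustness protocol; returns the
    per-run percentages and their replicate summary (mean, SD, CV).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    config = config or {}
    ct = image if isinstance(image, CTSlice) else read_dicom_slice(image)
    base_cfg = snake_config_for_image(config, ct.image_id, **snake_overrides)
    percentages = []
    for j in range(n_runs):
        cfg = replace(base_cfg, iterations=base_cfg.iterations + j * iteration_increment)
        _, fib = analyze_image(ct, cfg, hu_low=hu_low, hu_high=hu_high)
        percentages.append(round_half_up(fib.percentage, 2))
    return {
        "patient_id": ct.patient_id,
        "image_id": ct.image_id,
        "iterations": [
            base_cfg.iterations + j * iteration_increment for j in range(n_runs)
        ],
        "percentages": percentages,
        "summary": replicate_stats(percentages),
    }


def build_manifest(
    patients: dict[str, list[str]], config: dict, extra: dict | None = None
) -> dict:
    """JSON-serialisable run manifest: patient index, file lists, config
    digest and tool version."""
    all_files = [str(f) for files in patients.values() for f in files]
    if len(set(all_files)) != len(all_files):
        raise ValueError("every processed image must appear exactly once")
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "tool": "fibroct",
        "version": __version__,
        "config_digest": digest,
        "patients": {pid: list(files) for pid, files in patients.items()},
        "n_images": len(all_files),
    }
    if extra:
        manifest.update(extra)
    return manifest
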