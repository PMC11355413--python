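"""Bundled replicate tables from the pilot validation of the algorithm.

Two small patients x replicates tables of fibrosis percentages, used to
exercise the reliability-statistics layer at desk scale:

* :func:`multi_image_replicates` — each of eight patients measured on three
  different CT images of the same heart (between-image variability).
* :func:`repeat_run_replicates` — one image per patient processed three
  times with the snake iteration count increased by 10 between runs
  (algorithmic repeatability for the same observer).

The printed per-row summaries (mean, SD, CV) are exposed alongside the raw
replicates so round-trip checks can compare against them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "multi_image_replicates",
    "multi_image_summary",
    "repeat_run_replicates",
    "repeat_run_summary",
]

_MULTI_IMAGE = [
    # rep1, rep2, rep3, mean, sd, cv%
    (8.9, 9.2, 8.79, 8.96, 0.21, 1.93),
    (5.77, 7.57, 6.51, 6.62, 0.90, 11.16),
    (7.51, 9.75, 9.59, 8.95, 1.25, 11.40),
    (13.87, 11.08, 10.52, 11.82, 1.79, 12.39),
    (6.53, 9.17, 9.4, 8.37, 1.59, 15.56),
    (11.53, 10.4, 11.04, 10.99, 0.57, 4.21),
    (5.68, 4.86, 5.73, 5.42, 0.49, 7.35),
    (9.71, 9.94, 8.97, 9.54, 0.51, 4.34),
]

_REPEAT_RUN = [
    # run1, run2, run3, mean, cv%
    (8.9, 9.09, 8.82, 8.94, 1.27),
    (5.77, 5.81, 5.81, 5.80, 0.33),
    (7.51, 7.79, 7.4, 7.57, 2.17),
    (13.87, 13.85, 13.64, 13.79, 0.75),
    (6.53, 6.78, 6.53, 6.61, 1.78),
    (11.53, 11.55, 11.53, 11.54, 0.08),
    (5.68, 5.11, 5.75, 5.51, 5.20),
    (9.71, 9.83, 9.71, 9.75, 0.58),
]


def multi_image_replicates() -> np.ndarray:
    """8x3 matrix: fibrosis % from three different images per patient."""
    return np.array([row[:3] for row in _MULTI_IMAGE], dtype=float)


def multi_image_summary() -> pd.DataFrame:
    """Published per-patient mean / SD / CV for the multi-image table."""
    return pd.DataFrame(
        [row[3:] for row in _MULTI_IMAGE],
        columns=["mean", "sd_sample", "cv_percent"],
    )


def repeat_run_replicates() -> np.ndarray:
    """8x3 matrix: fibrosis % from three repeat runs on the same image."""
    return np.array([row[:3] for row in _REPEAT_RUN], dtype=float)


def repeat_run_summary() -> pd.DataFrame:
    """Published per-patient mean / CV for the repeat-run table."""
    return pd.DataFrame(
        [row[3:] for row in _REPEAT_RUN], columns=["mean", "cv_percent"]
    )
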