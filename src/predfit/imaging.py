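"""Prey-rounding quantification from fluorescence micrographs.

A rod-shaped prey cell projects as an elongated region; once remodelled
into a bdelloplast it becomes nearly circular.  Segmentation is a global
Otsu threshold followed by 8-connected labelling and a minimum-area
filter; each region's eccentricity

    e = sqrt(1 - minor^2 / major^2)

comes from the eigenvalues of its 2x2 second-central-moment matrix, so
e = 0 for a circle and e -> 1 for a line.  Cells with e below a threshold
count as rounded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import filters, measure

DEFAULT_MIN_AREA = 20
DEFAULT_E_THRESHOLD = 0.75


def segment(
    image: np.ndarray,
    background_method: str = "otsu",
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int | None = None,
) -> pd.DataFrame:
    """Segment a single-channel image into cell regions.

    Returns one row per retained region with area, centroid, axis lengths,
    moment-based eccentricity and a ``flag`` column: ``"oversized"`` for
    regions above ``max_area`` (typically merged cells) and
    ``"degenerate"`` for collinear-pixel regions (e pinned to 1).  A blank
    image yields an empty frame.
    """
    if image.ndim != 2:
        raise ValueError("segment expects a single-channel 2-D image")
    if background_method == "otsu":
        if np.ptp(image) == 0:
            return _empty_regions()
        thresh = filters.threshold_otsu(image)
    elif background_method == "mean":
        thresh = float(image.mean())
    else:
        raise ValueError(f"unknown background_method {background_method!r}")
    mask = image > thresh
    if not mask.any():
        return _empty_regions()
    labels = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        flag = ""
        if max_area is not None and region.area > max_area:
            flag = "oversized"
        minor, major = region.axis_minor_length, region.axis_major_length
        if major == 0 or minor == 0:
            ecc, flag = 1.0, (flag or "degenerate")
        else:
            ecc = region.eccentricity
        rows.append(
            {
                "label": region.label,
                "area": int(region.area),
                "centroid_r": region.centroid[0],
                "centroid_c": region.centroid[1],
                "major": major,
                "minor": minor,
                "eccentricity": float(ecc),
                "flag": flag,
            }
        )
    if not rows:
        return _empty_regions()
    return pd.DataFrame(rows).set_index("label")


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "area",
            "centroid_r",
            "centroid_c",
            "major",
            "minor",
            "eccentricity",
            "flag",
        ]
    )


def eccentricity(mask: np.ndarray):
    """Moment-based eccentricity of a binary pixel region.

    Eigen-decomposes the second-central-moment matrix of the foreground
    pixel coordinates and returns ``(e, degenerate)`` with
    ``e = sqrt(1 - lambda_minor / lambda_major)``; collinear regions
    (vanishing minor eigenvalue relative to the major one) return e = 1
    flagged degenerate.  Needs at least 3 foreground pixels.
    """
    rr, cc = np.nonzero(np.asarray(mask))
    if len(rr) < 3:
        raise ValueError("region needs at least 3 pixels")
    coords = np.stack([rr, cc]).astype(float)
    cov = np.cov(coords, bias=True)
    lam = np.sort(np.linalg.eigvalsh(cov))
    if lam[1] <= 0 or lam[0] / lam[1] < 1e-12:
        return 1.0, True
    return float(np.sqrt(1.0 - lam[0] / lam[1])), False


def rounded_fraction(eccentricities, e_threshold: float = DEFAULT_E_THRESHOLD) -> float:
    """Percentage of regions with eccentricity below the rounding cutoff."""
    e = np.asarray(eccentricities, dtype=float)
    if e.size == 0:
        raise ValueError("no regions: rounded fraction undefined")
    return 100.0 * float((e < e_threshold).mean())


def quantify_rounding(
    image: np.ndarray,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
) -> tuple[float, pd.DataFrame]:
    """Segment an image and return (percent rounded, region table)."""
    regions = segment(image, min_area=min_area)
    if len(regions) == 0:
        raise ValueError("no segmentable regions in image")
    return rounded_fraction(regions["eccentricity"], e_threshold), regions
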