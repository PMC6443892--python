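"""Top-view canopy imaging: color segmentation and calibrated measurements.

Plants are photographed from above against a blue background with a red
10 × 5 cm reference rectangle in frame.  Pixels are classified in HSV space
as plant (green), reference (red) or background (blue); the red reference of
known area calibrates cm² per pixel, from which canopy area and individual
leaf dimensions follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.color import rgb2hsv

#: physical area of the red reference rectangle (10 × 5 cm)
REFERENCE_AREA_CM2 = 50.0


@dataclass(frozen=True)
class ColorThresholds:
    """Hue ranges (degrees) and a common saturation floor for classification.

    The red range wraps around 0°.  Pixels matching no class, or below the
    saturation floor, stay unclassified.
    """

    green_hue: tuple[float, float] = (70.0, 170.0)
    red_hue: tuple[float, float] = (-20.0, 20.0)
    blue_hue: tuple[float, float] = (190.0, 260.0)
    min_saturation: float = 0.25


@dataclass
class SegmentationResult:
    green_count: int
    red_count: int
    blue_count: int
    unclassified_count: int
    green_mask: np.ndarray
    red_mask: np.ndarray
    red_reference_count: int  # largest connected red component

    @property
    def total(self) -> int:
        return (
            self.green_count + self.red_count + self.blue_count + self.unclassified_count
        )


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def segment_colors(
    image: np.ndarray, thresholds: ColorThresholds | None = None
) -> SegmentationResult:
    """Assign each pixel to plant / reference / background / unclassified.

    The calibration uses only the largest connected red component, guarding
    against stray red noise pixels.
    """
    thr = thresholds or ColorThresholds()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if img.dtype != np.float64:
        img = img.astype(np.float64) / (255.0 if img.max() > 1.0 else 1.0)
    hsv = rgb2hsv(img)
    hue = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    saturated = sat > thr.min_saturation

    def in_range(lo, hi):
        if lo < 0:  # wrap-around (red)
            return ((hue >= lo % 360.0) | (hue <= hi)) & saturated
        return (hue >= lo) & (hue <= hi) & saturated

    green = in_range(*thr.green_hue)
    red = in_range(*thr.red_hue)
    blue = in_range(*thr.blue_hue)
    # precedence is irrelevant for disjoint hue ranges; enforce exclusivity
    red &= ~green
    blue &= ~green & ~red
    unclassified = ~(green | red | blue)

    ref_count = 0
    if red.any():
        lbl = measure.label(red, connectivity=2)
        sizes = np.bincount(lbl.ravel())
        sizes[0] = 0
        ref_count = int(sizes.max())
    return SegmentationResult(
        green_count=int(green.sum()),
        red_count=int(red.sum()),
        blue_count=int(blue.sum()),
        unclassified_count=int(unclassified.sum()),
        green_mask=green,
        red_mask=red,
        red_reference_count=ref_count,
    )


def calibration_cm2_per_px(
    result: SegmentationResult, reference_area: float = REFERENCE_AREA_CM2
) -> float:
    if result.red_reference_count == 0:
        raise ValueError("no red reference detected: calibration unavailable")
    return reference_area / result.red_reference_count


def canopy_area(
    result: SegmentationResult, reference_area: float = REFERENCE_AREA_CM2
) -> float:
    """Green canopy area in cm², calibrated by the red reference rectangle."""
    return result.green_count * calibration_cm2_per_px(result, reference_area)


def leaf_dimensions(
    leaf_mask: np.ndarray, calibration: float
) -> tuple[float, float, float]:
    """Length, width (cm) and area (cm²) of a single connected leaf mask.

    Length is the extent along the major axis of the pixel cloud; width is
    the maximal extent perpendicular to it; area is pixel count times the
    cm²-per-pixel calibration.
    """
    mask = np.asarray(leaf_mask, bool)
    if not mask.any():
        raise ValueError("empty leaf mask")
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    pts -= pts.mean(axis=0)
    # principal axis of the pixel cloud
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    minor = np.array([-major[1], major[0]])
    scale = float(np.sqrt(calibration))  # cm per pixel
    # +1 px accounts for pixel extent, matching an N-pixel row spanning N px
    length = (np.ptp(pts @ major) + 1.0) * scale
    width = (np.ptp(pts @ minor) + 1.0) * scale
    area = float(mask.sum()) * calibration
    return float(length), float(width), float(area)
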