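"""Gap-assay fiber quantification on fluorescence-style images.

The quantifier mirrors the bespoke counting procedure used for the in-vitro
assays: threshold the grayscale image, place two ~20 um wide ROIs parallel
to the gap boundary (ROI 1 inside the gap flush against the boundary, ROI 2
directly behind it), count signal peaks in every pixel line, and report

``stopping% = 100 * (1 - mean_peaks(ROI2) / mean_peaks(ROI1))``

clipped to [0, 100].  A synthetic generator renders parallel, lightly
meandering fiber traces with a known stopping fraction for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "RoiSpec",
    "SyntheticImageTruth",
    "generate_gap_image",
    "threshold_image",
    "count_peaks_per_row",
    "quantify_stopping",
]


@dataclass(frozen=True)
class RoiSpec:
    """Geometry of the two counting ROIs.

    ``gap_far_edge`` is the pixel coordinate (along the growth axis) of the
    boundary between the gap and the second cue field.  ROI 1 spans the
    ``roi_width_px`` pixels just before it, ROI 2 the ones just after.
    """

    gap_far_edge: int
    roi_width_px: int = 20
    gap_axis: str = "horizontal"          # growth direction
    lateral_extent: Optional[Tuple[int, int]] = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_axis not in ("horizontal", "vertical"):
            raise ValueError("gap_axis must be horizontal or vertical")
        if self.roi_width_px < 1:
            raise ValueError("roi_width_px must be >= 1")

    def rois(self, shape: Tuple[int, int]) -> Tuple[slice, slice, slice]:
        """(lateral slice, ROI1 slice, ROI2 slice) along image axes."""
        h, w = shape
        extent = w if self.gap_axis == "horizontal" else h
        lat_max = h if self.gap_axis == "horizontal" else w
        e = self.gap_far_edge
        if not (self.roi_width_px <= e <= extent - self.roi_width_px):
            raise ValueError(
                f"ROIs around edge {e} do not fit in image extent {extent}"
            )
        lat = self.lateral_extent or (0, lat_max)
        if not (0 <= lat[0] < lat[1] <= lat_max):
            raise ValueError(f"lateral extent {lat} outside image")
        return (
            slice(lat[0], lat[1]),
            slice(e - self.roi_width_px, e),
            slice(e, e + self.roi_width_px),
        )


@dataclass
class SyntheticImageTruth:
    """Ground truth of a generated gap-assay image."""

    n_fibers: int = 40
    stop_fraction: float = 0.5
    noise_sigma: float = 4.0
    seed: int = 0
    fiber_paths: List[np.ndarray] = dc_field(default_factory=list)

    @property
    def n_crossing(self) -> int:
        return int(round(self.n_fibers * (1.0 - self.stop_fraction)))


def generate_gap_image(
    truth: SyntheticImageTruth,
    geometry: RoiSpec,
    rng: Optional[np.random.Generator] = None,
    shape: Tuple[int, int] = (320, 320),
    amplitude: float = 180.0,
    blur_sigma: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render meandering fiber traces with a known stopping fraction.

    Fibers grow along +x (``gap_axis='horizontal'``), evenly spaced in y
    with jitter.  A ``stop_fraction`` share terminates just before
    ``gap_far_edge`` (inside ROI 1), the rest cross and run to the image
    edge.  Returns ``(image, prenoise_mask)``; ``truth.fiber_paths`` is
    filled in place.
    """
    if truth.n_fibers < 1:
        raise ValueError("need at least one fiber")
    if not (0.0 <= truth.stop_fraction <= 1.0):
        raise ValueError("stop_fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng(truth.seed)
    h, w = shape
    lat = geometry.lateral_extent or (8, h - 8)
    n = truth.n_fibers
    n_cross = truth.n_crossing
    crossing = np.zeros(n, dtype=bool)
    crossing[rng.choice(n, size=n_cross, replace=False)] = True

    lanes = np.linspace(lat[0] + 2, lat[1] - 2, n)
    lanes = lanes + rng.uniform(-0.3, 0.3, size=n) * np.diff(lanes).mean()

    canvas = np.zeros(shape, dtype=float)
    truth.fiber_paths = []
    edge = geometry.gap_far_edge
    for k in range(n):
        if crossing[k]:
            x_end = w - 1
        else:
            # stop within ROI 1, flush against the boundary
            x_end = edge - 1 - int(rng.integers(0, max(geometry.roi_width_px // 3, 1)))
        xs = np.arange(0, x_end + 1)
        steps = rng.normal(0.0, 0.1, size=xs.size)
        meander = ndimage.gaussian_filter1d(np.cumsum(steps), 8.0)
        ys = lanes[k] + meander - meander[0]
        ys = np.clip(ys, 1, h - 2)
        truth.fiber_paths.append(np.stack([xs, ys], axis=1))
        yi = np.round(ys).astype(int)
        canvas[yi, xs] = 1.0
        canvas[np.clip(yi + 1, 0, h - 1), xs] = np.maximum(
            canvas[np.clip(yi + 1, 0, h - 1), xs], 0.5
        )
    clean = ndimage.gaussian_filter(canvas, blur_sigma) * amplitude
    # pre-noise foreground at the clean image's own Otsu level, so the
    # thresholding contract can be validated against it
    prenoise = clean > threshold_otsu(clean)
    img = clean + rng.normal(0.0, truth.noise_sigma, size=shape)
    return np.clip(img, 0.0, 255.0), prenoise


def threshold_image(
    image: np.ndarray,
    method: str = "otsu",
    fixed_value: Optional[float] = None,
) -> Tuple[np.ndarray, Dict]:
    """Foreground (axon signal) mask plus metadata on the threshold used."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed thresholding needs fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        if np.ptp(image) == 0:
            return np.zeros(image.shape, dtype=bool), {
                "method": "otsu", "value": None, "warning": "blank image",
            }
        thr = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return image > thr, {"method": method, "value": thr}


def count_peaks_per_row(
    binary_roi: np.ndarray,
    axis: str = "horizontal",
    min_width: int = 1,
) -> np.ndarray:
    """Number of signal peaks in each pixel line perpendicular to growth.

    A peak is a maximal run of consecutive foreground pixels (one fiber
    cross-section); runs shorter than ``min_width`` are ignored.  For
    horizontal growth the lines are the ROI's pixel columns (fibers cross
    them vertically).
    """
    roi = np.asarray(binary_roi, dtype=bool)
    if roi.size == 0:
        raise ValueError("empty ROI")
    if axis == "horizontal":
        roi = roi.T            # lines become rows
    padded = np.pad(roi, ((0, 0), (1, 1)))
    starts = (~padded[:, :-1]) & padded[:, 1:]
    if min_width <= 1:
        return starts.sum(axis=1)
    counts = np.zeros(roi.shape[0], dtype=int)
    for i, line in enumerate(roi):
        run = 0
        for v in np.append(line, False):
            if v:
                run += 1
            elif run:
                if run >= min_width:
                    counts[i] += 1
                run = 0
    return counts


def quantify_stopping(
    image: np.ndarray,
    roi: RoiSpec,
    threshold_method: str = "otsu",
    fixed_value: Optional[float] = None,
    min_width: int = 1,
) -> Dict:
    """Percent of fibers stopping at the gap boundary.

    Counts peaks per pixel line in both ROIs and reports
    ``100 * (1 - mean(ROI2) / mean(ROI1))`` clipped to [0, 100] (crossing
    fibers can fasciculate, so ROI 2 may occasionally out-count ROI 1).
    Raises if ROI 1 holds no signal (no fibers reached the gap).
    """
    binary, meta = threshold_image(image, threshold_method, fixed_value)
    lat, s1, s2 = roi.rois(binary.shape)
    if roi.gap_axis == "horizontal":
        roi1, roi2 = binary[lat, s1], binary[lat, s2]
    else:
        roi1, roi2 = binary[s1, lat], binary[s2, lat]
    c1 = count_peaks_per_row(roi1, roi.gap_axis, min_width)
    c2 = count_peaks_per_row(roi2, roi.gap_axis, min_width)
    mean1 = float(c1.mean())
    mean2 = float(c2.mean())
    if mean1 == 0.0:
        raise ValueError("no fibers detected in ROI 1 (gap side)")
    pct = float(np.clip(100.0 * (1.0 - mean2 / mean1), 0.0, 100.0))
    return {
        "stopping_percent": pct,
        "mean_counts": [mean1, mean2],
        "threshold": meta,
        "roi": {
            "gap_far_edge": roi.gap_far_edge,
            "roi_width_px": roi.roi_width_px,
            "gap_axis": roi.gap_axis,
        },
        "min_width": min_width,
    }
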