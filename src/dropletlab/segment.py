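"""Two-channel droplet segmentation.

Each Z-slice is processed independently: both channels are min--max
normalized to [0, 1], then droplets are detected iteratively — seed at the
brightest unassigned channel-1 pixel, flood-fill down to half of that
droplet's peak, split touching droplets by watershed on the distance
transform, and validate by circularity — until the brightest remaining
channel-1 pixel falls below a stopping threshold (default 75% of the slice's
normalized intensity).  Channel 1 (the scaffold-protein channel) drives
detection; channel 2 is measured on the same masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import perimeter_crofton as _perimeter
from skimage.segmentation import flood, watershed

from .images import ImageStack

__all__ = ["NormalizedSlice", "DropletRegion", "normalize_slice", "find_droplets", "circularity"]


@dataclass
class NormalizedSlice:
    """A two-channel slice with each channel min--max scaled to [0, 1].

    ``constant_channels[c]`` is True when channel ``c`` had zero dynamic
    range (all pixels equal); such channels are set to all zeros.
    """

    data: np.ndarray
    constant_channels: tuple[bool, ...]


def minmax_scale(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale an array to [0, 1]; a constant array maps to zeros (flagged)."""
    lo = float(np.min(values))
    hi = float(np.max(values))
    if hi == lo:
        return np.zeros_like(values, dtype=float), True
    return (values - lo) / (hi - lo), False


def normalize_slice(image_slice) -> NormalizedSlice:
    """Independently min--max scale each channel of a (C, Y, X) slice to [0, 1]."""
    if isinstance(image_slice, ImageStack):
        image_slice = image_slice.plane(0)
    arr = np.asarray(image_slice, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("expected a (C, Y, X) slice with at least two channels")
    out = np.empty_like(arr)
    flags = []
    for c in range(arr.shape[0]):
        out[c], const = minmax_scale(arr[c])
        flags.append(const)
        if const:
            warnings.warn(
                f"channel {c} is constant; normalized to zeros", stacklevel=2
            )
    return NormalizedSlice(out, tuple(flags))


@dataclass
class DropletRegion:
    """One segmented droplet on one Z-slice.

    ``mask`` is a full-size boolean array of member pixels; ``center_xy`` is
    the channel-1 intensity-weighted centroid, ``radius_px`` the radius of
    the equal-area circle, and ``circularity`` the isoperimetric score
    ``4*pi*Area/Perimeter**2``.
    """

    slice_index: int
    center_xy: tuple[float, float]
    radius_px: float
    mask: np.ndarray
    circularity: float
    peak_intensity: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def circularity(mask: np.ndarray) -> float:
    """Isoperimetric circularity ``4*pi*A/P**2`` of a boolean mask.

    1 for a perfect disk (rasterization may push it slightly above 1);
    approaches 0 for elongated or degenerate shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    area = mask.sum()
    if area == 0:
        raise ValueError("mask is empty")
    # Crofton perimeter (4 directions) is the least biased of skimage's
    # estimators for smooth convex shapes
    p = _perimeter(mask, directions=4)
    if p <= 0 or area <= 2:
        # single pixel or similar degenerate mask: no meaningful boundary
        return 0.0
    return float(4.0 * np.pi * area / p**2)


def _split_touching(region: np.ndarray) -> list[np.ndarray]:
    """Split a candidate region into droplets by watershed on the EDT."""
    dist = ndi.distance_transform_edt(region)
    min_dist = max(3, int(round(0.7 * dist.max())))
    coords = peak_local_max(dist, min_distance=min_dist, labels=region, exclude_border=False)
    if len(coords) <= 1:
        return [region]
    peaks = np.zeros(region.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, n = ndi.label(peaks)
    if n <= 1:
        return [region]
    labels = watershed(-dist, markers, mask=region)
    return [labels == lbl for lbl in range(1, n + 1)]


def find_droplets(
    normalized_slice,
    stop_threshold: float = 0.75,
    inclusion_fraction: float = 0.5,
    min_circularity: float = 0.8,
    min_area: int = 16,
    slice_index: int = 0,
) -> list[DropletRegion]:
    """Iteratively detect droplets on a normalized slice.

    Repeats {seed at the global channel-1 maximum among unassigned pixels;
    flood-fill the connected region above ``inclusion_fraction`` of that
    peak (the full-width-at-half-maximum boundary rule); split touching
    droplets by watershed; validate circularity} while the peak is at least
    ``stop_threshold``.  Pixels of every examined candidate are marked
    assigned whether or not it validates, so no pixel belongs to two regions
    and the loop terminates.  Regions are returned sorted by peak intensity,
    brightest first.
    """
    if isinstance(normalized_slice, NormalizedSlice):
        data = normalized_slice.data
    else:
        data = np.asarray(normalized_slice, dtype=float)
    ch1 = data[0]
    unassigned = np.ones(ch1.shape, dtype=bool)
    regions: list[DropletRegion] = []
    work = ch1.copy()
    low = -10.0  # sentinel well below any inclusion level
    while True:
        peak = work.max(initial=low, where=unassigned)
        if peak < stop_threshold:
            break
        seed = np.unravel_index(np.argmax(np.where(unassigned, work, low)), ch1.shape)
        level = inclusion_fraction * peak
        masked = np.where(unassigned, ch1, low)
        candidate = flood(masked, seed, tolerance=peak - level)
        unassigned &= ~candidate
        for part in _split_touching(candidate):
            area = int(part.sum())
            if area < min_area:
                continue
            score = circularity(part)
            if score < min_circularity:
                continue
            yy, xx = np.nonzero(part)
            w = ch1[yy, xx]
            wsum = w.sum()
            if wsum > 0:
                cx = float((xx * w).sum() / wsum)
                cy = float((yy * w).sum() / wsum)
            else:
                cx, cy = float(xx.mean()), float(yy.mean())
            regions.append(
                DropletRegion(
                    slice_index=slice_index,
                    center_xy=(cx, cy),
                    radius_px=float(np.sqrt(area / np.pi)),
                    mask=part,
                    circularity=score,
                    peak_intensity=float(ch1[part].max()),
                )
            )
    regions.sort(key=lambda r: r.peak_intensity, reverse=True)
    return regions
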