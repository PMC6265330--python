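"""End-to-end scene analysis: segmentation -> photometry -> quantitation.

These helpers run the full chain on a two-channel image: normalize and
segment on channel 1, measure per-droplet raw mean intensities on both
channels (excluding the droplet rim to avoid partial-volume bias), estimate
the image background as the median outside all masks, and convert
intensities to concentrations through calibration curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .images import ImageStack
from .quant import CalibrationCurve, LabeledSample, droplet_concentration
from .segment import DropletRegion, find_droplets, normalize_slice

__all__ = [
    "segment_scene",
    "estimate_background",
    "measure_regions",
    "concentrations_from_scene",
]

#: pixels eroded off each mask before photometry (rim partial-volume guard)
RIM_EXCLUDE_PX = 2


def segment_scene(stack: ImageStack, slice_index: int = 0, **kwargs) -> list[DropletRegion]:
    """Normalize one slice and detect droplets on it (channel 1 drives)."""
    plane = stack.plane(slice_index)
    norm = normalize_slice(plane)
    return find_droplets(norm, slice_index=slice_index, **kwargs)


def estimate_background(plane: np.ndarray, regions: list[DropletRegion], dilate_px: int = 3) -> np.ndarray:
    """Per-channel background: median over pixels outside all (dilated) masks."""
    outside = np.ones(plane.shape[1:], dtype=bool)
    for r in regions:
        mask = r.mask
        if dilate_px > 0:
            mask = ndi.binary_dilation(mask, iterations=dilate_px)
        outside &= ~mask
    if not outside.any():
        raise ValueError("no background pixels left outside droplet masks")
    return np.median(plane[:, outside], axis=1)


def measure_regions(
    stack: ImageStack,
    regions: list[DropletRegion],
    rim_exclude_px: int = RIM_EXCLUDE_PX,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Raw per-droplet photometry on every channel.

    Means are taken over the mask eroded by ``rim_exclude_px`` pixels (falling
    back to the full mask if erosion empties it) and, by default, the
    per-channel background median is subtracted.
    """
    plane_cache: dict[int, np.ndarray] = {}
    rows = []
    for i, region in enumerate(regions):
        z = region.slice_index
        if z not in plane_cache:
            plane_cache[z] = stack.plane(z)
        plane = plane_cache[z]
        mask = region.mask
        if rim_exclude_px > 0:
            eroded = ndi.binary_erosion(mask, iterations=rim_exclude_px)
            if eroded.any():
                mask = eroded
        same_slice = [r for r in regions if r.slice_index == z]
        bg = (
            estimate_background(plane, same_slice)
            if subtract_background
            else np.zeros(plane.shape[0])
        )
        row = {
            "droplet": i,
            "slice": z,
            "center_x": region.center_xy[0],
            "center_y": region.center_xy[1],
            "radius_px": region.radius_px,
            "radius_um": region.radius_px * stack.pixel_size_um,
            "circularity": region.circularity,
            "area_px": region.area,
        }
        for c in range(plane.shape[0]):
            row[f"mean_ch{c + 1}"] = float(plane[c][mask].mean() - bg[c])
            row[f"peak_ch{c + 1}"] = float(plane[c][region.mask].max())
            row[f"background_ch{c + 1}"] = float(bg[c])
        rows.append(row)
    return pd.DataFrame(rows)


def concentrations_from_scene(
    stack: ImageStack,
    curves: tuple[CalibrationCurve, CalibrationCurve],
    samples: tuple[LabeledSample, LabeledSample],
    **segment_kwargs,
) -> pd.DataFrame:
    """Segment a two-channel scene and quantify per-droplet concentrations.

    Returns the photometry table extended with ``conc_ch1_um`` and
    ``conc_ch2_um`` columns (total protein, µM) obtained through each
    channel's calibration curve and labeling stoichiometry.
    """
    regions = segment_scene(stack, **segment_kwargs)
    if not regions:
        raise ValueError("no droplets detected in the scene")
    table = measure_regions(stack, regions)
    for c, (curve, sample) in enumerate(zip(curves, samples)):
        table[f"conc_ch{c + 1}_um"] = [
            droplet_concentration(v, curve, sample) for v in table[f"mean_ch{c + 1}"]
        ]
    return table
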