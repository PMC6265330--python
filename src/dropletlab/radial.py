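"""Radial core--shell profiling of segmented droplets.

A segmented droplet is cropped, each channel is re-normalized to [0, 1] over
the crop (the secondary normalization; the crop extends past the droplet rim
so the normalization minimum sits at local background), and intensity is
sampled by bilinear interpolation along equally spaced rays from the centre
out to 1.2x the droplet radius.  Ray-averaged per-channel profiles, their
standard-deviation envelopes, the channel-1/channel-2 ratio trace and a
scalar shell-enrichment statistic quantify core--shell architecture: a
statistic above 1 flags a channel-1-rich boundary layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .images import ImageStack
from .segment import DropletRegion, minmax_scale

__all__ = [
    "RadialProfile",
    "RatioProfile",
    "secondary_normalize",
    "radial_profile",
    "ratio_profile",
    "shell_enrichment",
]

#: distances where the denominator channel falls below this (normalized
#: units) are masked in ratio traces
RATIO_EPS = 0.05

#: profiles extend this factor past the droplet radius so the interface is visible
PROFILE_EXTENT = 1.2


@dataclass
class RadialProfile:
    """Per-channel radial intensity profiles of one droplet.

    ``mean[c, k]`` is the mean normalized intensity of channel ``c`` over all
    rays at distance ``distances_um[k]`` from the centre; ``sd`` is the
    across-ray standard deviation and ``per_ray`` retains the individual ray
    traces (``(C, n_radii, n_steps)``).
    """

    distances_um: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_ray: np.ndarray
    n_radii: int
    radius_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.distances_um[0] != 0:
            raise ValueError("distances must start at 0")
        if self.n_radii < 8:
            raise ValueError("n_radii must be >= 8")
        if self.mean.shape[-1] != self.distances_um.size:
            raise ValueError("profile arrays must match the distance grid")


@dataclass
class RatioProfile:
    """Channel-1/channel-2 ratio vs distance, with mask and across-ray s.d."""

    distances_um: np.ndarray
    ratio: np.ndarray            # nan where masked
    mask: np.ndarray             # True where the ratio is valid
    sd: np.ndarray               # s.d. of per-ray ratios (nan where masked)
    radius_um: float


def secondary_normalize(droplet_pixels: np.ndarray) -> tuple[np.ndarray, tuple[bool, ...]]:
    """Min--max scale each channel of a droplet crop to [0, 1].

    Returns the normalized array and a per-channel flag that is True where a
    channel was constant (zero dynamic range; normalized to zeros).  The
    scaling is invariant to any positive linear gain on the input.
    """
    arr = np.asarray(droplet_pixels, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    out = np.empty_like(arr)
    flags = []
    for c in range(arr.shape[0]):
        out[c], const = minmax_scale(arr[c])
        flags.append(const)
        if const:
            warnings.warn(f"channel {c} is constant over the droplet", stacklevel=2)
    return out, tuple(flags)


def radial_profile(
    image,
    droplet: DropletRegion,
    n_radii: int = 30,
    n_steps: int | None = None,
    extent: float = PROFILE_EXTENT,
    pixel_size_um: float | None = None,
) -> RadialProfile:
    """Sample ray profiles of both channels around a droplet centre.

    ``n_radii`` equally spaced rays run from the centre to ``extent`` times
    the droplet radius; intensity is sampled by bilinear interpolation on the
    secondarily normalized crop and averaged across rays at each distance
    step (default step: one pixel).
    """
    if isinstance(image, ImageStack):
        if pixel_size_um is None:
            pixel_size_um = image.pixel_size_um
        data = image.plane(0) if not image.is_zstack else image.plane(droplet.slice_index)
    else:
        data = np.asarray(image, dtype=float)
    if pixel_size_um is None:
        pixel_size_um = 1.0
    cx, cy = droplet.center_xy
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < droplet.mask.shape[0] and 0 <= ix < droplet.mask.shape[1]):
        raise ValueError("droplet center lies outside the image")
    if not droplet.mask[iy, ix]:
        raise ValueError("droplet center does not lie inside the droplet mask")

    r_max = extent * droplet.radius_px
    pad = 2
    y0 = max(0, int(np.floor(cy - r_max)) - pad)
    y1 = min(data.shape[1], int(np.ceil(cy + r_max)) + pad + 1)
    x0 = max(0, int(np.floor(cx - r_max)) - pad)
    x1 = min(data.shape[2], int(np.ceil(cx + r_max)) + pad + 1)
    crop = data[:, y0:y1, x0:x1]
    norm, _flags = secondary_normalize(crop)

    if n_steps is None:
        n_steps = max(8, int(np.ceil(r_max)) + 1)
    radii = np.linspace(0.0, r_max, n_steps)
    angles = np.linspace(0.0, 2.0 * np.pi, n_radii, endpoint=False)
    yy = (cy - y0) + radii[None, :] * np.sin(angles)[:, None]
    xx = (cx - x0) + radii[None, :] * np.cos(angles)[:, None]
    coords = np.stack([yy.ravel(), xx.ravel()])
    per_ray = np.empty((norm.shape[0], n_radii, n_steps))
    for c in range(norm.shape[0]):
        per_ray[c] = ndi.map_coordinates(norm[c], coords, order=1, mode="nearest").reshape(
            n_radii, n_steps
        )
    return RadialProfile(
        distances_um=radii * pixel_size_um,
        mean=per_ray.mean(axis=1),
        sd=per_ray.std(axis=1, ddof=0),
        per_ray=per_ray,
        n_radii=n_radii,
        radius_um=droplet.radius_px * pixel_size_um,
        pixel_size_um=pixel_size_um,
    )


def ratio_profile(
    profile: RadialProfile,
    eps: float = RATIO_EPS,
    per_ray: bool = False,
) -> RatioProfile:
    """Channel-1 / channel-2 ratio trace along the radius.

    By default the ratio of ray-averaged means is computed; with
    ``per_ray=True`` the per-ray ratios are averaged instead.  Distances
    where the channel-2 mean falls below ``eps`` are masked; if everything is
    masked the epsilon is evidently too large for this droplet and an error
    advises adjusting it.
    """
    ch1, ch2 = profile.mean[0], profile.mean[1]
    valid = ch2 >= eps
    if not valid.any():
        raise ValueError(
            f"entire ratio trace masked: channel-2 mean never reaches eps={eps}; "
            "lower eps or check the segmentation"
        )
    ray2 = profile.per_ray[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(ray2 >= eps, profile.per_ray[0] / np.where(ray2 == 0, np.nan, ray2), np.nan)
    rr = np.where(valid[None, :], rr, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN distance steps
        sd = np.nanstd(rr, axis=0)
        if per_ray:
            ratio = np.nanmean(rr, axis=0)
        else:
            ratio = np.where(valid, ch1 / np.where(valid, ch2, 1.0), np.nan)
    ratio = np.where(valid, ratio, np.nan)
    sd = np.where(valid, sd, np.nan)
    return RatioProfile(
        distances_um=profile.distances_um,
        ratio=ratio,
        mask=valid,
        sd=sd,
        radius_um=profile.radius_um,
    )


def shell_enrichment(
    profile: RadialProfile,
    core_fraction: float = 0.5,
    shell_fraction: float = 0.15,
    eps: float = RATIO_EPS,
) -> float:
    """Shell-to-core ratio of the channel-1/channel-2 trace.

    Mean ratio over the outer annulus (``radius*(1 - shell_fraction)`` to
    ``radius``) divided by the mean ratio over the core (0 to
    ``radius*core_fraction``).  Values above 1 flag a channel-1-rich shell;
    the statistic is reciprocal under swapping the channels' enrichment.
    """
    rp = ratio_profile(profile, eps=eps)
    r = rp.distances_um
    radius = rp.radius_um
    core = (r <= core_fraction * radius) & rp.mask
    shell = (r >= (1.0 - shell_fraction) * radius) & (r <= radius) & rp.mask
    if not shell.any():
        raise ValueError("shell annulus is fully masked; cannot form the statistic")
    if not core.any():
        raise ValueError("core region is fully masked; cannot form the statistic")
    return float(np.nanmean(rp.ratio[shell]) / np.nanmean(rp.ratio[core]))
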