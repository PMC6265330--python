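"""Synthetic-data generation with recorded ground truth.

Every input the analysis pipeline consumes can be generated here with known
ground truth: two-channel droplet scenes with configurable core--shell
enrichment, uniform fluorescent bead fixtures, dye calibration fields at known
concentration, hyperbolic FRAP recovery traces, a finite-difference FRAP
diffusion simulator, tracer partition scenes, rotor-dye droplet fields and
turbidity grids with a known saturation boundary.

All randomness flows from explicit integer seeds; identical seeds reproduce
outputs bit-for-bit, and noiseless outputs satisfy their defining formulas
exactly at every pixel / time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import ImageStack

__all__ = [
    "DropletSpec",
    "SceneSpec",
    "FrapTrace",
    "make_droplet_image",
    "make_bead_image",
    "make_partition_scene",
    "make_frap_trace",
    "simulate_frap_diffusion",
    "make_calibration_fields",
    "make_phase_grid",
]


# ---------------------------------------------------------------------------
# droplet scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropletSpec:
    """Geometry and per-channel intensity of one synthetic droplet.

    The radial intensity of channel ``c`` is ``amplitude_c * g_c(r)`` where
    ``g_c`` is 1 in the core, ``shell_factor_c`` in an outer top-hat annulus
    occupying the last ``shell_width_fraction`` of the radius, and falls
    linearly to 0 over ``edge_softness`` pixels centred on the radius.
    """

    center_xy: tuple[float, float]          # (x, y) in pixels
    radius: float                           # pixels
    channel_amplitudes: tuple[float, ...] = (1.0, 1.0)
    shell_factor_per_channel: tuple[float, ...] = (1.0, 1.0)
    shell_width_fraction: float = 0.0
    edge_softness: float = 1.0              # pixels
    center_z: float | None = None           # plane index; None = mid-stack

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.shell_width_fraction <= 0.5:
            raise ValueError("shell_width_fraction must lie in [0, 0.5]")
        if any(a < 0 for a in self.channel_amplitudes):
            raise ValueError("channel amplitudes must be >= 0")
        if any(s < 0 for s in self.shell_factor_per_channel):
            raise ValueError("shell factors must be >= 0")
        if self.edge_softness < 0:
            raise ValueError("edge_softness must be >= 0")
        if len(self.channel_amplitudes) != len(self.shell_factor_per_channel):
            raise ValueError("one shell factor per channel is required")

    @property
    def n_channels(self) -> int:
        return len(self.channel_amplitudes)

    def radial_intensity(self, channel: int, r) -> np.ndarray:
        """Analytic radial profile ``amplitude * g(r)`` (no background).

        This is the generator's own ground truth; analysis results are
        compared against it in tests.
        """
        r = np.asarray(r, dtype=float)
        inner = self.radius * (1.0 - self.shell_width_fraction)
        g = np.where(r < inner, 1.0, self.shell_factor_per_channel[channel])
        if self.edge_softness > 0:
            half = self.edge_softness / 2.0
            ramp = np.clip((self.radius + half - r) / self.edge_softness, 0.0, 1.0)
        else:
            ramp = (r <= self.radius).astype(float)
        return self.channel_amplitudes[channel] * g * ramp


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic field of view: geometry, photometry and noise."""

    image_shape: tuple[int, ...]            # (Y, X) or (Z, Y, X)
    droplets: tuple[DropletSpec, ...] = ()
    pixel_size_um: float = 0.1
    background_level: float = 0.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"           # "gaussian" or "poisson"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be (Y, X) or (Z, Y, X)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        object.__setattr__(self, "droplets", tuple(self.droplets))

    @property
    def yx_shape(self) -> tuple[int, int]:
        return tuple(self.image_shape[-2:])  # type: ignore[return-value]

    @property
    def n_planes(self) -> int:
        return self.image_shape[0] if len(self.image_shape) == 3 else 1


def _check_in_bounds(scene: SceneSpec) -> None:
    ny, nx = scene.yx_shape
    for i, d in enumerate(scene.droplets):
        reach = d.radius + d.edge_softness / 2.0
        cx, cy = d.center_xy
        if cx - reach < 0 or cy - reach < 0 or cx + reach > nx - 1 or cy + reach > ny - 1:
            raise ValueError(
                f"droplet {i} (center ({cx}, {cy}), radius {d.radius}, edge "
                f"softness {d.edge_softness}) extends beyond the "
                f"{ny}x{nx} image bounds"
            )


def _paint_plane(scene: SceneSpec, n_channels: int, dz: float = 0.0) -> np.ndarray:
    """Render one noiseless (C, Y, X) plane; dz = plane offset from droplet centre."""
    ny, nx = scene.yx_shape
    out = np.full((n_channels, ny, nx), float(scene.background_level))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for d in scene.droplets:
        if dz != 0.0:
            # spherical cross-section: in-plane radius shrinks with |dz|
            if abs(dz) >= d.radius:
                continue
            r_plane = math.sqrt(d.radius**2 - dz**2)
            d = DropletSpec(
                center_xy=d.center_xy,
                radius=r_plane,
                channel_amplitudes=d.channel_amplitudes,
                shell_factor_per_channel=d.shell_factor_per_channel,
                shell_width_fraction=d.shell_width_fraction,
                edge_softness=d.edge_softness,
            )
        cx, cy = d.center_xy
        r = np.hypot(xx - cx, yy - cy)
        for c in range(d.n_channels):
            out[c] += d.radial_intensity(c, r)
    return out


def _add_noise(data: np.ndarray, scene: SceneSpec) -> np.ndarray:
    if scene.noise_sigma == 0 and scene.noise_model == "gaussian":
        return data
    rng = np.random.default_rng(scene.rng_seed)
    if scene.noise_model == "gaussian":
        return data + rng.normal(0.0, scene.noise_sigma, size=data.shape)
    # Poisson shot noise on the expected photon count
    return rng.poisson(np.clip(data, 0, None)).astype(float)


def make_droplet_image(scene: SceneSpec) -> tuple[ImageStack, pd.DataFrame]:
    """Render a scene and return the image plus its ground-truth table.

    Each droplet's radial intensity in channel ``c`` is
    ``background + amplitude_c * g_c(r)`` (see :class:`DropletSpec`).
    The ground-truth table records centres, radii and profile parameters.
    """
    _check_in_bounds(scene)
    n_channels = max((d.n_channels for d in scene.droplets), default=2)
    if scene.n_planes == 1:
        data = _paint_plane(scene, n_channels)
    else:
        nz = scene.n_planes
        planes = []
        for z in range(nz):
            # per-droplet dz; droplets may sit at different planes
            ny, nx = scene.yx_shape
            plane = np.full((n_channels, ny, nx), float(scene.background_level))
            yy, xx = np.mgrid[0:ny, 0:nx]
            for d in scene.droplets:
                cz = d.center_z if d.center_z is not None else (nz - 1) / 2.0
                dz = z - cz
                if abs(dz) >= d.radius:
                    continue
                r_plane = math.sqrt(d.radius**2 - dz**2)
                cx, cy = d.center_xy
                r = np.hypot(xx - cx, yy - cy)
                sub = DropletSpec(
                    center_xy=d.center_xy,
                    radius=r_plane,
                    channel_amplitudes=d.channel_amplitudes,
                    shell_factor_per_channel=d.shell_factor_per_channel,
                    shell_width_fraction=d.shell_width_fraction,
                    edge_softness=d.edge_softness,
                )
                for c in range(d.n_channels):
                    plane[c] += sub.radial_intensity(c, r)
            planes.append(plane)
        data = np.stack(planes, axis=1)
    data = _add_noise(data, scene)
    stack = ImageStack(data, pixel_size_um=scene.pixel_size_um)
    rows = []
    for i, d in enumerate(scene.droplets):
        row: dict = {
            "droplet": i,
            "center_x": d.center_xy[0],
            "center_y": d.center_xy[1],
            "radius_px": d.radius,
            "radius_um": d.radius * scene.pixel_size_um,
            "shell_width_fraction": d.shell_width_fraction,
            "edge_softness": d.edge_softness,
        }
        for c in range(d.n_channels):
            row[f"amplitude_ch{c + 1}"] = d.channel_amplitudes[c]
            row[f"shell_factor_ch{c + 1}"] = d.shell_factor_per_channel[c]
        rows.append(row)
    truth = pd.DataFrame(rows)
    return stack, truth


def make_bead_image(
    shape: tuple[int, int],
    bead_radius: float,
    amplitudes: tuple[float, float] = (1.0, 1.0),
    center_xy: tuple[float, float] | None = None,
    background: float = 0.0,
    edge_softness: float = 1.0,
    pixel_size_um: float = 0.1,
) -> ImageStack:
    """Uniform fluorescent bead: an identical disk in both channels.

    The bead is the chromatic-control fixture: any apparent core--shell
    signal an analyzer reports on it is an artifact.
    """
    ny, nx = shape
    if center_xy is None:
        center_xy = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    scene = SceneSpec(
        image_shape=shape,
        droplets=(
            DropletSpec(
                center_xy=center_xy,
                radius=bead_radius,
                channel_amplitudes=tuple(amplitudes),
                shell_factor_per_channel=(1.0,) * len(amplitudes),
                edge_softness=edge_softness,
            ),
        ),
        background_level=background,
        pixel_size_um=pixel_size_um,
    )
    stack, _ = make_droplet_image(scene)
    return stack


def make_partition_scene(
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    radius: float,
    dense_intensity: float,
    light_intensity: float,
    marker_amplitude: float = 1000.0,
    edge_softness: float = 1.0,
    noise_sigma: float = 0.0,
    pixel_size_um: float = 0.1,
    rng_seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Scene for partition-coefficient measurement of an inert tracer.

    Channel 1 is a bright droplet marker (drives segmentation); channel 2 is
    the tracer, at ``light_intensity`` in the surrounding light phase and
    ``dense_intensity`` inside the droplet (either may be the larger — a
    tracer can be depleted from the dense phase, K < 1).  The true partition
    coefficient ``dense_intensity / light_intensity`` is returned alongside.
    """
    if dense_intensity < 0 or light_intensity <= 0:
        raise ValueError("intensities must be positive (light strictly)")
    ny, nx = shape
    cx, cy = center_xy
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - cx, yy - cy)
    if edge_softness > 0:
        inside = np.clip((radius + edge_softness / 2.0 - r) / edge_softness, 0.0, 1.0)
    else:
        inside = (r <= radius).astype(float)
    marker = marker_amplitude * inside
    tracer = light_intensity + (dense_intensity - light_intensity) * inside
    data = np.stack([marker, tracer])
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    truth = {
        "k_true": dense_intensity / light_intensity,
        "center_xy": center_xy,
        "radius_px": radius,
    }
    return ImageStack(data, pixel_size_um=pixel_size_um), truth


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapTrace:
    """A normalized FRAP recovery trace (pre-bleach mean = 1).

    ``times`` are seconds since the bleach; the first sample is the first
    post-bleach frame.  ``roi_radius_um`` is the radius of the circular
    bleached region.
    """

    times: np.ndarray
    intensities: np.ndarray
    roi_radius_um: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if t.ndim != 1 or i.shape != t.shape:
            raise ValueError("times and intensities must be equal-length 1D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be >= 0")
        if self.roi_radius_um <= 0:
            raise ValueError("roi_radius_um must be positive")


def hyperbolic_recovery(t, i0: float, i_inf: float, t_half: float):
    """The hyperbolic recovery model ``I(t) = (I0 + I_inf t/t_half) / (1 + t/t_half)``.

    ``I0`` is the intensity immediately after the bleach, ``I_inf`` the
    recovery plateau and ``t_half`` the half-recovery time
    (``I(t_half) = (I0 + I_inf)/2``).
    """
    x = np.asarray(t, dtype=float) / t_half
    return (i0 + i_inf * x) / (1.0 + x)


def make_frap_trace(
    i0: float,
    i_inf: float,
    t_half: float,
    times,
    noise_sigma: float = 0.0,
    seed: int = 0,
    roi_radius_um: float = 0.5,
) -> FrapTrace:
    """Generate a recovery trace from the hyperbolic model, plus optional noise."""
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if not (0.0 <= i0 <= i_inf <= 1.0):
        raise ValueError("require 0 <= i0 <= i_inf <= 1")
    times = np.asarray(times, dtype=float)
    values = hyperbolic_recovery(times, i0, i_inf, t_half)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sigma, size=values.shape), 0, None)
    return FrapTrace(times, values, roi_radius_um=roi_radius_um)


def simulate_frap_diffusion(
    d_coeff: float,
    droplet_radius: float,
    bleach_radius: float,
    mobile_fraction: float,
    times,
    grid_step: float = 0.2,
) -> FrapTrace:
    """Finite-difference FRAP simulation: free diffusion on a disk.

    Fluorophores diffuse with coefficient ``d_coeff`` (µm²/s) inside a disk of
    ``droplet_radius`` (µm) with a reflecting boundary; a fraction
    ``1 - mobile_fraction`` of the fluorescence is immobile.  At t = 0 a
    concentric disk of ``bleach_radius`` is fully photobleached.  The returned
    trace is the mean intensity over the bleached region, normalized so that
    the pre-bleach level is 1 (first returned sample is post-bleach).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if bleach_radius >= droplet_radius:
        raise ValueError("bleach_radius must be smaller than droplet_radius")
    if d_coeff < 0:
        raise ValueError("d_coeff must be >= 0")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if grid_step > bleach_radius / 2.0:
        raise ValueError(
            "unstable discretization: grid_step must be <= bleach_radius/2 "
            "to resolve the bleached region"
        )
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("first output time must be 0 (the post-bleach frame)")

    n = int(np.ceil(droplet_radius / grid_step)) * 2 + 3
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - c, yy - c) * grid_step
    disk = r <= droplet_radius
    roi = r <= bleach_radius

    mobile = np.where(disk, mobile_fraction, 0.0)
    immobile = np.where(disk, 1.0 - mobile_fraction, 0.0)
    mobile[roi] = 0.0
    immobile[roi] = 0.0

    # explicit FTCS scheme with no-flux boundary: dt under the 2D stability
    # bound dt <= h^2/(4D), with margin
    if d_coeff > 0:
        dt = 0.2 * grid_step**2 / d_coeff
    else:
        dt = np.inf

    neighbor_shifts = ((1, 0), (-1, 0), (0, 1), (0, -1))

    def laplacian(u: np.ndarray) -> np.ndarray:
        lap = np.zeros_like(u)
        for dy, dx in neighbor_shifts:
            v = np.roll(np.roll(u, dy, axis=0), dx, axis=1)
            vmask = np.roll(np.roll(disk, dy, axis=0), dx, axis=1)
            # reflecting boundary: outside-disk neighbours contribute nothing
            lap += np.where(disk & vmask, v - u, 0.0)
        return lap

    out = np.empty_like(times)
    t_now = 0.0
    for k, t_target in enumerate(times):
        while t_now < t_target - 1e-12:
            step = min(dt, t_target - t_now)
            mobile = mobile + (d_coeff * step / grid_step**2) * laplacian(mobile)
            t_now += step
        out[k] = (mobile[roi] + immobile[roi]).mean()
    return FrapTrace(times, out, roi_radius_um=bleach_radius)


# ---------------------------------------------------------------------------
# calibration fields
# ---------------------------------------------------------------------------

def make_calibration_fields(
    concentrations,
    slope: float,
    background: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    pixel_size_um: float = 0.1,
) -> list[ImageStack]:
    """Uniform dye fields, one per concentration, mean = background + slope*conc."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    fields = []
    for conc in concentrations:
        data = np.full((1, *shape), background + slope * conc)
        if noise_sigma > 0:
            data = data + rng.normal(0.0, noise_sigma, size=data.shape)
        fields.append(ImageStack(data, pixel_size_um=pixel_size_um))
    return fields


# ---------------------------------------------------------------------------
# turbidity grids
# ---------------------------------------------------------------------------

def make_phase_grid(
    conc_a_values,
    conc_b_values,
    crowder_levels,
    csat_model,
    od_max: float = 1.0,
    steepness: float = 5.0,
    replicates: int = 1,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Turbidity grid over (conc_a, conc_b, crowder) with a known c_sat boundary.

    ``od340 = od_max * sigmoid(steepness * (min(conc_a, conc_b) - csat))``
    where ``csat = csat_model(crowder_percent)`` must be monotone
    non-increasing in the crowder level (crowding promotes phase separation).
    Ground-truth saturation concentrations are returned per crowder level.
    """
    crowder_levels = list(crowder_levels)
    csats = [float(csat_model(c)) for c in crowder_levels]
    for (c1, s1), (c2, s2) in zip(
        sorted(zip(crowder_levels, csats)), sorted(zip(crowder_levels, csats))[1:]
    ):
        if s2 > s1 + 1e-12:
            raise ValueError("csat_model must be monotone non-increasing in crowder")
    rng = np.random.default_rng(seed)
    rows = []
    for crowder, csat in zip(crowder_levels, csats):
        for a in conc_a_values:
            for b in conc_b_values:
                x = steepness * (min(a, b) - csat)
                od = od_max / (1.0 + math.exp(-x))
                for rep in range(replicates):
                    od_obs = od
                    if noise_sigma > 0:
                        od_obs = max(0.0, od + rng.normal(0.0, noise_sigma))
                    rows.append(
                        {
                            "conc_a": float(a),
                            "conc_b": float(b),
                            "crowder_percent": float(crowder),
                            "replicate": rep,
                            "od340": od_obs,
                        }
                    )
    truth = {"csat": dict(zip(map(float, crowder_levels), csats))}
    return pd.DataFrame(rows), truth
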