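"""Fluorescence-to-concentration quantitation.

Mean droplet fluorescence is converted to total protein concentration via a
linear dye calibration curve, a labeled-fraction dilution factor (only a
fraction of the protein carries the dye) and a quantum-yield correction
factor for the viscous droplet interior (0.73 for the green dye, 1.43 for
the red dye by default):

    conc = ((I - intercept) / slope) / labeled_fraction / correction_factor

On top of this sit per-droplet molar ratios, partition coefficients
(dense-phase over light-phase intensity after background subtraction),
light-phase concentrations from plate-reader standard curves, and
photobleaching-corrected time-lapse composition traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCurve",
    "LabeledSample",
    "CalibrationError",
    "fit_calibration",
    "droplet_concentration",
    "molar_ratio",
    "MolarRatioResult",
    "partition_coefficient",
    "light_phase_concentration",
    "composition_traces",
]

#: quantum-yield correction factors inside the viscous dense phase
GREEN_CORRECTION = 0.73
RED_CORRECTION = 1.43


class CalibrationError(ValueError):
    """Raised when a calibration does not meet the linearity requirement."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between dye concentration (µM) and mean fluorescence.

    The curve carries the crowder condition it was measured under; lookups
    under a different condition are refused unless explicitly overridden,
    since crowders change dye quantum yield.
    """

    dye_name: str
    slope: float                 # intensity per µM
    intercept: float             # intensity
    r_squared: float
    crowder_condition: str = ""
    correction_factor: float = 1.0
    conc_range: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be positive")

    def intensity_to_labeled_conc(self, intensity) -> np.ndarray:
        return (np.asarray(intensity, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class LabeledSample:
    """Labeling stoichiometry of a protein sample (e.g. 10% dye-conjugated)."""

    labeled_fraction: float
    total_concentration_um: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in (0, 1]")


def fit_calibration(
    concentrations,
    mean_intensities,
    dye_name: str = "",
    crowder_condition: str = "",
    correction_factor: float = 1.0,
    min_r_squared: float = 0.95,
) -> CalibrationCurve:
    """Ordinary least-squares calibration line with a linearity gate.

    Refuses (raises :class:`CalibrationError`) when R² falls below
    ``min_r_squared`` — fluorescence must vary linearly with dye
    concentration for the quantitation chain to be valid.
    """
    conc = np.asarray(concentrations, dtype=float)
    intens = np.asarray(mean_intensities, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(conc).size < 2:
        raise ValueError("calibration concentrations must be distinct")
    slope, intercept = np.polyfit(conc, intens, 1)
    pred = slope * conc + intercept
    ss_res = float(np.sum((intens - pred) ** 2))
    ss_tot = float(np.sum((intens - intens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r_squared:
        raise CalibrationError(
            f"calibration nonlinear: R²={r2:.4f} < {min_r_squared}; "
            "check for dye saturation or quenching"
        )
    if slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return CalibrationCurve(
        dye_name=dye_name,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        crowder_condition=crowder_condition,
        correction_factor=correction_factor,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def droplet_concentration(
    mean_intensity,
    curve: CalibrationCurve,
    sample: LabeledSample,
    condition: str | None = None,
    allow_condition_mismatch: bool = False,
):
    """Total protein concentration (µM) inside a droplet from its mean intensity.

    Applies, in order: the calibration line (intensity -> labeled-dye
    concentration), the labeled-fraction dilution factor, and the
    quantum-yield correction factor.  Intensities below the calibration
    intercept map to 0 with a warning; intensities outside the calibrated
    range draw an extrapolation warning.
    """
    if condition is not None and condition != curve.crowder_condition and not allow_condition_mismatch:
        raise ValueError(
            f"calibration measured under '{curve.crowder_condition}' but lookup "
            f"requested under '{condition}'; pass allow_condition_mismatch=True to override"
        )
    labeled = curve.intensity_to_labeled_conc(mean_intensity)
    scalar = np.isscalar(mean_intensity)
    labeled = np.atleast_1d(labeled)
    if np.any(labeled < 0):
        warnings.warn("intensity below calibration intercept; concentration clipped to 0",
                      stacklevel=2)
        labeled = np.clip(labeled, 0.0, None)
    lo, hi = curve.conc_range
    if np.any((labeled < lo) | (labeled > hi)):
        warnings.warn("intensity outside calibrated range; extrapolating the line",
                      stacklevel=2)
    conc = labeled / sample.labeled_fraction / curve.correction_factor
    return float(conc[0]) if scalar else conc


@dataclass
class MolarRatioResult:
    """Per-droplet concentration ratios with distribution summary."""

    ratios: np.ndarray
    mean: float
    sd: float
    n_excluded: int


def molar_ratio(conc_a, conc_b) -> MolarRatioResult:
    """Per-droplet molar ratio ``conc_a / conc_b`` with mean and s.d.

    Droplets with a zero denominator concentration are excluded and counted.
    """
    a = np.atleast_1d(np.asarray(conc_a, dtype=float))
    b = np.atleast_1d(np.asarray(conc_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conc_a and conc_b must have the same shape")
    keep = b > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all droplets have zero denominator concentration")
    ratios = a[keep] / b[keep]
    return MolarRatioResult(
        ratios=ratios,
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        n_excluded=n_excluded,
    )


def partition_coefficient(
    dense_mean_intensity: float,
    light_mean_intensity: float,
    background: float = 0.0,
) -> float:
    """Partition coefficient ``K = dense / light`` after background subtraction.

    K < 1 means the species is depleted from the dense phase (an inert
    crowder excluded by the droplet mesh); K > 1 means enrichment.
    """
    light = light_mean_intensity - background
    if light <= 0:
        raise ValueError("light-phase intensity must exceed background")
    dense = dense_mean_intensity - background
    return float(dense / light)


def light_phase_concentration(
    reading: float,
    standard_concentrations,
    standard_readings,
    labeled_fraction: float = 1.0,
) -> float:
    """Total concentration (µM) in the light phase from a plate-reader reading.

    Linear interpolation on the standard curve, divided by the labeled
    fraction.  Readings outside the standard range draw an extrapolation
    warning (the nearer line segment is extended).
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must lie in (0, 1]")
    conc = np.asarray(standard_concentrations, dtype=float)
    reads = np.asarray(standard_readings, dtype=float)
    if conc.size < 2:
        raise ValueError("need at least 2 standards")
    order = np.argsort(reads)
    reads, conc = reads[order], conc[order]
    if np.any(np.diff(reads) <= 0):
        raise ValueError("standard readings must be strictly monotone in concentration")
    if reading < reads[0] or reading > reads[-1]:
        warnings.warn("reading outside the standard range; extrapolating", stacklevel=2)
        # extend the nearest segment
        if reading < reads[0]:
            i = 0
        else:
            i = reads.size - 2
        slope = (conc[i + 1] - conc[i]) / (reads[i + 1] - reads[i])
        labeled = conc[i] + slope * (reading - reads[i])
    else:
        labeled = float(np.interp(reading, reads, conc))
    return float(labeled / labeled_fraction)


def composition_traces(
    times,
    ch1_intensities,
    ch2_intensities,
    bleach_rate_ch1: float = 0.0,
    bleach_rate_ch2: float = 0.0,
):
    """Photobleaching-corrected time-lapse composition of droplets.

    Both channels are divided by ``exp(-k t)`` with their respective bleach
    rates; channel 1 is then normalized to its value at the first frame (the
    image acquired immediately after the perturbation), and the channel-2 /
    channel-1 ratio is computed pointwise.  Returns
    ``(ch1_normalized, ratio_ch2_over_ch1)``.
    """
    t = np.asarray(times, dtype=float)
    y1 = np.asarray(ch1_intensities, dtype=float)
    y2 = np.asarray(ch2_intensities, dtype=float)
    if t.size == 0:
        raise ValueError("t0 frame missing: empty time-lapse")
    if y1.shape != t.shape or y2.shape != t.shape:
        raise ValueError("intensity arrays must match the time axis")
    if bleach_rate_ch1 < 0 or bleach_rate_ch2 < 0:
        raise ValueError("bleach rates must be >= 0")
    c1 = y1 / np.exp(-bleach_rate_ch1 * (t - t[0]))
    c2 = y2 / np.exp(-bleach_rate_ch2 * (t - t[0]))
    if c1[0] <= 0:
        raise ValueError("t0 channel-1 intensity must be positive")
    norm1 = c1 / c1[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c1 > 0, c2 / c1, np.nan)
    return norm1, ratio
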