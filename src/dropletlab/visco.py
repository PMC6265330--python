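"""Molecular-rotor (DCVJ) viscometry.

DCVJ is a molecular rotor whose fluorescence quantum yield rises with
solvent viscosity, following Förster--Hoffmann power-law behaviour
``I = a * eta**x``.  A standard curve is built from glycerol/water mixtures
of known viscosity (computed with the Cheng exponential-blending mixture
formula), fitted as a line in log--log space, and inverted to estimate the
viscosity inside droplets from their mean rotor intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ViscosityCurve",
    "SplineViscosityCurve",
    "ViscosityEstimate",
    "glycerol_water_viscosity",
    "fit_rotor_curve",
    "estimate_viscosity",
]


def glycerol_water_viscosity(mass_fraction: float, temperature_c: float = 25.0) -> float:
    """Dynamic viscosity (mPa·s) of a glycerol/water mixture.

    Cheng's exponential-blending parameterization: the mixture viscosity is
    ``mu_w**alpha * mu_g**(1 - alpha)`` where the weighting exponent alpha
    depends on the glycerol mass fraction and temperature.  Valid for
    temperatures of 0-100 °C and the full composition range.
    """
    if not 0.0 <= mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in [0, 1]")
    if not 0.0 <= temperature_c <= 100.0:
        raise ValueError("temperature must lie in 0-100 °C")
    t = temperature_c
    mu_w = 1.790 * math.exp((-1230.0 - t) * t / (36100.0 + 360.0 * t))
    mu_g = 12100.0 * math.exp((-1233.0 + t) * t / (9900.0 + 70.0 * t))
    cm = mass_fraction
    a = 0.705 - 0.0017 * t
    b = (4.9 + 0.036 * t) * a**2.5
    alpha = 1.0 - cm + (a * b * cm * (1.0 - cm)) / (a * cm + b * (1.0 - cm))
    return mu_w**alpha * mu_g ** (1.0 - alpha)


@dataclass(frozen=True)
class ViscosityCurve:
    """Förster--Hoffmann rotor standard curve: log10(I) = exponent*log10(eta) + log_a.

    ``exponent`` is the rotor sensitivity (dimensionless, > 0);
    ``calibration_range_pa_s`` spans the standards' viscosities (Pa·s).
    """

    exponent: float
    log_intercept: float
    calibration_range_pa_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("rotor exponent must be positive (intensity rises with viscosity)")
        lo, hi = self.calibration_range_pa_s
        if not 0 < lo < hi:
            raise ValueError("calibration range must be non-empty and positive")

    def intensity(self, viscosity_pa_s) -> np.ndarray:
        """Predicted rotor intensity at a given viscosity (Pa·s)."""
        eta = np.asarray(viscosity_pa_s, dtype=float)
        return 10.0 ** (self.exponent * np.log10(eta) + self.log_intercept)


@dataclass(frozen=True)
class SplineViscosityCurve:
    """Monotone-spline rotor standard curve in log--log space.

    Fallback for dyes that deviate from single-power-law behaviour; exact
    through the standards, inverted via the monotone inverse spline.
    """

    log_eta: np.ndarray
    log_intensity: np.ndarray
    calibration_range_pa_s: tuple[float, float]
    _forward: PchipInterpolator = field(init=False, repr=False, compare=False)
    _inverse: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_forward",
                           PchipInterpolator(self.log_eta, self.log_intensity,
                                             extrapolate=True))
        object.__setattr__(self, "_inverse",
                           PchipInterpolator(self.log_intensity, self.log_eta,
                                             extrapolate=True))

    def intensity(self, viscosity_pa_s) -> np.ndarray:
        eta = np.asarray(viscosity_pa_s, dtype=float)
        return 10.0 ** self._forward(np.log10(eta))

    def invert_log10(self, log_intensity: float) -> float:
        return float(self._inverse(log_intensity))


@dataclass(frozen=True)
class ViscosityEstimate:
    """A viscosity estimate (Pa·s) with an extrapolation flag."""

    value_pa_s: float
    extrapolated: bool

    def __float__(self) -> float:
        return self.value_pa_s


def fit_rotor_curve(
    viscosities_pa_s, mean_intensities, form: str = "power"
) -> ViscosityCurve | SplineViscosityCurve:
    """Rotor standard curve through (viscosity, intensity) pairs.

    ``form="power"`` (default) fits a least-squares line in log--log space
    (Förster--Hoffmann behaviour); ``form="spline"`` interpolates a monotone
    spline through the standards instead, for dyes that deviate from a
    single power law.  Requires at least 3 standards spanning at least one
    decade of viscosity, with intensity monotone increasing in viscosity.
    """
    eta = np.asarray(viscosities_pa_s, dtype=float)
    intens = np.asarray(mean_intensities, dtype=float)
    if eta.size < 3:
        raise ValueError("need at least 3 standards")
    if np.any(eta <= 0) or np.any(intens <= 0):
        raise ValueError("viscosities and intensities must be positive")
    order = np.argsort(eta)
    eta, intens = eta[order], intens[order]
    if eta[-1] / eta[0] < 10.0:
        raise ValueError("standards must span at least one decade of viscosity")
    if np.any(np.diff(intens) <= 0):
        raise ValueError("standard intensities must increase monotonically with viscosity")
    if form == "spline":
        return SplineViscosityCurve(
            log_eta=np.log10(eta),
            log_intensity=np.log10(intens),
            calibration_range_pa_s=(float(eta[0]), float(eta[-1])),
        )
    if form != "power":
        raise ValueError("form must be 'power' or 'spline'")
    slope, intercept = np.polyfit(np.log10(eta), np.log10(intens), 1)
    return ViscosityCurve(
        exponent=float(slope),
        log_intercept=float(intercept),
        calibration_range_pa_s=(float(eta[0]), float(eta[-1])),
    )


def estimate_viscosity(
    droplet_mean_intensity: float, curve: ViscosityCurve | SplineViscosityCurve
) -> ViscosityEstimate:
    """Invert the rotor standard curve at a droplet's mean intensity.

    Intensities mapping outside the calibrated viscosity range are still
    converted but flagged as extrapolated.
    """
    if droplet_mean_intensity <= 0:
        raise ValueError("intensity must be positive")
    log_i = math.log10(droplet_mean_intensity)
    if isinstance(curve, SplineViscosityCurve):
        log_eta = curve.invert_log10(log_i)
    else:
        log_eta = (log_i - curve.log_intercept) / curve.exponent
    eta = 10.0**log_eta
    lo, hi = curve.calibration_range_pa_s
    in_range = lo * (1.0 - 1e-9) <= eta <= hi * (1.0 + 1e-9)
    return ViscosityEstimate(value_pa_s=float(eta), extrapolated=not in_range)
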