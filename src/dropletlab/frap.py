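"""FRAP trace processing: bleach correction, recovery fitting, diffusion.

Recovery curves (normalized so the pre-bleach level is 1) are fitted to the
hyperbolic model

    I(t) = (I0 + I_inf * t/t_half) / (1 + t/t_half)

where I0 is the intensity immediately after the bleach, I_inf the recovery
plateau and t_half the half-recovery time.  The mobile fraction is
Mf = (I_inf - I0)/(1 - I0), and the apparent diffusion coefficient follows
from the half-time of recovery of a uniformly bleached circular spot,

    D_app = 0.224 * r**2 / t_half

with r the radius of the bleached circle.  Because D scales inversely with
viscosity, a hypothetical fold-change in droplet viscosity rescales t_half
proportionally, which lets the fitted model predict the recovered fraction
within any observation window under that viscosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthgen import FrapTrace, hyperbolic_recovery

__all__ = [
    "FrapFit",
    "fit_bleach_exponential",
    "correct_photobleaching",
    "normalize_trace",
    "fit_recovery",
    "apparent_d",
    "predict_recovery_under_viscosity",
]

#: default bleached-spot radius, µm (a 1 µm diameter circular ROI)
DEFAULT_ROI_RADIUS_UM = 0.5

#: Soumpasis prefactor relating the bleached-disk radius and half-time to D
D_APP_PREFACTOR = 0.224


@dataclass
class FrapFit:
    """Fitted hyperbolic recovery parameters and derived quantities.

    ``mobile_fraction`` is clipped to [0, 1]; the raw (unclipped) value is
    kept in ``mobile_fraction_raw``.  ``low_confidence`` is set when the
    plateau is not constrained by the data (no recovery, or the trace ends
    before one half-time).
    """

    i0: float
    i_inf: float
    t_half: float
    mobile_fraction: float
    mobile_fraction_raw: float
    d_app: float
    residual_rms: float
    covariance: np.ndarray | None = None
    roi_radius_um: float = DEFAULT_ROI_RADIUS_UM
    low_confidence: bool = False
    warnings: tuple[str, ...] = field(default=())


def fit_bleach_exponential(reference_times, reference_intensities) -> tuple[float, float]:
    """Fit ``A * exp(-k t)`` to an unbleached-reference trace.

    Returns ``(decay_rate, amplitude)`` with the decay rate constrained to be
    non-negative; a non-decaying reference yields ``k = 0`` with a warning.
    """
    t = np.asarray(reference_times, dtype=float)
    y = np.asarray(reference_intensities, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 reference points")
    if np.any(y <= 0):
        raise ValueError("reference intensities must be positive")
    # log-linear initializer, then nonlinear refinement
    slope, intercept = np.polyfit(t, np.log(y), 1)
    # tolerance absorbs floating-point jitter on a perfectly flat reference
    if slope >= -1e-12 * max(1.0, abs(np.log(y).mean())):
        warnings.warn("reference trace does not decay; decay rate set to 0", stacklevel=2)
        return 0.0, float(np.mean(y))
    p0 = (float(np.exp(intercept)), float(-slope))
    popt, _ = curve_fit(
        lambda tt, a, k: a * np.exp(-k * tt), t, y, p0=p0,
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
    )
    amplitude, rate = float(popt[0]), float(popt[1])
    return rate, amplitude


def correct_photobleaching(trace: FrapTrace, decay_rate: float) -> FrapTrace:
    """Divide a trace by ``exp(-decay_rate * t)`` to undo acquisition bleaching."""
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    corrected = trace.intensities / np.exp(-decay_rate * trace.times)
    return FrapTrace(trace.times, corrected, roi_radius_um=trace.roi_radius_um)


def normalize_trace(times, intensities, n_prebleach: int, roi_radius_um: float = DEFAULT_ROI_RADIUS_UM) -> FrapTrace:
    """Normalize a raw trace to its pre-bleach mean and drop the pre-bleach frames.

    The first ``n_prebleach`` samples are averaged to define the unbleached
    level; the returned trace starts at the first post-bleach frame with its
    time origin reset to 0.  A bleach depth shallower than 50% of the
    pre-bleach level draws a validation warning.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if n_prebleach < 1 or n_prebleach >= t.size:
        raise ValueError("n_prebleach must leave at least one post-bleach frame")
    pre = y[:n_prebleach].mean()
    if pre <= 0:
        raise ValueError("pre-bleach mean must be positive")
    post = y[n_prebleach:] / pre
    if post[0] > 0.5:
        warnings.warn(
            f"bleach depth reaches only {post[0]:.2f} of the pre-bleach level "
            "(expected <= 0.5)", stacklevel=2,
        )
    return FrapTrace(t[n_prebleach:] - t[n_prebleach], np.clip(post, 0, None),
                     roi_radius_um=roi_radius_um)


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Nonlinear least-squares fit of the hyperbolic recovery model.

    The initializer is deterministic: I0 from the first sample, I_inf from
    the last, t_half from the sample closest to the midpoint between them.
    A trace showing no recovery returns a zero-mobile-fraction fit flagged
    low-confidence rather than failing.
    """
    t = trace.times
    y = trace.intensities
    if t.size < 4:
        raise ValueError("need at least 4 samples to fit the recovery model")
    i0_guess = float(y[0])
    iinf_guess = float(y[-1])
    notes: list[str] = []

    if iinf_guess - i0_guess < 1e-6:
        # flat trace: plateau (and t_half) unidentifiable
        mf_raw = 0.0
        return FrapFit(
            i0=i0_guess, i_inf=iinf_guess, t_half=float("nan"),
            mobile_fraction=0.0, mobile_fraction_raw=mf_raw,
            d_app=float("nan"), residual_rms=float(np.std(y - y.mean())),
            covariance=None, roi_radius_um=trace.roi_radius_um,
            low_confidence=True, warnings=("no recovery detected; t_half unidentifiable",),
        )

    midpoint = (i0_guess + iinf_guess) / 2.0
    t_half_guess = float(t[np.argmin(np.abs(y - midpoint))])
    if t_half_guess <= 0:
        t_half_guess = float(t[1]) if t[0] == 0 else float(t[0])
    p0 = (i0_guess, iinf_guess, t_half_guess)
    try:
        popt, pcov = curve_fit(
            hyperbolic_recovery, t, y, p0=p0,
            bounds=([0.0, 0.0, 1e-12], [1.5, 1.5, np.inf]), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"recovery fit did not converge (initializer I0={p0[0]:.3g}, "
            f"I_inf={p0[1]:.3g}, t_half={p0[2]:.3g} s): {err}"
        ) from err
    i0, i_inf, t_half = map(float, popt)
    if i_inf < i0:
        # hyperbola fitted "backwards"; treat as no recovery
        notes.append("fitted plateau below bleach level")
    low_confidence = False
    if t[-1] < t_half:
        low_confidence = True
        notes.append("trace ends before one half-time; plateau poorly constrained")
    denom = 1.0 - i0
    mf_raw = (i_inf - i0) / denom if abs(denom) > 1e-9 else float("nan")
    residuals = y - hyperbolic_recovery(t, i0, i_inf, t_half)
    return FrapFit(
        i0=i0, i_inf=i_inf, t_half=t_half,
        mobile_fraction=float(np.clip(mf_raw, 0.0, 1.0)),
        mobile_fraction_raw=float(mf_raw),
        d_app=apparent_d(t_half, trace.roi_radius_um),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        covariance=pcov, roi_radius_um=trace.roi_radius_um,
        low_confidence=low_confidence, warnings=tuple(notes),
    )


def apparent_d(t_half: float, roi_radius_um: float = DEFAULT_ROI_RADIUS_UM) -> float:
    """Apparent diffusion coefficient ``0.224 r**2 / t_half`` in µm²/s."""
    if t_half <= 0 or roi_radius_um <= 0:
        raise ValueError("t_half and roi_radius_um must be positive")
    return D_APP_PREFACTOR * roi_radius_um**2 / t_half


def predict_recovery_under_viscosity(fit: FrapFit, viscosity_fold: float, window: float) -> float:
    """Fraction of fluorescence recovered within ``window`` seconds if the
    droplet viscosity were ``viscosity_fold`` times higher.

    D scales as 1/viscosity, so t_half scales proportionally to viscosity;
    the recovered fraction is ``Mf * x / (1 + x)`` with
    ``x = window / (t_half * viscosity_fold)``.  Monotone decreasing in the
    fold-change and increasing in the window.
    """
    if viscosity_fold < 1:
        raise ValueError("viscosity_fold must be >= 1")
    if window < 0:
        raise ValueError("window must be >= 0")
    x = window / (fit.t_half * viscosity_fold)
    return float(fit.mobile_fraction * x / (1.0 + x))
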