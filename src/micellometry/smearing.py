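"""Slit (line-beam) smearing and its inverse, plus curve smoothing and
absolute scaling — the reduction chain for Kratky-camera data.

A line-shaped beam integrates intensity along the slit length, so the
observed curve is

    Ĩ(q) = 2 ∫₀^tmax W(t) I(sqrt(q² + t²)) dt

with a symmetric beam-length profile W normalized as ∫₀^tmax W dt = 1/2.
Desmearing uses an iterative multiplicative correction (Lake-type): each
iterate is re-smeared and the observed/smeared ratio applied pointwise.
The round trip desmear(slit_smear(curve)) is the module's oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import ScatteringCurve
from .errors import InputError, NumericalError, StateError

log = logging.getLogger(__name__)

__all__ = ["SlitProfile", "slit_smear", "desmear", "smooth_curve", "absolute_scale"]

WATER_ABSOLUTE_REFERENCE = 1.68e-2  # standard scattering level of water
_FLOOR = 1e-12


@dataclass
class SlitProfile:
    """Tabulated beam-length weighting kernel W(t), t in Å⁻¹.

    ``t`` runs from 0 and W is renormalized on construction so that
    ∫₀^tmax W dt = 1/2 (the half-line of a symmetric kernel).
    """

    t: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.w.shape or self.t.size < 2:
            raise InputError("profile needs matching 1D t and W arrays (>= 2 points)")
        if self.t[0] != 0 or np.any(np.diff(self.t) <= 0):
            raise InputError("t grid must increase strictly from 0")
        if np.any(self.w < 0):
            raise InputError("W(t) must be non-negative")
        norm = np.trapezoid(self.w, self.t)
        if norm <= 0:
            raise InputError("W(t) integrates to zero")
        self.w = self.w / (2.0 * norm)

    @property
    def t_max(self) -> float:
        return float(self.t[-1])

    @classmethod
    def trapezoidal(cls, t1: float, t_max: float, n: int = 51) -> "SlitProfile":
        """Flat to ``t1`` then linear to zero at ``t_max`` — the typical
        line-collimation beam-length profile."""
        if not (0 <= t1 < t_max):
            raise InputError("need 0 <= t1 < t_max")
        t = np.linspace(0.0, t_max, n)
        w = np.where(t <= t1, 1.0, (t_max - t) / (t_max - t1))
        return cls(t, w)


def _tail_power_law(curve: ScatteringCurve):
    """Fit I = A q^m over the top half-decade of q for tail extrapolation."""
    q, i = curve.q, np.maximum(curve.intensity, _FLOOR)
    mask = q >= curve.q[-1] / np.sqrt(10.0)
    if mask.sum() < 3:
        mask = np.zeros_like(q, bool)
        mask[-3:] = True
    slope, intercept = np.polyfit(np.log(q[mask]), np.log(i[mask]), 1)
    return float(np.exp(intercept)), float(slope)


def _evaluate_extended(curve: ScatteringCurve, q_eval: np.ndarray) -> np.ndarray:
    """Interpolate I(q) inside the measured range, power-law beyond it."""
    amp, exponent = _tail_power_law(curve)
    out = np.interp(q_eval, curve.q, curve.intensity)
    beyond = q_eval > curve.q[-1]
    out[beyond] = amp * q_eval[beyond] ** exponent
    return out


def slit_smear(curve: ScatteringCurve, profile: SlitProfile) -> ScatteringCurve:
    """Apply the slit-smearing integral to an unsmeared curve.

    Beyond the measured q range the curve is extrapolated as a power-law
    tail fitted to the last half-decade of points.
    """
    if curve.smeared:
        raise StateError("curve is already slit-smeared")
    q = curve.q
    t = profile.t
    q_arg = np.sqrt(q[:, None] ** 2 + t[None, :] ** 2)
    i_arg = _evaluate_extended(curve, q_arg.ravel()).reshape(q_arg.shape)
    smeared = 2.0 * np.trapezoid(profile.w[None, :] * i_arg, t, axis=1)
    out = curve.with_intensity(smeared, sigma=curve.sigma)
    out.smeared = True
    return out


def desmear(curve: ScatteringCurve, profile: SlitProfile,
            max_iter: int = 20, tol: float = 1e-4) -> ScatteringCurve:
    """Iterative multiplicative (Lake-type) desmearing of a slit-smeared curve.

    I⁽ᵏ⁺¹⁾ = I⁽ᵏ⁾ · Ĩ_obs / smear(I⁽ᵏ⁾), started from I⁽⁰⁾ = Ĩ_obs and
    stopped when the maximum relative change falls below ``tol``.  The
    default iteration cap doubles as mild regularization: running the
    scheme to full convergence inverts the smearing exactly and maximally
    amplifies measurement noise.  On non-convergence the best iterate is
    returned with a warning and a diagnostic in the metadata.
    Uncertainties are propagated by preserving each point's relative
    error (σ/I), the standard approximation for the multiplicative
    scheme.  Non-positive observed intensities are clipped to a small
    positive floor (with a warning), as the scheme requires positivity.
    """
    if not curve.smeared:
        raise StateError("curve is not flagged as smeared")
    obs = curve.intensity
    if np.any(obs <= 0):
        log.warning("desmear: %d non-positive intensities clipped to floor",
                    int(np.sum(obs <= 0)))
        obs = np.maximum(obs, _FLOOR)
    work = ScatteringCurve(curve.q, obs.copy(), sigma=curve.sigma, smeared=False,
                           meta=dict(curve.meta))
    converged = False
    n_done = max_iter
    for iteration in range(1, max_iter + 1):
        resmeared = slit_smear(work, profile).intensity
        ratio = obs / np.maximum(resmeared, _FLOOR)
        new = work.intensity * ratio
        change = float(np.max(np.abs(new - work.intensity) /
                              np.maximum(np.abs(work.intensity), _FLOOR)))
        work = work.with_intensity(new, sigma=curve.sigma)
        if change < tol:
            converged = True
            n_done = iteration
            break
    if not converged:
        # slow residual drift is expected for noisy data (the fully
        # converged limit would amplify noise); only a large final change
        # indicates a real problem
        level = log.warning if change > 0.05 else log.debug
        level("desmear stopped after %d iterations (last change %.3g)",
              max_iter, change)
    if curve.sigma is not None:
        rel = curve.sigma / np.maximum(np.abs(obs), _FLOOR)
        work.sigma = rel * np.abs(work.intensity)
    work.meta.update(desmear_iterations=n_done, desmear_converged=converged)
    work.smeared = False
    return work


def smooth_curve(curve: ScatteringCurve, window: int = 11) -> ScatteringCurve:
    """Cubic moving-polynomial smoothing (Savitzky–Golay).

    Each point is replaced by the value at its q of a third-degree
    least-squares polynomial fitted over its ``window`` neighbours; edges
    use polynomial extrapolation of the terminal windows.  A curve that is
    exactly cubic in q is reproduced to machine precision.
    """
    if window < 5 or window % 2 == 0:
        raise InputError("window must be odd and >= 5")
    if window > len(curve):
        raise InputError("window exceeds curve length")
    smoothed = savgol_filter(curve.intensity, window_length=window, polyorder=3,
                             mode="interp")
    return curve.with_intensity(smoothed, sigma=curve.sigma, smoothing_window=window)


def absolute_scale(curve: ScatteringCurve, transmission: float,
                   measured_water_level: float,
                   water_reference: float = WATER_ABSOLUTE_REFERENCE) -> ScatteringCurve:
    """Put a solvent-subtracted curve on absolute scale against water.

    Multiplies intensity by ``water_reference / (transmission ·
    measured_water_level)`` where ``measured_water_level`` is the observed
    flat scattering level of pure water on the instrument's arbitrary
    scale.  The factor is recorded in the metadata and a second
    application raises.
    """
    if not (0 < transmission <= 1):
        raise InputError("transmission must lie in (0, 1]")
    if water_reference <= 0:
        raise InputError("water reference must be positive")
    if measured_water_level <= 0:
        raise NumericalError("measured water level must be positive")
    if curve.meta.get("absolute_scale_factor") is not None:
        raise StateError("curve is already on absolute scale")
    factor = water_reference / (transmission * measured_water_level)
    sigma = None if curve.sigma is None else curve.sigma * factor
    return curve.with_intensity(curve.intensity * factor, sigma=sigma,
                                absolute_scale_factor=factor)
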