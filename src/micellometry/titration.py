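"""Henderson–Hasselbalch titration fitting.

A fluorophore whose emission maximum differs between the protonated and
deprotonated state traces a sigmoid in pH:

    λ(pH) = λ_A + (λ_B − λ_A) / (1 + 10^(pKa − pH)),

the titration form of pH = pKa + log([A⁻]/[HA]).  ``hh_fit`` recovers the
three parameters by nonlinear least squares with automatic initialization
and reports the pKa standard error from the fit covariance.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import PkaFit, TitrationCurve
from .errors import InputError, NumericalError

__all__ = ["hh_sigmoid", "hh_fit"]


def hh_sigmoid(ph, pka, lambda_acid, lambda_base):
    """Henderson–Hasselbalch emission sigmoid."""
    ph = np.asarray(ph, dtype=float)
    return lambda_acid + (lambda_base - lambda_acid) / (1.0 + 10.0 ** (pka - ph))


def _auto_init(curve: TitrationCurve):
    lam_a = float(curve.wavelength[:3].mean())
    lam_b = float(curve.wavelength[-3:].mean())
    half = 0.5 * (lam_a + lam_b)
    # pKa guess: pH of the half-height crossing by interpolation
    w = curve.wavelength
    sign = np.sign(w - half)
    crossings = np.nonzero(np.diff(sign))[0]
    if crossings.size:
        i = crossings[0]
        frac = (half - w[i]) / (w[i + 1] - w[i]) if w[i + 1] != w[i] else 0.5
        pka0 = float(curve.ph[i] + frac * (curve.ph[i + 1] - curve.ph[i]))
    else:
        pka0 = float(np.median(curve.ph))
    return pka0, lam_a, lam_b


def hh_fit(curve: TitrationCurve, init: Optional[Sequence[float]] = None,
           weights: Optional[np.ndarray] = None) -> PkaFit:
    """Fit the Henderson–Hasselbalch sigmoid to a titration curve.

    ``init`` is (pKa, λ_acid, λ_base) or ``None`` for automatic
    initialization (plateaus from the three extreme points on each side,
    pKa from the half-height crossing).  The fit is unweighted unless
    per-point ``weights`` (1/σ) are given.  The pKa is box-constrained to
    (0, 14); data with no transition inside the pH range raise.
    """
    if len(curve) < 5:
        raise InputError("titration fit needs at least 5 points")
    p0 = tuple(init) if init is not None else _auto_init(curve)
    if len(p0) != 3:
        raise InputError("init must be (pKa, lambda_acid, lambda_base)")
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    span = float(curve.wavelength.max() - curve.wavelength.min())
    lo = curve.wavelength.min() - 10 * max(span, 1.0)
    hi = curve.wavelength.max() + 10 * max(span, 1.0)
    try:
        popt, pcov = curve_fit(
            hh_sigmoid, curve.ph, curve.wavelength, p0=p0, sigma=sigma,
            bounds=([1e-6, lo, lo], [14.0 - 1e-6, hi, hi]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise NumericalError(f"titration fit failed to converge: {exc}")
    pka, lam_a, lam_b = (float(v) for v in popt)
    resid = curve.wavelength - hh_sigmoid(curve.ph, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    # non-identifiable: transition outside the measured range or no contrast
    if pka <= curve.ph[0] - 1 or pka >= curve.ph[-1] + 1:
        raise NumericalError("no transition inside the measured pH range")
    if abs(lam_b - lam_a) < 5 * rms and abs(lam_b - lam_a) < 1e-6 * max(abs(lam_a), 1.0):
        raise NumericalError("titration data show no transition (flat signal)")
    if lam_a == lam_b:
        raise NumericalError("degenerate fit: plateaus coincide")
    return PkaFit(pka=pka, plateau_acid=lam_a, plateau_base=lam_b,
                  pka_stderr=stderr, residual_rms=rms)
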