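"""Forward scattering from bead models and analytic references.

The Debye sum

    I(q) = Σ_i Σ_j w_i w_j sin(q r_ij) / (q r_ij)

is the exact scattering intensity of a set of point scatterers and serves
as the forward model when comparing coordinate models against measured
curves (the role a hydration-shell program plays for atomistic models —
here without any shell contrast).  The exact pair-distance histogram
``pr_exact`` and its sine transform ``back_transform`` form the module's
central consistency oracle: back_transform(pr_exact(m)) ≈ debye_intensity(m).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .datatypes import BeadModel, PairDistribution, ScatteringCurve
from .errors import InputError, NumericalError

__all__ = [
    "debye_intensity",
    "sphere_form_factor",
    "sphere_pr",
    "pr_exact",
    "back_transform",
    "scale_to",
]

# Pair-chunk size bounding peak memory of the Debye sum (~8 bytes/pair ⇒
# ~400 MB per work array).
_PAIR_CHUNK = 50_000_000


def debye_intensity(model: BeadModel, q_grid) -> ScatteringCurve:
    """Exact Debye intensity of a bead model on ``q_grid`` (Å⁻¹).

    The absolute prefactor is arbitrary (curves are later matched by a
    scale factor); self terms contribute Σ w_i² and sin(x)/x is evaluated
    as 1 at x = 0, so I(q→0) = (Σ w_i)².
    """
    if model is None or len(model) == 0:
        raise InputError("empty bead model")
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise InputError("q grid must be strictly positive")
    w = model.weights
    self_term = float(np.sum(w * w))
    if len(model) == 1:
        return ScatteringCurve(q, np.full_like(q, self_term))
    d = pdist(model.positions)
    uniform = np.allclose(w, w[0])
    wprod = None if uniform else _pair_products(w)
    intensity = np.full(q.shape, self_term)
    for start in range(0, d.size, _PAIR_CHUNK):
        dc = d[start:start + _PAIR_CHUNK]
        wc = None if uniform else wprod[start:start + _PAIR_CHUNK]
        for k, qk in enumerate(q):
            sinc = np.sinc(qk * dc / np.pi)  # sin(x)/x with sinc(x/pi)
            intensity[k] += 2.0 * (w[0] ** 2 * sinc.sum() if uniform else (wc * sinc).sum())
    return ScatteringCurve(q, intensity, meta={"model": model.label})


def _pair_products(w):
    n = w.size
    iu, ju = np.triu_indices(n, k=1)
    return w[iu] * w[ju]


def sphere_form_factor(radius: float, q_grid, i0: float = 1.0) -> ScatteringCurve:
    """Analytic form factor of a uniform sphere, normalized to I(0)=i0.

    I(q)/I(0) = [3 (sin qR − qR cos qR) / (qR)³]².
    """
    if radius <= 0:
        raise InputError("sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    # series branch: the closed form loses all precision for qR → 0
    small = x < 1e-2
    amp = np.where(small, 1.0 - x**2 / 10.0 + x**4 / 280.0, amp)
    return ScatteringCurve(q, i0 * amp**2)


def sphere_pr(radius: float, r_grid=None, n_points: int = 201) -> PairDistribution:
    """Closed-form p(r) of a uniform sphere of radius R.

    p(r) ∝ r² (1 − 3x/2 + x³/2) with x = r/(2R); zero beyond D_max = 2R.
    """
    if radius <= 0:
        raise InputError("sphere radius must be positive")
    d_max = 2.0 * radius
    r = np.linspace(0, d_max, n_points) if r_grid is None else np.asarray(r_grid, float)
    x = np.clip(r / d_max, 0, 1)
    p = np.where(r <= d_max, r**2 * (1 - 1.5 * x + 0.5 * x**3), 0.0)
    return PairDistribution(r, p, d_max=d_max)


def pr_exact(model: BeadModel, bin_width: float) -> PairDistribution:
    """Weighted histogram of all pairwise distances of a bead model.

    Bin k covers [k·Δ, (k+1)·Δ); the stored r grid holds bin centres and
    D_max is the largest pairwise distance.  The histogram is normalized
    as a density, p(r) = Σ_{i<j} w_i w_j δ(r − r_ij) / (2π), so that
    ``back_transform`` applied to it reproduces ``debye_intensity`` (up to
    the Σw² self term, negligible for large models).
    """
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    if len(model) < 2:
        raise NumericalError("p(r) of a single bead is degenerate")
    d = pdist(model.positions)
    d_max = float(d.max())
    if d_max == 0:
        raise NumericalError("all beads coincide; p(r) is degenerate")
    n_bins = int(np.ceil(d_max / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    w = model.weights
    uniform = np.allclose(w, w[0])
    weights = None if uniform else _pair_products(w)
    hist, _ = np.histogram(d, bins=edges, weights=weights)
    if uniform:
        hist = hist * (w[0] ** 2)
    centres = 0.5 * (edges[:-1] + edges[1:])
    density = hist.astype(float) / (2.0 * np.pi * bin_width)
    return PairDistribution(centres, density, d_max=d_max)


def back_transform(pr: PairDistribution, q_grid) -> ScatteringCurve:
    """Sine transform of p(r):  I(q) = 4π ∫₀^Dmax p(r) sin(qr)/(qr) dr.

    Trapezoid quadrature on the stored r grid; I(0⁺) → 4π ∫ p dr.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise InputError("q grid must be strictly positive")
    kernel = np.sinc(np.outer(q, pr.r) / np.pi)
    intensity = 4.0 * np.pi * np.trapezoid(kernel * pr.p, pr.r, axis=1)
    return ScatteringCurve(q, intensity)


def scale_to(theoretical: ScatteringCurve, experimental: ScatteringCurve):
    """Least-squares scale of a theoretical curve onto an experimental one.

    The theoretical curve is linearly interpolated onto the experimental q
    grid (points outside the overlap are dropped).  Returns ``(scale, chi)``
    where ``scale`` minimizes Σ[(I_exp − s·I_th)/σ]² and
    ``chi = sqrt(min / (n − 1))``; σ = 1 where the experimental curve has
    no uncertainties.
    """
    lo = max(theoretical.q[0], experimental.q[0])
    hi = min(theoretical.q[-1], experimental.q[-1])
    mask = (experimental.q >= lo) & (experimental.q <= hi)
    if not np.any(mask):
        raise InputError("theoretical and experimental q ranges do not overlap")
    q = experimental.q[mask]
    i_exp = experimental.intensity[mask]
    sig = experimental.sigma[mask] if experimental.sigma is not None else np.ones_like(q)
    sig = np.where(sig > 0, sig, 1.0)
    i_th = np.interp(q, theoretical.q, theoretical.intensity)
    denom = float(np.sum((i_th / sig) ** 2))
    if denom == 0:
        raise NumericalError("theoretical curve is identically zero; scale undefined")
    scale = float(np.sum(i_exp * i_th / sig**2) / denom)
    resid = (i_exp - scale * i_th) / sig
    n = q.size
    chi = float(np.sqrt(np.sum(resid**2) / max(n - 1, 1)))
    return scale, chi
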