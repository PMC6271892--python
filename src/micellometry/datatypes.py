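"""Core in-memory containers shared by every analysis stage.

All lengths are in Å, scattering vectors in Å⁻¹, intensities in cm⁻¹ once
a curve has been put on absolute scale.  Containers validate their
invariants on construction and raise :class:`~micellometry.errors.InputError`
rather than silently repairing bad data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import GeometryError, InputError

__all__ = [
    "ScatteringCurve",
    "PairDistribution",
    "BeadModel",
    "GroundTruth",
    "CoordinateSet",
    "TitrationCurve",
    "MicelleGeometry",
    "ShapeReport",
    "RDFProfile",
    "DihedralSpec",
    "PkaFit",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ScatteringCurve:
    """A 1D scattering profile I(q).

    Parameters
    ----------
    q : array
        Scattering vector magnitudes, Å⁻¹; strictly increasing and positive.
    intensity : array
        Intensities, cm⁻¹ on absolute scale (arbitrary units otherwise).
    sigma : array, optional
        1-σ uncertainties in the same units as ``intensity``.  Absent means
        unweighted fits downstream.
    smeared : bool
        Whether the curve carries slit (line-beam) smearing.
    meta : dict
        Free-form metadata: wavelength (Å), sample label, concentration
        (wt%), absolute-scale factor, ...
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    smeared: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_1d(self.q, "q")
        self.intensity = _as_1d(self.intensity, "intensity")
        if self.q.size == 0:
            raise InputError("scattering curve is empty")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise InputError("q and intensity must be finite")
        if np.any(self.q <= 0):
            raise InputError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise InputError("q must be strictly increasing")
        if self.intensity.shape != self.q.shape:
            raise InputError("q and intensity lengths differ")
        if self.sigma is not None:
            self.sigma = _as_1d(self.sigma, "sigma")
            if self.sigma.shape != self.q.shape:
                raise InputError("sigma length differs from q")
            if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma < 0):
                raise InputError("sigma must be finite and non-negative")
        self.meta = dict(self.meta)

    def __len__(self) -> int:
        return self.q.size

    def with_intensity(self, intensity, sigma=None, **meta_updates) -> "ScatteringCurve":
        """Copy of this curve with new intensities (same q grid)."""
        new = replace(
            self,
            intensity=np.asarray(intensity, dtype=float),
            sigma=None if sigma is None else np.asarray(sigma, dtype=float),
        )
        new.meta.update(meta_updates)
        return new


@dataclass
class PairDistribution:
    """Pair-distance distribution p(r) on [0, D_max].

    ``p(0) == 0`` and ``p(r) == 0`` for ``r >= D_max`` by construction of
    either the exact histogram or the spline basis that produced it.
    When produced by the indirect Fourier transform, ``coefficients`` holds
    the spline coefficients and ``basis`` the fitted
    :class:`~micellometry.ift.SplineBasis`.
    """

    r: np.ndarray
    p: np.ndarray
    d_max: float
    sigma: Optional[np.ndarray] = None
    coefficients: Optional[np.ndarray] = None
    basis: Optional[object] = None

    def __post_init__(self):
        self.r = _as_1d(self.r, "r")
        self.p = _as_1d(self.p, "p")
        if self.r.size < 2:
            raise InputError("p(r) needs at least two grid points")
        if self.p.shape != self.r.shape:
            raise InputError("r and p lengths differ")
        if np.any(np.diff(self.r) <= 0):
            raise InputError("r must be strictly increasing")
        if self.r[0] < 0:
            raise InputError("r must be non-negative")
        if not np.all(np.isfinite(self.p)):
            raise InputError("p must be finite")
        self.d_max = float(self.d_max)
        if self.d_max <= 0:
            raise InputError("d_max must be positive")
        if self.sigma is not None:
            self.sigma = _as_1d(self.sigma, "sigma")
            if self.sigma.shape != self.r.shape:
                raise InputError("sigma length differs from r")


@dataclass
class BeadModel:
    """Point scatterers standing in for a micelle or molecule.

    ``weights`` are scattering lengths in arbitrary units; negative values
    encode core–shell contrast relative to the solvent.
    """

    positions: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InputError("positions must have shape (n, 3)")
        if self.positions.shape[0] < 1:
            raise InputError("bead model needs at least one bead")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions must be finite")
        self.weights = _as_1d(self.weights, "weights")
        if self.weights.shape[0] != self.positions.shape[0]:
            raise InputError("weights length differs from positions")
        if not np.any(self.weights != 0):
            raise InputError("at least one bead weight must be nonzero")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class GroundTruth:
    """Closed-form descriptors of a generated particle.

    For a uniform ellipsoid with semi-axes a ≥ b ≥ c:
    D_max = 2a, Rg = sqrt((a² + b² + c²)/5), axial ratio = a/b.
    """

    kind: str
    a: float
    b: float
    c: float
    d_max: float
    rg: float
    axial_ratio: float

    def __post_init__(self):
        if not (self.a >= self.b >= self.c > 0):
            raise GeometryError("semi-axes must satisfy a >= b >= c > 0")


# Standard atomic masses (Da) for elements that occur in the coordinate
# files this package reads.  Unknown elements get mass 0 and are excluded
# from mass-weighted computations (with a logged warning at read time).
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "FE": 55.845,
    "ZN": 65.38, "SE": 78.971,
}


@dataclass
class CoordinateSet:
    """Atomic (or coarse-grained) coordinates with light annotation.

    Positions in Å.  ``box`` holds orthorhombic box edge lengths in Å when
    periodic boundary information is available (GRO files), else ``None``.
    """

    positions: np.ndarray
    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions must be finite")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.res_names = np.asarray(self.res_names, dtype="U6")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.elements = np.asarray(self.elements, dtype="U2")
        self.masses = np.asarray(self.masses, dtype=float)
        for name, arr in (
            ("atom_names", self.atom_names), ("res_names", self.res_names),
            ("res_ids", self.res_ids), ("elements", self.elements),
            ("masses", self.masses),
        ):
            if arr.shape[0] != n:
                raise InputError(f"{name} length differs from positions")
        if np.any(self.masses < 0):
            raise InputError("masses must be non-negative")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise InputError("box edges must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def select(self, mask) -> "CoordinateSet":
        """Subset by boolean mask or index array (box is inherited)."""
        mask = np.asarray(mask)
        return CoordinateSet(
            self.positions[mask], self.atom_names[mask], self.res_names[mask],
            self.res_ids[mask], self.elements[mask], self.masses[mask],
            box=None if self.box is None else self.box.copy(),
        )


@dataclass
class TitrationCurve:
    """(pH, emission wavelength) pairs from a fluorescence titration."""

    ph: np.ndarray
    wavelength: np.ndarray

    def __post_init__(self):
        self.ph = _as_1d(self.ph, "ph")
        self.wavelength = _as_1d(self.wavelength, "wavelength")
        if self.ph.shape != self.wavelength.shape:
            raise InputError("pH and wavelength lengths differ")
        if self.ph.size == 0:
            raise InputError("titration curve is empty")
        if np.any(np.diff(self.ph) <= 0):
            raise InputError("pH values must be strictly increasing")
        if np.any(self.ph < 0) or np.any(self.ph > 14):
            raise InputError("pH values must lie in [0, 14]")
        if not np.all(np.isfinite(self.wavelength)):
            raise InputError("wavelengths must be finite")

    def __len__(self) -> int:
        return self.ph.size


@dataclass
class MicelleGeometry:
    """Principal-axis dimensions of a coordinate set.

    ``height`` is the extent along the first principal axis, ``width`` the
    mean of the two transverse extents; ``axial_ratio = height / width``.
    """

    rg: float
    height: float
    width: float
    axial_ratio: float

    def __post_init__(self):
        if not (self.height >= self.width > 0):
            raise GeometryError("height must be >= width > 0")


@dataclass
class ShapeReport:
    """Headline shape descriptors extracted from a p(r)."""

    d_max: float
    rg: float
    cross_section: Optional[float] = None
    axial_ratio: Optional[float] = None
    asymmetry: Optional[float] = None
    notes: tuple = ()


@dataclass
class RDFProfile:
    """Radial distribution function g(r) around a reference selection."""

    r: np.ndarray
    g: np.ndarray
    reference: str = ""
    target: str = ""

    def __post_init__(self):
        self.r = _as_1d(self.r, "r")
        self.g = _as_1d(self.g, "g")
        if self.r.shape != self.g.shape:
            raise InputError("r and g lengths differ")
        if np.any(self.g < 0):
            raise InputError("g(r) must be non-negative")


@dataclass
class DihedralSpec:
    """Four atom selectors defining a torsion angle.

    Each selector is ``(atom_name, res_id)``.  ``kind`` labels the angle in
    glycosidic-linkage convention: phi = O5–C1–O1–CX, psi = C1–O1–CX–C(X−1),
    omega for the (1→28) ester linkage.
    """

    atoms: tuple
    kind: str = ""

    def __post_init__(self):
        if len(self.atoms) != 4:
            raise InputError("a dihedral needs exactly four atom selectors")
        if len(set(self.atoms)) != 4:
            raise InputError("dihedral atom selectors must be distinct")


@dataclass
class PkaFit:
    """Result of a Henderson–Hasselbalch titration fit."""

    pka: float
    plateau_acid: float
    plateau_base: float
    pka_stderr: float
    residual_rms: float

    def __post_init__(self):
        if not (0 < self.pka < 14):
            raise InputError("fitted pKa outside (0, 14)")
        if self.plateau_acid == self.plateau_base:
            raise InputError("titration plateaus are not distinct")
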