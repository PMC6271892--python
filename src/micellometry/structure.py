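"""Coordinate-space descriptors of micelle models.

Radius of gyration, principal-axis height/width, radial distribution
functions around designated atoms, solvent-accessible surface area
(Shrake–Rupley with a deterministic golden-spiral point set), torsion
angles in the glycosidic-linkage convention, and logarithmic
aggregation-growth trend fits.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import CoordinateSet, DihedralSpec, MicelleGeometry, RDFProfile
from .errors import GeometryError, InputError, NumericalError

__all__ = [
    "radius_of_gyration",
    "principal_extents",
    "select_atoms",
    "rdf",
    "sasa",
    "dihedral",
    "growth_trend",
    "VDW_RADII",
]

# Van der Waals radii (Å) for SASA; probe default 1.4 Å (water).
VDW_RADII = {"C": 1.70, "O": 1.52, "N": 1.55, "H": 1.20, "S": 1.80, "P": 1.80}


def radius_of_gyration(coords: CoordinateSet, weighting: str = "mass") -> float:
    """Rg = sqrt(Σ wᵢ |rᵢ − r̄|² / Σ wᵢ) with mass or uniform weights.

    Atoms with zero mass are excluded under mass weighting.
    """
    if len(coords) < 2:
        raise InputError("radius of gyration needs at least two atoms")
    if weighting == "mass":
        w = coords.masses
    elif weighting == "uniform":
        w = np.ones(len(coords))
    else:
        raise InputError(f"unknown weighting {weighting!r}")
    total = float(w.sum())
    if total <= 0:
        raise InputError("all weights are zero")
    centre = (w[:, None] * coords.positions).sum(axis=0) / total
    dev = coords.positions - centre
    return float(np.sqrt((w * np.sum(dev**2, axis=1)).sum() / total))


def principal_extents(coords: CoordinateSet) -> MicelleGeometry:
    """Height/width along the principal axes of the position covariance.

    ``height`` = extent (max − min projection) along the first principal
    axis; ``width`` = mean of the two transverse extents;
    ``axial_ratio = height / width``.  Rg (mass-weighted) is included.

    For bodies with a (near-)degenerate transverse covariance —
    square-section boxes, spheroids — the eigenvector pair spanning the
    transverse plane is arbitrary, so the transverse axes are fixed
    instead by the minimum-area enclosing rectangle of the transverse
    projection (rotating calipers over the convex hull).  This is
    deterministic, rotation-invariant, and exact for axis-aligned boxes.
    """
    if len(coords) < 4:
        raise InputError("principal extents need at least 4 atoms")
    pos = coords.positions - coords.positions.mean(axis=0)
    cov = pos.T @ pos / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[-1], 1.0):
        raise GeometryError("degenerate (collinear) configuration")
    axis1 = evecs[:, -1]
    height = float(np.ptp(pos @ axis1))
    plane = np.column_stack([pos @ evecs[:, 0], pos @ evecs[:, 1]])
    w1, w2 = _min_area_rect_extents(plane)
    # near-spherical bodies: sampling noise can put a transverse extent
    # marginally above the height; clamp to keep height >= width
    width = float(min(0.5 * (w1 + w2), height))
    weighting = "mass" if np.any(coords.masses > 0) else "uniform"
    return MicelleGeometry(
        rg=radius_of_gyration(coords, weighting),
        height=height, width=width, axial_ratio=height / width,
    )


def _min_area_rect_extents(points2d: np.ndarray) -> tuple[float, float]:
    """Side lengths (larger, smaller) of the minimum-area enclosing
    rectangle of a 2D point set, via rotating calipers over the convex
    hull (the optimal rectangle has a side parallel to a hull edge)."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points2d, dtype=float)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except Exception:  # flat/degenerate in 2D: fall back to axis extents
        return float(np.ptp(pts[:, 0])), float(np.ptp(pts[:, 1]))
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    best = None
    for ang in angles:
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, s], [-s, c]])
        proj = verts @ rot.T
        ext = np.ptp(proj, axis=0)
        area = ext[0] * ext[1]
        if best is None or area < best[0] - 1e-12:
            best = (area, float(max(ext)), float(min(ext)))
    return best[1], best[2]


def select_atoms(coords: CoordinateSet, names=None, res_names=None, res_ids=None) -> np.ndarray:
    """Boolean mask of atoms matching any given name/residue filters."""
    mask = np.ones(len(coords), dtype=bool)
    if names is not None:
        mask &= np.isin(coords.atom_names, np.atleast_1d(names))
    if res_names is not None:
        mask &= np.isin(coords.res_names, np.atleast_1d(res_names))
    if res_ids is not None:
        mask &= np.isin(coords.res_ids, np.atleast_1d(res_ids))
    return mask


def rdf(coords: CoordinateSet, reference_mask, target_mask, r_max: float,
        bin_width: float = 0.1, use_box: bool = True) -> RDFProfile:
    """Radial distribution function g(r) of targets around references.

    g(r) = ⟨n(r)⟩ / (4πr²Δr ρ) with the target number density ρ taken from
    the periodic box volume when the coordinate set has one (minimum-image
    distances are then used), and from the bounding sphere of the target
    set otherwise (an approximation, noted for open systems).
    """
    if bin_width <= 0 or r_max <= 0:
        raise InputError("r_max and bin_width must be positive")
    ref_mask = np.asarray(reference_mask, bool)
    tgt_mask = np.asarray(target_mask, bool)
    if not ref_mask.any() or not tgt_mask.any():
        raise InputError("empty reference or target selection")
    if np.any(ref_mask & tgt_mask):
        raise InputError("reference and target selections must be disjoint")
    ref = coords.positions[ref_mask]
    tgt = coords.positions[tgt_mask]
    box = coords.box if use_box else None
    delta = ref[:, None, :] - tgt[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    dist = np.linalg.norm(delta, axis=-1).ravel()
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, _ = np.histogram(dist, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centres**2 * bin_width
    if box is not None:
        volume = float(np.prod(box))
    else:
        centre = tgt.mean(axis=0)
        radius = float(np.max(np.linalg.norm(tgt - centre, axis=1)))
        volume = 4.0 / 3.0 * np.pi * max(radius, bin_width) ** 3
    density = tgt.shape[0] / volume
    g = hist / (ref.shape[0] * shell * density)
    return RDFProfile(centres, g)


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([rho * np.cos(golden * k), rho * np.sin(golden * k), z])


def sasa(coords: CoordinateSet, radii: dict | None = None,
         probe_radius: float = 1.4, n_sphere_points: int = 960,
         per_atom: bool = False):
    """Shrake–Rupley solvent-accessible surface area in Å².

    Each atom's sphere of radius rᵢ + probe is sampled at
    ``n_sphere_points`` deterministic golden-spiral points; the accessible
    fraction times the sphere area is the atom's contribution.  Unknown
    elements without a radius override raise.
    """
    if probe_radius < 0:
        raise InputError("probe radius must be non-negative")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    try:
        r_atom = np.array([table[el.upper()] for el in coords.elements])
    except KeyError as exc:
        raise InputError(f"no van der Waals radius for element {exc}; pass radii=...")
    r_ext = r_atom + probe_radius
    sphere = _golden_spiral(n_sphere_points)
    pos = coords.positions
    tree = cKDTree(pos)
    max_r = float(r_ext.max())
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = pos[i] + r_ext[i] * sphere
        neighbours = [j for j in tree.query_ball_point(pos[i], r_ext[i] + max_r) if j != i]
        if neighbours:
            npos = pos[neighbours]
            nr = r_ext[neighbours]
            d2 = np.sum((pts[:, None, :] - npos[None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < nr[None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r_ext[i] ** 2
    return areas if per_atom else float(areas.sum())


def dihedral(coords: CoordinateSet, spec: DihedralSpec) -> float:
    """Signed torsion angle in degrees, in (−180, 180].

    Atom selectors are (atom_name, res_id) pairs that must resolve to
    exactly one atom each.  Sign follows the standard convention: looking
    along the central bond, positive for clockwise rotation of the far
    bond (mirror images negate the angle).
    """
    points = []
    for name, res_id in spec.atoms:
        mask = (coords.atom_names == name) & (coords.res_ids == res_id)
        n_hit = int(mask.sum())
        if n_hit != 1:
            raise InputError(
                f"selector ({name!r}, residue {res_id}) matches {n_hit} atoms; "
                "need exactly one"
            )
        points.append(coords.positions[np.argmax(mask)])
    p0, p1, p2, p3 = points
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    if np.linalg.norm(np.cross(b1, b2)) < 1e-10 or np.linalg.norm(np.cross(b2, b3)) < 1e-10:
        raise NumericalError("collinear atoms; dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def growth_trend(sizes) -> tuple[float, float, float]:
    """Logarithmic growth-trend fit: dimension = a + b·ln(n_monomers).

    ``sizes`` is a sequence of (n_monomers, dimension) pairs; at least 3
    distinct n are required.  Returns (a, b, R) with R the Pearson
    correlation between observed and fitted values (R = 1 for an exact
    logarithmic law; sign follows b).
    """
    pts = [(float(n), float(dim)) for n, dim in sizes]
    ns = np.array([p[0] for p in pts])
    dims = np.array([p[1] for p in pts])
    if np.any(ns < 1):
        raise InputError("monomer counts must be >= 1")
    if np.unique(ns).size < 3:
        raise InputError("growth trend needs at least 3 distinct sizes")
    x = np.log(ns)
    b, a = np.polyfit(x, dims, 1)
    fitted = a + b * x
    sd_obs = dims.std()
    sd_fit = fitted.std()
    if sd_obs == 0 or sd_fit == 0:
        r = 0.0 if b == 0 else 1.0
    else:
        r = float(np.corrcoef(dims, fitted)[0, 1])
    return float(a), float(b), r
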