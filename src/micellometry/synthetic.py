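"""Seeded generators for every input the pipeline needs.

Bead-filled ellipsoids and core–shell spheres with closed-form ground
truth, amphiphile-like aggregates with buried tails, noisy (optionally
slit-smeared) scattering curves, solvated boxes for RDF/SASA checks, and
sigmoidal titration tables.  All generators are bit-reproducible under a
fixed seed.

Default study conditions follow the experimental setup this package
emulates: q from 0.02 to 0.6 Å⁻¹, micelle-scale particles of maximum
dimension ≈ 75 Å with axial ratio ≈ 1.8, and titrations spanning pH
2.4–11.1.
"""

from __future__ import annotations

import numpy as np

from .datatypes import BeadModel, CoordinateSet, GroundTruth, ScatteringCurve, TitrationCurve
from .errors import GeometryError, InputError, PackingError
from .scattering import debye_intensity

__all__ = [
    "make_ellipsoid",
    "make_core_shell_sphere",
    "make_monomer_template",
    "make_aggregate",
    "make_noisy_curve",
    "make_titration",
    "make_solvated_box",
]

DEFAULT_Q_RANGE = (0.02, 0.6)  # Å⁻¹, the measured window this emulates


def _fill_ellipsoid(a, b, c, n, rng):
    """Uniform rejection sampling of n points inside an ellipsoid."""
    pts = []
    got = 0
    while got < n:
        trial = rng.uniform(-1.0, 1.0, size=(max(n, 1000), 3))
        keep = np.sum(trial**2, axis=1) <= 1.0
        pts.append(trial[keep])
        got += int(keep.sum())
    return np.concatenate(pts)[:n] * np.array([a, b, c])


def make_ellipsoid(a, b, c, n_beads=5000, seed=0, label=""):
    """Uniform bead-filled ellipsoid with semi-axes a ≥ b ≥ c (Å).

    Returns ``(BeadModel, GroundTruth)`` with unit bead weights and the
    closed forms D_max = 2a, Rg = sqrt((a²+b²+c²)/5), axial ratio a/b.
    """
    if not (a >= b >= c > 0):
        raise GeometryError("semi-axes must satisfy a >= b >= c > 0")
    if n_beads < 10:
        raise InputError("n_beads must be at least 10 for meaningful sampling")
    rng = np.random.default_rng(seed)
    positions = _fill_ellipsoid(a, b, c, n_beads, rng)
    model = BeadModel(positions, np.ones(n_beads), label=label or f"ellipsoid-{a}x{b}x{c}")
    kind = "sphere" if a == b == c else "prolate"
    truth = GroundTruth(
        kind=kind, a=a, b=b, c=c,
        d_max=2.0 * a,
        rg=float(np.sqrt((a**2 + b**2 + c**2) / 5.0)),
        axial_ratio=a / b,
    )
    return model, truth


def make_core_shell_sphere(r_core, r_shell, w_core, w_shell, n_beads=5000, seed=0):
    """Bead sphere of radius ``r_shell`` with two-level radial contrast.

    Beads inside ``r_core`` get weight ``w_core``, the rest ``w_shell``.
    """
    if not (0 < r_core < r_shell):
        raise GeometryError("need 0 < r_core < r_shell")
    if not (np.isfinite(w_core) and np.isfinite(w_shell)):
        raise InputError("weights must be finite")
    if n_beads < 10:
        raise InputError("n_beads must be at least 10")
    rng = np.random.default_rng(seed)
    positions = _fill_ellipsoid(r_shell, r_shell, r_shell, n_beads, rng)
    radii = np.linalg.norm(positions, axis=1)
    weights = np.where(radii <= r_core, float(w_core), float(w_shell))
    if not np.any(weights != 0):
        raise InputError("all bead weights are zero")
    return BeadModel(positions, weights, label=f"core-shell-{r_core}/{r_shell}")


def make_monomer_template(n_tail=4, n_head=6, bond=1.6):
    """Schematic amphiphile: a straight tail of hydrophobic beads capped by
    a blob of hydrophilic head beads.

    Returns (positions (n,3), labels array of 'tail'/'head').  This is a
    cartoon of a surfactant monomer — a few-Å tail attached to a bulkier
    polar head — not a reconstruction of any particular molecule.
    """
    if n_tail < 1 or n_head < 1:
        raise InputError("template needs at least one tail and one head bead")
    tail = np.column_stack([
        -bond * (1 + np.arange(n_tail)), np.zeros(n_tail), np.zeros(n_tail),
    ])
    # head beads on a small deterministic spiral shell around the origin
    k = np.arange(n_head)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_head
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    head = 1.8 * np.column_stack([rho * np.cos(golden * k), rho * np.sin(golden * k), z])
    head[:, 0] += bond
    positions = np.vstack([tail, head])
    labels = np.array(["tail"] * n_tail + ["head"] * n_head)
    return positions, labels


def make_aggregate(
    n_monomers,
    monomer_template=None,
    envelope=(36.0, 20.0, 20.0),
    min_dist=1.5,
    seed=0,
    max_retries=2000,
):
    """Place randomly rotated amphiphile copies inside a prolate envelope.

    Monomers are placed the way a micelle organizes: hydrophilic heads
    anchor near the envelope surface with tail axes oriented inward, so
    tails are biased toward the centre without being forced onto it.
    Surface coverage uses a deterministic golden-spiral direction per
    monomer (jittered per attempt) so small aggregates still reach the
    envelope poles; the radial anchor fraction is drawn from
    U(0.90, 0.99) and each copy gets a random spin about its tail axis.
    Copies clashing with already-placed atoms (< ``min_dist`` Å) or
    leaking out of 1.05× the envelope are re-sampled.  Returns a
    :class:`CoordinateSet` with tail beads named TL (residue TAI) and
    head beads HD (residue HEA), one residue id per monomer.
    """
    if n_monomers < 1:
        raise InputError("n_monomers must be >= 1")
    if monomer_template is None:
        monomer_template = make_monomer_template()
    positions, labels = monomer_template
    positions = np.asarray(positions, dtype=float)
    if set(labels) < {"tail", "head"}:
        raise InputError("template must label both tail and head beads")
    rng = np.random.default_rng(seed)
    a, b, c = envelope
    head_centroid = positions[labels == "head"].mean(axis=0)
    k = np.arange(n_monomers)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_monomers
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    base_dirs = np.column_stack([rho * np.cos(golden * k),
                                 rho * np.sin(golden * k), z])
    placed = []
    all_atoms = []
    for mono in range(n_monomers):
        for attempt in range(max_retries):
            direction = base_dirs[mono] + 0.12 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            frac = rng.uniform(0.90, 0.99)
            anchor = frac * direction * np.array([a, b, c])
            # template tail points −x: map +x onto the outward normal so
            # the tail extends inward, with a random spin about that axis
            rot = _rotation_onto(np.array([1.0, 0.0, 0.0]), direction) @ _random_axis_spin(rng)
            coords = (positions - head_centroid) @ rot.T + anchor
            # reject copies leaking out of the envelope
            scaled = coords / np.array([a, b, c])
            if np.any(np.sum(scaled**2, axis=1) > 1.1025):
                continue
            if all_atoms:
                prev = np.concatenate(all_atoms)
                dmin = np.min(
                    np.linalg.norm(prev[:, None, :] - coords[None, :, :], axis=-1)
                )
                if dmin < min_dist:
                    continue
            all_atoms.append(coords)
            placed.append(mono)
            break
        else:
            raise PackingError(
                f"could not place monomer {mono + 1}/{n_monomers} without a "
                f"clash after {max_retries} attempts"
            )
    coords = np.concatenate(all_atoms)
    n_per = positions.shape[0]
    names = np.tile(np.where(labels == "tail", "TL", "HD"), n_monomers)
    res_names = np.tile(np.where(labels == "tail", "TAI", "HEA"), n_monomers)
    res_ids = np.repeat(np.arange(1, n_monomers + 1), n_per)
    elements = np.tile(np.where(labels == "tail", "C", "O"), n_monomers)
    masses = np.tile(np.where(labels == "tail", 12.011, 15.999), n_monomers)
    return CoordinateSet(coords, names, res_names, res_ids, elements, masses)


def _rotation_onto(u, v):
    """Rotation matrix sending unit vector u onto unit vector v."""
    cross = np.cross(u, v)
    s = np.linalg.norm(cross)
    cdot = float(np.dot(u, v))
    if s < 1e-12:
        if cdot > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    kmat = np.array([
        [0, -cross[2], cross[1]],
        [cross[2], 0, -cross[0]],
        [-cross[1], cross[0], 0],
    ])
    return np.eye(3) + kmat + kmat @ kmat * ((1 - cdot) / s**2)


def _random_axis_spin(rng):
    """Random rotation about the template tail axis (x)."""
    ang = rng.uniform(0, 2 * np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    return np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])


def make_noisy_curve(model: BeadModel, q_grid=None, noise_frac=0.01,
                     smear_profile=None, seed=0) -> ScatteringCurve:
    """Debye curve of a bead model with multiplicative Gaussian noise.

    I = Debye(model), optionally slit-smeared with ``smear_profile``, then
    multiplied by (1 + ε) with ε ~ Normal(0, noise_frac); σ is stored as
    noise_frac · I_true.  ``noise_frac = 0`` returns the exact curve.
    """
    if noise_frac < 0:
        raise InputError("noise_frac must be non-negative")
    if q_grid is None:
        q_grid = np.linspace(*DEFAULT_Q_RANGE, 150)
    curve = debye_intensity(model, q_grid)
    if smear_profile is not None:
        from .smearing import slit_smear

        curve = slit_smear(curve, smear_profile)
    rng = np.random.default_rng(seed)
    true = curve.intensity
    noisy = true * (1.0 + rng.normal(0.0, noise_frac, size=true.shape)) if noise_frac > 0 else true.copy()
    sigma = noise_frac * np.abs(true) if noise_frac > 0 else None
    return ScatteringCurve(curve.q, noisy, sigma=sigma, smeared=curve.smeared,
                           meta={**curve.meta, "noise_frac": noise_frac, "seed": seed})


def make_titration(pka=7.2, lambda_acid=340.0, lambda_base=440.0,
                   ph_grid=None, noise_nm=0.2, seed=0) -> TitrationCurve:
    """Sigmoidal titration table λ(pH) with Gaussian wavelength noise.

    λ(pH) = λ_acid + (λ_base − λ_acid) / (1 + 10^(pKa − pH)) + N(0, noise).
    The default pH grid spans the measured titration window 2.4–11.1.
    """
    if ph_grid is None:
        ph_grid = np.arange(2.4, 11.1 + 1e-9, 0.5)
    ph = np.asarray(ph_grid, dtype=float)
    if np.any(ph < 0) or np.any(ph > 14):
        raise InputError("pH grid must lie in [0, 14]")
    rng = np.random.default_rng(seed)
    lam = lambda_acid + (lambda_base - lambda_acid) / (1.0 + 10.0 ** (pka - ph))
    if noise_nm > 0:
        lam = lam + rng.normal(0.0, noise_nm, size=lam.shape)
    return TitrationCurve(ph, lam)


def make_solvated_box(solute: CoordinateSet | None, box_edge, n_solvent,
                      min_dist=2.4, seed=0, max_retries=200) -> CoordinateSet:
    """Uniform random solvent points in a cubic box around a centred solute.

    Points closer than ``min_dist`` Å to any solute atom are rejected and
    re-drawn.  With no solute the points are plain uniform (ideal gas).
    Solvent atoms are named OW (residue SOL, element O); solute atoms, if
    any, come first with their own annotation.
    """
    if box_edge <= 0:
        raise InputError("box edge must be positive")
    rng = np.random.default_rng(seed)
    box = np.array([box_edge] * 3, dtype=float)
    if solute is not None and len(solute) > 0:
        centre = solute.positions.mean(axis=0)
        solute_pos = solute.positions - centre + box / 2.0
    else:
        solute_pos = np.empty((0, 3))
    accepted = []
    n_acc = 0
    for _ in range(max_retries):
        if n_acc >= n_solvent:
            break
        trial = rng.uniform(0.0, box_edge, size=(max(n_solvent, 1000), 3))
        if solute_pos.shape[0]:
            from scipy.spatial import cKDTree

            tree = cKDTree(solute_pos)
            dist, _ = tree.query(trial, k=1)
            trial = trial[dist >= min_dist]
        accepted.append(trial)
        n_acc += trial.shape[0]
    else:
        raise PackingError(
            f"could not place {n_solvent} solvent points at min_dist={min_dist} "
            f"in a box of edge {box_edge}"
        )
    solvent = np.concatenate(accepted)[:n_solvent]
    n_solute = solute_pos.shape[0]
    positions = np.vstack([solute_pos, solvent])
    names = np.concatenate([
        solute.atom_names if n_solute else np.empty(0, "U6"),
        np.full(n_solvent, "OW"),
    ])
    res_names = np.concatenate([
        solute.res_names if n_solute else np.empty(0, "U6"),
        np.full(n_solvent, "SOL"),
    ])
    offset = int(solute.res_ids.max()) if n_solute else 0
    res_ids = np.concatenate([
        solute.res_ids if n_solute else np.empty(0, int),
        offset + 1 + np.arange(n_solvent),
    ])
    elements = np.concatenate([
        solute.elements if n_solute else np.empty(0, "U2"),
        np.full(n_solvent, "O"),
    ])
    masses = np.concatenate([
        solute.masses if n_solute else np.empty(0, float),
        np.full(n_solvent, 15.999),
    ])
    return CoordinateSet(positions, names, res_names, res_ids, elements, masses, box=box)
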