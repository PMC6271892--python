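"""Readers and writers for every on-disk artifact the pipeline touches.

Curve, p(r) and titration files are whitespace-delimited text with optional
``#`` or ``;`` comment lines.  Coordinate files are PDB (fixed-column
ATOM/HETATM subset) and GRO; parsing is delegated to biotite, with GRO
nanometre coordinates converted to Å and elements inferred from atom names
when the element column is blank.  The internal length unit is Å
throughout.
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np
import yaml

from .datatypes import (
    ELEMENT_MASSES,
    CoordinateSet,
    PairDistribution,
    ScatteringCurve,
    TitrationCurve,
)
from .errors import FormatError, InputError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "read_curve", "write_curve", "read_pr", "write_pr",
    "read_coordinates", "write_coordinates",
    "read_titration", "write_titration",
    "read_config", "write_config",
]

_COMMENT = ("#", ";")


def _read_columns(path, min_cols, max_cols, kind):
    """Parse a whitespace-delimited numeric table, skipping comments.

    Returns (columns, header_lines).  Raises :class:`ParseError` naming the
    first malformed line.
    """
    rows = []
    header = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(_COMMENT):
                header.append(stripped.lstrip("#; ").rstrip())
                continue
            fields = stripped.split()
            if not (min_cols <= len(fields) <= max_cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {min_cols}–{max_cols} columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})")
    if not rows:
        raise InputError(f"{path}: empty {kind} file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise ParseError(f"{path}: inconsistent column count across rows")
    return np.array(rows, dtype=float).T, header


def read_curve(path, dialect: str = "auto") -> ScatteringCurve:
    """Read a scattering curve from a q/I(/σ) text file.

    ``dialect`` is one of ``two-column``, ``three-column``,
    ``header-annotated`` or ``auto`` (accept either column count; header
    comment lines become metadata either way).
    """
    if dialect not in ("auto", "two-column", "three-column", "header-annotated"):
        raise FormatError(f"unknown curve dialect {dialect!r}")
    lo, hi = {"two-column": (2, 2), "three-column": (3, 3)}.get(dialect, (2, 3))
    cols, header = _read_columns(path, lo, hi, "curve")
    q, intensity = cols[0], cols[1]
    sigma = cols[2] if cols.shape[0] == 3 else None
    meta = _meta_from_header(header)
    return ScatteringCurve(
        q, intensity, sigma=sigma,
        smeared=bool(meta.pop("smeared", False)), meta=meta,
    )


def write_curve(path, curve: ScatteringCurve) -> None:
    """Write a curve as text: ``# key: value`` header then q I [sigma]."""
    with open(path, "w") as fh:
        fh.write("# columns: q[1/A] I[1/cm]" + (" sigma[1/cm]" if curve.sigma is not None else "") + "\n")
        if curve.smeared:
            fh.write("# smeared: true\n")
        for key, value in sorted(curve.meta.items()):
            fh.write(f"# {key}: {value}\n")
        cols = [curve.q, curve.intensity]
        if curve.sigma is not None:
            cols.append(curve.sigma)
        np.savetxt(fh, np.column_stack(cols), fmt="%.8g")


def _meta_from_header(header):
    meta = {}
    for line in header:
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key in ("columns",):
            continue
        try:
            meta[key] = yaml.safe_load(value)
        except yaml.YAMLError:
            meta[key] = value
    return meta


def read_pr(path) -> PairDistribution:
    """Read a p(r) table: three columns r, p, σ (σ optional)."""
    cols, header = _read_columns(path, 2, 3, "p(r)")
    r, p = cols[0], cols[1]
    sigma = cols[2] if cols.shape[0] == 3 else None
    meta = _meta_from_header(header)
    d_max = float(meta.get("d_max", r[-1]))
    return PairDistribution(r, p, d_max=d_max, sigma=sigma)


def write_pr(path, pr: PairDistribution) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: r[A] p sigma\n")
        fh.write(f"# d_max: {pr.d_max:.6g}\n")
        sigma = pr.sigma if pr.sigma is not None else np.zeros_like(pr.r)
        np.savetxt(fh, np.column_stack([pr.r, pr.p, sigma]), fmt="%.8g")


def read_titration(path) -> TitrationCurve:
    """Read a two-column (pH, emission wavelength in nm) table."""
    cols, _ = _read_columns(path, 2, 2, "titration")
    return TitrationCurve(cols[0], cols[1])


def write_titration(path, curve: TitrationCurve) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: pH lambda_em[nm]\n")
        np.savetxt(fh, np.column_stack([curve.ph, curve.wavelength]), fmt="%.6g")


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    # Two-letter elements that occur in surfactant/solvent systems.
    head = "".join(ch for ch in name if ch.isalpha()).upper()
    for two in ("CL", "BR", "NA", "MG", "CA", "FE", "ZN", "SE"):
        if head.startswith(two):
            return two
    return head[:1]


def read_coordinates(path) -> CoordinateSet:
    """Read a PDB or GRO coordinate file into a :class:`CoordinateSet`.

    The format is chosen by extension.  GRO coordinates (nm) are converted
    to Å.  Elements missing from the file are inferred from atom names;
    elements with no entry in the mass table get mass 0 and are excluded
    from mass-weighted computations downstream (a warning is logged).
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        reader = PDBFile
    elif ext == ".gro":
        from biotite.structure.io.gro import GROFile

        reader = GROFile
    else:
        raise FormatError(f"{path}: unrecognized coordinate extension {ext!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # element guessing is expected
            atoms = reader.read(str(path)).get_structure(model=1)
    except InputError:
        raise
    except Exception as exc:  # biotite raises format-specific errors
        raise ParseError(f"{path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise InputError(f"{path}: no atoms")
    elements = np.array(
        [el if el else _infer_element(an) for el, an in zip(atoms.element, atoms.atom_name)],
        dtype="U2",
    )
    masses = np.array([ELEMENT_MASSES.get(el.upper(), 0.0) for el in elements])
    unknown = sorted({el for el, m in zip(elements, masses) if m == 0.0})
    if unknown:
        log.warning(
            "%s: elements %s not in mass table; assigned mass 0 and excluded "
            "from mass-weighted computations", path, unknown,
        )
    box = None
    if atoms.box is not None:
        edges = np.diag(np.asarray(atoms.box, dtype=float))
        if np.all(edges > 0):
            box = edges
    return CoordinateSet(
        positions=np.asarray(atoms.coord, dtype=float),
        atom_names=atoms.atom_name,
        res_names=atoms.res_name,
        res_ids=atoms.res_id,
        elements=elements,
        masses=masses,
        box=box,
    )


def write_coordinates(path, coords: CoordinateSet) -> None:
    """Write a :class:`CoordinateSet` as PDB or GRO (by extension)."""
    import biotite.structure as struc

    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = coords.positions.astype(np.float32)
    atoms.atom_name = coords.atom_names
    atoms.res_name = coords.res_names
    atoms.res_id = coords.res_ids
    atoms.element = coords.elements
    atoms.chain_id = np.full(n, "A", dtype="U4")
    atoms.hetero = np.full(n, False)
    if coords.box is not None:
        atoms.box = np.diag(coords.box).astype(np.float32)
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        out = PDBFile()
        out.set_structure(atoms)
    elif ext == ".gro":
        from biotite.structure.io.gro import GROFile

        out = GROFile()
        if atoms.box is None:
            # GRO requires a box line; use a bounding box with margin
            span = coords.positions.max(0) - coords.positions.min(0) + 10.0
            atoms.box = np.diag(span).astype(np.float32)
        out.set_structure(atoms)
    else:
        raise FormatError(f"{path}: unrecognized coordinate extension {ext!r}")
    out.write(str(path))


def read_config(path) -> dict:
    """Read a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
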