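"""Reading molecular structures and normalizing their pose into the unit ball.

Molecules enter the descriptor pipeline as bags of atom spheres: an element
symbol, Cartesian coordinates in Å and a van der Waals radius per atom
(occupancy and temperature factor are carried along when the source format
provides them, e.g. PDB, but are not used by the default depth map).
``normalize_pose`` translates the unweighted centroid to the origin and
applies one uniform scale so that every atom-sphere surface point lies inside
the unit ball — the domain on which the spherical depth map is defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Fallback van der Waals radius (Å) for elements without a tabulated value.
FALLBACK_VDW_RADIUS = 1.5


class FormatError(ValueError):
    """The file could not be parsed in the requested format."""


class EmptyMoleculeError(ValueError):
    """The parsed molecule contains no atoms."""


class EmbeddingError(RuntimeError):
    """A SMILES string could not be embedded into 3D coordinates."""


class DegenerateGeometryError(ValueError):
    """All atoms coincide with zero radius; no unit-ball scale exists."""


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, position and spherical extent.

    Coordinates are in Å before normalization and dimensionless (unit-ball
    units) afterwards; the radius is scaled by the same factor so the shape
    is preserved.
    """

    element: str
    coords: np.ndarray
    vdw_radius: float
    occupancy: float | None = None
    temp_factor: float | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")
        if not (self.vdw_radius > 0 and np.isfinite(self.vdw_radius)):
            raise ValueError("vdw_radius must be positive and finite")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class Molecule:
    """An ordered collection of atoms with an id and optional activity label."""

    id: str
    atoms: tuple[Atom, ...]
    normalized: bool = False
    scale_factor: float = 1.0
    activity: float | None = None

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise EmptyMoleculeError(f"molecule {self.id!r} has no atoms")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix."""
        return np.array([a.coords for a in self.atoms])

    def radii_array(self) -> np.ndarray:
        """(n_atoms,) van der Waals radii."""
        return np.array([a.vdw_radius for a in self.atoms])


def vdw_radius(element: str) -> float:
    """Tabulated van der Waals radius for an element symbol (Å).

    Uses the rdkit periodic table; unknown elements or missing entries fall
    back to :data:`FALLBACK_VDW_RADIUS` with a log message.
    """
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    try:
        r = pt.GetRvdw(element.capitalize())
    except Exception:
        r = 0.0
    if not r or r <= 0:
        logger.warning(
            "no tabulated vdW radius for element %r; using fallback %.2f Å",
            element, FALLBACK_VDW_RADIUS,
        )
        return FALLBACK_VDW_RADIUS
    return float(r)


# ---------------------------------------------------------------------------
# Parsers


def _from_rdkit(rdmol, mol_id: str) -> Molecule:
    if rdmol is None:
        raise FormatError("rdkit failed to parse the input")
    if rdmol.GetNumAtoms() == 0:
        raise EmptyMoleculeError("molecule has zero atoms")
    if rdmol.GetNumConformers() == 0:
        raise FormatError("molecule has no 3D coordinates")
    conf = rdmol.GetConformer()
    atoms = []
    for at in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(at.GetIdx())
        occupancy = temp_factor = None
        info = at.GetPDBResidueInfo()
        if info is not None:
            occupancy = info.GetOccupancy()
            temp_factor = info.GetTempFactor()
        sym = at.GetSymbol()
        atoms.append(Atom(
            element=sym,
            coords=np.array([pos.x, pos.y, pos.z]),
            vdw_radius=vdw_radius(sym),
            occupancy=occupancy,
            temp_factor=temp_factor,
        ))
    zs = np.array([a.coords[2] for a in atoms])
    if len(atoms) > 1 and np.allclose(zs, 0.0):
        logger.warning("molecule %r looks 2D (all z = 0); accepted as-is", mol_id)
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return Molecule(id=name or mol_id, atoms=tuple(atoms))


def _read_xyz(path: Path, mol_id: str) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: first line must hold the atom count") from exc
    if n < 1:
        raise EmptyMoleculeError(f"{path}: zero atoms declared")
    body = lines[2:2 + n]
    if len(body) < n:
        raise FormatError(f"{path}: declared {n} atoms, found {len(body)}")
    atoms = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom line {ln!r}")
        el = parts[0]
        try:
            xyz = np.array([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric coordinates in {ln!r}") from exc
        atoms.append(Atom(element=el, coords=xyz, vdw_radius=vdw_radius(el)))
    title = lines[1].strip() if len(lines) > 1 else ""
    return Molecule(id=title or mol_id, atoms=tuple(atoms))


def _embed_smiles(smiles: str, mol_id: str, seed: int = 2019) -> Molecule:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise FormatError(f"unparseable SMILES {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise EmbeddingError(f"could not embed {smiles!r} in 3D")
    AllChem.MMFFOptimizeMolecule(rdmol)
    return _from_rdkit(rdmol, mol_id)


def read_molecule(path: str | Path, format: str | None = None) -> Molecule:
    """Read one molecular structure from a file.

    Parameters
    ----------
    path
        Input file. For ``smiles`` the first non-empty line is embedded in 3D
        with rdkit's ETKDG conformer generator.
    format
        One of ``sdf``, ``mol``, ``xyz``, ``pdb``, ``smiles``; inferred from
        the file suffix when omitted (``.smi`` → smiles).

    Returns
    -------
    Molecule
        Hydrogens are retained as present in the input; vdW radii come from
        the element table; PDB occupancy/B-factor are populated.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "smi":
        fmt = "smiles"
    mol_id = path.stem

    if fmt == "xyz":
        return _read_xyz(path, mol_id)
    if fmt in ("sdf", "mol"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                supplier = Chem.SDMolSupplier(str(path), removeHs=False,
                                              sanitize=False)
                rdmol = next(iter(supplier), None)
        except OSError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if rdmol is None:
            raise FormatError(f"{path}: no parseable molecule block")
        return _from_rdkit(rdmol, mol_id)
    if fmt == "pdb":
        rdmol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
        return _from_rdkit(rdmol, mol_id)
    if fmt == "smiles":
        for line in path.read_text().splitlines():
            line = line.strip()
            if line:
                smiles = line.split()[0]
                return _embed_smiles(smiles, mol_id)
        raise FormatError(f"{path}: no SMILES found")
    raise FormatError(f"unknown format {fmt!r}")


def write_xyz(mol: Molecule, path: str | Path) -> None:
    """Write a molecule as an XYZ file (element, x, y, z per atom)."""
    lines = [str(mol.n_atoms), mol.id]
    for a in mol.atoms:
        lines.append(f"{a.element} {a.coords[0]:.8f} {a.coords[1]:.8f} {a.coords[2]:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pose normalization


def normalize_pose(mol: Molecule) -> Molecule:
    """Center a molecule and scale it to fit within the unit ball.

    The unweighted centroid of the atom positions is translated to the
    origin and one uniform scale ``s = 1 / max_i(|c_i| + r_i)`` is applied
    to coordinates and radii alike, so the farthest atom-sphere surface
    point lands exactly on the unit sphere. Idempotent.
    """
    if mol.normalized:
        return mol
    coords = mol.coords_array()
    radii = mol.radii_array()
    centered = coords - coords.mean(axis=0)
    extent = np.linalg.norm(centered, axis=1) + radii
    max_extent = float(extent.max())
    if max_extent < 1e-12 or not np.isfinite(max_extent):
        raise DegenerateGeometryError(
            f"molecule {mol.id!r}: coincident atoms with zero radius")
    s = 1.0 / max_extent
    atoms = tuple(
        replace(a, coords=c * s, vdw_radius=a.vdw_radius * s)
        for a, c in zip(mol.atoms, centered)
    )
    return replace(mol, atoms=atoms, normalized=True,
                   scale_factor=mol.scale_factor * s)
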