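"""Molecular data types, structure file I/O and atomic property weights.

A :class:`Molecule` is the substrate of every descriptor in this package: an
ordered list of atoms with 3D coordinates (Å) plus an undirected bond graph.
Structure files are read and written through RDKit; the topological distance
matrix (shortest path in bonds) comes from :mod:`scipy.sparse.csgraph`.

Atomic weighting schemes follow the DRAGON convention: each atomic property
(mass ``m``, Sanderson electronegativity ``e``, polarizability ``p``, van der
Waals volume ``v``) is divided by the carbon value, so carbon always weighs 1
and the unweighted scheme ``u`` is a vector of ones.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Atom",
    "Molecule",
    "AtomPropertyTable",
    "QuantumRecord",
    "MoleculeParseError",
    "read_sdf",
    "write_sdf",
    "read_xyz",
    "perceive_bonds",
    "topo_distance_matrix",
    "geom_distance_matrix",
    "carbon_scaled_weights",
    "WEIGHT_SCHEMES",
]

#: valid atomic weighting schemes: unweighted, mass, Sanderson
#: electronegativity, polarizability, van der Waals volume
WEIGHT_SCHEMES = ("u", "m", "e", "p", "v")

_SCHEME_COLUMNS = {
    "m": "mass",
    "e": "sanderson_en",
    "p": "polarizability",
    "v": "vdw_volume",
}


class MoleculeParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    element: str
    atomic_number: int
    coords: np.ndarray  # (3,), Å
    formal_charge: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.element}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class Molecule:
    """An ordered atom list plus an undirected bond graph.

    Bonds are stored once per pair as ``(i, j, order)`` with 0-based indices
    ``i < j``. ``planar_2d`` is set by readers when every z-coordinate is zero,
    a hint that the source file may hold 2D coordinates only.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    explicit_hydrogens: bool = True
    planar_2d: bool = False

    def __post_init__(self) -> None:
        n = len(self.atoms)
        normed = []
        seen = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"molecule {self.id}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id}: bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.id}: duplicate bond {key}")
            seen.add(key)
            normed.append((key[0], key[1], float(order)))
        self.bonds = normed

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def without_hydrogens(self) -> "Molecule":
        """Return an H-depleted copy, remapping bond indices."""
        keep = [i for i, a in enumerate(self.atoms) if a.element != "H"]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [self.atoms[i] for i in keep]
        bonds = [
            (remap[i], remap[j], o)
            for i, j, o in self.bonds
            if i in remap and j in remap
        ]
        return Molecule(self.id, atoms, bonds, explicit_hydrogens=False,
                        planar_2d=self.planar_2d)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Molecule":
        """Rigidly transform coordinates; descriptors must be invariant to this."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        atoms = [
            Atom(a.element, a.atomic_number, xyz[i], a.formal_charge)
            for i, a in enumerate(self.atoms)
        ]
        return Molecule(self.id, atoms, list(self.bonds),
                        explicit_hydrogens=self.explicit_hydrogens)

    def permuted(self, perm: Sequence[int]) -> "Molecule":
        """Reorder atoms by ``perm`` (new index -> old index)."""
        perm = list(perm)
        inv = {old: new for new, old in enumerate(perm)}
        atoms = [self.atoms[old] for old in perm]
        bonds = [(inv[i], inv[j], o) for i, j, o in self.bonds]
        return Molecule(self.id, atoms, bonds,
                        explicit_hydrogens=self.explicit_hydrogens)


@dataclass(frozen=True)
class QuantumRecord:
    """Frontier-orbital energies (eV) and dipole vector (Debye) for one molecule."""

    e_homo: float
    e_lumo: float
    dipole: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.e_homo > self.e_lumo:
            warnings.warn(
                f"E_HOMO ({self.e_homo}) above E_LUMO ({self.e_lumo}); "
                "check the orbital assignment", stacklevel=3)

    @property
    def dipx(self) -> float:
        return float(self.dipole[0])


class AtomPropertyTable:
    """Per-element atomic properties, carbon-scaled on demand.

    The packaged table holds CRC atomic masses, Sanderson electronegativities,
    atomic polarizabilities (Å³), van der Waals volumes derived from Bondi
    radii (Å³), and Cordero covalent radii (Å).
    """

    def __init__(self, frame: pd.DataFrame):
        if "C" not in frame.index:
            raise ValueError("property table must contain carbon")
        if (frame[list(_SCHEME_COLUMNS.values())] <= 0).any().any():
            raise ValueError("atomic property values must be positive")
        self._frame = frame

    @classmethod
    def default(cls) -> "AtomPropertyTable":
        with resources.files("tyroqsar.data").joinpath("atomic_properties.csv").open() as fh:
            frame = pd.read_csv(fh).set_index("element")
        return cls(frame)

    @property
    def elements(self) -> list[str]:
        return list(self._frame.index)

    def value(self, element: str, column: str) -> float:
        try:
            return float(self._frame.at[element, column])
        except KeyError:
            raise KeyError(f"element {element!r} not in the atomic property table") from None

    def covalent_radius(self, element: str) -> float:
        return self.value(element, "covalent_radius")

    def atomic_number(self, element: str) -> int:
        return int(self.value(element, "atomic_number"))


_DEFAULT_TABLE: AtomPropertyTable | None = None


def default_property_table() -> AtomPropertyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AtomPropertyTable.default()
    return _DEFAULT_TABLE


def carbon_scaled_weights(mol: Molecule, scheme: str,
                          table: AtomPropertyTable | None = None) -> np.ndarray:
    """Atomic weight vector w_i = property(element_i) / property(C).

    ``scheme`` is one of ``u`` (unweighted: all ones), ``m`` (mass), ``e``
    (Sanderson electronegativity), ``p`` (polarizability), ``v`` (van der
    Waals volume).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")
    if scheme == "u":
        return np.ones(mol.n_atoms)
    table = table or default_property_table()
    col = _SCHEME_COLUMNS[scheme]
    carbon = table.value("C", col)
    return np.array([table.value(a.element, col) / carbon for a in mol.atoms])


# ---------------------------------------------------------------------------
# structure file I/O (RDKit-backed)
# ---------------------------------------------------------------------------

def _rdkit():
    from rdkit import Chem, RDLogger
    RDLogger.DisableLog("rdApp.*")
    return Chem


def _from_rdkit(rdmol, mol_id: str) -> Molecule:
    Chem = _rdkit()
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    if conf is None:
        raise MoleculeParseError(f"record {mol_id!r} carries no coordinates")
    atoms = []
    for a in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), a.GetAtomicNum(),
                          np.array([pos.x, pos.y, pos.z]), a.GetFormalCharge()))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    mol = Molecule(mol_id, atoms, bonds)
    if mol.n_atoms > 1 and np.allclose(mol.coords[:, 2], 0.0):
        mol.planar_2d = True
    return mol


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read an SDF/MOL V2000 file into a list of Molecules.

    Atom order and explicit hydrogens are preserved as written; no
    sanitization or aromaticity perception is applied beyond what the file
    encodes. A record whose counts line or bond block is malformed raises
    :class:`MoleculeParseError` naming the record. Molecules whose
    z-coordinates are all zero are flagged ``planar_2d``.
    """
    Chem = _rdkit()
    text = Path(path).read_text()
    if not text.strip():
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise MoleculeParseError(f"{path}: record {i + 1} is not valid V2000")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mols.append(_from_rdkit(rdmol, name.strip() or f"mol{i + 1}"))
    return mols


_BOND_TYPES = {1.0: "SINGLE", 2.0: "DOUBLE", 3.0: "TRIPLE", 1.5: "AROMATIC"}


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write Molecules as a multi-record V2000 SDF (coordinates in Å)."""
    Chem = _rdkit()
    from rdkit.Chem import rdchem
    from rdkit.Geometry import Point3D

    buf = io.StringIO()
    for mol in mols:
        rw = rdchem.RWMol()
        for a in mol.atoms:
            ra = rdchem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNoImplicit(True)
            rw.AddAtom(ra)
        for i, j, order in mol.bonds:
            bt = getattr(rdchem.BondType, _BOND_TYPES.get(order, "SINGLE"))
            rw.AddBond(i, j, bt)
        conf = rdchem.Conformer(mol.n_atoms)
        for i, a in enumerate(mol.atoms):
            conf.SetAtomPosition(i, Point3D(*a.coords))
        rd = rw.GetMol()
        rd.AddConformer(conf)
        rd.SetProp("_Name", mol.id)
        buf.write(Chem.MolToMolBlock(rd, kekulize=False))
        buf.write("$$$$\n")
    Path(path).write_text(buf.getvalue())


def read_xyz(path: str | Path, table: AtomPropertyTable | None = None) -> Molecule:
    """Read a standard XYZ file (count line, comment, element x y z rows).

    Coordinates may use plain or scientific notation. The returned Molecule
    has an empty bond list; attach bonds with :func:`perceive_bonds` when
    topological descriptors are needed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise MoleculeParseError(f"{path}: empty file")
    try:
        declared = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise MoleculeParseError(f"{path}: first line must be the atom count") from None
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) != declared:
        raise MoleculeParseError(
            f"{path}: count line declares {declared} atoms, found {len(rows)}")
    table = table or default_property_table()
    atoms = []
    for k, ln in enumerate(rows):
        parts = ln.split()
        if len(parts) < 4:
            raise MoleculeParseError(f"{path}: atom row {k + 1} malformed: {ln!r}")
        element = parts[0]
        try:
            xyz = np.array([float(v) for v in parts[1:4]])
        except ValueError:
            raise MoleculeParseError(
                f"{path}: atom row {k + 1} has non-numeric coordinates") from None
        atoms.append(Atom(element, table.atomic_number(element), xyz))
    mol = Molecule(path.stem, atoms, [])
    if mol.n_atoms > 1 and np.allclose(mol.coords[:, 2], 0.0):
        mol.planar_2d = True
    return mol


def perceive_bonds(mol: Molecule, scale: float = 1.15,
                   table: AtomPropertyTable | None = None) -> Molecule:
    """Attach single bonds between atoms closer than scale × (r_cov_i + r_cov_j).

    A simple deterministic distance rule for XYZ inputs, which carry no
    connectivity. ``scale`` defaults to 1.15.
    """
    table = table or default_property_table()
    radii = np.array([table.covalent_radius(a.element) for a in mol.atoms])
    dist = geom_distance_matrix(mol)
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonds = [
        (i, j, 1.0)
        for i in range(mol.n_atoms)
        for j in range(i + 1, mol.n_atoms)
        if dist[i, j] < cutoff[i, j]
    ]
    return Molecule(mol.id, list(mol.atoms), bonds,
                    explicit_hydrogens=mol.explicit_hydrogens,
                    planar_2d=mol.planar_2d)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def topo_distance_matrix(mol: Molecule) -> np.ndarray:
    """Shortest-path length in bonds between every atom pair.

    Returns a symmetric float matrix with zero diagonal; pairs in different
    connected components are ``inf``.
    """
    n = mol.n_atoms
    if n == 0:
        raise ValueError("empty molecule")
    rows = [i for i, j, _ in mol.bonds] + [j for i, j, _ in mol.bonds]
    cols = [j for i, j, _ in mol.bonds] + [i for i, j, _ in mol.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def geom_distance_matrix(mol: Molecule) -> np.ndarray:
    """Pairwise Euclidean interatomic distances in Å."""
    if mol.n_atoms == 1:
        return np.zeros((1, 1))
    return squareform(pdist(mol.coords))
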