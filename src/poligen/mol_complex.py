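"""Molecular data model, SDF/PDB I/O, pocket extraction and joint graphs.

A diffused ligand is a triple of coordinates (N x 3, Angstrom), one-hot atom
types over a configurable heavy-element vocabulary, and a symmetric N x N
bond-category matrix over {none, single, double, triple}.  The protein pocket
contributes fixed context atoms grouped by residue; its internal edges are
all of category ``none``.  The joint graph used for message passing is fully
connected within the ligand and a radius graph (default 5 A) for
pocket-pocket and ligand-pocket pairs.

All operations act on heavy atoms only; hydrogens are dropped on input and
re-inferred where chemistry needs them (H-bond typing, force fields).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

logger = logging.getLogger(__name__)

# element vocabulary: common drug-like heavy atoms + padding slot for others
ATOM_VOCAB: Tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl", "P", "Br", "B", "I", "*")
BOND_VOCAB: Tuple[str, ...] = ("none", "single", "double", "triple")

BOND_NONE, BOND_SINGLE, BOND_DOUBLE, BOND_TRIPLE = range(4)

_RDKIT_BOND = {
    BOND_SINGLE: Chem.BondType.SINGLE,
    BOND_DOUBLE: Chem.BondType.DOUBLE,
    BOND_TRIPLE: Chem.BondType.TRIPLE,
}
_BOND_FROM_RDKIT = {
    Chem.BondType.SINGLE: BOND_SINGLE,
    Chem.BondType.DOUBLE: BOND_DOUBLE,
    Chem.BondType.TRIPLE: BOND_TRIPLE,
}


def element_index(symbol: str) -> int:
    try:
        return ATOM_VOCAB.index(symbol)
    except ValueError:
        return len(ATOM_VOCAB) - 1  # padding slot


def one_hot(indices: Sequence[int], n: int) -> np.ndarray:
    out = np.zeros((len(indices), n))
    out[np.arange(len(indices)), indices] = 1.0
    return out


@dataclass
class Ligand:
    """Heavy-atom ligand: coordinates, one-hot elements, bond-category matrix."""

    coords: np.ndarray          # N x 3, Angstrom
    atom_types: np.ndarray      # N x A one-hot
    bonds: np.ndarray           # N x N int categories, symmetric, zero diagonal
    name: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_types = np.asarray(self.atom_types, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("ligand needs at least one atom")
        if self.bonds.shape != (n, n):
            raise ValueError("bond matrix shape mismatch")
        if not np.array_equal(self.bonds, self.bonds.T):
            raise ValueError("bond matrix must be symmetric")
        if np.any(np.diag(self.bonds) != BOND_NONE):
            raise ValueError("bond matrix diagonal must be 'none'")
        if not np.allclose(self.atom_types.sum(axis=1), 1.0):
            raise ValueError("atom_types rows must be one-hot")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def elements(self) -> List[str]:
        return [ATOM_VOCAB[i] for i in self.atom_types.argmax(axis=1)]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def translated(self, shift: np.ndarray) -> "Ligand":
        return Ligand(self.coords + shift, self.atom_types.copy(),
                      self.bonds.copy(), self.name)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Build an RDKit molecule (raises on invalid valences if sanitize)."""
        mol = Chem.RWMol()
        for el in self.elements:
            mol.AddAtom(Chem.Atom(el if el != "*" else "C"))
        iu, ju = np.triu_indices(self.n_atoms, k=1)
        for i, j in zip(iu, ju):
            cat = int(self.bonds[i, j])
            if cat != BOND_NONE:
                mol.AddBond(int(i), int(j), _RDKIT_BOND[cat])
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        mol = mol.GetMol()
        mol.AddConformer(conf)
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "Ligand":
        try:
            mol = Chem.RemoveHs(mol)
            Chem.Kekulize(mol, clearAromaticFlags=True)
        except Exception:
            # unsanitized molecule (permissive reading): use raw connectivity
            mol = Chem.Mol(mol)
            mol.UpdatePropertyCache(strict=False)
        n = mol.GetNumAtoms()
        coords = mol.GetConformer().GetPositions()
        idx = [element_index(a.GetSymbol()) for a in mol.GetAtoms()]
        bonds = np.zeros((n, n), dtype=np.int64)
        for b in mol.GetBonds():
            cat = _BOND_FROM_RDKIT.get(b.GetBondType())
            if cat is None:
                raise ValueError(f"unsupported bond type {b.GetBondType()}")
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            bonds[i, j] = bonds[j, i] = cat
        return cls(coords, one_hot(idx, len(ATOM_VOCAB)), bonds,
                   name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""))


@dataclass
class Pocket:
    """Fixed protein context atoms with residue grouping; edges are all 'none'."""

    coords: np.ndarray                       # M x 3
    atom_types: np.ndarray                   # M x A one-hot
    residue_ids: List[Tuple[str, int]]       # (chain, resseq) per atom
    atom_names: List[str] = field(default_factory=list)
    res_names: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.atom_types = np.asarray(self.atom_types, dtype=np.float64)
        if len(self.residue_ids) != self.coords.shape[0]:
            raise ValueError("residue_ids length mismatch")
        if not self.atom_names:
            self.atom_names = [""] * self.n_atoms
        if not self.res_names:
            self.res_names = ["UNK"] * self.n_atoms

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def elements(self) -> List[str]:
        return [ATOM_VOCAB[i] for i in self.atom_types.argmax(axis=1)]

    @property
    def residues(self) -> List[Tuple[str, int]]:
        seen, out = set(), []
        for rid in self.residue_ids:
            if rid not in seen:
                seen.add(rid)
                out.append(rid)
        return out

    def translated(self, shift: np.ndarray) -> "Pocket":
        return Pocket(self.coords + shift, self.atom_types.copy(),
                      list(self.residue_ids), list(self.atom_names),
                      list(self.res_names))


@dataclass
class ProteinAtoms:
    """Flat heavy-atom records of a protein chain(s) with residue grouping."""

    coords: np.ndarray
    elements: List[str]
    residue_ids: List[Tuple[str, int]]
    atom_names: List[str]
    res_names: List[str]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class PLComplex:
    """Joint ligand-pocket graph for message passing.

    ``edge_src``/``edge_dst`` index into the stacked node list (ligand first,
    then pocket); ``edge_cat`` is the bond category (``none`` for every edge
    touching the pocket); ``edge_role`` is one of ``ll``, ``pp``, ``lp``,
    ``pl``.
    """

    ligand: Ligand
    pocket: Pocket
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_cat: np.ndarray
    edge_role: np.ndarray  # array of strings

    @property
    def n_nodes(self) -> int:
        return self.ligand.n_atoms + self.pocket.n_atoms

    def coords(self) -> np.ndarray:
        return np.vstack([self.ligand.coords, self.pocket.coords])


# ---------------------------------------------------------------------------
# pocket extraction & graph construction


def extract_pocket(protein: ProteinAtoms, ligand: Ligand, cutoff: float = 5.0) -> Pocket:
    """Residue-complete pocket: a residue is included iff any of its atoms is
    within ``cutoff`` (inclusive) of any ligand atom; included residues
    contribute all their atoms.
    """
    if protein.n_atoms == 0:
        raise ValueError("empty protein")
    if ligand.n_atoms == 0:
        raise ValueError("empty ligand")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dmin = cdist(protein.coords, ligand.coords).min(axis=1)
    included = set()
    for rid, d in zip(protein.residue_ids, dmin):
        if d <= cutoff:
            included.add(rid)
    mask = np.array([rid in included for rid in protein.residue_ids])
    if not mask.any():
        warnings.warn(f"no residue within {cutoff} A of the ligand; empty pocket")
        return Pocket(np.zeros((0, 3)), np.zeros((0, len(ATOM_VOCAB))), [])
    idx = [element_index(e) for e, m in zip(protein.elements, mask) if m]
    return Pocket(
        protein.coords[mask],
        one_hot(idx, len(ATOM_VOCAB)),
        [rid for rid, m in zip(protein.residue_ids, mask) if m],
        [a for a, m in zip(protein.atom_names, mask) if m],
        [r for r, m in zip(protein.res_names, mask) if m],
    )


def build_complex(ligand: Ligand, pocket: Pocket, radius: float = 5.0) -> PLComplex:
    """Fully connected ligand graph + radius graph for pocket/cross edges."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    nl, np_ = ligand.n_atoms, pocket.n_atoms
    src, dst, cat, role = [], [], [], []

    # ligand-ligand: complete directed graph with bond categories
    for i in range(nl):
        for j in range(nl):
            if i == j:
                continue
            src.append(i)
            dst.append(j)
            cat.append(int(ligand.bonds[i, j]))
            role.append("ll")

    if np_ > 0:
        allc = np.vstack([ligand.coords, pocket.coords])
        d = cdist(allc, allc)
        # pocket-pocket
        for i in range(np_):
            for j in range(np_):
                if i != j and d[nl + i, nl + j] <= radius:
                    src.append(nl + i)
                    dst.append(nl + j)
                    cat.append(BOND_NONE)
                    role.append("pp")
        # cross edges, both directions
        for i in range(nl):
            for j in range(np_):
                if d[i, nl + j] <= radius:
                    src.append(i); dst.append(nl + j)
                    cat.append(BOND_NONE); role.append("lp")
                    src.append(nl + j); dst.append(i)
                    cat.append(BOND_NONE); role.append("pl")

    return PLComplex(ligand, pocket,
                     np.asarray(src, dtype=np.int64),
                     np.asarray(dst, dtype=np.int64),
                     np.asarray(cat, dtype=np.int64),
                     np.asarray(role, dtype=object))


# ---------------------------------------------------------------------------
# I/O


def read_sdf(path, strict: bool = True) -> List[Ligand]:
    """Read a (V2000) SDF; unparseable records are skipped with a warning.

    ``strict=False`` keeps valence-invalid records (e.g. raw generated
    molecules) by reading without sanitization.
    """
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=strict, sanitize=strict)
    for k, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparseable SDF record %d in %s", k, path)
            warnings.warn(f"skipping unparseable SDF record {k} in {path}")
            continue
        try:
            if not strict:
                mol.UpdatePropertyCache(strict=False)
            out.append(Ligand.from_rdkit(mol))
        except Exception as exc:  # conversion failure counts as unparseable
            logger.warning("skipping SDF record %d in %s: %s", k, path, exc)
            warnings.warn(f"skipping SDF record {k} in {path}: {exc}")
    return out


def write_sdf(ligands: Sequence[Ligand], path, properties: Optional[List[dict]] = None):
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for k, lig in enumerate(ligands):
        try:
            mol = lig.to_rdkit(sanitize=True)
        except Exception:
            mol = lig.to_rdkit(sanitize=False)
        if lig.name:
            mol.SetProp("_Name", lig.name)
        if properties is not None:
            for key, val in properties[k].items():
                mol.SetProp(str(key), str(val))
        writer.write(mol)
    writer.close()


def read_pdb(path, drop_hydrogens: bool = True) -> ProteinAtoms:
    """Read coordinate records of the first model of a PDB file."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("prot", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no coordinates in {path}")
    coords, elements, rids, anames, rnames = [], [], [], [], []
    for chain in models[0]:
        for residue in chain:
            for atom in residue:
                el = (atom.element or "").strip().capitalize()
                if drop_hydrogens and el == "H":
                    continue
                coords.append(atom.coord)
                elements.append(el or "C")
                rids.append((chain.id, residue.id[1]))
                anames.append(atom.get_name())
                rnames.append(residue.get_resname())
    if not coords:
        raise ValueError(f"no (heavy-)atom coordinates in {path}")
    return ProteinAtoms(np.asarray(coords, dtype=np.float64), elements,
                        rids, anames, rnames)


def write_pocket_pdb(pocket: Pocket, path):
    """Write pocket atoms as standard ATOM records (one chain per input chain)."""
    with open(path, "w") as fh:
        serial = 1
        for i in range(pocket.n_atoms):
            chain, resseq = pocket.residue_ids[i]
            name = pocket.atom_names[i] or pocket.elements[i]
            el = pocket.elements[i]
            x, y, z = pocket.coords[i]
            fh.write(
                f"ATOM  {serial:5d} {name:<4s} {pocket.res_names[i]:>3s} "
                f"{chain:1s}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n"
            )
            serial += 1
        fh.write("END\n")
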