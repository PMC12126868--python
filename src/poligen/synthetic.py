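"""Synthetic pocket-ligand fixtures.

Generates valence-valid toy ligands of 5-15 heavy atoms over {C, N, O} and
cage-like pockets of residue-grouped atoms on a 3-6 A shell around the
ligand.  Two structurally distinct ligand families are provided so that
latent conditioning has something to separate:

* family ``A`` — acyclic carbon chains (with optional short branches)
  terminated by oxygens on both ends (diol-like);
* family ``B`` — molecules containing a 5/6-membered ring with ring
  nitrogens (azacycle-like), no oxygen.

Geometry is deliberately simplistic: bond lengths ~1.5 A with jitter and
no angular realism.  That is sufficient for diffusion, conditioning and
graph tests; it is not meant to produce low strain energies.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .diffusion import EmpiricalPrior
from .mol_complex import (ATOM_VOCAB, BOND_NONE, BOND_SINGLE, Ligand, PLComplex,
                          Pocket, build_complex, element_index, one_hot)

FAMILIES = ("A", "B")

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _place_next(coords: List[np.ndarray], anchor: np.ndarray,
                rng: np.random.Generator, bond_len: float = 1.5,
                min_sep: float = 1.2, tries: int = 200) -> np.ndarray:
    """Place an atom bonded to ``anchor`` avoiding close non-bonded contacts."""
    for _ in range(tries):
        pos = anchor + _random_unit(rng) * (bond_len + rng.normal(0.0, 0.05))
        if all(np.linalg.norm(pos - c) > min_sep for c in coords):
            return pos
    return pos  # fall back to the last candidate


def make_toy_ligand(family: str, n_atoms: int, rng: np.random.Generator) -> Ligand:
    """Build one valence-valid toy ligand of the requested family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if n_atoms < 5:
        raise ValueError("toy ligands need at least 5 heavy atoms")

    elements: List[str] = []
    bonds: List[Tuple[int, int]] = []
    coords: List[np.ndarray] = []

    if family == "A":
        # oxygen-terminated chain: O-C-...-C-O, optional one-carbon branches
        chain_len = n_atoms
        elements = ["O"] + ["C"] * (chain_len - 2) + ["O"]
        coords.append(np.zeros(3))
        for i in range(1, chain_len):
            coords.append(_place_next(coords, coords[i - 1], rng))
            bonds.append((i - 1, i))
    else:
        # azacycle: ring of 5 or 6 atoms with 2 nitrogens, carbon tail
        ring_size = 6 if n_atoms >= 8 else 5
        ring_elems = ["C"] * ring_size
        ring_elems[0] = "N"
        ring_elems[ring_size // 2] = "N"
        elements = list(ring_elems)
        # planar ring polygon in a random orientation
        theta = np.linspace(0.0, 2 * np.pi, ring_size, endpoint=False)
        r = 1.5 / (2 * np.sin(np.pi / ring_size))
        flat = np.stack([r * np.cos(theta), r * np.sin(theta),
                         np.zeros(ring_size)], axis=1)
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        ring_xyz = flat @ q.T + rng.normal(0.0, 0.02, size=(ring_size, 3))
        coords.extend(list(ring_xyz))
        for i in range(ring_size):
            bonds.append((i, (i + 1) % ring_size))
        # carbon tail off a ring carbon
        anchor = 1
        for i in range(ring_size, n_atoms):
            elements.append("C")
            coords.append(_place_next(coords, coords[anchor], rng))
            bonds.append((anchor, i))
            anchor = i

    n = len(elements)
    bond_mat = np.zeros((n, n), dtype=np.int64)
    for i, j in bonds:
        bond_mat[i, j] = bond_mat[j, i] = BOND_SINGLE
    # valence sanity (single bonds only, so degree == valence used)
    deg = (bond_mat != BOND_NONE).sum(axis=1)
    for el, d in zip(elements, deg):
        assert d <= _MAX_VALENCE[el], "generator produced an over-valent atom"
    xyz = np.asarray(coords)
    xyz -= xyz.mean(axis=0)
    idx = [element_index(e) for e in elements]
    return Ligand(xyz, one_hot(idx, len(ATOM_VOCAB)), bond_mat,
                  name=f"toy-{family}-{n}")


_RES_COMPOSITIONS = (["C", "C", "O"], ["C", "N", "C"], ["C", "C", "C", "O"],
                     ["C", "N", "C", "C"], ["C", "C", "N", "O", "C"])


def make_toy_complex(ligand: Ligand, n_residues: int,
                     rng: np.random.Generator,
                     shell: Tuple[float, float] = (3.0, 6.0),
                     radius: float = 5.0,
                     polar_contact: bool = False) -> PLComplex:
    """Cage pocket: residue clusters on a shell around the ligand.

    Each residue is a 3-5 atom cluster whose nearest-atom distance to the
    ligand lies in ``shell``.  With ``polar_contact`` the first residue
    places a polar atom within H-bond range (~3.0 A) of a polar ligand atom
    when the ligand has one.
    """
    lo, hi = shell
    coords, elements, rids, anames, rnames = [], [], [], [], []
    lig_xyz = ligand.coords
    center = lig_xyz.mean(axis=0)

    polar_idx: Optional[int] = None
    if polar_contact:
        els = ligand.elements
        cand = [i for i, e in enumerate(els) if e in ("N", "O")]
        if cand:
            polar_idx = cand[int(rng.integers(len(cand)))]

    for ri in range(n_residues):
        comp = list(_RES_COMPOSITIONS[int(rng.integers(len(_RES_COMPOSITIONS)))])
        for attempt in range(300):
            u = _random_unit(rng)
            # support of the ligand along u plus a shell offset for the center
            support = (lig_xyz - center) @ u
            d_center = support.max() + rng.uniform(lo + 1.0, hi - 0.5)
            c = center + u * d_center
            cluster = np.stack([c + _random_unit(rng) * rng.uniform(0.3, 0.8)
                                for _ in comp])
            dmin = np.linalg.norm(cluster[:, None, :] - lig_xyz[None, :, :],
                                  axis=2).min()
            ok_others = True
            if coords:
                prev = np.asarray(coords)
                ok_others = np.linalg.norm(
                    cluster[:, None, :] - prev[None, :, :], axis=2).min() > 1.5
            if lo <= dmin <= hi and ok_others:
                break
        if ri == 0 and polar_idx is not None:
            # drag one polar cluster atom to H-bond distance of the ligand atom
            comp[0] = "O" if ligand.elements[polar_idx] == "N" else "N"
            direction = cluster[0] - lig_xyz[polar_idx]
            direction /= np.linalg.norm(direction)
            cluster[0] = lig_xyz[polar_idx] + direction * rng.uniform(2.9, 3.3)
        for k, el in enumerate(comp):
            coords.append(cluster[k])
            elements.append(el)
            rids.append(("A", ri + 1))
            anames.append(f"{el}{k + 1}")
            rnames.append("UNK")

    idx = [element_index(e) for e in elements]
    pocket = Pocket(np.asarray(coords), one_hot(idx, len(ATOM_VOCAB)),
                    rids, anames, rnames)
    return build_complex(ligand, pocket, radius=radius)


def make_dataset(n_complexes: int, rng: np.random.Generator,
                 family_mix: float = 0.5,
                 n_atoms_range: Tuple[int, int] = (5, 15),
                 n_residues_range: Tuple[int, int] = (3, 5),
                 polar_contact: bool = False,
                 ) -> Tuple[List[PLComplex], EmpiricalPrior]:
    """Sample a corpus of toy complexes plus its smoothed empirical prior.

    ``family_mix`` is the probability of family ``A``; atom counts are
    uniform over ``n_atoms_range``.
    """
    complexes = []
    atom_counts = np.zeros(len(ATOM_VOCAB))
    bond_counts = np.zeros(4)
    for _ in range(n_complexes):
        fam = "A" if rng.random() < family_mix else "B"
        n = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
        lig = make_toy_ligand(fam, n, rng)
        nres = int(rng.integers(n_residues_range[0], n_residues_range[1] + 1))
        cpx = make_toy_complex(lig, nres, rng, polar_contact=polar_contact)
        complexes.append(cpx)
        atom_counts += lig.atom_types.sum(axis=0)
        iu, ju = np.triu_indices(lig.n_atoms, k=1)
        cats, counts = np.unique(lig.bonds[iu, ju], return_counts=True)
        bond_counts[cats] += counts
    prior = EmpiricalPrior.from_counts(atom_counts, bond_counts, pseudo=1.0)
    return complexes, prior
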