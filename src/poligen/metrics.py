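"""Evaluation suite: similarity, drug-likeness and pose-quality metrics.

* Shape similarity — Tanimoto of atom-centered Gaussian overlap volumes,
  V_AB / (V_AA + V_BB - V_AB), with one isotropic width per heavy atom
  (carbon-sized), computed in the shared pocket frame without alignment.
* Chemical similarity — Tanimoto of 2048-bit ECFP4 (Morgan radius-2)
  fingerprints.
* Drug-likeness — QED, Crippen logP, H-bond acceptor/donor counts, heavy
  atom count, normalized synthetic accessibility (10 - SA)/9, and a
  five-criterion Lipinski-style count (MW, logP, donors, acceptors,
  rotatable bonds).
* Pose quality — steric clash count against Bondi van-der-Waals radii with
  a 0.5 A tolerance, residue-resolved hydrogen-bond interaction
  fingerprints with recovery percentages against a reference ligand, and
  force-field strain energy (pose energy after constrained cleanup minus
  the minimum over relaxed conformers).
"""

from __future__ import annotations

import os
import sys
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, Crippen, Descriptors, QED, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors
from rdkit import DataStructs

from .mol_complex import Ligand, Pocket
from .sample import reconstruct_molecule

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib synthetic-accessibility scorer)

__all__ = [
    "shape_similarity", "chemical_similarity", "lipinski_count",
    "drug_likeness_panel", "clash_count", "hbond_fingerprint",
    "hbond_recovery", "strain_energy", "evaluate",
]

# Bondi van der Waals radii (Angstrom)
VDW_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "S": 1.80,
    "Cl": 1.75, "P": 1.80, "Br": 1.85, "B": 1.92, "I": 1.98, "*": 1.70,
}

_CARBON_RADIUS = 1.70
# Gaussian width so the atom Gaussian rho = p*exp(-a r^2) matches a hard
# sphere of the carbon vdW radius (ROCS convention, p = 2.7)
_P_GAUSS = 2.7
_ALPHA = np.pi * (3.0 * _P_GAUSS / (4.0 * np.pi)) ** (2.0 / 3.0) / _CARBON_RADIUS ** 2

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


# ---------------------------------------------------------------------------
# similarity


def _overlap_volume(A: np.ndarray, B: np.ndarray) -> float:
    """Sum of pairwise first-order Gaussian overlap volumes."""
    d2 = cdist(A, B) ** 2
    pref = _P_GAUSS ** 2 * (np.pi / (2.0 * _ALPHA)) ** 1.5
    return float(pref * np.exp(-0.5 * _ALPHA * d2).sum())


def shape_similarity(a: Ligand, b: Ligand) -> float:
    """Gaussian-overlap shape Tanimoto in the shared (pocket) frame."""
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("shape similarity of an empty molecule is undefined")
    vab = _overlap_volume(a.coords, b.coords)
    vaa = _overlap_volume(a.coords, a.coords)
    vbb = _overlap_volume(b.coords, b.coords)
    return vab / (vaa + vbb - vab)


def _fingerprint(mol_or_lig):
    if isinstance(mol_or_lig, Ligand):
        mol, _ = reconstruct_molecule(mol_or_lig, require_connected=False)
        if mol is None:
            # valence-invalid molecules can still be fingerprinted on their
            # raw connectivity (ring perception + property cache only)
            try:
                mol = mol_or_lig.to_rdkit(sanitize=False)
                mol.UpdatePropertyCache(strict=False)
                Chem.GetSymmSSSR(mol)
            except Exception:
                return None
    else:
        mol = mol_or_lig
    return _morgan.GetFingerprint(mol)


def chemical_similarity(a, b) -> float:
    """Tanimoto of 2048-bit ECFP4 fingerprints (Ligand or rdkit Mol inputs)."""
    fa, fb = _fingerprint(a), _fingerprint(b)
    if fa is None or fb is None:
        raise ValueError("cannot fingerprint an invalid molecule")
    return float(DataStructs.TanimotoSimilarity(fa, fb))


# ---------------------------------------------------------------------------
# drug-likeness


def _as_mol(mol_or_lig) -> Chem.Mol:
    if isinstance(mol_or_lig, Ligand):
        mol, _ = reconstruct_molecule(mol_or_lig, require_connected=False)
        if mol is None:
            raise ValueError("invalid molecule")
        return mol
    return mol_or_lig


def lipinski_count(mol_or_lig) -> int:
    """Satisfied criteria among MW<=500, logP<=5, HBD<=5, HBA<=10, RotB<=10."""
    mol = _as_mol(mol_or_lig)
    rules = [
        Descriptors.MolWt(mol) <= 500.0,
        Crippen.MolLogP(mol) <= 5.0,
        rdMolDescriptors.CalcNumHBD(mol) <= 5,
        rdMolDescriptors.CalcNumHBA(mol) <= 10,
        rdMolDescriptors.CalcNumRotatableBonds(mol) <= 10,
    ]
    return int(sum(rules))


def drug_likeness_panel(mol_or_lig) -> Dict[str, float]:
    """QED, logP, H-acceptors/donors, heavy-atom count, normalized SA."""
    mol = _as_mol(mol_or_lig)
    sa_raw = sascorer.calculateScore(mol)
    return {
        "qed": float(QED.qed(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "hba": int(rdMolDescriptors.CalcNumHBA(mol)),
        "hbd": int(rdMolDescriptors.CalcNumHBD(mol)),
        "n_atoms": int(mol.GetNumHeavyAtoms()),
        "sa": float((10.0 - sa_raw) / 9.0),
    }


# ---------------------------------------------------------------------------
# pose quality


def clash_count(ligand: Ligand, pocket: Pocket, tolerance: float = 0.5,
                radii: Dict[str, float] = VDW_RADII) -> int:
    """Heavy-atom pairs closer than r_vdw(i) + r_vdw(j) - tolerance."""
    if pocket.n_atoms == 0:
        return 0
    d = cdist(ligand.coords, pocket.coords)
    rl = np.array([radii.get(e, _CARBON_RADIUS) for e in ligand.elements])
    rp = np.array([radii.get(e, _CARBON_RADIUS) for e in pocket.elements])
    thresh = rl[:, None] + rp[None, :] - tolerance
    return int((d < thresh).sum())


def _ligand_polar_atoms(ligand: Ligand) -> Tuple[List[int], List[int]]:
    """(donor indices, acceptor indices) of the ligand's heavy atoms.

    Donors are N/O carrying at least one (implicit) hydrogen inferred from
    unused valence; acceptors are all N/O.
    """
    donors, acceptors = [], []
    max_val = {"N": 3, "O": 2}
    for i, el in enumerate(ligand.elements):
        if el not in ("N", "O"):
            continue
        acceptors.append(i)
        order = {0: 0, 1: 1, 2: 2, 3: 3}
        used = sum(order[int(c)] for c in ligand.bonds[i])
        if max_val[el] - used >= 1:
            donors.append(i)
    return donors, acceptors


def _pocket_polar_atoms(pocket: Pocket) -> Tuple[List[int], List[int]]:
    """Pocket N/O atoms; both roles are allowed (hydrogens unknown,
    distance-only criterion applies)."""
    donors = [i for i, e in enumerate(pocket.elements) if e in ("N", "O")]
    return donors, list(donors)


def hbond_fingerprint(ligand: Ligand, pocket: Pocket,
                      d_max: float = 3.5) -> Dict[Tuple, bool]:
    """Binary interaction fingerprint over (residue id, direction) keys.

    ``direction`` is ``donor-to-ligand`` (pocket donor, ligand acceptor) or
    ``acceptor-from-ligand`` (ligand donor, pocket acceptor).  A bit is set
    iff a donor/acceptor heavy-atom pair lies within ``d_max``; explicit
    hydrogens are unavailable, so the distance-only criterion is used.
    """
    lig_don, lig_acc = _ligand_polar_atoms(ligand)
    poc_don, poc_acc = _pocket_polar_atoms(pocket)
    fp: Dict[Tuple, bool] = {}
    if pocket.n_atoms == 0:
        return fp
    d = cdist(ligand.coords, pocket.coords)
    for j in poc_don:
        rid = pocket.residue_ids[j]
        key = (rid, "donor-to-ligand")
        if any(d[i, j] <= d_max for i in lig_acc):
            fp[key] = True
    for j in poc_acc:
        rid = pocket.residue_ids[j]
        key = (rid, "acceptor-from-ligand")
        if any(d[i, j] <= d_max for i in lig_don):
            fp[key] = True
    return fp


def hbond_recovery(generated: Sequence[Ligand], reference: Ligand,
                   pocket: Pocket) -> float:
    """Mean percentage of reference H-bond bits recovered per generated ligand."""
    fp_ref = hbond_fingerprint(reference, pocket)
    if not fp_ref:
        warnings.warn("reference ligand forms no H-bonds; recovery undefined")
        return float("nan")
    vals = []
    for lig in generated:
        fp_gen = hbond_fingerprint(lig, pocket)
        hits = sum(1 for k in fp_ref if fp_gen.get(k, False))
        vals.append(100.0 * hits / len(fp_ref))
    return float(np.mean(vals))


def strain_energy(ligand: Ligand, n_conformers: int = 20,
                  seed: int = 0xC0FFEE % (2 ** 31)) -> float:
    """Force-field pose strain: E(pose, H/geometry cleanup) - min E(relaxed).

    Uses MMFF94 (UFF fallback).  The pose energy keeps heavy atoms fixed and
    relaxes only added hydrogens; the reference is the minimum energy over
    ``n_conformers`` freshly embedded, fully relaxed conformers.  Negative
    results (conformer-search noise) are clipped to zero with a warning.
    """
    mol, valid = reconstruct_molecule(ligand, require_connected=False)
    if mol is None:
        raise ValueError("cannot build a force-field model of an invalid molecule")
    molH = Chem.AddHs(mol, addCoords=True)

    def _ff(m, conf_id=-1):
        props = AllChem.MMFFGetMoleculeProperties(m)
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(m, props, confId=conf_id)
            if ff is not None:
                return ff
        return AllChem.UFFGetMoleculeForceField(m, confId=conf_id)

    # pose energy: heavy atoms pinned, hydrogens relax
    ff = _ff(molH)
    for atom in molH.GetAtoms():
        if atom.GetAtomicNum() != 1:
            ff.AddFixedPoint(atom.GetIdx())
    ff.Minimize(maxIts=200)
    e_pose = float(ff.CalcEnergy())

    # relaxed reference: embedded conformers, fully minimized
    ref = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    cids = AllChem.EmbedMultipleConfs(ref, numConfs=n_conformers, params=params)
    energies = []
    for cid in cids:
        ffc = _ff(ref, conf_id=cid)
        ffc.Minimize(maxIts=500)
        energies.append(float(ffc.CalcEnergy()))
    if not energies:
        # fall back: relax the pose itself without constraints
        ff2 = _ff(Chem.AddHs(mol, addCoords=True))
        ff2.Minimize(maxIts=500)
        energies = [float(ff2.CalcEnergy())]
    strain = e_pose - min(energies)
    if strain < 0:
        warnings.warn("negative strain (conformer-search noise); clipping to 0")
        strain = 0.0
    return strain


# ---------------------------------------------------------------------------
# batch evaluation


def evaluate(generated: Sequence[Ligand], reference: Ligand, pocket: Pocket,
             compute_strain: bool = False) -> pd.DataFrame:
    """Per-molecule metric table (+ mean/std summary rows).

    Invalid molecules get NaN for chemistry-based metrics; ``validity`` is 1
    when the molecule sanitizes and is a single connected component.  Strain
    energy is optional (conformer embedding dominates the cost).
    """
    if len(generated) == 0:
        raise ValueError("no molecules to evaluate")
    rows = []
    for lig in generated:
        mol, valid = reconstruct_molecule(lig)
        row = {"name": lig.name, "validity": float(valid),
               "shape_sim": shape_similarity(lig, reference),
               "clash_count": clash_count(lig, pocket)}
        fp_ref = hbond_fingerprint(reference, pocket)
        if fp_ref:
            row["hbond_recovery"] = hbond_recovery([lig], reference, pocket)
        if mol is not None:
            row["chem_sim"] = chemical_similarity(mol, _as_mol(reference))
            row["lipinski"] = lipinski_count(mol)
            row.update(drug_likeness_panel(mol))
            if compute_strain:
                row["strain_energy"] = strain_energy(lig)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("name")
    summary = df.agg(["mean", "std"])
    summary.index = ["__mean__", "__std__"]
    return pd.concat([df, summary])
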