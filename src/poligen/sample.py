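"""Latent-conditioned reverse-diffusion sampling.

Generation starts from the prior (zero-CoM Gaussian coordinates, empirical
categorical atom/bond types) and iterates the reverse chain t = T..1: at each
step the denoiser predicts the clean ligand from the current noisy state,
the pocket, the seed latent z and the conditioning strength lambda; then the
Gaussian and categorical posteriors are sampled one step backwards.  The
final step returns the posterior mean for coordinates and the argmax
category for discrete modalities, so the last step is deterministic.

``generate_guided`` adds importance-sampling guidance: K parallel
trajectories are periodically resampled with weights proportional to
exp(score / tau) of the surrogate synthetic-accessibility head.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from rdkit import Chem

from .diffusion import (EmpiricalPrior, categorical_posterior_step,
                        gaussian_posterior_step, sample_prior,
                        symmetric_bond_noise)
from .mol_complex import ATOM_VOCAB, BOND_VOCAB, Ligand, Pocket, one_hot
from .train import Checkpoint, Model

__all__ = ["generate", "generate_guided", "reconstruct_molecule"]


def _resolve_model(checkpoint: Union[Checkpoint, Model]) -> Model:
    return checkpoint.build() if isinstance(checkpoint, Checkpoint) else checkpoint


def _seed_latent(model: Model, seed, unconditional: bool
                 ) -> Tuple[Optional[np.ndarray], Optional[Ligand]]:
    if unconditional:
        return None, seed if isinstance(seed, Ligand) else None
    if isinstance(seed, Ligand):
        return model.encode(seed), seed
    z = np.asarray(seed, dtype=np.float64).reshape(-1)
    return z, None


class _Trajectory:
    """State of one reverse chain."""

    __slots__ = ("coords", "atoms", "bonds")

    def __init__(self, coords, atoms, bonds):
        self.coords, self.atoms, self.bonds = coords, atoms, bonds


def _reverse_step(model: Model, traj: _Trajectory, pocket: Pocket,
                  z: Optional[np.ndarray], t: int, lam: float,
                  rng: np.random.Generator) -> float:
    """Advance one trajectory from t to t-1 in place; returns the SA score."""
    sched = model.schedule
    out = model.denoiser.predict(traj.coords, traj.atoms, traj.bonds, pocket,
                                 z, t, sched.T, lam=lam if z is not None else 0.0)
    traj.coords = gaussian_posterior_step(out.X0_hat, traj.coords, t, sched, rng)
    traj.atoms = categorical_posterior_step(
        out.H0_hat, traj.atoms, t, sched, model.prior.p_atom, rng, "atom_types")
    n = len(traj.atoms)
    iu, ju = np.triu_indices(n, k=1)
    if len(iu):
        eb = categorical_posterior_step(
            out.E0_hat[iu, ju], traj.bonds[iu, ju], t, sched,
            model.prior.p_bond, rng, "bond_types")
        bonds = np.zeros((n, n), dtype=np.int64)
        bonds[iu, ju] = eb
        bonds[ju, iu] = eb
        traj.bonds = bonds
    return out.sa_pred


def _finalize(traj: _Trajectory, center: np.ndarray, name: str) -> Ligand:
    at = one_hot(traj.atoms, len(ATOM_VOCAB))
    return Ligand(traj.coords + center, at, traj.bonds, name=name)


def generate(pocket: Pocket, seed, lam: float = 1.0, n_samples: int = 1,
             n_atoms: Union[int, str] = "from_seed",
             checkpoint: Union[Checkpoint, Model] = None,
             rng: Optional[np.random.Generator] = None,
             unconditional: bool = False) -> List[Ligand]:
    """Sample ligands into ``pocket`` conditioned on a seed ligand (or latent).

    ``seed`` may be a :class:`Ligand` (encoded on the fly; its CoM defines
    the generation frame and, by default, its atom count the sample size) or
    a precomputed latent vector.  ``lam`` in (0, 1] scales the latent's
    influence; ``unconditional=True`` drops the latent entirely (the
    lambda -> 0 limit).
    """
    if not unconditional and not (0.0 < lam <= 1.0):
        raise ValueError("lambda must lie in (0, 1]; "
                         "use unconditional=True for the lambda=0 limit")
    model = _resolve_model(checkpoint)
    rng = rng or np.random.default_rng()
    z, seed_lig = _seed_latent(model, seed, unconditional)
    if n_atoms == "from_seed":
        if seed_lig is None:
            raise ValueError("n_atoms='from_seed' requires a Ligand seed")
        n_atoms = seed_lig.n_atoms
    center = (seed_lig.centroid() if seed_lig is not None
              else pocket.coords.mean(axis=0))
    pocket_c = pocket.translated(-center)

    out: List[Ligand] = []
    T = model.schedule.T
    for k in range(n_samples):
        prior_state = sample_prior(int(n_atoms), model.prior, rng, t=T)
        traj = _Trajectory(prior_state.coords, prior_state.atom_cats,
                           prior_state.bond_cats)
        for t in range(T, 0, -1):
            _reverse_step(model, traj, pocket_c, z, t, lam, rng)
        out.append(_finalize(traj, center, name=f"gen-{k}"))
    return out


def generate_guided(pocket: Pocket, seed, lam: float = 1.0, n_samples: int = 8,
                    checkpoint: Union[Checkpoint, Model] = None,
                    rng: Optional[np.random.Generator] = None,
                    population: int = 8, resample_every: int = 50,
                    temperature: float = 0.1,
                    n_atoms: Union[int, str] = "from_seed",
                    unconditional: bool = False) -> List[Ligand]:
    """Importance-sampling guidance toward high surrogate SA scores.

    Runs ``population`` parallel trajectories; every ``resample_every``
    reverse steps the trajectories are resampled (multinomial, with
    replacement) with weights proportional to exp(score / temperature).
    """
    if population < 2:
        raise ValueError("population must be at least 2")
    if not unconditional and not (0.0 < lam <= 1.0):
        raise ValueError("lambda must lie in (0, 1]")
    model = _resolve_model(checkpoint)
    rng = rng or np.random.default_rng()
    z, seed_lig = _seed_latent(model, seed, unconditional)
    if n_atoms == "from_seed":
        if seed_lig is None:
            raise ValueError("n_atoms='from_seed' requires a Ligand seed")
        n_atoms = seed_lig.n_atoms
    center = (seed_lig.centroid() if seed_lig is not None
              else pocket.coords.mean(axis=0))
    pocket_c = pocket.translated(-center)
    T = model.schedule.T

    out: List[Ligand] = []
    while len(out) < n_samples:
        trajs = []
        for _ in range(population):
            st = sample_prior(int(n_atoms), model.prior, rng, t=T)
            trajs.append(_Trajectory(st.coords, st.atom_cats, st.bond_cats))
        steps_done = 0
        for t in range(T, 0, -1):
            scores = np.array([
                _reverse_step(model, tr, pocket_c, z, t, lam, rng)
                for tr in trajs])
            steps_done += 1
            if steps_done % resample_every == 0 and t > 1:
                w = np.exp((scores - scores.max()) / temperature)
                w /= w.sum()
                pick = rng.choice(population, size=population, p=w)
                trajs = [_Trajectory(trajs[i].coords.copy(),
                                     trajs[i].atoms.copy(),
                                     trajs[i].bonds.copy()) for i in pick]
        for tr in trajs:
            if len(out) < n_samples:
                out.append(_finalize(tr, center, name=f"gen-sa-{len(out)}"))
    return out


def reconstruct_molecule(ligand: Ligand, require_connected: bool = True
                         ) -> Tuple[Optional[Chem.Mol], bool]:
    """Build an RDKit molecule from categories + coordinates and check it.

    Validity requires passing valence sanitization and (by default) being a
    single connected component.  Returns ``(mol_or_None, valid)``.
    """
    try:
        mol = ligand.to_rdkit(sanitize=True)
    except Exception:
        return None, False
    frags = Chem.GetMolFrags(mol)
    if require_connected and len(frags) > 1:
        return mol, False
    return mol, True
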