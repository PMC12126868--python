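"""Forward, posterior and reverse diffusion kernels.

Coordinates diffuse as a zero-center-of-mass (CoM) Gaussian under the usual
DDPM marginal; atom and bond categories diffuse as categorical chains whose
single-step kernel mixes the identity with a fixed empirical prior p:

    Q_t     = alpha_t      * I + (1 - alpha_t)     * 1 p^T
    Q_bar_t = alpha_bar_t  * I + (1 - alpha_bar_t) * 1 p^T

The model is trained under the data parameterization: the network predicts
the clean sample M0_hat and the reverse step samples from the tractable
posterior q(x_{t-1} | x_t, x0_hat).

Bond noise is drawn on the upper triangle only and mirrored so bond matrices
stay symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol_complex import ATOM_VOCAB, BOND_VOCAB
from .schedule import NoiseSchedule

__all__ = [
    "EmpiricalPrior", "NoisyLigand", "project_zero_com", "gaussian_forward",
    "gaussian_posterior_step", "categorical_forward", "categorical_posterior_step",
    "categorical_posterior", "sample_prior",
]


@dataclass
class EmpiricalPrior:
    """Laplace-smoothed category frequencies from a training corpus."""

    p_atom: np.ndarray
    p_bond: np.ndarray

    def __post_init__(self):
        self.p_atom = np.asarray(self.p_atom, dtype=np.float64)
        self.p_bond = np.asarray(self.p_bond, dtype=np.float64)
        for p in (self.p_atom, self.p_bond):
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("prior entries must be a probability vector")

    @classmethod
    def uniform(cls, n_atom: int = len(ATOM_VOCAB), n_bond: int = len(BOND_VOCAB)):
        return cls(np.full(n_atom, 1.0 / n_atom), np.full(n_bond, 1.0 / n_bond))

    @classmethod
    def from_counts(cls, atom_counts, bond_counts, pseudo: float = 1.0):
        a = np.asarray(atom_counts, dtype=np.float64) + pseudo
        b = np.asarray(bond_counts, dtype=np.float64) + pseudo
        return cls(a / a.sum(), b / b.sum())


@dataclass
class NoisyLigand:
    """Ligand-shaped state at diffusion step t (categories, not one-hot)."""

    coords: np.ndarray       # N x 3, zero CoM
    atom_cats: np.ndarray    # N ints
    bond_cats: np.ndarray    # N x N ints, symmetric, zero diagonal
    t: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        com = self.coords.mean(axis=0)
        if np.linalg.norm(com) > 1e-6:
            raise ValueError("noisy ligand coordinates must have zero CoM")


def project_zero_com(coords: np.ndarray) -> np.ndarray:
    """Remove the column mean (center of mass) from coordinates."""
    coords = np.asarray(coords, dtype=np.float64)
    return coords - coords.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Gaussian (coordinates)


def gaussian_forward(X0: np.ndarray, t: int, schedule: NoiseSchedule,
                     noise: np.ndarray) -> np.ndarray:
    """Marginal forward sample X_t = sqrt(ab) X0 + sqrt(1-ab) eps (zero-CoM)."""
    ab = schedule.alpha_bar(t, "coords")
    return np.sqrt(ab) * X0 + np.sqrt(1.0 - ab) * noise


def gaussian_posterior_step(X0_hat: np.ndarray, Xt: np.ndarray, t: int,
                            schedule: NoiseSchedule,
                            rng: np.random.Generator) -> np.ndarray:
    """One reverse step: sample q(X_{t-1} | X_t, X0_hat); returns the mean at t=1.

    Posterior mean and variance follow the standard DDPM identities

        mu  = sqrt(ab_{t-1}) beta_t / (1 - ab_t) * X0_hat
            + sqrt(alpha_t) (1 - ab_{t-1}) / (1 - ab_t) * X_t
        var = beta_t (1 - ab_{t-1}) / (1 - ab_t)

    with sampled noise projected to the zero-CoM subspace.
    """
    ab_t = schedule.alpha_bar(t, "coords")
    ab_prev = schedule.alpha_bar(t - 1, "coords")
    a_t = schedule.alpha(t, "coords")
    b_t = 1.0 - a_t
    mean = (np.sqrt(ab_prev) * b_t / (1.0 - ab_t)) * X0_hat \
        + (np.sqrt(a_t) * (1.0 - ab_prev) / (1.0 - ab_t)) * Xt
    if t == 1:
        return mean
    var = b_t * (1.0 - ab_prev) / (1.0 - ab_t)
    eps = project_zero_com(rng.standard_normal(Xt.shape))
    return mean + np.sqrt(var) * eps


# ---------------------------------------------------------------------------
# categorical (atom / bond types)


def _Q(alpha: float, p: np.ndarray) -> np.ndarray:
    """Transition matrix alpha*I + (1-alpha) 1 p^T (rows: from-state)."""
    K = p.shape[0]
    return alpha * np.eye(K) + (1.0 - alpha) * np.ones((K, 1)) * p[None, :]


def categorical_forward(H0: np.ndarray, t: int, schedule: NoiseSchedule,
                        p: np.ndarray, rng: np.random.Generator,
                        modality: str) -> np.ndarray:
    """Sample categories from rows of H0 @ Q_bar_t (H0 one-hot rows)."""
    ab = float(schedule.alpha_bar(t, modality))
    probs = H0 @ _Q(ab, p)
    return _sample_rows(probs, rng)


def categorical_posterior(H0_hat: np.ndarray, Ht_cats: np.ndarray, t: int,
                          schedule: NoiseSchedule, p: np.ndarray,
                          modality: str) -> np.ndarray:
    """Posterior probability rows q(x_{t-1} | x_t, x0_hat).

    Per row: q proportional to Q_t[:, x_t] * (Q_bar_{t-1}^T @ x0_hat).
    """
    a_t = float(schedule.alpha(t, modality))
    ab_prev = float(schedule.alpha_bar(t - 1, modality))
    Qt = _Q(a_t, p)
    Qbar_prev = _Q(ab_prev, p)
    like = Qt[:, Ht_cats].T                  # R x K: Q_t[i, x_t] per row
    prior = H0_hat @ Qbar_prev               # R x K: sum_k x0hat_k Qbar[k, i]
    post = like * prior
    z = post.sum(axis=1, keepdims=True)
    if np.any(z <= 0):
        raise ValueError("zero normalizer in categorical posterior")
    return post / z


def categorical_posterior_step(H0_hat: np.ndarray, Ht_cats: np.ndarray, t: int,
                               schedule: NoiseSchedule, p: np.ndarray,
                               rng: np.random.Generator, modality: str,
                               final_mode: str = "argmax") -> np.ndarray:
    """Sample one reverse categorical step; at t=1 use argmax (or sample)."""
    post = categorical_posterior(H0_hat, Ht_cats, t, schedule, p, modality)
    if t == 1 and final_mode == "argmax":
        return post.argmax(axis=1)
    return _sample_rows(post, rng)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a probability matrix."""
    cdf = probs.cumsum(axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((probs.shape[0], 1))
    return (u > cdf).sum(axis=1)


# ---------------------------------------------------------------------------
# prior sampling and symmetric-bond helpers


def symmetric_bond_noise(n: int, sampler) -> np.ndarray:
    """Build a symmetric zero-diagonal category matrix by sampling the upper
    triangle with ``sampler(n_entries) -> categories`` and mirroring."""
    iu, ju = np.triu_indices(n, k=1)
    vals = sampler(len(iu))
    out = np.zeros((n, n), dtype=np.int64)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def sample_prior(n_atoms: int, prior: EmpiricalPrior,
                 rng: np.random.Generator, t: int = 0) -> NoisyLigand:
    """Draw M_T: zero-CoM standard-normal coordinates, i.i.d. categorical
    atom/bond types from the empirical prior (bonds symmetric)."""
    coords = project_zero_com(rng.standard_normal((n_atoms, 3)))
    atoms = rng.choice(len(prior.p_atom), size=n_atoms, p=prior.p_atom)
    bonds = symmetric_bond_noise(
        n_atoms, lambda m: rng.choice(len(prior.p_bond), size=m, p=prior.p_bond))
    return NoisyLigand(coords, atoms, bonds, t=t)
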