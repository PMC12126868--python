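"""Joint training of the denoiser and latent encoder.

Per optimization step: draw a batch of pocket-ligand complexes and a step
t ~ U{1..T}; encode each clean ligand into its latent z; corrupt every
modality at its own cumulative noise level; run the denoiser on the noisy
ligand with pocket, z and t as context; and minimize

    L = w_s(t) * ( lx * ||X0 - X0_hat||^2
                 + lh * CE(H0, H0_hat) + le * CE(E0, E0_hat) )
        + mmd_weight * MMD^2(Z, Z_prior) + node_count_weight * CE(count)

with (lx, lh, le) = (3, 0.4, 2).  The coordinate term is summed over atoms,
the cross-entropy terms are averaged over atoms / upper-triangle bond
entries, and everything is averaged over the batch.  The MMD term matches
the batch of latents to an isotropic Gaussian; the node-count head is the
encoder's self-supervised task.  Optimization uses AdamW with gradient-norm
clipping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Parameter, Tensor, concat, log_softmax, softmax
from .diffusion import (EmpiricalPrior, categorical_forward, gaussian_forward,
                        project_zero_com, symmetric_bond_noise)
from .mol_complex import ATOM_VOCAB, BOND_VOCAB, Ligand, PLComplex, Pocket
from .networks import (Denoiser, DenoiserConfig, DenoiserOutput, EncoderConfig,
                       LatentEncoder)
from .schedule import NoiseSchedule

logger = logging.getLogger(__name__)


@dataclass
class LossWeights:
    """Modality weights of the diffusion loss plus auxiliary-loss weights."""

    lx: float = 3.0
    lh: float = 0.4
    le: float = 2.0
    mmd_weight: float = 1.0
    node_count_weight: float = 0.1
    composition_weight: float = 1.0   # self-supervised atom-fraction task

    def to_dict(self):
        return self.__dict__.copy()


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    lr: float = 2e-4
    weight_decay: float = 1e-12
    grad_clip: float = 10.0
    seed: int = 0
    lam_train: float = 1.0
    lam_min: float = 1.0          # <1: per-example lambda ~ U(lam_min, lam_train)
    sa_head_weight: float = 0.0   # >0 trains the surrogate SA head jointly

    def to_dict(self):
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# losses (public numpy forms + internal autodiff forms)


def diffusion_loss(ligand: Ligand, output: DenoiserOutput, t: int,
                   schedule: NoiseSchedule,
                   weights: LossWeights = LossWeights()) -> float:
    """Weighted denoising loss against the clean (zero-CoM) ligand."""
    X0 = project_zero_com(ligand.coords)
    if output.X0_hat.shape != X0.shape:
        raise ValueError("coordinate shape mismatch")
    coord = float(((X0 - output.X0_hat) ** 2).sum())
    eps = 1e-12
    ce_h = float(-(ligand.atom_types * np.log(output.H0_hat + eps)).sum(axis=1).mean())
    iu, ju = np.triu_indices(ligand.n_atoms, k=1)
    if len(iu):
        true_oh = np.zeros((len(iu), len(BOND_VOCAB)))
        true_oh[np.arange(len(iu)), ligand.bonds[iu, ju]] = 1.0
        ce_e = float(-(true_oh * np.log(output.E0_hat[iu, ju] + eps)).sum(axis=1).mean())
    else:
        ce_e = 0.0
    w = float(schedule.snr_weight(t))
    return w * (weights.lx * coord + weights.lh * ce_h + weights.le * ce_e)


def _diffusion_loss_t(ligand: Ligand, out: Dict, t: int,
                      schedule: NoiseSchedule, weights: LossWeights) -> Tensor:
    X0 = Tensor(project_zero_com(ligand.coords))
    diffc = X0 - out["x0"]
    coord = (diffc * diffc).sum()
    logp_h = log_softmax(out["h_logits"], axis=1)
    ce_h = -(Tensor(ligand.atom_types) * logp_h).sum(axis=1).mean()
    iu, ju = out["iu"], out["ju"]
    if len(iu):
        true_oh = np.zeros((len(iu), len(BOND_VOCAB)))
        true_oh[np.arange(len(iu)), ligand.bonds[iu, ju]] = 1.0
        logp_e = log_softmax(out["e_logits"], axis=1)
        ce_e = -(Tensor(true_oh) * logp_e).sum(axis=1).mean()
    else:
        ce_e = Tensor(0.0)
    w = float(schedule.snr_weight(t))
    return (coord * weights.lx + ce_h * weights.lh + ce_e * weights.le) * w


def _mmd_t(Z: Tensor, Z_prior: np.ndarray, biased: bool = False) -> Tensor:
    """Multi-bandwidth Gaussian-kernel squared MMD (unbiased by default)."""
    B, _ = Z.shape
    Bp = Z_prior.shape[0]
    allp = np.vstack([Z.data, Z_prior])
    d2_all = ((allp[:, None, :] - allp[None, :, :]) ** 2).sum(-1)
    off = d2_all[~np.eye(len(allp), dtype=bool)]
    base = np.median(off) if np.any(off > 0) else 1.0
    scales = [0.25, 0.5, 1.0, 2.0, 4.0]

    Zp = Tensor(Z_prior)

    def sq_dists(A: Tensor, Bt: Tensor) -> Tensor:
        aa = (A * A).sum(axis=1, keepdims=True)
        bb = (Bt * Bt).sum(axis=1, keepdims=True)
        return aa + bb.T - (A @ Bt.T) * 2.0

    def kmean(A: Tensor, Bt: Tensor, exclude_diag: bool) -> Tensor:
        d2 = sq_dists(A, Bt)
        n, m = d2.shape
        total = Tensor(0.0)
        for s in scales:
            total = total + (d2 * (-1.0 / (2.0 * s * base))).exp()
        if exclude_diag:
            mask = 1.0 - np.eye(n)
            return (total * Tensor(mask)).sum() * (1.0 / (n * (n - 1)))
        return total.sum() * (1.0 / (n * m))

    ex = not biased
    return kmean(Z, Z, ex) + kmean(Zp, Zp, ex) - kmean(Z, Zp, False) * 2.0


def mmd_loss(Z: np.ndarray, Z_prior: np.ndarray, biased: bool = False) -> float:
    """Squared maximum mean discrepancy between latents and Gaussian draws."""
    return float(_mmd_t(Tensor(np.asarray(Z, dtype=np.float64)),
                        np.asarray(Z_prior, dtype=np.float64), biased).data)


def node_count_loss(logits: np.ndarray, n_true: int, n_min: int = 1) -> float:
    """Cross-entropy of the encoder's node-count head."""
    return float(_node_count_t(Tensor(np.asarray(logits, dtype=np.float64)),
                               n_true, n_min).data)


def _node_count_t(logits: Tensor, n_true: int, n_min: int) -> Tensor:
    logp = log_softmax(logits.reshape(1, -1), axis=1)
    idx = n_true - n_min
    if not (0 <= idx < logits.shape[-1]):
        raise ValueError(f"atom count {n_true} outside the count-head range")
    onehot = np.zeros((1, logits.shape[-1]))
    onehot[0, idx] = 1.0
    return -(Tensor(onehot) * logp).sum()


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    def __init__(self, params: Sequence[Parameter], lr: float = 2e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-12):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in self.params if p.grad is not None))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.wd * p.data)


# ---------------------------------------------------------------------------
# model bundle & checkpointing


@dataclass
class Checkpoint:
    """Weights + configs + schedule + empirical prior, serializable to .npz."""

    encoder_state: Dict[str, np.ndarray]
    denoiser_state: Dict[str, np.ndarray]
    encoder_config: EncoderConfig
    denoiser_config: DenoiserConfig
    schedule: NoiseSchedule
    prior: EmpiricalPrior
    weights: LossWeights = field(default_factory=LossWeights)

    def save(self, path):
        meta = json.dumps({
            "encoder_config": self.encoder_config.to_dict(),
            "denoiser_config": self.denoiser_config.to_dict(),
            "schedule": self.schedule.to_dict(),
            "weights": self.weights.to_dict(),
        })
        arrays = {f"enc::{k}": v for k, v in self.encoder_state.items()}
        arrays.update({f"den::{k}": v for k, v in self.denoiser_state.items()})
        arrays["prior::p_atom"] = self.prior.p_atom
        arrays["prior::p_bond"] = self.prior.p_bond
        arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            enc = {k[5:]: data[k] for k in data.files if k.startswith("enc::")}
            den = {k[5:]: data[k] for k in data.files if k.startswith("den::")}
            prior = EmpiricalPrior(data["prior::p_atom"], data["prior::p_bond"])
        return cls(enc, den,
                   EncoderConfig.from_dict(meta["encoder_config"]),
                   DenoiserConfig.from_dict(meta["denoiser_config"]),
                   NoiseSchedule.from_dict(meta["schedule"]),
                   prior, LossWeights(**meta["weights"]))

    def build(self) -> "Model":
        rng = np.random.default_rng(0)
        enc = LatentEncoder(self.encoder_config, rng)
        den = Denoiser(self.denoiser_config, rng)
        enc.load_state_dict(self.encoder_state)
        den.load_state_dict(self.denoiser_state)
        return Model(enc, den, self.schedule, self.prior)


@dataclass
class Model:
    """Trained (or freshly initialized) encoder + denoiser bundle."""

    encoder: LatentEncoder
    denoiser: Denoiser
    schedule: NoiseSchedule
    prior: EmpiricalPrior

    def encode(self, ligand: Ligand) -> np.ndarray:
        z, _ = self.encoder.encode(ligand)
        return z

    def checkpoint(self, weights: LossWeights = LossWeights()) -> Checkpoint:
        return Checkpoint(self.encoder.state_dict(), self.denoiser.state_dict(),
                          self.encoder.config, self.denoiser.config,
                          self.schedule, self.prior, weights)


# ---------------------------------------------------------------------------
# training example preparation (kept separate so tests can control the noise)


@dataclass
class TrainingExample:
    ligand: Ligand           # clean, zero-CoM
    pocket: Pocket           # translated with the ligand
    t: int
    noisy_coords: np.ndarray
    noisy_atoms: np.ndarray
    noisy_bonds: np.ndarray


def prepare_example(cpx: PLComplex, t: int, schedule: NoiseSchedule,
                    prior: EmpiricalPrior, rng: np.random.Generator,
                    coord_noise: Optional[np.ndarray] = None) -> TrainingExample:
    """Center the complex on the ligand CoM and corrupt every modality."""
    shift = -cpx.ligand.centroid()
    lig = cpx.ligand.translated(shift)
    poc = cpx.pocket.translated(shift)
    if coord_noise is None:
        coord_noise = project_zero_com(rng.standard_normal(lig.coords.shape))
    Xt = gaussian_forward(lig.coords, t, schedule, coord_noise)
    atom_cats = lig.atom_types.argmax(axis=1)
    H0 = np.eye(len(ATOM_VOCAB))[atom_cats]
    Ht = categorical_forward(H0, t, schedule, prior.p_atom, rng, "atom_types")
    iu, ju = np.triu_indices(lig.n_atoms, k=1)
    E0_ut = np.eye(len(BOND_VOCAB))[lig.bonds[iu, ju]]
    Et_ut = categorical_forward(E0_ut, t, schedule, prior.p_bond, rng,
                                "bond_types")
    Et = np.zeros_like(lig.bonds)
    Et[iu, ju] = Et_ut
    Et[ju, iu] = Et_ut
    return TrainingExample(lig, poc, t, Xt, Ht, Et)


def example_losses(encoder: LatentEncoder, denoiser: Denoiser,
                   ex: TrainingExample, schedule: NoiseSchedule,
                   weights: LossWeights, lam: float = 1.0,
                   sa_target: Optional[float] = None,
                   ) -> Tuple[Tensor, Tensor, Tensor, Optional[Tensor]]:
    """(diffusion loss, z, auxiliary CE, optional SA regression) tensors.

    The auxiliary term is the node-count cross-entropy plus the
    self-supervised composition loss (squared error between softmaxed
    composition-head output and the ligand's atom-type fractions), the
    latter scaled by ``weights.composition_weight``.
    """
    z, count_logits = encoder.forward(ex.ligand)
    out = denoiser.forward(ex.noisy_coords, ex.noisy_atoms, ex.noisy_bonds,
                           ex.pocket, z, ex.t / schedule.T, lam)
    dloss = _diffusion_loss_t(ex.ligand, out, ex.t, schedule, weights)
    closs = _node_count_t(count_logits, ex.ligand.n_atoms,
                          encoder.config.count_range[0])
    if weights.composition_weight > 0:
        frac = ex.ligand.atom_types.mean(axis=0, keepdims=True)
        pred = softmax(encoder.comp_head(z.reshape(1, -1)), axis=1)
        diff = pred - Tensor(frac)
        closs = closs + (diff * diff).sum() * weights.composition_weight
    sa_loss = None
    if sa_target is not None:
        diff = out["sa"] - Tensor(np.array([[sa_target]]))
        sa_loss = (diff * diff).sum()
    return dloss, z, closs, sa_loss


def train(dataset: Sequence[PLComplex], config: TrainConfig,
          schedule: Optional[NoiseSchedule] = None,
          prior: Optional[EmpiricalPrior] = None,
          encoder_config: Optional[EncoderConfig] = None,
          denoiser_config: Optional[DenoiserConfig] = None,
          weights: LossWeights = LossWeights(),
          sa_targets: Optional[Sequence[float]] = None,
          log: Optional[List[dict]] = None) -> Checkpoint:
    """Joint training loop; returns the final checkpoint.

    ``sa_targets`` (one normalized SA score per complex) switches on the
    surrogate head when ``config.sa_head_weight > 0``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    schedule = schedule or NoiseSchedule()
    prior = prior or EmpiricalPrior.uniform()
    encoder_config = encoder_config or EncoderConfig()
    denoiser_config = denoiser_config or DenoiserConfig()
    rng = np.random.default_rng(config.seed)
    encoder = LatentEncoder(encoder_config, rng)
    denoiser = Denoiser(denoiser_config, rng)
    params = encoder.parameters() + denoiser.parameters()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            t = int(rng.integers(1, schedule.T + 1))
            dsum, csum, ssum = Tensor(0.0), Tensor(0.0), Tensor(0.0)
            zs = []
            for idx in batch:
                ex = prepare_example(dataset[idx], t, schedule, prior, rng)
                tgt = (sa_targets[idx] if sa_targets is not None
                       and config.sa_head_weight > 0 else None)
                # exercising intermediate lambdas during training makes the
                # sampling-time conditioning-strength knob well-defined
                lam = config.lam_train
                if config.lam_min < config.lam_train and rng.random() < 0.5:
                    lam = float(rng.uniform(config.lam_min, config.lam_train))
                dl, z, cl, sl = example_losses(encoder, denoiser, ex, schedule,
                                               weights, lam, tgt)
                dsum = dsum + dl
                csum = csum + cl
                if sl is not None:
                    ssum = ssum + sl
                zs.append(z.reshape(1, -1))
            bsz = len(batch)
            total = dsum * (1.0 / bsz) + csum * (weights.node_count_weight / bsz)
            if config.sa_head_weight > 0:
                total = total + ssum * (config.sa_head_weight / bsz)
            if weights.mmd_weight > 0 and bsz > 1:
                Z = concat(zs, axis=0)
                Zp = rng.standard_normal((bsz, encoder_config.k))
                total = total + _mmd_t(Z, Zp) * weights.mmd_weight
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start}: {total.data}")
            total.backward()
            opt.clip_grad_norm(config.grad_clip)
            opt.step()
            if log is not None:
                log.append({"epoch": epoch, "t": t,
                            "loss": float(total.data),
                            "diffusion": float(dsum.data) / bsz})
    model = Model(encoder, denoiser, schedule, prior)
    return model.checkpoint(weights)
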