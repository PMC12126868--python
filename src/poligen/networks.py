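"""Invariant latent encoder, equivariant denoiser and AdaLN conditioning.

Both networks are E(3)-aware message-passing networks built from invariant
scalar messages (radial basis features of interatomic distances plus edge
categories).  The encoder never touches coordinates, so its latent ``z`` is
invariant to rotations, translations and atom permutations by construction;
the denoiser updates ligand coordinates along relative difference vectors,
which makes its coordinate head rotation-equivariant.

The latent is injected through adaptive layer normalization (AdaLN): the
per-channel scale and shift of the node-embedding normalization are predicted
from ``z`` by linear layers and blended with plain layer normalization by the
control parameter ``lambda`` in (0, 1] — at ``lambda -> 0`` the denoiser
reverts to an unconditional model.  (A literal gate in which the whole output
is scaled by ``lambda`` is available behind ``literal_gate=True``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Parameter, Tensor, concat, log_softmax, segment_sum, softmax
from .mol_complex import ATOM_VOCAB, BOND_VOCAB, Ligand, Pocket

N_ATOM = len(ATOM_VOCAB)
N_BOND = len(BOND_VOCAB)


# ---------------------------------------------------------------------------
# building blocks


class Module:
    """Tiny parameter container with named state."""

    def named_parameters(self, prefix: str = "") -> Dict[str, Parameter]:
        out: Dict[str, Parameter] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                out[key] = attr
            elif isinstance(attr, Module):
                out.update(attr.named_parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> List[Parameter]:
        return list(self.named_parameters().values())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        params = self.named_parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=np.float64).copy()
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Linear stack with SiLU between layers (none after the last)."""

    def __init__(self, sizes: List[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.layers):
            x = lin(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x


def rbf_expand(d: Tensor, n_rbf: int, r_max: float) -> Tensor:
    """Gaussian radial basis features of a distance column (E x 1)."""
    centers = np.linspace(0.0, r_max, n_rbf)[None, :]
    gamma = 0.5 * ((n_rbf - 1) / r_max) ** 2
    diff = d - Tensor(centers)
    return (diff * diff * (-gamma)).exp()


def time_embedding(t_frac: float, dim: int = 8) -> np.ndarray:
    """Sinusoidal embedding of the diffusion progress t/T."""
    freqs = 2.0 ** np.arange(dim // 2)
    ang = np.pi * t_frac * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


# ---------------------------------------------------------------------------
# AdaLN


class AdaLNParams(Module):
    """Linear maps z -> per-channel scale s(z) and shift b(z).

    Initialized at the identity (s(z)=1, b(z)=0 for every z) so conditioning
    starts as plain layer normalization and deviations are learned
    gradually — the usual stabilization for adaptive-normalization
    conditioning in diffusion models.
    """

    def __init__(self, k: int, hidden: int, rng: np.random.Generator):
        self.scale = Linear(k, hidden, rng)
        self.shift = Linear(k, hidden, rng)
        self.scale.W.data[:] = 0.0
        self.scale.b.data[:] = 1.0
        self.shift.W.data[:] = 0.0
        self.shift.b.data[:] = 0.0


def adaptive_layer_norm(H: Tensor, z: Optional[Tensor], lam: float,
                        params: Optional[AdaLNParams] = None,
                        literal_gate: bool = False) -> Tensor:
    """Latent-conditioned layer normalization across the node axis.

    mean/std are computed per feature channel over nodes.  The committed gate
    interpolates plain LN and full AdaLN:

        out = ((1 - lam) + lam * s(z)) * H_norm + lam * b(z)

    so ``lam -> 0`` recovers plain normalization regardless of z.  With
    ``literal_gate`` the scale is ``lam * s(z)`` (the whole output then
    vanishes as lam -> 0).
    """
    mu = H.mean(axis=0, keepdims=True)
    centered = H - mu
    var = (centered * centered).mean(axis=0, keepdims=True)
    sigma = (var + 1e-12).sqrt()
    # guard tiny channels: add eps to near-zero denominators
    eps_mask = (sigma.data < 1e-6) * 1e-5
    H_norm = centered / (sigma + Tensor(eps_mask))
    if lam == 0.0 or z is None or params is None:
        return H_norm
    z_row = z.reshape(1, -1)
    s = params.scale(z_row)      # 1 x hidden
    b = params.shift(z_row)
    if literal_gate:
        gate = s * lam
    else:
        gate = s * lam + (1.0 - lam)
    return gate * H_norm + b * lam


# ---------------------------------------------------------------------------
# configs


@dataclass
class EncoderConfig:
    layers: int = 8
    hidden: int = 128
    edge_dim: int = 16
    radius: float = 5.0
    k: int = 128
    n_rbf: int = 16
    count_range: Tuple[int, int] = (1, 64)

    def to_dict(self):
        d = self.__dict__.copy()
        d["count_range"] = list(self.count_range)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["count_range"] = tuple(d["count_range"])
        return cls(**d)


@dataclass
class DenoiserConfig:
    layers: int = 12
    hidden: int = 256
    edge_dim: int = 128
    k: int = 128
    n_rbf: int = 16
    time_dim: int = 8
    r_max: float = 10.0          # RBF support, not a connectivity cutoff
    literal_gate: bool = False

    def to_dict(self):
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


# ---------------------------------------------------------------------------
# latent encoder


class LatentEncoder(Module):
    """G-invariant graph encoder with attention pooling and node-count head."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        h, e = config.hidden, config.edge_dim
        self.lin_in = Linear(N_ATOM, h, rng)
        self.edge_proj = [Linear(config.n_rbf + N_BOND, e, rng)
                          for _ in range(config.layers)]
        self.msg = [MLP([2 * h + e, h, h], rng) for _ in range(config.layers)]
        self.upd = [MLP([2 * h, h, h], rng) for _ in range(config.layers)]
        self.att = Linear(h, 1, rng)
        self.proj_out = Linear(h, config.k, rng)
        n_counts = config.count_range[1] - config.count_range[0] + 1
        self.count_head = MLP([config.k, config.k, n_counts], rng)
        # self-supervised composition head: atom-type fractions from z
        self.comp_head = MLP([config.k, config.k, N_ATOM], rng)

    def _edges(self, coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        d = cdist(coords, coords)
        src, dst = np.nonzero((d <= self.config.radius) & ~np.eye(len(d), dtype=bool))
        return src, dst

    def forward(self, ligand: Ligand) -> Tuple[Tensor, Tensor]:
        """Return (z, node_count_logits) as autodiff tensors."""
        cfg = self.config
        n = ligand.n_atoms
        if not (cfg.count_range[0] <= n <= cfg.count_range[1]):
            raise ValueError(f"atom count {n} outside {cfg.count_range}")
        src, dst = self._edges(ligand.coords)
        d = np.linalg.norm(ligand.coords[src] - ligand.coords[dst],
                           axis=1, keepdims=True)
        bond_oh = np.zeros((len(src), N_BOND))
        bond_oh[np.arange(len(src)), ligand.bonds[src, dst]] = 1.0
        rbf = rbf_expand(Tensor(d), cfg.n_rbf, cfg.radius)
        h = self.lin_in(Tensor(ligand.atom_types))
        for l in range(cfg.layers):
            e_feat = self.edge_proj[l](concat([rbf, Tensor(bond_oh)], axis=1))
            m = self.msg[l](concat([h[src], h[dst], e_feat], axis=1))
            agg = segment_sum(m, dst, n)
            h = h + self.upd[l](concat([h, agg], axis=1))
        att = softmax(self.att(h), axis=0)               # N x 1
        z = (att * self.proj_out(h)).sum(axis=0)         # k
        logits = self.count_head(z.reshape(1, -1)).reshape(-1)
        return z, logits

    def encode(self, ligand: Ligand) -> Tuple[np.ndarray, np.ndarray]:
        """Numpy convenience wrapper: (z, node-count logits)."""
        z, logits = self.forward(ligand)
        return z.data.copy(), logits.data.copy()


# ---------------------------------------------------------------------------
# denoiser


@dataclass
class DenoiserOutput:
    """Clean-sample prediction: coordinates plus category probabilities."""

    X0_hat: np.ndarray   # N x 3 (zero CoM)
    H0_hat: np.ndarray   # N x A probability rows
    E0_hat: np.ndarray   # N x N x B, symmetric probability entries
    sa_pred: float = float("nan")


class Denoiser(Module):
    """Pocket- and latent-conditioned equivariant denoiser.

    Ligand nodes carry the noisy atom categories; pocket nodes are fixed
    context (their coordinates and features are never predicted).  Scalar
    embeddings update through invariant messages; ligand coordinates update
    along relative difference vectors, normalized by distance.
    """

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        self.config = config
        h, e = config.hidden, config.edge_dim
        n_in = N_ATOM + 1 + config.time_dim       # one-hot + ligand flag + time
        self.lin_in = Linear(n_in, h, rng)
        self.edge_proj = [Linear(config.n_rbf + N_BOND + 2, e, rng)
                          for _ in range(config.layers)]
        self.msg = [MLP([2 * h + e, h, h], rng) for _ in range(config.layers)]
        self.upd = [MLP([2 * h, h, h], rng) for _ in range(config.layers)]
        self.coord_gate = [MLP([h, h, 1], rng) for _ in range(config.layers)]
        self.adaln = [AdaLNParams(config.k, h, rng) for _ in range(config.layers)]
        self.head_atom = MLP([h, h, N_ATOM], rng)
        self.head_bond = MLP([2 * h + config.n_rbf, h, N_BOND], rng)
        self.head_sa = MLP([h, h, 1], rng)

    # -- graph building ----------------------------------------------------
    @staticmethod
    def _complex_edges(lig_xyz: np.ndarray, poc_xyz: np.ndarray,
                       bond_cats: np.ndarray, radius: float = 5.0):
        nl, npk = len(lig_xyz), len(poc_xyz)
        src, dst, cat, role = [], [], [], []
        for i in range(nl):
            for j in range(nl):
                if i != j:
                    src.append(i); dst.append(j)
                    cat.append(int(bond_cats[i, j])); role.append((1, 1))
        if npk:
            dpp = cdist(poc_xyz, poc_xyz)
            pi, pj = np.nonzero((dpp <= radius) & ~np.eye(npk, dtype=bool))
            for i, j in zip(pi, pj):
                src.append(nl + i); dst.append(nl + j)
                cat.append(0); role.append((0, 0))
            dlp = cdist(lig_xyz, poc_xyz)
            li, pj = np.nonzero(dlp <= radius)
            for i, j in zip(li, pj):
                src.append(i); dst.append(nl + j); cat.append(0); role.append((1, 0))
                src.append(nl + j); dst.append(i); cat.append(0); role.append((0, 1))
        return (np.asarray(src), np.asarray(dst), np.asarray(cat),
                np.asarray(role, dtype=np.float64))

    def forward(self, lig_coords: np.ndarray, lig_atom_cats: np.ndarray,
                lig_bond_cats: np.ndarray, pocket: Pocket,
                z: Optional[Tensor], t_frac: float, lam: float,
                ) -> Dict[str, Tensor]:
        """Run the denoiser; returns autodiff tensors (see ``predict``)."""
        cfg = self.config
        nl = len(lig_coords)
        npk = pocket.n_atoms
        n = nl + npk

        src, dst, cat, role = self._complex_edges(lig_coords, pocket.coords,
                                                  lig_bond_cats)
        cat_oh = np.zeros((len(src), N_BOND))
        cat_oh[np.arange(len(src)), cat] = 1.0
        edge_const = np.concatenate([cat_oh, role], axis=1)

        atom_oh = np.zeros((nl, N_ATOM))
        atom_oh[np.arange(nl), lig_atom_cats] = 1.0
        temb = time_embedding(t_frac, cfg.time_dim)
        feats = np.zeros((n, N_ATOM + 1 + cfg.time_dim))
        feats[:nl, :N_ATOM] = atom_oh
        feats[nl:, :N_ATOM] = pocket.atom_types if npk else 0.0
        feats[:nl, N_ATOM] = 1.0
        feats[:, N_ATOM + 1:] = temb[None, :]

        lig_mask = np.zeros((n, 1))
        lig_mask[:nl] = 1.0

        h = self.lin_in(Tensor(feats))
        x = Tensor(np.vstack([lig_coords, pocket.coords]) if npk
                   else lig_coords.copy())
        for l in range(cfg.layers):
            diff = x[dst] - x[src]
            d2 = (diff * diff).sum(axis=1, keepdims=True)
            d = (d2 + 1e-12).sqrt()
            rbf = rbf_expand(d, cfg.n_rbf, cfg.r_max)
            e_feat = self.edge_proj[l](concat([rbf, Tensor(edge_const)], axis=1))
            m = self.msg[l](concat([h[src], h[dst], e_feat], axis=1))
            agg = segment_sum(m, dst, n)
            h = h + self.upd[l](concat([h, agg], axis=1))
            # latent conditioning on the node embeddings
            h = adaptive_layer_norm(h, z, lam, self.adaln[l],
                                    literal_gate=cfg.literal_gate)
            # equivariant coordinate update, ligand nodes only
            gate = self.coord_gate[l](m).tanh()
            contrib = diff / (d + 1.0) * gate
            x = x + segment_sum(contrib, dst, n) * Tensor(lig_mask)

        h_lig = h[np.arange(nl)]
        xl = x[np.arange(nl)]
        x0 = xl - xl.mean(axis=0, keepdims=True)       # zero-CoM prediction
        h_logits = self.head_atom(h_lig)

        iu, ju = np.triu_indices(nl, k=1)
        if len(iu):
            d0 = np.linalg.norm(lig_coords[iu] - lig_coords[ju], axis=1,
                                keepdims=True)
            rbf0 = rbf_expand(Tensor(d0), cfg.n_rbf, cfg.r_max)
            pair = concat([h_lig[iu] + h_lig[ju],
                           h_lig[iu] * h_lig[ju], rbf0], axis=1)
            e_logits = self.head_bond(pair)
        else:
            e_logits = Tensor(np.zeros((0, N_BOND)))

        sa = self.head_sa(h_lig.mean(axis=0, keepdims=True)).sigmoid()
        return {"x0": x0, "h_logits": h_logits, "e_logits": e_logits,
                "iu": iu, "ju": ju, "sa": sa, "h_final": h_lig}

    def predict(self, lig_coords, lig_atom_cats, lig_bond_cats, pocket,
                z: Optional[np.ndarray], t: int, T: int,
                lam: float = 1.0) -> DenoiserOutput:
        """Numpy interface: probabilities via softmax, symmetric bond tensor."""
        zt = Tensor(z) if z is not None else None
        out = self.forward(np.asarray(lig_coords), np.asarray(lig_atom_cats),
                           np.asarray(lig_bond_cats), pocket, zt, t / T, lam)
        nl = len(lig_coords)
        H = softmax(out["h_logits"], axis=1).data
        E = np.zeros((nl, nl, N_BOND))
        if len(out["iu"]):
            probs = softmax(out["e_logits"], axis=1).data
            E[out["iu"], out["ju"]] = probs
            E[out["ju"], out["iu"]] = probs
        diag = np.zeros(N_BOND)
        diag[0] = 1.0
        E[np.arange(nl), np.arange(nl)] = diag
        return DenoiserOutput(out["x0"].data.copy(), H, E,
                              float(out["sa"].data.reshape(())))
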