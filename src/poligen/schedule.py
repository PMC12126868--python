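"""Adaptive per-modality cosine noise schedules.

Diffusion over a pocket-bound ligand corrupts three modalities — atomic
coordinates, atom types and bond types — and each decays at its own rate.
The cumulative signal-retention coefficient is

    alpha_bar(t) = cos( (pi/2) * ((t/T + s)^nu) / (1 + s) )^2

where the exponent ``nu`` is modality specific: a larger ``nu`` keeps the
argument smaller for longer, so the signal decays more slowly.  Defaults
follow the adaptive scheduler convention ``nu = 2.5`` for coordinates,
``1.5`` for bond types and ``1.0`` for atom types; ``nu = 1`` recovers the
standard cosine schedule.

Numerical notes (documented in the methods note): for ``nu > 1`` and
``s > 0`` the raw cosine argument exceeds pi/2 in the last few steps, so the
argument is capped at pi/2; after clamping alpha_bar into
``[alpha_min, 1 - alpha_min]`` a strictly-decreasing enforcement (running
minimum with a 1e-9 relative decrement) guarantees monotonicity, which the
posterior coefficients rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

MODALITIES = ("coords", "atom_types", "bond_types")

DEFAULT_NU: Dict[str, float] = {"coords": 2.5, "bond_types": 1.5, "atom_types": 1.0}


def cosine_alpha_bar(t, T: int, s: float = 0.008, nu: float = 1.0) -> np.ndarray:
    """Raw adaptive-cosine alpha_bar, argument capped at pi/2, no clamping."""
    t = np.asarray(t, dtype=np.float64)
    u = ((t / T + s) ** nu) / (1.0 + s)
    ang = np.minimum(u, 1.0) * (np.pi / 2.0)
    return np.cos(ang) ** 2


@dataclass
class NoiseSchedule:
    """Per-modality cumulative noise schedule with derived quantities.

    Parameters
    ----------
    T:
        Number of diffusion steps (default 500).
    s:
        Cosine offset (dimensionless, default 0.008).
    nu:
        Mapping modality -> exponent; missing modalities fall back to the
        defaults above.
    alpha_min:
        Clamp floor for alpha_bar; the ceiling is ``1 - alpha_min``.
    w_min, w_max:
        Truncation bounds of the SNR loss weight ``w_s(t)``.
    weight_modality:
        Which modality's SNR drives ``snr_weight`` (coordinates by default).
    """

    T: int = 500
    s: float = 0.008
    nu: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NU))
    alpha_min: float = 1e-5
    w_min: float = 0.05
    w_max: float = 1.5
    weight_modality: str = "coords"

    def __post_init__(self):
        for m in MODALITIES:
            self.nu.setdefault(m, DEFAULT_NU[m])
        self._alpha_bar: Dict[str, np.ndarray] = {}
        ts = np.arange(self.T + 1)
        for m in MODALITIES:
            ab = cosine_alpha_bar(ts, self.T, self.s, self.nu[m])
            ab = np.clip(ab, self.alpha_min, 1.0 - self.alpha_min)
            # enforce strict decrease (flat clamp regions would give alpha_t = 1)
            for i in range(1, len(ab)):
                ab[i] = min(ab[i], ab[i - 1] * (1.0 - 1e-9))
            self._alpha_bar[m] = ab

    # -- accessors ---------------------------------------------------------
    def alpha_bar(self, t, modality: str) -> np.ndarray:
        """Clamped cumulative signal retention at step ``t`` (0..T)."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError(f"step t={t} outside [0, {self.T}]")
        return self._alpha_bar[modality][t]

    def alpha(self, t, modality: str) -> np.ndarray:
        """Single-step retention alpha_t = alpha_bar_t / alpha_bar_{t-1}, t in 1..T."""
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"step t={t} outside [1, {self.T}]")
        ab = self._alpha_bar[modality]
        return ab[t] / ab[t - 1]

    def beta(self, t, modality: str) -> np.ndarray:
        return 1.0 - self.alpha(t, modality)

    def snr(self, t, modality: str) -> np.ndarray:
        ab = self.alpha_bar(t, modality)
        return ab / (1.0 - ab)

    def snr_weight(self, t) -> np.ndarray:
        """Truncated-SNR loss weight w_s(t) = clip(SNR(t), w_min, w_max)."""
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"step t={t} outside [1, {self.T}]")
        return np.clip(self.snr(t, self.weight_modality), self.w_min, self.w_max)

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "s": self.s,
            "nu": dict(self.nu),
            "alpha_min": self.alpha_min,
            "w_min": self.w_min,
            "w_max": self.w_max,
            "weight_modality": self.weight_modality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return cls(**d)
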