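"""Bilinear attention fusion of patient and drug representations.

For a patient matrix h_p ∈ R^{2×l} (expression / pathway rows) and a drug
matrix h_d ∈ R^{2×l} (heavy / light rows), each attention head h computes
an interaction map

    I = ((1·q_hᵀ) ∘ σ(h_p U)) · σ(h_d V)ᵀ            (2×2)

where U, V ∈ R^{l×K} are shared across heads, q_h ∈ R^K is per-head, 1 is
the all-ones vector over patient rows and σ the rectifier.  Bilinear
pooling then forms f′ ∈ R^K with

    f′_k = σ(h_p U)_{·,k}ᵀ · I · σ(h_d V)_{·,k}

Heads are summed, and a one-dimensional non-overlapping SumPool with
stride s (default 3) compresses f′ to the fused vector f ∈ R^{K/s}.

No softmax is applied to I before pooling; a row-normalized copy is
exported for interpretation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ValidationError

__all__ = [
    "BilinearParams",
    "InteractionMap",
    "FusedRepresentation",
    "interaction_map",
    "bilinear_pool",
    "sum_pool",
    "fuse",
    "attention_maps_table",
]

SUMPOOL_STRIDE = 3
DEFAULT_JOINT_DIM = 768  # divisible by the stride

PATIENT_ROW_NAMES = ("EXP", "PATH")
DRUG_ROW_NAMES = ("heavy", "light")


def _activate(x: np.ndarray, sigma: str) -> np.ndarray:
    if sigma == "relu":
        return np.maximum(x, 0.0)
    if sigma == "identity":  # test-only mode for bilinearity checks
        return x
    raise ValidationError(f"unknown activation {sigma!r}")


@dataclass
class BilinearParams:
    """U, V shared across heads; one query vector q per head."""

    U: np.ndarray
    V: np.ndarray
    q: np.ndarray  # (H, K)
    stride: int = SUMPOOL_STRIDE
    sigma: str = "relu"

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=np.float64))
        if self.U.shape != self.V.shape or self.U.ndim != 2:
            raise ValidationError("U and V must both be l×K")
        if self.q.shape[1] != self.U.shape[1]:
            raise ValidationError("q width must equal K")
        if self.U.shape[1] % self.stride != 0:
            raise ValidationError(
                f"K={self.U.shape[1]} not divisible by stride {self.stride}")

    @property
    def latent_dim(self) -> int:
        return self.U.shape[0]

    @property
    def joint_dim(self) -> int:
        return self.U.shape[1]

    @property
    def n_heads(self) -> int:
        return self.q.shape[0]

    @classmethod
    def init(cls, latent_dim: int, joint_dim: int, n_heads: int,
             rng: np.random.Generator, stride: int = SUMPOOL_STRIDE
             ) -> "BilinearParams":
        scale = 1.0 / np.sqrt(latent_dim)
        return cls(rng.standard_normal((latent_dim, joint_dim)) * scale,
                   rng.standard_normal((latent_dim, joint_dim)) * scale,
                   rng.standard_normal((n_heads, joint_dim)) * scale,
                   stride=stride)


@dataclass
class InteractionMap:
    """Per-head 2×2 map of patient-row × drug-row interaction strengths."""

    head: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("interaction map must be finite")

    def normalized(self) -> np.ndarray:
        """Copy normalized to sum 1 (interpretation only)."""
        total = np.abs(self.values).sum()
        return self.values / total if total > 0 else self.values.copy()


@dataclass
class FusedRepresentation:
    f_prime: np.ndarray  # pre-pool, length K
    f: np.ndarray        # post-SumPool, length K / stride
    maps: list[InteractionMap] = field(default_factory=list)


def _check_pair(h_p: np.ndarray, h_d: np.ndarray, params: BilinearParams
                ) -> tuple[np.ndarray, np.ndarray]:
    h_p = np.asarray(h_p, dtype=np.float64)
    h_d = np.asarray(h_d, dtype=np.float64)
    l = params.latent_dim
    if h_p.ndim != 2 or h_p.shape[1] != l:
        raise ValidationError(f"h_p must be rows×{l}, got {h_p.shape}")
    if h_d.ndim != 2 or h_d.shape[1] != l:
        raise ValidationError(f"h_d must be rows×{l}, got {h_d.shape}")
    return h_p, h_d


def interaction_map(h_p: np.ndarray, h_d: np.ndarray, params: BilinearParams,
                    head: int = 0) -> InteractionMap:
    """I = ((1·q_hᵀ) ∘ σ(h_p U)) · σ(h_d V)ᵀ for one head."""
    h_p, h_d = _check_pair(h_p, h_d, params)
    P = _activate(h_p @ params.U, params.sigma)      # (rows_p, K)
    D = _activate(h_d @ params.V, params.sigma)      # (rows_d, K)
    I = (params.q[head] * P) @ D.T                   # broadcast of 1·qᵀ
    return InteractionMap(head, I)


def bilinear_pool(h_p: np.ndarray, h_d: np.ndarray, imap: InteractionMap,
                  params: BilinearParams, head: int = 0) -> np.ndarray:
    """f′_k = σ(h_p U)_{·,k}ᵀ I σ(h_d V)_{·,k} for k = 1..K."""
    h_p, h_d = _check_pair(h_p, h_d, params)
    P = _activate(h_p @ params.U, params.sigma)
    D = _activate(h_d @ params.V, params.sigma)
    I = imap.values
    if I.shape != (P.shape[0], D.shape[0]):
        raise ValidationError(
            f"interaction map shape {I.shape} does not match rows "
            f"({P.shape[0]}, {D.shape[0]})")
    return np.einsum("ik,ij,jk->k", P, I, D)


def sum_pool(f_prime: np.ndarray, stride: int = SUMPOOL_STRIDE) -> np.ndarray:
    """Non-overlapping block sums of size ``stride``."""
    f_prime = np.asarray(f_prime, dtype=np.float64)
    if f_prime.ndim != 1:
        raise ValidationError("sum_pool expects a vector")
    if f_prime.size % stride != 0:
        raise ValidationError(
            f"length {f_prime.size} not divisible by stride {stride}")
    return f_prime.reshape(-1, stride).sum(axis=1)


def fuse(h_p: np.ndarray, h_d: np.ndarray, params: BilinearParams
         ) -> FusedRepresentation:
    """Multi-head fusion: per-head f′ summed over heads, then SumPooled."""
    h_p, h_d = _check_pair(h_p, h_d, params)
    f_prime = np.zeros(params.joint_dim)
    maps = []
    for h in range(params.n_heads):
        imap = interaction_map(h_p, h_d, params, h)
        f_prime += bilinear_pool(h_p, h_d, imap, params, h)
        maps.append(imap)
    return FusedRepresentation(f_prime, sum_pool(f_prime, params.stride), maps)


def attention_maps_table(maps: list[InteractionMap]) -> pd.DataFrame:
    """Flatten normalized attention maps for TSV export."""
    rows = []
    for imap in maps:
        norm = imap.normalized()
        for i, prow in enumerate(PATIENT_ROW_NAMES[: norm.shape[0]]):
            for j, drow in enumerate(DRUG_ROW_NAMES[: norm.shape[1]]):
                rows.append((imap.head, prow, drow, norm[i, j]))
    return pd.DataFrame(rows, columns=["head", "patient_row", "drug_row",
                                       "weight"])
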