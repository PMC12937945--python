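"""Patient and drug feature encoders.

The patient encoder maps the expression vector a_EXP and the pathway-score
vector a_PATH through two separate rectifier MLP stacks into latents t_EXP
and t_PATH of a common width l, stacked vertically into h_p ∈ R^{2×l}.

The drug encoder consumes per-chain amino-acid sequence embeddings (480
per chain by default, concatenated heavy∥light to 960) and projects each
chain through its own stack to an l-vector, giving h_d ∈ R^{2×l} whose
rows mirror the patient's two semantic rows.

Chain embeddings come from any provider implementing :class:`ChainEmbedder`
(deterministic, fixed width).  The default provider is a seeded
hash-stream embedder that derives a reproducible pseudo-random vector from
a stable digest of the sequence, so the whole pipeline runs offline;
providers backed by a protein language model plug in behind the same
interface, or precomputed per-chain vectors can be loaded from TSV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AntibodyRecord, ValidationError

__all__ = [
    "MLPStack",
    "PatientEmbedding",
    "DrugEmbedding",
    "ChainEmbedder",
    "HashChainEmbedder",
    "PrecomputedChainEmbedder",
    "mlp_forward",
    "encode_patient",
    "embed_drug_chains",
    "project_drug",
]

DEFAULT_CHAIN_WIDTH = 480  # per heavy or light chain
DEFAULT_RAW_WIDTH = 2 * DEFAULT_CHAIN_WIDTH  # 960 concatenated
DEFAULT_LATENT = 256
DEFAULT_HIDDEN = (1024,)


@dataclass
class MLPStack:
    """A stack of affine layers with rectifier activations.

    ``weights[i]`` has shape (out_i, in_i); the forward map per layer is
    t = relu(W a + b).  Used both as a plain numpy forward (inspection,
    oracles) and, via :meth:`tensors`, as trainable autodiff parameters.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ValidationError("weights/biases length mismatch")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.shape != (w.shape[0],):
                raise ValidationError(f"layer {i}: bad parameter shapes")
            if i > 0 and w.shape[1] != self.weights[i - 1].shape[0]:
                raise ValidationError(
                    f"layer {i}: input width {w.shape[1]} does not chain "
                    f"with previous output {self.weights[i - 1].shape[0]}")

    @property
    def in_dim(self) -> int:
        return self.weights[0].shape[1]

    @property
    def out_dim(self) -> int:
        return self.weights[-1].shape[0]

    @classmethod
    def init(cls, sizes: list[int], rng: np.random.Generator) -> "MLPStack":
        """He-normal initialization for a chain of layer sizes."""
        ws, bs = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            ws.append(rng.standard_normal((fan_out, fan_in))
                      * np.sqrt(2.0 / fan_in))
            bs.append(np.zeros(fan_out))
        return cls(ws, bs)

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "MLPStack":
        n = len(arrays) // 2
        return cls([np.asarray(arrays[f"w{i}"]) for i in range(n)],
                   [np.asarray(arrays[f"b{i}"]) for i in range(n)])


@dataclass
class PatientEmbedding:
    """h_p ∈ R^{2×l}: row 0 the expression latent, row 1 the pathway latent."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 2:
            raise ValidationError("patient embedding must be 2×l")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("patient embedding must be finite")


@dataclass
class DrugEmbedding:
    """Raw heavy∥light chain vector and optional projected 2×l matrix."""

    drug_name: str
    raw: np.ndarray
    projected: np.ndarray | None = None
    chain_width: int = DEFAULT_CHAIN_WIDTH

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.raw.shape != (2 * self.chain_width,):
            raise ValidationError(
                f"{self.drug_name}: raw width {self.raw.shape} != "
                f"{2 * self.chain_width}")
        if self.projected is not None:
            self.projected = np.asarray(self.projected, dtype=np.float64)
            if self.projected.ndim != 2 or self.projected.shape[0] != 2:
                raise ValidationError("projected embedding must be 2×l")

    @property
    def heavy(self) -> np.ndarray:
        return self.raw[: self.chain_width]

    @property
    def light(self) -> np.ndarray:
        return self.raw[self.chain_width:]


class ChainEmbedder:
    """Interface: deterministic sequence → fixed-width vector."""

    name: str = "abstract"
    width: int = DEFAULT_CHAIN_WIDTH

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class HashChainEmbedder(ChainEmbedder):
    """Deterministic pseudo-random chain embedder.

    Seeds a PCG64 stream from a stable digest of the (uppercased) sequence
    and draws a standard-normal vector.  Platform-independent, cache-free
    reproducible, and collision-free in practice for distinct sequences.
    """

    def __init__(self, width: int = DEFAULT_CHAIN_WIDTH):
        self.width = int(width)
        self.name = f"hash-stream-{self.width}"

    def embed(self, sequence: str) -> np.ndarray:
        digest = hashlib.sha256(sequence.upper().encode()).digest()
        seed = int.from_bytes(digest[:8], "little")
        rng = np.random.Generator(np.random.PCG64(seed))
        return rng.standard_normal(self.width)


class PrecomputedChainEmbedder(ChainEmbedder):
    """Serve per-chain vectors from a TSV of (drug_name, chain, values...).

    Lookup is by (drug, chain role), so the provider must be used through
    :func:`embed_drug_chains` with matching drug names.
    """

    def __init__(self, path, width: int = DEFAULT_CHAIN_WIDTH):
        df = pd.read_csv(path, sep="\t")
        self.width = int(width)
        self.name = f"precomputed-{self.width}"
        self._table: dict[tuple[str, str], np.ndarray] = {}
        for row in df.itertuples(index=False):
            vec = np.asarray(row[2:], dtype=np.float64)
            if vec.size != self.width:
                raise ValidationError(
                    f"{row[0]}/{row[1]}: got {vec.size} values, "
                    f"expected {self.width}")
            self._table[(str(row[0]), str(row[1]).lower())] = vec

    def lookup(self, drug_name: str, role: str) -> np.ndarray:
        key = (drug_name, role)
        if key not in self._table:
            raise ValidationError(f"no precomputed embedding for {key}")
        return self._table[key]


def mlp_forward(stack: MLPStack, x: np.ndarray) -> np.ndarray:
    """Plain numpy forward pass: t = relu(W a + b) per layer."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != stack.in_dim:
        raise ValidationError(
            f"input width {x.shape[-1]} != stack input {stack.in_dim}")
    for w, b in zip(stack.weights, stack.biases):
        x = np.maximum(x @ w.T + b, 0.0)
    return x


def encode_patient(a_exp: np.ndarray, a_path: np.ndarray,
                   exp_stack: MLPStack, path_stack: MLPStack
                   ) -> PatientEmbedding:
    """Stack the two patient latents into h_p = [t_EXP; t_PATH]."""
    if exp_stack.out_dim != path_stack.out_dim:
        raise ValidationError(
            f"latent widths differ: {exp_stack.out_dim} vs "
            f"{path_stack.out_dim}")
    t_exp = mlp_forward(exp_stack, a_exp)
    t_path = mlp_forward(path_stack, a_path)
    return PatientEmbedding(np.stack([t_exp, t_path]))


_embed_cache: dict[tuple[str, str], np.ndarray] = {}


def embed_drug_chains(record: AntibodyRecord, embedder: ChainEmbedder
                      ) -> DrugEmbedding:
    """Embed heavy and light chains and concatenate heavy∥light.

    Results are cached by (drug name, embedder name); embedder failures
    are re-raised with the drug name attached.
    """
    key = (record.drug_name, embedder.name)
    if key in _embed_cache:
        raw = _embed_cache[key]
    else:
        try:
            if isinstance(embedder, PrecomputedChainEmbedder):
                heavy = embedder.lookup(record.drug_name, "heavy")
                light = embedder.lookup(record.drug_name, "light")
            else:
                heavy = embedder.embed(record.heavy_chain)
                light = embedder.embed(record.light_chain)
        except Exception as exc:
            raise ValidationError(
                f"chain embedding failed for drug {record.drug_name!r}: "
                f"{exc}") from exc
        raw = np.concatenate([heavy, light])
        _embed_cache[key] = raw
    return DrugEmbedding(record.drug_name, raw.copy(),
                         chain_width=embedder.width)


def project_drug(embedding: DrugEmbedding, heavy_stack: MLPStack,
                 light_stack: MLPStack) -> DrugEmbedding:
    """Project each chain's raw vector to l, giving h_d = [heavy; light]."""
    if heavy_stack.in_dim != embedding.chain_width or \
            light_stack.in_dim != embedding.chain_width:
        raise ValidationError("stack input width != chain width")
    if heavy_stack.out_dim != light_stack.out_dim:
        raise ValidationError("chain stacks must share the output width")
    proj = np.stack([mlp_forward(heavy_stack, embedding.heavy),
                     mlp_forward(light_stack, embedding.light)])
    return DrugEmbedding(embedding.drug_name, embedding.raw, proj,
                         embedding.chain_width)
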