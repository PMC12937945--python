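"""Prediction heads, loss, fold assignment, training loops and grid search.

Both branches share the same skeleton: patient-side encoder stacks feed a
fusion step (bilinear attention for bulk; edge-featured graph attention
for single-cell), whose output enters a predictor head — hidden layers of
512 and 128 units, each with batch normalization and a rectifier, then a
single logistic output unit.  Training minimizes the binary cross-entropy
loss

    L = −(1/n) Σ [ y log ŷ + (1−y) log(1−ŷ) ]

with adaptive-moment stochastic optimization, mini-batches, dropout, and
early stopping on a held-out validation split.  Everything is driven by
seeded generators: same seed, same data → bit-identical runs.

Hyperparameter selection is a two-phase grid search: phase 1 scans
learning rate × batch size (4×4 cells), phase 2 fixes the winners and
scans attention heads × dropout (4×5 cells), each cell scored by mean
inner-CV AUROC.  Ties break toward the smaller learning rate in phase 1
and the smaller dropout in phase 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Adam, Tensor, concat
from .core_data import ValidationError
from .encoders import DEFAULT_CHAIN_WIDTH, MLPStack
from .evaluation import classification_metrics

__all__ = [
    "TrainingConfig",
    "FoldAssignment",
    "BulkDataset",
    "SCDatasetTensors",
    "BulkModel",
    "SCModel",
    "bce_loss",
    "stratified_folds",
    "train_model",
    "grid_search",
    "cross_validate",
    "save_model",
    "load_model",
]

LOSS_EPS = 1e-7


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimization and architecture settings plus the search grids."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    n_heads: int = 2
    dropout: float = 0.1
    weight_decay: float = 0.0
    epochs: int = 200
    patience: int = 20
    seed: int = 0
    val_fraction: float = 0.15
    # architecture
    hidden: int = 1024
    latent: int = 256
    joint_dim: int = 768          # K; divisible by the SumPool stride
    sum_pool_stride: int = 3
    head_hidden: tuple[int, ...] = (512, 128)
    extra_head_layer: bool = False  # optional third hidden layer (32)
    gat_head_dim: int = 64
    gat_layers: int = 2
    attn_variant: str = "as_printed"
    variant: str = "full"         # or "expression_only"
    use_drug: bool = True         # single-cell head consumes drug embedding
    proportions_in_nodes: bool = True
    proportions_in_readout: bool = True
    chain_width: int = DEFAULT_CHAIN_WIDTH
    # grids (phase 1 = lr × batch, phase 2 = heads × dropout)
    lr_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5)
    batch_grid: tuple[int, ...] = (32, 64, 128, 256)
    heads_grid: tuple[int, ...] = (1, 2, 3, 4)
    dropout_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)

    def __post_init__(self):
        if not (self.lr_grid and self.batch_grid and self.heads_grid
                and self.dropout_grid):
            raise ValidationError("search grids must be non-empty")
        if self.joint_dim % self.sum_pool_stride != 0:
            raise ValidationError("joint_dim must be divisible by the stride")

    def head_sizes(self) -> tuple[int, ...]:
        return self.head_hidden + ((32,) if self.extra_head_layer else ())


def scaled_config(**overrides) -> TrainingConfig:
    """A compact configuration for CPU-budget evaluation runs."""
    base = dict(hidden=128, latent=32, joint_dim=48, head_hidden=(64, 32),
                gat_head_dim=16, epochs=80, patience=12)
    base.update(overrides)
    return TrainingConfig(**base)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(y_true, y_pred, eps: float = LOSS_EPS) -> float:
    """Mean binary cross-entropy with predictions clamped to [eps, 1−eps]."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.size == 0:
        raise ValidationError("empty label vector")
    if not np.all((y_true == 0) | (y_true == 1)):
        raise ValidationError("labels must be binary")
    p = np.clip(y_pred, eps, 1.0 - eps)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


def _bce_tensor(y: np.ndarray, p: Tensor, eps: float = LOSS_EPS) -> Tensor:
    p = p * (1.0 - 2.0 * eps) + eps  # keeps gradients finite at the rails
    yt = Tensor(y)
    return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    assignment: dict[str, int]
    k: int

    def fold_of(self, sample_id: str) -> int:
        return self.assignment[sample_id]

    def responder_counts(self, labels: dict[str, int]) -> list[int]:
        counts = [0] * self.k
        for s, f in self.assignment.items():
            counts[f] += labels[s]
        return counts

    def test_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def train_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f != fold]


def stratified_folds(labels: dict[str, int], k: int = 5,
                     strata: dict[str, str] | None = None,
                     seed: int = 0) -> FoldAssignment:
    """Label-stratified (optionally stratum-spread) fold assignment.

    Within each label class, samples are shuffled and dealt round-robin to
    folds; with strata, dealing proceeds stratum by stratum while the
    round-robin pointer carries over, spreading every stratum across
    folds while keeping per-fold responder counts within one sample of
    each other.
    """
    labels = dict(labels)
    n_pos = sum(labels.values())
    n_min = min(n_pos, len(labels) - n_pos)
    if k > n_min:
        raise ValidationError(
            f"k={k} exceeds minority class count {n_min}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for lab in (1, 0):
        members = sorted(s for s, y in labels.items() if y == lab)
        if strata is not None:
            by_stratum: dict[str, list[str]] = {}
            for s in members:
                by_stratum.setdefault(str(strata[s]), []).append(s)
            batches = [by_stratum[g] for g in sorted(by_stratum)]
        else:
            batches = [members]
        pointer = int(rng.integers(k))
        for batch in batches:
            batch = list(batch)
            rng.shuffle(batch)
            for s in batch:
                assignment[s] = pointer
                pointer = (pointer + 1) % k
    return FoldAssignment(assignment, k)


# ---------------------------------------------------------------------------
# trainable building blocks
# ---------------------------------------------------------------------------

class _Linear:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.standard_normal((fan_in, fan_out))
                        * np.sqrt(2.0 / fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _BatchNorm:
    def __init__(self, width: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data[0])
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data[0])
            inv = (var + self.eps) ** -0.5
            return xc * inv * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        inv = Tensor((self.running_var + self.eps) ** -0.5)
        return xc * inv * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


def _dropout(x: Tensor, rate: float, rng: np.random.Generator,
             train: bool) -> Tensor:
    if not train or rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class _TrainableMLP:
    """Rectifier MLP with dropout after each hidden layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 dropout: float = 0.0):
        self.layers = [_Linear(a, b, rng)
                       for a, b in zip(sizes[:-1], sizes[1:])]
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 train: bool) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x).relu()
            if i < len(self.layers) - 1:
                x = _dropout(x, self.dropout, rng, train)
        return x

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def to_stack(self) -> MLPStack:
        return MLPStack([l.W.data.T.copy() for l in self.layers],
                        [l.b.data.copy() for l in self.layers])


class _PredictorHead:
    """Hidden layers (512, 128 by default) with BN + rectifier, logistic
    output unit."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...],
                 rng: np.random.Generator, dropout: float = 0.0):
        sizes = [in_dim, *hidden]
        self.linears = [_Linear(a, b, rng)
                        for a, b in zip(sizes[:-1], sizes[1:])]
        self.bns = [_BatchNorm(b) for b in sizes[1:]]
        self.out = _Linear(sizes[-1], 1, rng)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 train: bool) -> Tensor:
        for lin, bn in zip(self.linears, self.bns):
            x = bn(lin(x), train).relu()
            x = _dropout(x, self.dropout, rng, train)
        B = x.shape[0]
        return self.out(x).sigmoid().reshape(B)

    def params(self):
        ps = [p for l in self.linears for p in l.params()]
        ps += [p for bn in self.bns for p in bn.params()]
        return ps + self.out.params()


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class BulkDataset:
    """Arrays for the bulk branch, row-aligned by sample."""

    sample_ids: list[str]
    x_exp: np.ndarray      # (n, n_genes), z-scored
    x_path: np.ndarray     # (n, n_sets)
    drug_raw: np.ndarray   # (n, 2*chain_width)
    labels: np.ndarray     # (n,) in {0, 1}
    gene_ids: list[str] = field(default_factory=list)
    set_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sample_ids)
        for name, arr in (("x_exp", self.x_exp), ("x_path", self.x_path),
                          ("drug_raw", self.drug_raw)):
            if arr.shape[0] != n:
                raise ValidationError(f"{name} row count != {n}")
        if self.labels.shape != (n,):
            raise ValidationError("labels shape mismatch")

    def subset(self, idx: np.ndarray) -> "BulkDataset":
        return BulkDataset([self.sample_ids[i] for i in idx],
                           self.x_exp[idx], self.x_path[idx],
                           self.drug_raw[idx], self.labels[idx],
                           self.gene_ids, self.set_ids)

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class SCDatasetTensors:
    """Padded per-patient graph arrays for the single-cell branch."""

    sample_ids: list[str]
    a_exp: np.ndarray        # (n, T, n_genes), z-scored pseudo-bulk
    a_path: np.ndarray       # (n, T, n_sets)
    proportions: np.ndarray  # (n, T), zero at absent types
    node_mask: np.ndarray    # (n, T) bool
    edge_features: np.ndarray  # (n, T, T)
    adjacency: np.ndarray    # (n, T, T) bool incl. self-loops
    drug_raw: np.ndarray     # (n, 2*chain_width)
    labels: np.ndarray
    cell_types: list[str] = field(default_factory=list)

    def subset(self, idx: np.ndarray) -> "SCDatasetTensors":
        return SCDatasetTensors(
            [self.sample_ids[i] for i in idx], self.a_exp[idx],
            self.a_path[idx], self.proportions[idx], self.node_mask[idx],
            self.edge_features[idx], self.adjacency[idx],
            self.drug_raw[idx], self.labels[idx], self.cell_types)

    def __len__(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class BulkModel:
    """Patient/drug encoders + bilinear attention fusion + predictor head."""

    def __init__(self, n_genes: int, n_sets: int, config: TrainingConfig):
        self.config = config
        self.input_dims = {"n_genes": n_genes, "n_sets": n_sets}
        rng = np.random.default_rng(config.seed)
        c = config
        self.exp_mlp = _TrainableMLP([n_genes, c.hidden, c.latent], rng,
                                     c.dropout)
        self.path_mlp = _TrainableMLP([n_sets, c.hidden, c.latent], rng,
                                      c.dropout)
        self.heavy_mlp = _TrainableMLP([c.chain_width, c.latent], rng,
                                       c.dropout)
        self.light_mlp = _TrainableMLP([c.chain_width, c.latent], rng,
                                       c.dropout)
        scale = 1.0 / np.sqrt(c.latent)
        self.U = Tensor(rng.standard_normal((c.latent, c.joint_dim)) * scale,
                        requires_grad=True)
        self.V = Tensor(rng.standard_normal((c.latent, c.joint_dim)) * scale,
                        requires_grad=True)
        self.q = Tensor(rng.standard_normal((c.n_heads, c.joint_dim)) * scale,
                        requires_grad=True)
        self.head = _PredictorHead(c.joint_dim // c.sum_pool_stride,
                                   c.head_sizes(), rng, c.dropout)

    def params(self):
        ps = (self.exp_mlp.params() + self.path_mlp.params()
              + self.heavy_mlp.params() + self.light_mlp.params())
        return ps + [self.U, self.V, self.q] + self.head.params()

    def forward(self, data: BulkDataset, rng: np.random.Generator,
                train: bool) -> Tensor:
        c = self.config
        B = len(data)
        t_exp = self.exp_mlp(Tensor(data.x_exp), rng, train)
        rows = [t_exp.reshape(B, 1, c.latent)]
        if c.variant != "expression_only":
            t_path = self.path_mlp(Tensor(data.x_path), rng, train)
            rows.append(t_path.reshape(B, 1, c.latent))
        h_p = rows[0] if len(rows) == 1 else concat(rows, axis=1)
        heavy = Tensor(data.drug_raw[:, :c.chain_width])
        light = Tensor(data.drug_raw[:, c.chain_width:])
        h_d = concat([self.heavy_mlp(heavy, rng, train).reshape(B, 1, c.latent),
                      self.light_mlp(light, rng, train).reshape(B, 1, c.latent)],
                     axis=1)
        P = (h_p @ self.U).relu()            # (B, rows_p, K)
        D = (h_d @ self.V).relu()            # (B, 2, K)
        f_sum = None
        for h in range(c.n_heads):
            QP = P * self.q[h]
            I = QP @ D.swapaxes(-1, -2)      # (B, rows_p, 2)
            M = I @ D                        # (B, rows_p, K)
            f = (P * M).sum(axis=1)          # (B, K)
            f_sum = f if f_sum is None else f_sum + f
        pooled = f_sum.reshape(B, c.joint_dim // c.sum_pool_stride,
                               c.sum_pool_stride).sum(axis=2)
        return self.head(pooled, rng, train)

    def predict(self, data: BulkDataset) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused in eval mode
        return self.forward(data, rng, train=False).data


class SCModel:
    """Shared patient encoder on pseudo-bulk nodes + edge-featured graph
    attention + proportion-weighted readout + predictor head."""

    def __init__(self, n_genes: int, n_sets: int, n_types: int,
                 config: TrainingConfig):
        self.config = config
        self.input_dims = {"n_genes": n_genes, "n_sets": n_sets,
                           "n_types": n_types}
        c = config
        rng = np.random.default_rng(config.seed)
        self.exp_mlp = _TrainableMLP([n_genes, c.hidden, c.latent], rng,
                                     c.dropout)
        self.path_mlp = _TrainableMLP([n_sets, c.hidden, c.latent], rng,
                                      c.dropout)
        node_dim = 2 * c.latent + (1 if c.proportions_in_nodes else 0)
        H, Dh = c.n_heads, c.gat_head_dim
        self.gat = []
        in_dim = node_dim
        for _ in range(c.gat_layers):
            layer = {
                "Wt": Tensor(rng.standard_normal((H, in_dim, Dh))
                             * np.sqrt(2.0 / in_dim), requires_grad=True),
                "att": Tensor(rng.standard_normal((H, 2 * Dh + 1))
                              * np.sqrt(1.0 / Dh), requires_grad=True),
                "Mt": Tensor(rng.standard_normal((H, Dh + 1, Dh))
                             * np.sqrt(2.0 / (Dh + 1)), requires_grad=True),
                "Rt": (Tensor(rng.standard_normal((in_dim, H * Dh))
                              * np.sqrt(1.0 / in_dim), requires_grad=True)
                       if in_dim != H * Dh else None),
            }
            self.gat.append(layer)
            in_dim = H * Dh
        head_in = in_dim + (2 * c.chain_width if c.use_drug else 0)
        self.head = _PredictorHead(head_in, c.head_sizes(), rng, c.dropout)

    def params(self):
        ps = self.exp_mlp.params() + self.path_mlp.params()
        for layer in self.gat:
            ps += [layer["Wt"], layer["att"], layer["Mt"]]
            if layer["Rt"] is not None:
                ps.append(layer["Rt"])
        return ps + self.head.params()

    def _gat_layer(self, X: Tensor, layer: dict, E: Tensor, mask: Tensor,
                   slope: float) -> Tensor:
        c = self.config
        B, T = X.shape[0], X.shape[1]
        H, Dh = c.n_heads, c.gat_head_dim
        outs = []
        for h in range(H):
            Xp = X @ layer["Wt"][h]                       # (B, T, Dh)
            a1 = layer["att"][h][:Dh]
            a2 = layer["att"][h][Dh:2 * Dh]
            ae = layer["att"][h][2 * Dh:2 * Dh + 1]
            s1 = (Xp @ a1).reshape(B, T, 1)
            s2 = (Xp @ a2).reshape(B, 1, T)
            if c.attn_variant == "as_printed":
                S = (s1 + s2 + E * ae).leaky_relu(slope)
            else:
                Xl = Xp.leaky_relu(slope)
                S = ((Xl @ a1).reshape(B, T, 1)
                     + (Xl @ a2).reshape(B, 1, T)
                     + E.leaky_relu(slope) * ae)
            masked_max = np.max(np.where(mask.data > 0, S.data, -np.inf),
                                axis=2, initial=-np.inf, keepdims=True)
            has_nbr = mask.data.sum(axis=2, keepdims=True) > 0
            shift = Tensor(np.where(has_nbr, masked_max, 0.0))
            expS = (S - shift).exp() * mask
            alpha = expS / (expS.sum(axis=2, keepdims=True) + 1e-12)
            msg_x = alpha @ Xp                            # (B, T, Dh)
            msg_e = (alpha * E).sum(axis=2, keepdims=True)
            outs.append(concat([msg_x, msg_e], axis=-1) @ layer["Mt"][h])
        out = outs[0] if len(outs) == 1 else concat(outs, axis=-1)
        res = X if layer["Rt"] is None else X @ layer["Rt"]
        return out + res

    def forward(self, data: SCDatasetTensors, rng: np.random.Generator,
                train: bool) -> Tensor:
        c = self.config
        B, T, G = data.a_exp.shape
        nS = data.a_path.shape[2]
        t_exp = self.exp_mlp(Tensor(data.a_exp.reshape(B * T, G)), rng,
                             train).reshape(B, T, c.latent)
        t_path = self.path_mlp(Tensor(data.a_path.reshape(B * T, nS)), rng,
                               train).reshape(B, T, c.latent)
        X = concat([t_exp, t_path], axis=-1)
        if c.proportions_in_nodes:
            X = concat([X, Tensor(data.proportions.reshape(B, T, 1))],
                       axis=-1)
        # absent nodes carry zero features and no edges
        node_mask = Tensor(data.node_mask.astype(np.float64).reshape(B, T, 1))
        X = X * node_mask
        E = Tensor(data.edge_features)
        adj = Tensor(data.adjacency.astype(np.float64))
        for layer in self.gat:
            X = self._gat_layer(X, layer, E, adj, slope=0.2) * node_mask
        if c.proportions_in_readout:
            w = data.proportions * data.node_mask
        else:
            w = data.node_mask.astype(np.float64)
        denom = w.sum(axis=1, keepdims=True)
        if np.any(denom <= 0):
            raise ValidationError("patient with no present cell types")
        w = w / denom
        readout = (X * Tensor(w.reshape(B, T, 1))).sum(axis=1)
        if c.use_drug:
            readout = concat([readout, Tensor(data.drug_raw)], axis=-1)
        return self.head(readout, rng, train)

    def predict(self, data: SCDatasetTensors) -> np.ndarray:
        rng = np.random.default_rng(0)
        return self.forward(data, rng, train=False).data


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/validation index split."""
    train_idx, val_idx = [], []
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(fraction * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def train_model(branch: str, data, config: TrainingConfig,
                val_data=None):
    """Train a bulk or single-cell model with early stopping.

    Returns (model, history) where history rows are
    (epoch, train_loss, val_loss).  Aborts on non-finite loss.
    """
    if branch not in ("bulk", "single_cell"):
        raise ValidationError(f"unknown branch {branch!r}")
    rng = np.random.default_rng(config.seed)
    if branch == "bulk":
        model = BulkModel(data.x_exp.shape[1], data.x_path.shape[1], config)
    else:
        model = SCModel(data.a_exp.shape[2], data.a_path.shape[2],
                        data.a_exp.shape[1], config)
    if val_data is None and config.val_fraction > 0 and \
            min(np.bincount(data.labels.astype(int), minlength=2)) >= 2:
        tr_idx, va_idx = _stratified_split(data.labels, config.val_fraction,
                                           rng)
        train_set, val_data = data.subset(tr_idx), data.subset(va_idx)
    else:
        train_set = data

    params = model.params()
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    patience_left = config.patience
    history = []
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, config.batch_size):
            batch = train_set.subset(order[lo:lo + config.batch_size])
            opt.zero_grad()
            probs = model.forward(batch, rng, train=True)
            loss = _bce_tensor(batch.labels.astype(np.float64), probs)
            if not np.isfinite(loss.data):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        if val_data is not None and len(val_data) > 0:
            val_loss = bce_loss(val_data.labels,
                                model.predict(val_data))
        else:
            val_loss = train_loss
        history.append((epoch, train_loss, val_loss))
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [p.data.copy() for p in params]
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    for p, s in zip(params, best_state):
        p.data = s
    return model, history


# ---------------------------------------------------------------------------
# cross-validation & grid search
# ---------------------------------------------------------------------------

def cross_validate(branch: str, data, config: TrainingConfig, k: int = 5,
                   strata: dict[str, str] | None = None, seed: int = 0):
    """k-fold stratified CV; returns (per-fold metrics, pooled scores).

    The pooled scores array is aligned with ``data`` row order; each
    entry is the out-of-fold predicted responder probability.
    """
    labels = {s: int(y) for s, y in zip(data.sample_ids, data.labels)}
    folds = stratified_folds(labels, k, strata, seed)
    pooled = np.full(len(data), np.nan)
    fold_metrics = []
    for f in range(k):
        te = np.array([i for i, s in enumerate(data.sample_ids)
                       if folds.fold_of(s) == f])
        tr = np.array([i for i, s in enumerate(data.sample_ids)
                       if folds.fold_of(s) != f])
        model, _ = train_model(branch, data.subset(tr),
                               replace(config, seed=config.seed + f))
        scores = model.predict(data.subset(te))
        pooled[te] = scores
        fold_metrics.append(classification_metrics(data.labels[te], scores))
    return fold_metrics, pooled, folds


def _default_scorer(branch: str, data, config: TrainingConfig,
                    inner_k: int = 3) -> float:
    """Mean inner-CV AUROC for one grid cell."""
    metrics, _, _ = cross_validate(branch, data, config, k=inner_k,
                                   seed=config.seed)
    return float(np.mean([m.auroc for m in metrics]))


def grid_search(data, config: TrainingConfig, branch: str = "bulk",
                scorer=None):
    """Two-phase grid search.

    Phase 1 scans learning rate × batch size; phase 2 fixes the winners
    and scans attention heads × dropout.  ``scorer(branch, data, cfg)``
    returns the cell's score (mean inner-CV AUROC by default).  Ties
    break toward the smaller learning rate (phase 1) and smaller dropout
    (phase 2).  Returns (best_config, phase1_table, phase2_table) with
    tables as lists of dict rows.
    """
    if scorer is None:
        scorer = _default_scorer
    phase1 = []
    for lr in config.lr_grid:
        for bs in config.batch_grid:
            cfg = replace(config, learning_rate=lr, batch_size=bs)
            phase1.append({"learning_rate": lr, "batch_size": bs,
                           "score": scorer(branch, data, cfg)})
    best1 = max(phase1,
                key=lambda r: (r["score"], -r["learning_rate"],
                               -r["batch_size"]))
    phase2 = []
    for nh in config.heads_grid:
        for dr in config.dropout_grid:
            cfg = replace(config, learning_rate=best1["learning_rate"],
                          batch_size=best1["batch_size"], n_heads=nh,
                          dropout=dr)
            phase2.append({"n_heads": nh, "dropout": dr,
                           "score": scorer(branch, data, cfg)})
    best2 = max(phase2, key=lambda r: (r["score"], -r["dropout"],
                                       -r["n_heads"]))
    best = replace(config, learning_rate=best1["learning_rate"],
                   batch_size=best1["batch_size"], n_heads=best2["n_heads"],
                   dropout=best2["dropout"])
    return best, phase1, phase2


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _model_state(model) -> dict[str, np.ndarray]:
    state = {f"param_{i:04d}": p.data for i, p in enumerate(model.params())}
    bns = model.head.bns
    for j, bn in enumerate(bns):
        state[f"bn_{j}_mean"] = bn.running_mean
        state[f"bn_{j}_var"] = bn.running_var
    return state


def save_model(model, directory, extra: dict | None = None) -> None:
    """Write a checkpoint: parameter tensors + JSON config + provenance."""
    import dataclasses
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "parameters.npz", **_model_state(model))
    meta = {
        "branch": "bulk" if isinstance(model, BulkModel) else "single_cell",
        "config": dataclasses.asdict(model.config),
        "dims": model.input_dims,
        **(extra or {}),
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))


def load_model(directory):
    """Rebuild a model from a checkpoint directory."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    cfg_dict = meta["config"]
    for key in ("head_hidden", "lr_grid", "batch_grid", "heads_grid",
                "dropout_grid"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = TrainingConfig(**cfg_dict)
    dims = meta["dims"]
    if meta["branch"] == "bulk":
        model = BulkModel(dims["n_genes"], dims["n_sets"], config)
    else:
        model = SCModel(dims["n_genes"], dims["n_sets"], dims["n_types"],
                        config)
    state = np.load(directory / "parameters.npz")
    for i, p in enumerate(model.params()):
        p.data = state[f"param_{i:04d}"]
    for j, bn in enumerate(model.head.bns):
        bn.running_mean = state[f"bn_{j}_mean"]
        bn.running_var = state[f"bn_{j}_var"]
    return model
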