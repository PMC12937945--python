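"""Single-cell branch: pseudo-bulk profiles, cell-type graphs, and
edge-featured graph attention.

Per patient, cells are averaged within each annotated cell type to give
pseudo-bulk profiles and cell-type proportions.  A per-(sample, type)
activity scalar — the mean z-scored pseudo-bulk expression over a gene
panel — makes cohort-level Pearson correlation (and hence the SSN
perturbation) well-defined for cell-type pairs; the resulting kept edges
become the patient graph's edge features.

The graph attention layer follows the additive, edge-featured form

    a_ij = LeakyReLU( ∂ᵀ [X_i ∥ X_j ∥ E_ij] )          (raw score)
    α_ij = softmax_j a_ij   over j ∈ neighbors(i) ∪ {i}
    m_i  = Σ_j α_ij · (X_j ∥ E_ij) · M                  (message, mapped to D)

with X the head's linear projection of node features, per-head attention
vectors, heads concatenated, and a residual connection (projected when
widths differ).  The printed form applies the leaky rectifier outside
the ∂ᵀ product; the canonical dynamic-attention variant (rectifier
inside, before ∂ᵀ) is available as ``variant="v2"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import (CellAnnotationTable, ExpressionMatrix,
                        ValidationError)
from .encoders import MLPStack, encode_patient
from .pathway import PathwayScoreMatrix
from .ssn import SampleNetwork

__all__ = [
    "PseudoBulkProfile",
    "PatientGraph",
    "GraphAttentionParams",
    "pseudobulk_profiles",
    "pseudobulk_matrix",
    "celltype_activity",
    "activity_matrix",
    "assemble_patient_graph",
    "gatv2_layer",
    "graph_readout",
]

logger = logging.getLogger(__name__)

SELF_LOOP_EDGE = 1.0
PSEUDOBULK_SEP = "::"  # joins sample and type into one column id


@dataclass
class PseudoBulkProfile:
    """Per-sample, per-cell-type mean expression with counts/proportions."""

    sample_id: str
    gene_ids: list[str]
    cell_types: list[str]
    means: np.ndarray        # (n_types, n_genes)
    cell_counts: np.ndarray  # (n_types,)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.cell_counts = np.asarray(self.cell_counts, dtype=np.int64)
        if self.means.shape != (len(self.cell_types), len(self.gene_ids)):
            raise ValidationError("pseudo-bulk mean shape mismatch")
        if not np.all(np.isfinite(self.means)):
            raise ValidationError("pseudo-bulk means must be finite")
        if self.cell_counts.size == 0 or self.cell_counts.min() <= 0 or \
                len(self.cell_counts) != len(self.cell_types):
            raise ValidationError("every present type needs >=1 cell")

    @property
    def proportions(self) -> np.ndarray:
        return self.cell_counts / self.cell_counts.sum()


def pseudobulk_profiles(counts: ExpressionMatrix,
                        annotations: CellAnnotationTable
                        ) -> dict[str, PseudoBulkProfile]:
    """Average cells within each (sample, annotated type)."""
    cell_idx = {c: i for i, c in enumerate(counts.sample_ids)}
    missing = [c for c in annotations.cell_ids if c not in cell_idx]
    if missing:
        raise ValidationError(
            f"annotated cells absent from the count matrix: {missing[:5]}")
    by_sample: dict[str, dict[str, list[int]]] = {}
    for cell, (sample, ctype) in annotations.cells.items():
        by_sample.setdefault(sample, {}).setdefault(ctype, []).append(
            cell_idx[cell])
    profiles = {}
    vocab_order = {t: i for i, t in enumerate(annotations.vocabulary)}
    for sample, groups in by_sample.items():
        if not groups:
            raise ValidationError(f"sample {sample} has zero cells")
        types = sorted(groups, key=lambda t: vocab_order[t])
        means = np.stack([counts.values[:, groups[t]].mean(axis=1)
                          for t in types])
        n_cells = np.array([len(groups[t]) for t in types])
        profiles[sample] = PseudoBulkProfile(
            sample, list(counts.gene_ids), types, means, n_cells)
    return profiles


def pseudobulk_matrix(profiles: dict[str, PseudoBulkProfile]
                      ) -> ExpressionMatrix:
    """Pool all (sample, type) pseudo-bulk columns into one matrix.

    Column ids are ``sample::type``; pooling keeps pathway scores and
    activities comparable across types.
    """
    first = next(iter(profiles.values()))
    cols, vecs = [], []
    for sample, prof in profiles.items():
        if prof.gene_ids != first.gene_ids:
            raise ValidationError("profiles disagree on gene ids")
        for t, row in zip(prof.cell_types, prof.means):
            cols.append(f"{sample}{PSEUDOBULK_SEP}{t}")
            vecs.append(row)
    return ExpressionMatrix(list(first.gene_ids), cols, np.stack(vecs).T)


def _zscore_vector(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def celltype_activity(profile: PseudoBulkProfile, cell_type: str,
                      gene_panel: list[str]) -> float:
    """Mean z-scored pseudo-bulk expression of the panel for one type.

    The profile vector is z-scored across its own genes first, so the
    activity is a within-profile contrast; an empty panel intersection
    errors.
    """
    if cell_type not in profile.cell_types:
        raise ValidationError(
            f"type {cell_type!r} absent from sample {profile.sample_id}")
    gidx = {g: i for i, g in enumerate(profile.gene_ids)}
    idx = [gidx[g] for g in gene_panel if g in gidx]
    if not idx:
        raise ValidationError("gene panel does not intersect measured genes")
    row = profile.means[profile.cell_types.index(cell_type)]
    return float(_zscore_vector(row)[idx].mean())


def activity_matrix(profiles: dict[str, PseudoBulkProfile],
                    gene_panel: list[str],
                    cell_types: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Types×samples activity scalars plus a presence mask.

    Missing (sample, type) combinations get activity 0 and mask False.
    """
    samples = list(profiles)
    act = np.zeros((len(cell_types), len(samples)))
    present = np.zeros((len(cell_types), len(samples)), dtype=bool)
    for j, s in enumerate(samples):
        prof = profiles[s]
        for i, t in enumerate(cell_types):
            if t in prof.cell_types:
                act[i, j] = celltype_activity(prof, t, gene_panel)
                present[i, j] = True
    return act, present


@dataclass
class PatientGraph:
    """Cell-type graph for one patient.

    Node features X_i concatenate the flattened encoder latent (2l) with
    the type's proportion; edges carry the clamped SSN weight, self-loops
    a constant 1.  ``adjacency`` includes self-loops.
    """

    sample_id: str
    node_names: list[str]
    node_features: np.ndarray   # (n, F)
    proportions: np.ndarray     # (n,), renormalized over present nodes
    edge_features: np.ndarray   # (n, n)
    adjacency: np.ndarray       # (n, n) bool, incl. self-loops
    omitted_types: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.node_names)
        if self.node_features.shape[0] != n or \
                self.edge_features.shape != (n, n) or \
                self.adjacency.shape != (n, n):
            raise ValidationError("patient graph shape mismatch")
        if not np.all(np.isfinite(self.node_features)) or \
                not np.all(np.isfinite(self.edge_features)):
            raise ValidationError("graph features must be finite")
        if not np.all(np.diag(self.adjacency)):
            raise ValidationError("self-loops must be present")

    def to_json(self) -> str:
        return json.dumps({
            "sample_id": self.sample_id,
            "nodes": [
                {"name": t, "proportion": float(p),
                 "features": f.tolist()}
                for t, p, f in zip(self.node_names, self.proportions,
                                   self.node_features)],
            "edges": [
                {"i": self.node_names[i], "j": self.node_names[j],
                 "weight": float(self.edge_features[i, j])}
                for i in range(len(self.node_names))
                for j in range(i + 1, len(self.node_names))
                if self.adjacency[i, j]],
            "omitted_types": self.omitted_types,
        })


def assemble_patient_graph(profile: PseudoBulkProfile,
                           exp_stack: MLPStack, path_stack: MLPStack,
                           pathway_scores: PathwayScoreMatrix,
                           network: SampleNetwork,
                           include_proportion_feature: bool = True
                           ) -> PatientGraph:
    """Build one patient's cell-type graph.

    Node features come from the shared patient encoder applied to the
    type's z-scored pseudo-bulk (EXP row) and its pathway scores (PATH
    row); edges are the sample network's kept pairs plus self-loops.
    Types absent from the sample are omitted (and logged); proportions
    are renormalized over present nodes.
    """
    score_cols = {s: j for j, s in enumerate(pathway_scores.sample_ids)}
    nodes, feats = [], []
    for t, row in zip(profile.cell_types, profile.means):
        col = f"{profile.sample_id}{PSEUDOBULK_SEP}{t}"
        if col not in score_cols:
            raise ValidationError(f"no pathway scores for column {col!r}")
        a_exp = _zscore_vector(row)
        a_path = pathway_scores.values[:, score_cols[col]]
        h_p = encode_patient(a_exp, a_path, exp_stack, path_stack)
        nodes.append(t)
        feats.append(h_p.matrix.ravel())
    omitted = [t for t in network.variable_ids if t not in nodes]
    if omitted:
        logger.info("sample %s: omitting absent types %s",
                    profile.sample_id, omitted)
    props = profile.proportions
    X = np.stack(feats)
    if include_proportion_feature:
        X = np.hstack([X, props[:, None]])

    n = len(nodes)
    E = np.zeros((n, n))
    adj = np.eye(n, dtype=bool)
    np.fill_diagonal(E, SELF_LOOP_EDGE)
    nidx = {t: i for i, t in enumerate(nodes)}
    for e in network.edges:
        if not e.kept or e.var_i not in nidx or e.var_j not in nidx:
            continue
        i, j = nidx[e.var_i], nidx[e.var_j]
        E[i, j] = E[j, i] = e.e_s_clamped
        adj[i, j] = adj[j, i] = True
    return PatientGraph(profile.sample_id, nodes, X, props / props.sum(),
                        E, adj, omitted)


@dataclass
class GraphAttentionParams:
    """One attention layer: per-head projection, attention vector, message
    map, and an optional residual projection."""

    W: np.ndarray          # (H, D, F) node-feature projection
    att: np.ndarray        # (H, 2D+1) attention vector ∂ per head
    M: np.ndarray          # (H, D, D+1) message map over (X_j ∥ E_ij)
    residual: np.ndarray | None = None  # (H*D, F) when F != H*D
    negative_slope: float = 0.2
    variant: str = "as_printed"  # or "v2"

    def __post_init__(self):
        H, D, F = self.W.shape
        if self.att.shape != (H, 2 * D + 1):
            raise ValidationError("attention vector must be (H, 2D+1)")
        if self.M.shape != (H, D, D + 1):
            raise ValidationError("message map must be (H, D, D+1)")
        if F != H * D and self.residual is None:
            raise ValidationError(
                f"input width {F} != H*D {H * D}: residual projection needed")
        if self.residual is not None and self.residual.shape != (H * D, F):
            raise ValidationError("residual projection must be (H*D, F)")
        if self.variant not in ("as_printed", "v2"):
            raise ValidationError(f"unknown variant {self.variant!r}")

    @property
    def n_heads(self) -> int:
        return self.W.shape[0]

    @property
    def head_dim(self) -> int:
        return self.W.shape[1]

    @classmethod
    def init(cls, in_dim: int, n_heads: int, head_dim: int,
             rng: np.random.Generator, variant: str = "as_printed"
             ) -> "GraphAttentionParams":
        scale_w = np.sqrt(2.0 / in_dim)
        W = rng.standard_normal((n_heads, head_dim, in_dim)) * scale_w
        att = rng.standard_normal((n_heads, 2 * head_dim + 1)) \
            * np.sqrt(1.0 / head_dim)
        M = rng.standard_normal((n_heads, head_dim, head_dim + 1)) \
            * np.sqrt(2.0 / (head_dim + 1))
        residual = None
        if in_dim != n_heads * head_dim:
            residual = rng.standard_normal((n_heads * head_dim, in_dim)) \
                * np.sqrt(1.0 / in_dim)
        return cls(W, att, M, residual, variant=variant)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def gatv2_layer(graph: PatientGraph, params: GraphAttentionParams
                ) -> tuple[np.ndarray, np.ndarray]:
    """One attention layer on a single graph (numpy reference path).

    Returns (updated node features (n, H*D), attention tensor (H, n, n)).
    """
    X, E, adj = graph.node_features, graph.edge_features, graph.adjacency
    n = X.shape[0]
    if not np.all(adj.sum(axis=1) > 0):
        raise ValidationError("node without neighbors or self-loop")
    D = params.head_dim
    outs, alphas = [], []
    for h in range(params.n_heads):
        Xp = X @ params.W[h].T                      # (n, D)
        a1, a2, ae = (params.att[h, :D], params.att[h, D:2 * D],
                      params.att[h, 2 * D])
        if params.variant == "as_printed":
            S = _leaky(Xp @ a1[:, None] + (Xp @ a2)[None, :] + ae * E,
                       params.negative_slope)
        else:  # dynamic attention: rectifier inside, before ∂ᵀ
            S = (_leaky(Xp, params.negative_slope) @ a1)[:, None] \
                + (_leaky(Xp, params.negative_slope) @ a2)[None, :] \
                + ae * _leaky(E, params.negative_slope)
        S = np.where(adj, S, -np.inf)
        S = S - S.max(axis=1, keepdims=True)
        expS = np.where(adj, np.exp(S), 0.0)
        alpha = expS / expS.sum(axis=1, keepdims=True)
        msg_x = alpha @ Xp                          # (n, D)
        msg_e = (alpha * E).sum(axis=1, keepdims=True)
        m = np.hstack([msg_x, msg_e]) @ params.M[h].T
        outs.append(m)
        alphas.append(alpha)
    out = np.hstack(outs)
    res = X if params.residual is None else X @ params.residual.T
    return out + res, np.stack(alphas)


def graph_readout(node_features: np.ndarray, proportions: np.ndarray
                  ) -> np.ndarray:
    """Proportion-weighted sum of final node features."""
    proportions = np.asarray(proportions, dtype=np.float64)
    if proportions.sum() <= 0:
        raise ValidationError("all-zero proportions")
    w = proportions / proportions.sum()
    return w @ np.asarray(node_features, dtype=np.float64)
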