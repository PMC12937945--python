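"""Single-sample network (SSN) inference.

The SSN idea: the influence of one sample s on a cohort-level Pearson
correlation is amplified into a per-sample edge weight.  With e^N the
correlation over all N samples and e^{N−s} the correlation with s removed,

    e^s = N · (e^N − e^{N−s}) + e^{N−s}

Edge significance follows the differential-correlation z-test

    z = (e^N − e^{N−s}) / ((1 − (e^{N−s})²) / (N − 1))

with a two-sided normal p-value; edges with p ≥ α are flagged not kept.

The default mode is leave-one-out (the reference cohort includes s); an
add-one-in mode (reference excludes s, with the target appended) is
available behind a flag.  e^s can exceed [−1, 1]; a clamped copy is
provided for downstream edge features while the raw value is retained.

The same machinery applies to gene pairs (bulk diagnostics) and to
cell-type activity pairs (single-cell edge features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core_data import ValidationError

__all__ = [
    "ReferenceCorrelation",
    "EdgeRecord",
    "SampleNetwork",
    "pearson_matrix",
    "ssn_perturb",
    "edge_significance",
    "build_sample_network",
    "group_average_networks",
    "network_table",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class ReferenceCorrelation:
    """Symmetric Pearson matrix over N reference samples."""

    variable_ids: list[str]
    values: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        k = len(self.variable_ids)
        if self.values.shape != (k, k):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")
        if self.n_samples < 3:
            raise ValidationError("need at least 3 samples")


@dataclass(frozen=True)
class EdgeRecord:
    var_i: str
    var_j: str
    e_ref: float    # e^{N−s}
    e_full: float   # e^N
    e_s: float      # raw perturbed weight (may exceed [-1, 1])
    z: float
    p: float
    kept: bool

    @property
    def e_s_clamped(self) -> float:
        return float(np.clip(self.e_s, -1.0, 1.0))


@dataclass
class SampleNetwork:
    sample_id: str
    variable_ids: list[str]
    edges: list[EdgeRecord]
    alpha: float
    mode: str
    dropped_variables: list[str] = field(default_factory=list)

    def edge_matrix(self, kept_only: bool = True, clamped: bool = True
                    ) -> np.ndarray:
        """Dense symmetric matrix of edge weights (zeros where not kept)."""
        k = len(self.variable_ids)
        idx = {v: i for i, v in enumerate(self.variable_ids)}
        out = np.zeros((k, k))
        for e in self.edges:
            if kept_only and not e.kept:
                continue
            w = e.e_s_clamped if clamped else e.e_s
            out[idx[e.var_i], idx[e.var_j]] = w
            out[idx[e.var_j], idx[e.var_i]] = w
        return out


def pearson_matrix(values: np.ndarray, variable_ids: list[str] | None = None
                   ) -> ReferenceCorrelation:
    """Pearson coefficients over variables×samples data.

    Zero-variance variables are dropped with a warning before computing.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValidationError("expected variables×samples matrix")
    k, n = values.shape
    if n < 3:
        raise ValidationError(f"need >=3 samples, got {n}")
    if variable_ids is None:
        variable_ids = [f"v{i}" for i in range(k)]
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [v for v, k_ in zip(variable_ids, keep) if not k_]
    if dropped:
        logger.warning("dropping zero-variance variables: %s", dropped)
    kept_ids = [v for v, k_ in zip(variable_ids, keep) if k_]
    corr = np.corrcoef(values[keep])
    corr = np.clip(np.atleast_2d(corr), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ReferenceCorrelation(kept_ids, corr, n)


def ssn_perturb(e_n, e_nms, n: int):
    """Perturbed single-sample edge weight e^s = N(e^N − e^{N−s}) + e^{N−s}."""
    if n < 3:
        raise ValidationError("need N >= 3")
    e_n = np.asarray(e_n, dtype=np.float64)
    e_nms = np.asarray(e_nms, dtype=np.float64)
    return n * (e_n - e_nms) + e_nms


def edge_significance(e_n, e_nms, n: int):
    """Differential-correlation z and two-sided normal p for one edge.

    z = ΔPCC / ((1 − e_{N−s}²) / (N − 1)) with ΔPCC = e^N − e^{N−s}.
    """
    e_n = np.asarray(e_n, dtype=np.float64)
    e_nms = np.asarray(e_nms, dtype=np.float64)
    if np.any(np.abs(e_nms) >= 1.0):
        raise ValidationError("|e^{N-s}| = 1: degenerate variance")
    z = (e_n - e_nms) / ((1.0 - e_nms ** 2) / (n - 1))
    p = 2.0 * ndtr(-np.abs(z))
    return z, p


def _pearson_pairs(values: np.ndarray) -> np.ndarray:
    """Correlation matrix without variance guards (caller pre-filters)."""
    return np.clip(np.corrcoef(values), -1.0, 1.0)


def build_sample_network(values: np.ndarray, variable_ids: list[str],
                         target_sample: str, sample_ids: list[str],
                         alpha: float = DEFAULT_ALPHA,
                         mode: str = "leave_out") -> SampleNetwork:
    """Build the full SSN for one target sample.

    ``values`` is variables×samples.  In ``leave_out`` mode (default) the
    reference includes the target: e^N is computed over all N columns and
    e^{N−s} with the target removed.  In ``add_in`` mode the reference
    excludes the target: e^{N−s} is the reference correlation over the
    other N−1 columns and e^N re-adds the target.  Zero-variance variables
    (in either correlation) are excluded and recorded.
    """
    if mode not in ("leave_out", "add_in"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    values = np.asarray(values, dtype=np.float64)
    if target_sample not in sample_ids:
        raise ValidationError(f"target sample {target_sample!r} not found")
    n_total = values.shape[1]
    if n_total < 4:
        raise ValidationError("need >=4 samples (>=3 after removal)")
    s_idx = sample_ids.index(target_sample)
    rest = np.delete(values, s_idx, axis=1)

    sd_full = values.std(axis=1, ddof=1)
    sd_rest = rest.std(axis=1, ddof=1)
    keep = (sd_full > 0) & (sd_rest > 0)
    dropped = [v for v, k_ in zip(variable_ids, keep) if not k_]
    if dropped:
        logger.info("sample %s: excluding zero-variance variables %s",
                    target_sample, dropped)
    ids = [v for v, k_ in zip(variable_ids, keep) if k_]
    full = _pearson_pairs(values[keep])
    minus = _pearson_pairs(rest[keep])
    # in both modes e^N spans the cohort including s (N columns) and
    # e^{N-s} excludes s; the modes differ in which count plays N
    n_for_eq = n_total if mode == "leave_out" else n_total - 1

    e_s = ssn_perturb(full, minus, n_for_eq)
    z, p = edge_significance(
        full, np.clip(minus, -1 + 1e-12, 1 - 1e-12), n_for_eq)

    edges = []
    k = len(ids)
    for i in range(k):
        for j in range(i + 1, k):
            edges.append(EdgeRecord(
                ids[i], ids[j],
                float(minus[i, j]), float(full[i, j]), float(e_s[i, j]),
                float(z[i, j]), float(p[i, j]), bool(p[i, j] < alpha)))
    return SampleNetwork(target_sample, ids, edges, alpha, mode, dropped)


def group_average_networks(networks: list[SampleNetwork],
                           labels: dict[str, int]) -> dict[int, np.ndarray]:
    """Mean kept-edge weight matrices per response label group."""
    if not networks:
        raise ValidationError("no networks to average")
    var_ids = networks[0].variable_ids
    groups: dict[int, list[np.ndarray]] = {}
    for net in networks:
        if net.variable_ids != var_ids:
            raise ValidationError("networks have inconsistent variables")
        groups.setdefault(labels[net.sample_id], []).append(
            net.edge_matrix(kept_only=True, clamped=True))
    return {g: np.mean(mats, axis=0) for g, mats in groups.items()}


def network_table(networks: list[SampleNetwork]) -> pd.DataFrame:
    """Flatten edge records for TSV export."""
    rows = []
    for net in networks:
        for e in net.edges:
            rows.append((net.sample_id, e.var_i, e.var_j, e.e_ref, e.e_full,
                         e.e_s, e.z, e.p, e.kept))
    return pd.DataFrame(rows, columns=[
        "sample", "var_i", "var_j", "e_ref", "e_full", "e_s", "z", "p",
        "kept"])
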