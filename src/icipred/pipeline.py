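"""End-to-end assembly: cohorts → model-ready datasets → trained models.

Bulk branch: sample-level z-scoring → pathway scoring → chain embeddings
→ :class:`~icipred.training.BulkDataset`.

Single-cell branch: log1p counts → per-(sample, type) pseudo-bulk →
pooled pathway scoring → cell-type activity scalars → per-patient
single-sample networks → padded graph tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dataclasses import replace

import pandas as pd

from .core_data import zscore_normalize
from .interpret import (global_importance, shapley_values,
                        top_variance_features)
from .encoders import ChainEmbedder, HashChainEmbedder, embed_drug_chains
from .pathway import gsva_scores
from .sc_graph import (PSEUDOBULK_SEP, SELF_LOOP_EDGE, activity_matrix,
                       pseudobulk_matrix, pseudobulk_profiles)
from .ssn import build_sample_network
from .synthetic import BulkCohort, SCCohort
from .training import (BulkDataset, SCDatasetTensors, stratified_folds,
                       train_model)

__all__ = ["prepare_bulk_dataset", "prepare_sc_dataset", "SCPreparation",
           "fold_aggregated_importance"]


def prepare_bulk_dataset(cohort: BulkCohort,
                         embedder: ChainEmbedder | None = None,
                         min_set_size: int = 2) -> BulkDataset:
    """Z-score, score pathways, embed drugs, and row-align everything."""
    if embedder is None:
        embedder = HashChainEmbedder()
    z = zscore_normalize(cohort.expression)
    scores = gsva_scores(z, cohort.gene_sets, min_set_size=min_set_size)
    drug_vecs = {rec.drug_name: embed_drug_chains(rec, embedder).raw
                 for rec in cohort.drugs}
    sample_ids = list(z.sample_ids)
    drug_raw = np.stack([drug_vecs[cohort.drug_assignment[s]]
                         for s in sample_ids])
    labels = cohort.response.label_vector(sample_ids)
    return BulkDataset(sample_ids, z.values.T.copy(), scores.values.T.copy(),
                       drug_raw, labels, list(z.gene_ids),
                       list(scores.set_ids))


@dataclass
class SCPreparation:
    """The dataset tensors plus the intermediate objects behind them."""

    dataset: SCDatasetTensors
    profiles: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    activities: np.ndarray | None = None
    pathway_scores: object = None


def prepare_sc_dataset(cohort: SCCohort, alpha: float = 0.05,
                       embedder: ChainEmbedder | None = None,
                       ssn_mode: str = "leave_out") -> SCPreparation:
    """Build padded per-patient graph tensors from a single-cell cohort.

    The per-type activity scalar feeding the SSN step is the mean
    z-scored pseudo-bulk expression over the union of the gene-set
    collection's genes (the activity panel).
    """
    if embedder is None:
        embedder = HashChainEmbedder()
    log_counts = cohort.counts
    log_counts = type(log_counts)(list(log_counts.gene_ids),
                                  list(log_counts.sample_ids),
                                  np.log1p(log_counts.values))
    profiles = pseudobulk_profiles(log_counts, cohort.annotations)
    patient_ids = [p for p in cohort.response.sample_ids if p in profiles]
    profiles = {p: profiles[p] for p in patient_ids}
    types = list(cohort.annotations.vocabulary)
    T = len(types)

    pooled = pseudobulk_matrix(profiles)
    scores = gsva_scores(pooled, cohort.gene_sets, min_set_size=2)
    score_col = {c: j for j, c in enumerate(scores.sample_ids)}

    panel = cohort.gene_sets.all_genes()
    act, present = activity_matrix(profiles, panel, types)

    networks = {}
    for pid in patient_ids:
        networks[pid] = build_sample_network(
            act, types, pid, patient_ids, alpha=alpha, mode=ssn_mode)

    n = len(patient_ids)
    n_genes = len(log_counts.gene_ids)
    n_sets = len(scores.set_ids)
    a_exp = np.zeros((n, T, n_genes))
    a_path = np.zeros((n, T, n_sets))
    proportions = np.zeros((n, T))
    node_mask = np.zeros((n, T), dtype=bool)
    E = np.zeros((n, T, T))
    adj = np.zeros((n, T, T), dtype=bool)
    tidx = {t: i for i, t in enumerate(types)}
    for i, pid in enumerate(patient_ids):
        prof = profiles[pid]
        props = prof.proportions
        for t, row, pr in zip(prof.cell_types, prof.means, props):
            ti = tidx[t]
            node_mask[i, ti] = True
            proportions[i, ti] = pr
            sd = row.std(ddof=1)
            a_exp[i, ti] = (row - row.mean()) / sd if sd > 0 else 0.0
            a_path[i, ti] = scores.values[
                :, score_col[f"{pid}{PSEUDOBULK_SEP}{t}"]]
            adj[i, ti, ti] = True
            E[i, ti, ti] = SELF_LOOP_EDGE
        for e in networks[pid].edges:
            if not e.kept:
                continue
            ti, tj = tidx[e.var_i], tidx[e.var_j]
            if node_mask[i, ti] and node_mask[i, tj]:
                E[i, ti, tj] = E[i, tj, ti] = e.e_s_clamped
                adj[i, ti, tj] = adj[i, tj, ti] = True

    drug_vecs = {rec.drug_name: embed_drug_chains(rec, embedder).raw
                 for rec in cohort.drugs}
    drug_raw = np.stack([drug_vecs[cohort.drug_assignment[p]]
                         for p in patient_ids])
    labels = cohort.response.label_vector(patient_ids)
    dataset = SCDatasetTensors(patient_ids, a_exp, a_path, proportions,
                               node_mask, E, adj, drug_raw, labels, types)
    return SCPreparation(dataset, profiles, networks, act, scores)


def bulk_feature_matrix(dataset: BulkDataset) -> tuple[np.ndarray, list[str]]:
    """Patient-side input matrix (genes ∥ pathway scores) and its names."""
    return (np.hstack([dataset.x_exp, dataset.x_path]),
            dataset.gene_ids + dataset.set_ids)


def bulk_patient_model_fn(model, dataset: BulkDataset):
    """Wrap a trained bulk model as f(patient features) with drug fixed.

    The drug input is held at the cohort's first drug embedding so the
    attribution isolates patient-side features.
    """
    n_genes = dataset.x_exp.shape[1]
    drug_row = dataset.drug_raw[:1]

    def model_fn(X: np.ndarray) -> np.ndarray:
        sub = BulkDataset(["_"] * X.shape[0], X[:, :n_genes],
                          X[:, n_genes:],
                          np.repeat(drug_row, X.shape[0], axis=0),
                          np.zeros(X.shape[0], dtype=np.int64))
        return model.predict(sub)

    return model_fn


def fold_aggregated_importance(dataset: BulkDataset, config,
                               k: int = 5, n_replicates: int = 2,
                               n_explain: int = 12, n_background: int = 15,
                               budget: int = 1200, top_genes: int = 500,
                               seed: int = 0):
    """Global feature importance aggregated over cross-validation models.

    Mirrors the per-fold attribution protocol: for every CV fold (and
    ``n_replicates`` training seeds per fold) a model is trained on the
    fold's training split and explained on training samples via sampled
    Shapley attribution over the top-variance genes plus all pathway
    scores.  Per-model mean-|value| importances are averaged; averaging
    across models suppresses each single network's idiosyncratic reliance
    on noise features while preserving signal shared by all of them.

    Returns (aggregated importance DataFrame, per-model importance list,
    fold assignment).
    """
    labels = {s: int(y) for s, y in zip(dataset.sample_ids, dataset.labels)}
    folds = stratified_folds(labels, k, seed=seed)
    feats, names = bulk_feature_matrix(dataset)
    n_genes = dataset.x_exp.shape[1]
    gene_sel = top_variance_features(dataset.x_exp, dataset.gene_ids,
                                     top_genes)
    fidx = np.array(gene_sel + list(range(n_genes, feats.shape[1])))
    fnames = [names[j] for j in fidx]
    per_model = []
    for f in range(k):
        tr = np.array([i for i, s in enumerate(dataset.sample_ids)
                       if folds.fold_of(s) != f])
        for r in range(n_replicates):
            model, _ = train_model(
                "bulk", dataset.subset(tr),
                replace(config, seed=config.seed + 10 * f + 1000 * r))
            model_fn = bulk_patient_model_fn(model, dataset)
            rng = np.random.default_rng(seed + 100 + 10 * f + r)
            bg = feats[tr[rng.choice(len(tr), min(n_background, len(tr)),
                                     replace=False)]]
            ex = tr[rng.choice(len(tr), min(n_explain, len(tr)),
                               replace=False)]
            result = shapley_values(
                model_fn, bg, feats[ex],
                [dataset.sample_ids[i] for i in ex], fnames,
                method="sampled", budget=budget,
                seed=seed + 10 * f + r, feature_idx=fidx)
            per_model.append(
                global_importance(result).set_index("feature")["importance"])
    agg = pd.concat(per_model, axis=1).mean(axis=1) \
        .sort_values(ascending=False)
    agg_df = agg.reset_index()
    agg_df.columns = ["feature", "importance"]
    return agg_df, per_model, folds
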