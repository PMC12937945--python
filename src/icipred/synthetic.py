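"""Seeded synthetic cohorts with planted, recoverable response signal.

Two generators emulate the data shapes the pipeline consumes:

* **Bulk cohort** — genes×samples Gaussian expression with a subset of
  informative genes mean-shifted in responders (effect in SD units),
  grouped into planted gene sets inside a larger decoy collection, plus
  RECIST labels, two synthetic antibody drugs and per-sample drug
  assignments.
* **Pseudo-single-cell cohort** — per patient, cell-type proportions
  drawn from a Dirichlet whose concentration is elevated for
  response-associated types (exhausted CD8 T cells, M2-like macrophages)
  in responders; per cell, Poisson counts around type-specific rates
  modulated by a patient-level latent factor whose coupling to a shared
  gene panel is stronger in responders, so cross-type correlation — and
  hence the single-sample-network edge weights — differ by group.

Everything is a pure function of the manifest: same manifest, same
bytes.  Expression is Gaussian (not counts) for bulk because the
pipeline consumes z-scored values; single-cell counts use log-scale
rates with Poisson sampling for mild realism.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .core_data import (AntibodyRecord, CellAnnotationTable,
                        DEFAULT_CELL_TYPES, ExpressionMatrix, GeneSet,
                        GeneSetCollection, ResponseTable, ValidationError,
                        recist_to_binary)
from .encoders import DEFAULT_RAW_WIDTH, DrugEmbedding

__all__ = [
    "BulkManifest",
    "SCManifest",
    "BulkCohort",
    "SCCohort",
    "gen_bulk_cohort",
    "gen_sc_cohort",
    "gen_drug_embedding",
    "dataset_hash",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class BulkManifest:
    """Study conditions for the bulk generator."""

    seed: int = 0
    n_samples: int = 300
    n_genes: int = 1000
    n_informative: int = 20
    n_planted_sets: int = 4
    effect: float = 1.5          # responder mean shift, SD units
    prevalence: float = 0.35     # responder fraction
    n_decoy_sets: int = 36
    genes_per_decoy: int = 5
    n_drugs: int = 2

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ValidationError("more informative genes than genes")
        if self.n_informative % self.n_planted_sets != 0:
            raise ValidationError(
                "informative genes must split evenly into planted sets")


@dataclass(frozen=True)
class SCManifest:
    """Study conditions for the pseudo-single-cell generator."""

    seed: int = 0
    n_patients: int = 120
    n_genes: int = 250
    cells_per_patient: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    prevalence: float = 0.4
    shifted_types: tuple[str, ...] = ("CD8T_Tex", "Mac_M2like")
    proportion_shift: float = 2.0       # concentration multiplier
    base_concentration: float = 5.0
    coupling_responder: float = 0.8
    coupling_nonresponder: float = 0.3
    type_noise_sd: float = 0.25
    panel_size: int = 60
    n_sets: int = 15
    genes_per_set: int = 8
    n_drugs: int = 2

    def __post_init__(self):
        if len(self.cell_types) < 2:
            raise ValidationError("need at least 2 cell types")
        missing = set(self.shifted_types) - set(self.cell_types)
        if missing:
            raise ValidationError(f"shifted types not in vocabulary: "
                                  f"{sorted(missing)}")
        if self.panel_size + self.genes_per_set > self.n_genes:
            raise ValidationError(
                "panel_size + genes_per_set must not exceed n_genes")


@dataclass
class BulkCohort:
    manifest: BulkManifest
    expression: ExpressionMatrix
    response: ResponseTable
    gene_sets: GeneSetCollection
    drugs: list[AntibodyRecord]
    drug_assignment: dict[str, str]
    informative_genes: list[str] = field(default_factory=list)
    planted_set_names: list[str] = field(default_factory=list)


@dataclass
class SCCohort:
    manifest: SCManifest
    counts: ExpressionMatrix          # genes×cells
    annotations: CellAnnotationTable
    response: ResponseTable
    drugs: list[AntibodyRecord]
    drug_assignment: dict[str, str]
    gene_sets: GeneSetCollection
    panel_genes: list[str] = field(default_factory=list)
    latent_factors: dict[str, float] = field(default_factory=dict)


def _labels(rng: np.random.Generator, n: int, prevalence: float
            ) -> np.ndarray:
    n_pos = int(round(prevalence * n))
    lab = np.zeros(n, dtype=int)
    lab[:n_pos] = 1
    rng.shuffle(lab)
    return lab


def _recist_from_labels(rng: np.random.Generator, sample_ids, labels
                        ) -> ResponseTable:
    cats = {}
    for s, y in zip(sample_ids, labels):
        if y:
            cats[s] = "CR" if rng.random() < 0.3 else "PR"
        else:
            cats[s] = "SD" if rng.random() < 0.5 else "PD"
    return recist_to_binary(cats)


def _synthetic_drugs(rng: np.random.Generator, n_drugs: int
                     ) -> list[AntibodyRecord]:
    drugs = []
    for d in range(n_drugs):
        heavy = "".join(rng.choice(AMINO_ACIDS, size=120))
        light = "".join(rng.choice(AMINO_ACIDS, size=110))
        drugs.append(AntibodyRecord(f"SYN-mab-{d}", heavy, light))
    return drugs


def gen_bulk_cohort(manifest: BulkManifest) -> BulkCohort:
    """Generate a bulk cohort with planted responder-enriched genes."""
    m = manifest
    rng = np.random.default_rng(m.seed)
    gene_ids = [f"G{i:04d}" for i in range(m.n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(m.n_samples)]
    labels = _labels(rng, m.n_samples, m.prevalence)

    values = rng.standard_normal((m.n_genes, m.n_samples))
    info_idx = rng.choice(m.n_genes, size=m.n_informative, replace=False)
    values[np.ix_(info_idx, labels == 1)] += m.effect
    informative = [gene_ids[i] for i in sorted(info_idx)]

    per_set = m.n_informative // m.n_planted_sets
    info_sorted = sorted(info_idx)
    sets = []
    for k in range(m.n_planted_sets):
        genes = tuple(gene_ids[i]
                      for i in info_sorted[k * per_set:(k + 1) * per_set])
        sets.append(GeneSet(f"PLANTED_{k}", genes, "planted responder set"))
    non_info = np.setdiff1d(np.arange(m.n_genes), info_idx)
    for k in range(m.n_decoy_sets):
        idx = rng.choice(non_info, size=m.genes_per_decoy, replace=False)
        sets.append(GeneSet(f"DECOY_{k:03d}",
                            tuple(gene_ids[i] for i in sorted(idx)),
                            "decoy set"))

    response = _recist_from_labels(rng, sample_ids, labels)
    drugs = _synthetic_drugs(rng, m.n_drugs)
    assignment = {s: drugs[int(rng.integers(m.n_drugs))].drug_name
                  for s in sample_ids}
    return BulkCohort(m, ExpressionMatrix(gene_ids, sample_ids, values),
                      response, GeneSetCollection(sets), drugs, assignment,
                      informative, [s.name for s in sets[:m.n_planted_sets]])


def gen_sc_cohort(manifest: SCManifest) -> SCCohort:
    """Generate a multi-patient pseudo-single-cell cohort.

    Cell counts: per cell of type t in patient p, counts ~ Poisson(rate)
    with log rate = base_t[g] + c(label_p)·f_p·1[g ∈ panel] + noise_{p,t},
    f_p a patient latent factor.  Proportions: Dirichlet with shifted
    concentration for response-associated types in responders.
    """
    m = manifest
    rng = np.random.default_rng(m.seed)
    gene_ids = [f"g{i:04d}" for i in range(m.n_genes)]
    patient_ids = [f"P{i:03d}" for i in range(m.n_patients)]
    labels = _labels(rng, m.n_patients, m.prevalence)
    types = list(m.cell_types)
    T = len(types)

    # type-specific base log-rates around a modest depth
    base = rng.normal(loc=0.0, scale=0.7, size=(T, m.n_genes))
    panel = np.zeros(m.n_genes, dtype=bool)
    panel[rng.choice(m.n_genes, size=m.panel_size, replace=False)] = True
    panel_genes = [g for g, in_p in zip(gene_ids, panel) if in_p]

    alpha0 = np.full(T, m.base_concentration)
    shifted = np.array([t in m.shifted_types for t in types])

    all_counts, cell_ids, cells = [], [], {}
    factors: dict[str, float] = {}
    for p_i, pid in enumerate(patient_ids):
        y = labels[p_i]
        alpha = alpha0.copy()
        if y:
            alpha[shifted] *= m.proportion_shift
        props = rng.dirichlet(alpha)
        n_cells = rng.multinomial(m.cells_per_patient, props)
        f_p = rng.standard_normal()
        factors[pid] = float(f_p)
        c = m.coupling_responder if y else m.coupling_nonresponder
        for t_i, t in enumerate(types):
            k = int(n_cells[t_i])
            if k == 0:
                continue
            eta = rng.normal(0.0, m.type_noise_sd)
            log_rate = base[t_i] + (c * f_p + eta) * panel
            rate = np.exp(np.clip(log_rate, -8, 5))
            block = rng.poisson(rate, size=(k, m.n_genes))
            all_counts.append(block)
            for j in range(k):
                cid = f"{pid}_c{len(cell_ids):05d}"
                cell_ids.append(cid)
                cells[cid] = (pid, t)
    counts = np.concatenate(all_counts).T.astype(np.float64)

    # gene sets over the measured genes; the first sets tile the panel
    sets = []
    panel_idx = np.flatnonzero(panel)
    other_idx = np.flatnonzero(~panel)
    for k in range(m.n_sets):
        if (k + 1) * m.genes_per_set <= panel_idx.size:
            idx = panel_idx[k * m.genes_per_set:(k + 1) * m.genes_per_set]
            name, desc = f"SC_PANEL_{k:02d}", "panel tile"
        else:
            idx = rng.choice(other_idx, size=m.genes_per_set, replace=False)
            name, desc = f"SC_OTHER_{k:02d}", "off-panel set"
        sets.append(GeneSet(name, tuple(gene_ids[i] for i in sorted(idx)),
                            desc))

    response = _recist_from_labels(rng, patient_ids, labels)
    drugs = _synthetic_drugs(rng, m.n_drugs)
    assignment = {p: drugs[int(rng.integers(m.n_drugs))].drug_name
                  for p in patient_ids}
    return SCCohort(
        m, ExpressionMatrix(gene_ids, cell_ids, counts),
        CellAnnotationTable(cells, tuple(types)), response, drugs,
        assignment, GeneSetCollection(sets), panel_genes, factors)


def gen_drug_embedding(drug_name: str, width: int = DEFAULT_RAW_WIDTH
                       ) -> DrugEmbedding:
    """Deterministic raw drug embedding keyed by name (heavy ∥ light)."""
    if width % 2 != 0:
        raise ValidationError("width must be even (half per chain)")
    digest = hashlib.sha256(drug_name.encode()).digest()
    seed = int.from_bytes(digest[:8], "little")
    rng = np.random.Generator(np.random.PCG64(seed))
    raw = rng.standard_normal(width)
    return DrugEmbedding(drug_name, raw, chain_width=width // 2)


def dataset_hash(*arrays) -> str:
    """Stable digest of a tuple of arrays/strings — reproducibility probe."""
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, np.ndarray):
            h.update(np.ascontiguousarray(a).tobytes())
        else:
            h.update(str(a).encode())
    return h.hexdigest()
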