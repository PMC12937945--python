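# icipred

Predicting immune-checkpoint-inhibitor (ICI) response from
transcriptomes, jointly with a representation of the antibody drug.

A substantial fraction of patients receiving PD-1/PD-L1 or CTLA-4
blockade do not benefit from it, and predicting who will respond from
pre-treatment molecular data remains an open problem.  `icipred` is a
research toolkit for computational biologists working on this question.
It implements a two-branch architecture:

- **Bulk branch.**  A patient is encoded from two views: the z-scored
  expression vector a_EXP and a vector a_PATH of per-sample gene-set
  enrichment scores (GSVA-style kernel-density ranks + KS random walk)
  over an immune-related collection.  Two rectifier MLPs produce
  latents of common width l, stacked into h_p ∈ R^{2×l}.  The drug is
  encoded from its heavy/light chain sequence embeddings (480 per
  chain, concatenated to 960, projected per chain to l) into
  h_d ∈ R^{2×l}.  The two are fused by multi-head **bilinear
  attention**,

      I = ((1·qᵀ) ∘ σ(h_p U)) · σ(h_d V)ᵀ,
      f′_k = σ(h_p U)ₖᵀ · I · σ(h_d V)ₖ,

  followed by a stride-3 SumPool, and an MLP head (512/128 units, batch
  norm + ReLU, logistic output) predicts the responder probability.

- **Single-cell branch.**  Annotated cells are averaged into per-type
  pseudo-bulk profiles and proportions.  Per-patient **single-sample
  networks** over cell-type activity scalars,

      e^s = N·(e^N − e^{N−s}) + e^{N−s},

  provide significance-filtered edge features; node features come from
  the shared patient encoder; an edge-featured **graph attention**
  layer (additive scores over [X_i ∥ X_j ∥ E_ij], softmax over
  neighbors, residual connections) produces node embeddings, a
  proportion-weighted readout summarizes the patient, and the head
  predicts response from readout ∥ drug embedding.

Training (cross-entropy loss, Adam, early stopping, two-phase grid
search), stratified cross-validated evaluation (accuracy / F1 / AUROC,
bootstrap CIs, DeLong and McNemar paired tests), and Shapley-value
interpretation (exact and sampled estimators, global importance,
cross-fold intersection, waterfall export) are all included, along with
seeded synthetic cohort generators that plant recoverable response
signal — the package is exercisable end-to-end without any external
data.  Labels follow RECIST: CR/PR = responder, SD/PD = non-responder.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

Train and evaluate the bulk branch on a small synthetic cohort with
planted signal:

```python
import icipred as ip

cohort = ip.gen_bulk_cohort(ip.BulkManifest(seed=1, n_samples=120,
                                            n_genes=300, n_decoy_sets=16))
dataset = ip.prepare_bulk_dataset(cohort)          # z-score, GSVA, drug embeddings
config = ip.scaled_config(seed=0)                  # compact CPU-friendly network
metrics, scores, folds = ip.cross_validate("bulk", dataset, config,
                                           k=5, seed=0)
for f, m in enumerate(metrics):
    print(f"fold {f}: accuracy={m.accuracy:.3f}  F1={m.f1:.3f}  AUROC={m.auroc:.3f}")
pooled = ip.classification_metrics(dataset.labels, scores)
lo, hi = ip.bootstrap_ci(dataset.labels, scores, "auroc", seed=0)
print(f"pooled AUROC={pooled.auroc:.4f} (95% CI {lo:.4f}-{hi:.4f})")
```

Output:

```
fold 0: accuracy=0.880  F1=0.800  AUROC=1.000
fold 1: accuracy=0.917  F1=0.857  AUROC=1.000
fold 2: accuracy=0.833  F1=0.750  AUROC=0.961
fold 3: accuracy=0.696  F1=0.667  AUROC=0.858
fold 4: accuracy=0.875  F1=0.824  AUROC=0.978
pooled AUROC=0.9423 (95% CI 0.9007-0.9752)
```

Each fold line reports held-out performance of a model trained on the
other four folds; the pooled AUROC pools all out-of-fold responder
probabilities, with a percentile-bootstrap interval.  The cohort plants
20 genes shifted +1.5 SD in responders (grouped into 4 gene sets among
16 decoys), so a well-functioning pipeline should sit well above
chance — and does.

The same flow works from the shell:

```sh
icipred simulate bulk --seed 1 --out data/
icipred gsva --expr data/expression.tsv --gmt data/gene_sets.gmt --out scores.tsv
icipred ssn  --expr scores.tsv --out edges.tsv
icipred train-bulk --sim-seed 1 --seed 0 --out run/
icipred explain --sim-seed 1 --seed 0 --out shap/
```

Every artifact-writing command leaves a `*.provenance.json` sidecar
(command, seed, config, package version) sufficient to re-run it.

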