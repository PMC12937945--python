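# Methods

`icipred` predicts whether a cancer patient will respond to an immune
checkpoint inhibitor (ICI) from transcriptomic data, jointly with a
representation of the administered antibody drug.  It has two branches
sharing a patient feature encoder: a bulk branch that fuses patient and
drug representations through bilinear attention, and a single-cell
branch that models the tumor microenvironment as a cell-type interaction
graph processed by edge-featured graph attention.  This note documents
the models, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the package's numerical conventions.

## Preprocessing and labels

Expression matrices are genes×samples.  Each sample column is z-scored
across its genes (divisor n−1; a zero-variance column maps to zeros)
so that cohorts processed independently remain comparable and a single
future patient can be normalized without reference to a cohort.  Inputs
are assumed to already be on a log scale; the package applies `log1p`
only to raw single-cell counts.  RECIST categories map to binary labels:
CR and PR are responders (1), SD and PD non-responders (0).  Gene-id
matching is exact and case-sensitive; no symbol aliasing is attempted.

## Pathway scoring

Per-sample gene-set scores follow the GSVA construction: a Gaussian
kernel cumulative-density estimate per gene (bandwidth s_g/4, the
published default; degenerate genes fall back to a near-zero bandwidth
giving ties), a per-sample symmetric rank statistic z = rank − p/2, and
a Kolmogorov–Smirnov random walk over genes in decreasing-statistic
order, with increments |z|^τ normalized within the set and decrements
1/(p−m) off the set.  The enrichment score is the maximum positive walk
deviation minus the magnitude of the maximum negative deviation
("max-diff" convention), always in [−1, 1].  Defaults: τ = 1, minimum
surviving set size 2, ties in the gene order broken lexicographically
by gene id so the whole module is bit-deterministic.  Scores of one
sample depend on other samples only through the density step — a
documented, tested property.

## Patient and drug encoders

The patient encoder maps the z-scored expression vector and the pathway
score vector through two separate rectifier MLPs (Eq. form
t = σ(ωa + b), two hidden layers) to latents of a common width l and
stacks them into h_p ∈ R^{2×l}.  Library defaults are hidden 1024 and
l = 256; the evaluation runs in this repository use a compact
configuration (hidden 128, l = 32) so that cross-validated training and
repeated ablations fit a single-CPU budget — the architecture is
identical, only widths differ.

Drug representations start from per-chain amino-acid embeddings: 480
values per heavy or light chain, concatenated heavy∥light into a
960-vector.  The default provider derives a reproducible pseudo-random
vector from a stable digest of the sequence; it preserves the interface
contract (deterministic, fixed-width, collision-free in practice) while
carrying no biochemical information, which is sufficient here because
the synthetic benchmark assigns drugs at random and therefore treats the
drug vector as an exchangeable covariate.  Any provider emitting
fixed-width per-chain vectors — e.g. a protein language model — plugs in
behind the same interface, or precomputed vectors can be loaded from
TSV.  Each chain is projected 480 → l by its own single rectifier
layer, giving h_d ∈ R^{2×l} whose rows (heavy, light) mirror the
patient's two semantic rows (expression, pathway).

## Bilinear attention fusion (bulk branch)

For one head with query q ∈ R^K and shared U, V ∈ R^{l×K}:

    I  = ((1·qᵀ) ∘ σ(h_p U)) · σ(h_d V)ᵀ            (2×2 interaction map)
    f′_k = σ(h_p U)_{·,k}ᵀ · I · σ(h_d V)_{·,k}     (bilinear pooling)

The "1" is the all-ones vector over patient rows, broadcasting q —
the only reading under which the expression is dimensionally
consistent.  σ is the rectifier throughout (an identity mode exists for
tests of the bilinearity property only).  Heads share U and V and own
their q; per-head f′ are summed (a concatenation flag exists), then a
non-overlapping SumPool with stride 3 yields f ∈ R^{K/3}.  K defaults
to 768 (evaluation configuration 48); K must be divisible by the
stride.  No softmax is applied to I before pooling; a normalized copy
is exported for inspection only.

## Single-sample networks

For variables i, j and target sample s, with e^N the Pearson
correlation over all N samples and e^{N−s} the correlation with s
removed:

    e^s = N·(e^N − e^{N−s}) + e^{N−s}

Significance uses the differential-correlation z-test
z = (e^N − e^{N−s}) / ((1 − (e^{N−s})²)/(N−1)) with a two-sided normal
p-value; edges with p ≥ α (default 0.05) are flagged not kept.  The
default mode is leave-one-out (reference includes s); an add-one-in
mode (reference excludes s, the original formulation of the method the
construction derives from) sits behind a flag.  e^s can exceed [−1, 1];
downstream edge features use a clamped copy while records retain the
raw value.  The implementation is verified against brute-force
leave-one-out recomputation to 1e-12.

## Single-cell branch

Cells are averaged within each annotated cell type per patient
(pseudo-bulk), yielding per-type mean profiles and proportions.  The
default type vocabulary has the 12 major tumor-microenvironment types
(B, Plasma, CD4T, CD8T_Tex, CD8T_Teff, Tregs, NK, Mac_M1like,
Mac_M2like, Mo, DC, Mast).

Because Pearson correlation needs one scalar per (sample, variable),
cell types get an *activity* scalar: the mean z-scored pseudo-bulk
expression over a gene panel, by default the union of the gene-set
collection.  This is the minimal construction that makes the
single-sample-network step well-defined for cell-type pairs, and it is
an interpretation — the graph's edge semantics inherit whatever the
panel measures.  Activities across the cohort feed the SSN step per
type pair; each patient's kept edges (clamped weights) become edge
features, self-loops carry weight 1.

Node features concatenate the shared patient encoder's output on the
type's z-scored pseudo-bulk (expression row) and its pathway scores
(pathway row), flattened, plus the type's proportion (both uses of
proportions — node feature and readout weight — are on by default,
each behind a flag).  Missing types are omitted and proportions
renormalized.

The attention layer, per head, scores edge (i, j) as

    a_ij = LeakyReLU( ∂ᵀ [X_i ∥ X_j ∥ E_ij] )

with X the head's linear projection of node features — the rectifier
applied *outside* the ∂ᵀ product, exactly as the formulation this
implements prints it.  The canonical dynamic-attention ordering
(rectifier inside, before ∂ᵀ) is available as `variant="v2"`; the two
disagree in general and the discrepancy is deliberately surfaced as a
flag rather than silently resolved.  Scores are softmax-normalized over
each node's neighbors including its self-loop; messages α·(X_j ∥ E_ij)
are linearly mapped to the head width D, heads concatenated, and a
residual (projected when widths differ) added.  Defaults: two layers,
H = 2 heads, D = 64 (evaluation configuration 16), negative slope 0.2.
The patient readout is the proportion-weighted sum of final node
features; the single-cell head consumes readout ∥ raw drug embedding —
no bilinear fusion in this branch.

## Heads, loss, and training

Both predictor heads use hidden layers of 512 and 128 units — the
printed description says "three hidden layers with 512 and 128
neurons", which is internally inconsistent; two layers are implemented
with an optional third (32 units) behind a flag.  Each hidden layer has
batch normalization and a rectifier (the printed "Softmax" per hidden
layer is read as a rectifier, since a softmax over one unit is
constant); the output unit is logistic.  The loss is mean binary
cross-entropy with predictions clamped at 1e-7.  Optimization is
adaptive-moment stochastic gradient descent (decoupled L2 weight decay
available, default off), mini-batches, dropout 0.1 after hidden layers,
early stopping on a stratified 15% validation split (patience 20 at
full scale, 12 in the compact configuration).  All randomness flows
from seeded generators: same seed and data give bit-identical runs
(asserted in tests with dropout 0).

All tensor operations run on an in-package reverse-mode automatic
differentiation engine over numpy arrays, gradient-checked numerically
in the test suite.

Hyperparameter selection is a two-phase grid search: learning rate
{1e-2, 1e-3, 1e-4, 1e-5} × batch size {32, 64, 128, 256} first, then,
with the winners fixed, attention heads {1, 2, 3, 4} × dropout
{0.1 … 0.5}, each cell scored by mean inner 3-fold CV AUROC (the inner
protocol is the package's choice).  Ties break toward the smaller
learning rate and smaller dropout.  The scoring callable is injectable,
which the tests use to verify the phase structure without paying for
full neural training in every cell.

## Evaluation

Five-fold stratified cross-validation: within each label class samples
are dealt round-robin to folds (per-fold responder counts within one of
each other, guaranteed by construction); with strata (e.g. cancer
types) dealing proceeds per stratum with a carried-over pointer so
every stratum spreads across folds.  Metrics are accuracy and
responder-class F1 at threshold 0.5 (fixed, matching a probability
head) and rank-based AUROC.  Confidence intervals are percentile
bootstrap (B = 1000) over sample-level resamples, redrawn when a class
is missing — the interval procedure is labeled in every report since
the convention is not fixed by the numbers it reproduces.  Paired
comparisons: DeLong's test via structural components for AUROC;
McNemar's test for accuracy, exact two-sided binomial when discordant
pairs ≤ 25 and continuity-corrected chi-square otherwise.

## Shapley interpretation

Attributions are computed on the patient-side input vector (genes and
pathway scores) with the drug input held fixed.  Marginalization is
interventional: absent features are replaced by draws from a background
set of training samples.  The exact estimator enumerates all 2^m
coalitions (m ≤ 15); the sampled estimator draws coalitions with the
Shapley kernel weights, always includes the empty, full, singleton and
all-but-one coalitions, and solves a weighted least squares with the
sum constraint eliminated — so local accuracy (base + Σφ = output)
holds exactly by construction.  For high-dimensional inputs,
attribution restricts to the top-variance 500 genes plus all pathway
scores; unattributed features stay at the explained sample's values and
are absorbed into the per-sample base value.

Global importance is mean |φ| per feature.  Because any single trained
network may idiosyncratically rely on noise features (and, when two
input modalities encode the same signal, may pick either), global
importance for cohort-level claims is aggregated over the
cross-validation fold models (and a second training seed per fold):
noise-feature importance is model-specific and averages away, while
genuinely informative features are important in every model.  The
per-fold extraction mirrors how the cross-validated attribution
analysis is defined; the cross-fold top-k intersection operator is also
provided.

## Synthetic cohorts

The generators define the benchmark conditions; they are pure functions
of their manifest (same seed → identical bytes).

**Bulk**: 300 samples × 1000 genes, baseline N(0, 1), responder
prevalence 0.35 (a realistic ICI response rate).  20 informative genes
are shifted +1.5 SD in responders and tiled into 4 planted sets of 5
genes inside a 40-set collection (36 decoys of 5 non-informative genes
each).  Two synthetic antibody records with random sequences are
assigned to samples at random.  Gaussian expression is used rather than
counts because the pipeline consumes z-scored values.  A logistic
regression on the planted genes alone reaches held-out AUROC ≥ 0.9 —
the recoverability ceiling the model is judged against.

**Single-cell**: 120 patients × 12 types × 2000 cells (the scale of a
typical annotated ICI scRNA-seq cohort), 250 genes, prevalence 0.4.
Proportions are Dirichlet (concentration 5) with the concentration of
exhausted CD8 T cells and M2-like macrophages doubled in responders.
Counts are Poisson around type-specific log-rates; a 60-gene panel is
modulated by a patient latent factor with coupling 0.8 in responders vs
0.3 in non-responders plus per-(patient, type) noise (SD 0.25), so
cross-type activity correlations — and hence SSN edge weights — are
systematically stronger in responders.  Pseudo-bulk expression carries
no direct label signal beyond the coupling, so the graph branch's
performance is attributable to proportions and interaction structure.

What the generators do **not** emulate: batch effects, count
overdispersion and dropout, doublets or ambient RNA, annotation errors,
correlated gene-gene structure within the bulk background, or real
antibody sequence biology.  Passing the recovery checks therefore
demonstrates that the architecture and training machinery can extract
planted mean-shift, proportion and coupling signal at realistic sample
sizes — not that the model reaches any particular accuracy on clinical
cohorts.

## Problem sizes used in the shipped evaluation

The acceptance script and acceptance-level tests use the compact
network configuration (hidden 128, l = 32, K = 48, head 64/32, GAT head
width 16) at the full cohort sizes above, five-fold CV throughout, 100
seeded trials for the pathway detection rate, 50 random instances for
each oracle-equivalence check, and 10 model replicates (5 folds × 2
seeds, 12 explained samples each, 1200-coalition budget) for the
aggregated importance.  These sizes are the package's own evaluation
choices and are expected to run end-to-end in a few minutes on one CPU.

## Known limitations

- The drug branch is exercised with hash-derived embeddings; no claim
  is made about transfer to real antibody sequences.
- The cell-type activity scalar (and therefore the meaning of a
  cell-type edge) depends on the chosen gene panel.
- The printed attention form ("as printed") is kept as the default even
  though the canonical dynamic-attention ordering may be what was
  actually intended; both are available.
- Exact Shapley is limited to 15 features; the sampled estimator's
  per-feature values on 500+ features are noisy at the shipped budget —
  reliable for rankings aggregated over models, not for single-sample,
  single-feature readouts.
- The single-cell branch consumes pre-annotated cells; clustering and
  annotation are out of scope.
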