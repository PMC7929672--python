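# Methods

## Problem

Experimentally verified miRNA–disease associations are sparse: most
miRNA–disease pairs have simply never been tested.  The package treats
association discovery as implicit-feedback link prediction on a binary
incidence matrix *A* ∈ {0,1}^{M×N} (rows miRNAs, columns diseases):
1-entries are verified associations, 0-entries are *unobserved*, not
verified negatives.  Side information enters through two integrated
similarity matrices built from a disease ontology, a weighted gene
functional network, and the association profiles themselves.

## Similarity construction

**Disease semantic similarity (SSD).**  Each disease is represented by
the ancestor closure of its term in a disease ontology DAG.  Within the
DAG of disease *d*, the focal term contributes 1 and every other node *t*
contributes `max over children t' of 0.5·D_d(t')` — contributions halve
per level walking toward the root.  The semantic value DD(*d*) is the sum
of contributions, and

    SSD(d_i, d_j) = Σ_{t ∈ T_i ∩ T_j} (D_{d_i}(t) + D_{d_j}(t)) / (DD(d_i) + DD(d_j)).

Identical DAGs score 1, disjoint node sets score 0.  Contribution
maximisation is restricted to children *inside* the DAG, since
contributions are only defined for ancestors of the focal disease.

**Disease functional similarity (FSD).**  Gene-pair similarity is 1 for
identical genes, the min–max-normalised log-likelihood score for network
edges, 0 otherwise (normalisation is pluggable; min–max over all edges is
the default as it maps onto the [0,1] similarity scale).  FSD between two
disease gene sets is the best-match average: every gene's maximum
similarity into the other set, summed both ways and divided by the total
set size.

**miRNA functional similarity (FSM).**  The same best-match-average
construction applied to the two miRNAs' associated disease sets, with SSD
as the element-level similarity.  A miRNA with no associated disease has
no defined FSM; its entries are stored as 0 so that integration falls
back to the Gaussian kernel.

**Gaussian interaction-profile kernels (GD, GM).**  An RBF kernel over
the binary rows (miRNAs) or columns (diseases) of *A*,
`K(i,j) = exp(−β‖IP(i)−IP(j)‖²)`, with bandwidth
`β = β′ / mean(‖IP‖²)` and `β′ = 1` (the standard convention): the kernel
width adapts to the mean number of associations per entity.  A profile
set that is entirely zero leaves the bandwidth undefined and is rejected.

**Integration.**  `ISM = FSM where FSM ≠ 0, else GM`.
`ISD = (FSD + SSD)/2 where either is non-zero, else GD`.  The disease
rule is applied literally: when exactly one of FSD/SSD is non-zero the
surviving value is still halved.  A `nonzero_mean` flag averages only the
non-zero terms instead; it is off by default because the literal rule is
the defining one.  "≠ 0" is exact comparison against 0.0 — these values
are constructed, not measured.  All matrices are built in double
precision from the upper triangle and mirrored.

## The fused predictor

Two submodels share one embedding table per entity (one M×k table for
miRNAs, one N×k for diseases; k = 32 by default):

* **NNMF towers** — the miRNA and disease embeddings each pass through a
  two-layer fully connected ReLU network ([k, k] widths); the outputs are
  combined by elementwise product `y = p ⊙ q`, the neural generalisation
  of the matrix-factorisation inner product.  The product is kept as a
  k-vector because it is subsequently concatenated, not summed; a
  parameter-free scalar readout `σ(Σ y)` is exposed separately.
* **MLP towers** — the *i*-th row of ISM and the *j*-th row of ISD are
  mapped by separate ReLU MLPs with strictly narrowing widths
  ([input, input/2, k] by default) to k-vectors `m^MLP`, `d^MLP`.

The fusion input concatenates `[y, m^MLP, m, d^MLP, d]` (5k values); a
learned affine map plus sigmoid produces the pair score in (0,1).  A
sigmoid applied to a bare concatenation is not a scalar, so the learned
output layer is the natural completion.  Submodel-only variants for
ablation apply the same learned head to `y` alone ("nnmf") or to
`[m^MLP, d^MLP]` ("mlp").

**Training.**  Summed binary cross-entropy (predictions clipped at
1e-7) over the known associations (label 1) plus uniformly sampled
unobserved pairs (label 0) at a 1:4 ratio, drawn once per run before any
fold splitting.  Optimisation is mini-batch Adam (learning rate 1e-3,
batch 256, 50 epochs) with decoupled weight decay 1e-4 on weights and
embeddings.  The network is small, so forward and backward passes are
written directly in numpy; analytic gradients are validated against
central finite differences (relative error ≤ 1e-4) in the test suite.

**Initialisation.**  Tower weights are He-scaled
(`N(0, sqrt(2/fan_in))`) with small positive biases (0.01); a uniform
tiny-variance initialisation was evaluated first but starves the shared
embeddings of gradient through the two ReLU tower layers and leaves the
factorisation path untrained.  Embeddings default to a *spectral*
initialisation: the top-k eigenvectors of ISM (miRNAs) and ISD
(diseases), scaled by the root eigenvalues, normalised to RMS 0.5, plus
seeded jitter 0.02.  Rows of such embeddings inner-product approximately
like the similarity matrices themselves, so the factorisation path starts
from the similarity geometry rather than noise — this is the one place
the architecture can express interactions between the similarity
features, and it is worth several AUC points on recovery experiments.
`embedding_init="random"` restores plain Gaussian embeddings.

**Ensembling.**  The default configuration trains 3 members that differ
only in a derived initialisation/batch-order seed and averages their
predicted probabilities (`n_models`, set to 1 to disable).  All training
randomness flows from `rng_seed`; two runs with the same seed are
bit-identical.

## Evaluation protocol

Positives and sampled negatives are partitioned jointly into k = 10
random near-equal folds; each fold is scored by an ensemble trained on
the rest.  Metrics: ROC/AUC (trapezoidal over the exact step points,
equal to the half-tie rank statistic), precision–recall, and F1 when the
K top-scoring samples are called positive (grid 100…1000 by default,
clipped to the test-set size).  Pooled-over-folds metrics are the
headline; per-fold mean and SD are reported alongside, since the two
pooling conventions genuinely differ.  Ties in rankings and at the top-K
boundary break deterministically (score descending, then identifier or
position ascending).

**Leakage control.**  The Gaussian-kernel similarities are functions of
the association matrix, so scoring a held-out fold against kernels
computed from the full matrix leaks test labels.  The default
(`gip_mode="train_only"`) recomputes GD/GM — and hence the fallback
entries of ISM/ISD — from the training fold only, with held-out positives
masked to 0.  `gip_mode="full_matrix"` keeps the single full-data kernel,
reproducing the apparent protocol of earlier work in this area; it is
labelled as leaky and is not the default.  Published AUCs on curated
association databases (≈0.95) are therefore not directly comparable to
the leak-free numbers reported here.

Per-disease candidate ranking scores all miRNAs whose pair with the
target disease is unobserved in training, sorted by descending score;
observed pairs are never returned.

## Synthetic worlds

The generator produces a self-consistent dataset — associations, a
disease ontology, a gene network, and a disease→gene map — with planted
low-rank structure, so the whole pipeline is testable without downloads.

**Factor model.**  miRNA and disease factors of rank r = 5 are drawn
around latent *functional family* centroids (10 miRNA families, 8
disease families, centroids N(0, I), within-family spread 0.25).
Association probabilities are `σ(g·u_i·v_j/√r + c)` with signal gain
g = 6 and the intercept *c* calibrated by bisection so the mean
probability equals the requested density exactly.  Labels are Bernoulli
draws, then flipped independently with probability `noise_rate`.

The family structure matters: with fully independent Gaussian factors at
the default sparsity (density 0.05 on 100×80 ≈ 5 associations per
entity), the planted factors are statistically unrecoverable — every
estimator evaluated, including oracle-tuned logistic matrix
factorisation, stalls ~0.15 AUC below the Bayes-optimal score — so
recovery experiments would measure an information-theoretic wall rather
than method quality.  Real miRNAs and diseases also organise into
families with correlated association profiles, which is exactly what the
mixture model emulates.

**Noise ceiling.**  Flip noise 0.02 at density 0.05 makes roughly 28% of
the observed positives pure noise; since those rank like random
negatives, the Bayes-optimal AUC is capped near `1 − φ/2 ≈ 0.86`
regardless of factor separability.  Measured recovery (10-fold CV, 5
seeds, default configuration) is a grand mean AUC ≈ 0.85 — close to that
ceiling.  AUC degrades monotonically as the flip rate rises through
0.0/0.1/0.2.

**Ontology and gene network.**  The ontology is built by recursive
2-means bisection of the disease factors (depth drawn from `dag_depth`),
so factor-similar diseases share deeper ancestors; the Spearman
correlation between SSD and factor cosine similarity is positive by
construction, and the test suite asserts it exceeds 0.2 at the default
world size.  Genes
are organised into per-family pools with stronger intra-pool edges over a
sparse random background; each disease draws most of its gene set from
its family pool, giving FSD genuine signal.  The generator does *not*
emulate the heavy-tailed degree distributions of curated databases,
miRNA nomenclature semantics, or ontology multi-parenthood beyond what
the bisection tree produces — passing recovery tests shows the method
recovers planted logistic low-rank structure under these conditions, not
that it attains any particular accuracy on real curated data.

## Numerical and engineering notes

* Similarity identifiers are normalised at read time (trimmed,
  lowercased, "has-mir"/"has-let" unified to "hsa-"); outputs keep the
  normalised form.  Vocabulary order is first-appearance order of the
  association file, which pins embeddings and fold assignments across
  runs.
* Problem sizes in the shipped experiments (100×80 recovery worlds,
  40×30/60×40 in unit and property tests, 5 seeds, 10 folds) were chosen
  so the full suite runs on a single CPU in a few minutes while keeping
  the recovery estimates stable.
* Degenerate inputs fail loudly: all-zero profile sets (undefined kernel
  bandwidth), empty gene/disease sets where a measure is undefined,
  ontology cycles (named node), conflicting duplicate network edges,
  non-finite losses during training (named epoch).
* The pair-list association format cannot represent entities with zero
  associations; a write→read round trip preserves the labelled relation,
  with label order given by first appearance in the file.

## Known limitations

* The fusion layer is additive in the two MLP outputs, so similarity
  features influence pair scores through per-entity terms and through the
  spectral embedding initialisation, not through a learned pairwise
  interaction; the factorisation path carries all learned interaction.
* Negative sampling treats unobserved pairs as negatives; some are true
  associations, which biases probabilities downward (shared by all
  implicit-feedback training).
* Hyperparameters are fixed defaults, not searched; GPU execution and
  multi-type associations are out of scope.
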