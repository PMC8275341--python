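# Methods

## The model

`lupilink` predicts disease–gene associations on a heterogeneous network
with three undirected relations — gene–gene functional similarity,
disease–disease phenotype similarity, and known gene–disease associations
— by learning a low-dimensional embedding per node and scoring a candidate
pair (i, j) with the logistic inner product

    s(i, j) = sigmoid(⟨m_i, m_j⟩).

Embeddings come from a relational graph convolutional encoder. One layer
updates node i as

    h_i' = ReLU( Σ_{r∈R} Σ_{j∈N_i^r} (1/c_ir) W_r h_j + W_0 h_i ),

with a separate weight matrix per relation, mean normalization
c_ir = |N_i^r| (empty neighborhoods contribute nothing), and a linear
final layer so embeddings can take either sign.

The distinguishing component is *learning using privileged information*
(LUPI): a second encoder with the identical architecture (the *dropout
net*) maps training-only privileged features x\* to a per-node variance

    d_i = g( softplus(f_1(x*_i)), …, softplus(f_m(x*_i)) ),    g ∈ {mean, sum, median},

and the training-time embedding is the heteroscedastic Gaussian dropout
sample

    v_i = m_i ⊙ (1 + sqrt(d_i) ε),    ε ~ N(0, I).

Nodes whose privileged features mark them as unreliable receive noisier
embeddings during training, discouraging the decoder from leaning on their
feature content. At evaluation time the dropout net and the privileged
features are never consulted (v = m exactly), which is what allows test
nodes to lack the privileged features entirely.

Training maximizes a variational lower bound: the expected reconstruction
log-likelihood of the gene–disease associations (one uniformly sampled
non-edge per positive, resampled every epoch) minus a KL divergence from
the embedding posterior to a standard-normal prior. The posterior entering
the KL follows the active dropout semantics: variance m²·d (+ floor) for
the default multiplicative reading, or d (+ floor) for the additive
reading. The expectation is estimated with one reparameterized sample per
epoch.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `architecture` | `L2E16` | two layers, 16 units per layer (both nets mirrored) |
| `learning_rate` | 1e-4 | Adam step size |
| `epochs` | 200 | passes over the training pairs |
| `batch_size` | 32 | positive pairs per optimizer step |
| `negative_ratio` | 1 | sampled non-edges per positive |
| `aggregator` | mean | g(·) collapsing dropout-net outputs to one variance |
| `dropout_semantics` | multiplicative | reading of the dropout sample (see above) |
| `variance_floor` | 1e-6 | lower bound on d |
| `kl_weight` | `"auto"` = 1/N | weight of the KL term |
| `standardize` | True | feature standardization inside `fit` |
| `init_scheme` | spectral | similarity-preserving initialization |

Notes on the less obvious choices:

* **KL weight.** The unweighted bound sums the KL over all nodes and
  embedding dimensions, which at desk scale (hundreds of nodes, hundreds
  of training pairs) dwarfs the reconstruction term. The default weights
  the KL by 1/N — per-node averaging, the convention of reference
  variational graph auto-encoder implementations. `kl_weight=1.0` restores
  the literal bound.
* **Epochs and batches.** An epoch is a full pass over the training
  positives in mini-batches of pairs. Message passing is always performed
  on the full training graph — there is no neighborhood sampling; only the
  link-likelihood terms are batched. The KL is distributed across a
  epoch's batches proportionally to batch size.
* **Feature standardization.** Columns of the public features are centered
  and scaled to unit variance using all-node statistics (no edge labels
  are involved); entries that are missing (mask 0) are re-zeroed
  afterwards, preserving the zero-fill convention for missingness.
  Privileged features are centered but divided by a single global scale:
  their whole point is that magnitudes encode per-node measurement
  reliability, and per-column unit-variance scaling would erase exactly
  that structure.
* **Initialization.** With a few hundred training pairs and a fixed small
  step budget, an encoder initialized with random dense weights starts as
  an arbitrary quadratic form over features — embedding inner products
  carry no meaning and the budget goes into undoing the randomness. The
  `spectral` scheme instead starts the encoder as a similarity-preserving
  graph smoother: the first layer's base matrix is the rectifier-transparent
  pairing [Q, −Q] (because relu(a) − relu(−a) = a, a linear readout of xQ
  survives the ReLU), with Q the leading principal directions of the
  standardized features; the last layer pairs a random partial isometry as
  [B; −B]; every relation matrix starts at 0.3× the layer's base plus
  small noise, so message passing begins as neighbor averaging in the same
  coordinate system. At initialization, embedding similarity therefore
  approximates graph-smoothed feature similarity, and training refines
  from there. `glorot` (conventional random init) is available for
  comparison.
* **Model selection.** The weights of the epoch with the best validation
  AUPRC are returned. Validation and test metrics are computed against
  every non-edge when the gene×disease grid has at most 200 000 cells,
  otherwise against the split's sampled negatives.

## Evaluation protocols

Splits operate on canonical undirected edges (lexicographically smaller id
first), so an association and its reversed duplicate can never land in
different partitions. Four regimes: `general` (10-fold 80/10/10),
`new_disease` (held-out diseases keep no association in train/val),
`new_association` (both endpoints held out; edges touching exactly one
held-out endpoint are discarded), `singleton` (the single association of
every gene with full-graph gene–disease degree 1). `leakage_check`
verifies the disjointness and regime invariants structurally. Evaluation-
time message passing uses train+val edges only.

Feature-masking experiments keep a random k% of feature dimensions per
test-scope node (zeroing the rest), and the masking draw is repeated
(ten times in the reference protocol) because a single draw is noisy.

## The synthetic benchmark

The generator plants exactly the structure the decoder family assumes:
each node receives a latent factor z ~ N(0, I_8), and every candidate edge
of relation r appears independently with probability
sigmoid(⟨z_u, z_v⟩ + b_r). The default offsets b_r were solved numerically
for expected densities of ≈3% (gene–disease), ≈2% (gene–gene) and ≈5%
(disease–disease) on the default 200-gene/60-disease graph — desk-scale
analogues of the sparsity ordering of real disease–gene networks. Public
features are a fixed linear readout of the latents plus per-node Gaussian
noise whose scale follows a two-group reliability mixture (70% of nodes at
sd 0.3, 30% at sd 3.0, against a per-feature signal sd of sqrt(8) ≈ 2.8).
Privileged features encode the node's noise scale and group — information
absent from the public features — so the dropout net has a planted reason
to modulate variance. A configurable fraction of genes (default 27.7%,
matching the sparse-feature share reported for real gene feature sets) has
95% of its public feature dimensions zeroed.

Registered fixtures: `tiny` (11 nodes, hand-checkable), `small` (the
200/60 benchmark), `sparse` (50% sparse genes, 40% noisy nodes, 40 public
dims so that 95% zeroing leaves exactly the 5% nonzero boundary).

What the generator does *not* emulate: the degree distributions, feature
correlation structure, and ontology-derived block structure of real
disease–gene networks; features whose informativeness varies by dimension
rather than by node; and any relation between feature sparsity and degree.
Passing the recovery experiments therefore shows that the implementation
optimizes its objective and exploits planted latent structure — not that
the method attains any particular accuracy on real curated networks.

## Numerical choices

* All computation is float64 NumPy/SciPy; gradients are analytic
  (backpropagation written out per layer) and are validated against
  central finite differences (step 1e-4, relative error < 1e-3) in the
  test suite.
* softplus keeps the dropout variance positive; a floor of 1e-6 avoids a
  zero variance, and the KL adds 1e-8 inside the logarithm so nodes with
  m = 0 stay finite under the multiplicative semantics.
* Scores are clipped to (0, 1) exclusive; a log-space scoring path exists
  for strongly negative inner products.
* Ranking ties break by ascending gene id, making prediction tables
  byte-reproducible.
* The median aggregator routes gradients to the middle order statistic(s).

## Known limitations

* Within 200 epochs at learning rate 1e-4, the dropout net's learned
  per-node variance correlates only weakly with the planted reliability
  (the correlation moves from an arbitrary initialization value toward the
  right sign but remains small). The privileged-information advantage at
  this scale comes mostly from learned per-node noise acting as a
  regularizer on the main net; its margin over the plain encoder
  (~+0.01–0.04 AUROC under heavy masking) is real but smaller than
  run-to-run training noise, which is why paired comparisons average over
  training replicates and masking draws.
* Full-graph message passing stores dense normalized adjacencies per
  relation; the implementation targets desk-scale graphs (thousands of
  nodes), not the full genome-scale network.
* Scores are not calibrated to empirical association probabilities.
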