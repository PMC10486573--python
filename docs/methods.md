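# Methods

## The model

`sanepool` predicts the synergy score of a drug pair applied to a cell line
from the pair's *molecular network*: the genes of a curated signaling
interactome plus one node per drug, wired to the drug's target genes.  Gene
node features are `[expression, hit-by-drug-A, hit-by-drug-B]`; drug nodes
carry the constant feature vector (−1, −1, −1), so a drug's identity is
expressed purely through its connectivity.  The same gene receives the same
*global index* in every network (gene names sorted lexicographically, plus
two reserved drug slots), which is what allows edge weights to be shared
across samples.

One pooling layer performs, on representations Z and adjacency A:

1. **Attention features** `H = tanh(D̃⁻¹ Ã Z Θ)` with `Ã = A + I` — one round
   of row-normalised neighbourhood aggregation.
2. **Attention scores** `Att_i = ⟨p, H_i⟩ / (‖p‖₂ ‖H_i‖₂) ∈ [−1, 1]` — cosine
   between a node's attention feature and a trainable projection.  The L2
   norm is the only choice that guarantees the stated [−1, 1] bound.
3. **Top-k selection** of gene nodes (drug nodes are always retained, since
   the readout is defined on them).  Fractional k keeps ⌈k·n_genes⌉ genes;
   ties break toward the smaller global id.
4. **Edge re-weighting** `A′ = A(idx, idx) ∘ W(gids, gids)` with a trainable
   symmetric matrix W over the global vocabulary (W is stored dense and
   symmetrised as (W + Wᵀ)/2 at every use; initialised to all-ones so the
   untrained layer is plain induced-subgraph pooling).  An optional
   pairwise-MLP mode scores each edge as `relu(MLP(H_i ∥ H_j))` instead; it
   materialises all n² pairs and is therefore capped at a configurable node
   count.
5. **Edge filtering** keeps the ⌈f·E⌉ undirected edges of largest absolute
   weight (default f = 0.9), zeroing the rest symmetrically.

The full model stacks `[pool → graph convolution]` blocks (two of each by
default), so the *first* selection acts directly on the raw 3-dimensional
features and all information reaching the readout must pass through the
retained genes — this is what makes the pooling trace interpretable rather
than decorative.  The final representations u₁, u₂ of the two drug nodes
feed the factorisation readout `score = u₁ᵀ Dᵀ D u₂`, symmetric in the two
drugs; single-drug cohorts use a two-layer MLP head on the lone drug
embedding instead.

After selection, kept gene rows are multiplied by `(1 + Att)/2 ∈ [0, 1]`
(drug rows pass unchanged).  This gating is what routes loss gradient into
the attention parameters p and Θ — plain index slicing would leave them
without any training signal because top-k itself is not differentiable.
The gate is a *positive monotone* map of the score rather than the signed
score itself: with a signed gate the model can park informative genes at
Att ≈ −1 (a harmless sign flip of their features), which decouples
"informative" from "selected" and muddles the interpretability of the
retained gene sets.

### Invariances

The score is invariant to node permutation (all operations are
permutation-equivariant and the readout reads named drug nodes), and
invariant to drug relabelling under the documented swap contract: swapping
the two indicator feature columns together with the two drug slots of every
W.  Two implementation details are required for the latter to hold exactly:
the first-layer weights of the two indicator columns are tied, and W is
always symmetrised.  With all-ones (tied) edge weights, the edge filter
breaks ties by global-id pair, which is not symmetric under slot renaming —
the invariance is exact for generic (distinct-weight) W, which is what the
tests use.

### Numerical choices

- Attention-feature activation is tanh (bounded features stabilise the
  cosine); representation activations are leaky rectifiers with slope 0.1 —
  in narrow graph networks a hard rectifier repeatedly collapsed entire
  layers to zero mid-training, a failure mode the leaky slope removes.
- Degrees inside the model use |Ã| row sums so trained (possibly negative)
  edge weights cannot drive the normaliser through zero; for binary inputs
  this equals the textbook rule.
- Attention rows with norm below 1e−12 score 0 (the neutral cosine).
- Attention weights and projections are initialised *non-negative*, so that
  before training a node's score increases with its expression and
  drug-target indicators.  This encodes the model's own premise — targeted,
  transcriptionally active genes are the prior candidates for driving
  synergy — and breaks the sign symmetry of the cosine, under which
  "select the informative genes" and "discard the informative genes" are
  equally good optima of the prediction loss.
- `edge_filter` takes the edge budget E as an explicit parameter (defaulting
  to the current edge count).  Keeping the budget explicit makes re-applying
  the filter a no-op and keeps "90% of the layer's edges" well defined; a
  self-referential budget would shave a further 10% on every application.

## Training and evaluation

Training minimises MSE on raw synergy scores with Adam (default peak
learning rate 5e−3, cosine-annealed to 10%, batch size 4, 100 epochs).  The
small batch size is deliberate: the factorisation readout needs the four
background-drug embeddings to spread into mutually obtuse directions to
express negative scores, and larger batches average away the asymmetric
updates that drive that separation.

Evaluation is 5-fold cross-validation, by default *inductive*: all samples
sharing an unordered drug pair land in one fold, so tested combinations are
never seen in training.  Folds are seeded and deal shuffled groups
round-robin, giving group counts that differ by at most one.  Metrics are
Pearson r and MSE/RMSE, reported per fold and as mean ± s.d.

## Interpretability statistics

"Used by the model" means: present in the final pooled layer's gene set —
the genes actually feeding the readout.  Per cell line, a gene's synergic
(non-synergic) importance is the fraction of samples with synergy > 0
(< 0) whose final gene set contains it; samples with synergy exactly 0 are
excluded.  A two-sample Kolmogorov–Smirnov test (asymptotic p-values, no
small-sample enumeration) compares the per-cell-line importance
distributions, and genes with synergic − non-synergic difference strictly
above a threshold (default 0.1) form the core sub-network together with
their induced interactions.  Importance can be computed from a single model
over all samples or from held-out predictions collected during
cross-validation.

## The synthetic cohort

The generator emulates the structure of the drug-combination benchmarks:
a scale-free gene–gene network (preferential attachment; signaling
interactomes are heavy-tailed), per-cell-line expression, drug–target
links, and real-valued synergy labels.  Causality is planted: a connected
gene module (internal edges densified to ~50%) drives synergy via

    synergy = effect·[both drugs hit module AND module active in cell]
            − effect·[neither drug hits module] + N(0, noise_sd)

Module drugs draw all their targets from the module, background drugs from
the rest; the module is transcriptionally active (expression shifted by
+1.5) in 3 of the 4 desk cell lines.  Defaults (the *desk preset*):
150 genes, 8 drugs (4 module / 4 background), 4 cell lines, 8 targets per
drug, module size 30, effect 2.0, noise s.d. 0.5.  The *paper preset*
mirrors the published cohort dimensions (1364 genes, 21 drugs, edge density
chosen to give ≈25k edges).  A fixed seed makes the emitted files
byte-identical across runs.

The module size and pure-module targeting were chosen by a
model-independent representability analysis: an oracle that selects exactly
the causal genes was used to verify that the planted phenomenon (higher
synergic importance on module genes; distributional separation between the
importance profiles) is actually present in the generated cohorts.  At 150
genes the K-S phenomenon is only marginally representable even for the
oracle — see Limitations.

What the generator does **not** emulate: dose–response surfaces, assay
noise structure, gene–gene correlation beyond the module shift, drug
chemistry, and the hundreds of cell lines of real screens.  Passing tests
on this cohort demonstrate that the machinery recovers a planted signal at
desk scale, not that the model attains its published accuracy on real
screens.

## Problem sizes

The default test-and-acceptance workload trains one model on the desk
cohort (112 samples of 152-node graphs, hidden width 64, k schedule
60 → 30, 100 epochs, ≈1 minute on one core) and runs a single forward pass
at the published network scale (1364 genes + 2 drugs, k 400 → 200) to check
the pooling arithmetic.

## Known limitations

- The K-S separation between synergic and non-synergic importance profiles
  is statistically underpowered at desk scale: with 150 genes the 0.05
  critical distance for the two-sample statistic is ≈0.157, versus ≈0.05 at
  the published 1364-gene scale.  Oracle selection on the desk cohort
  yields D ≈ 0.05–0.19 — mostly below the critical value — because the
  randomly-signed mixed drug pairs contribute identical selection patterns
  to both classes and dilute any distributional difference.  The trained
  model's D values sit in the same range, i.e. near the ceiling of what any
  detector could show at this scale.
- Which optimisation basin the attention lands in (select-module vs
  discard-module) remains seed-sensitive despite the non-negative
  initialisation; importance summaries from a single short training run
  should be treated as noisy.
- The dense N×N global weight matrices are memory-hungry beyond ~10⁴ genes;
  the pairwise-MLP edge mode is quadratic in nodes and capped accordingly.
- Asymptotic K-S p-values are anti-conservative for very small gene sets.
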