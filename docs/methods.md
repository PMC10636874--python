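# Methods

## Model

`lncgo` treats lncRNA function prediction as annotation transfer on a
heterogeneous molecular network.  The premise is guilt by association:
physically interacting or co-expressed molecules tend to share function,
so a network that connects lncRNAs, proteins and miRNAs lets curated
protein GO annotations reach the unannotated lncRNAs.  The pipeline has
four stages — network assembly, diffusion-based feature extraction,
autoencoder compression, and per-term classification — followed by a
CAFA-style evaluation.

### Network assembly

The global network G is a symmetric nonnegative block matrix over the
fixed node order lncRNA → protein → miRNA, built from three intra-kind
similarity networks (L, P, M) and three inter-kind association networks
(LP, LM, PM); each off-diagonal block is mirrored by its transpose.
Conventions:

- Co-expression similarity is the Pearson correlation of expression
  rows.  Pairs with PCC ≤ 0 are dropped by default (configurable):
  G must be nonnegative for the walk probabilities to be well formed,
  and anti-correlation is weak evidence of shared function.
- Diagonals of L, P, M are zero.  Self-loops would only inflate the
  restart mass of the walk.
- Multi-source lncRNA–protein correlation scores are fused with the
  noisy-OR rule S = 1 − Π(1 − Sₙ) over the positive source scores; a
  pair whose scores are all non-positive is absent.  The fused score is
  monotone in each source and dominates the best single source.
- Curated interaction lists are binarized to weight 1.  When a pair has
  both a fused co-expression score and a binary interaction, the merge
  takes the maximum: both are confidence-like in [0, 1] and an
  experimentally verified interaction (score 1) should not be diluted.
- Edge lists are undirected; duplicate (a,b)/(b,a) records must agree in
  weight within 1e−9 or the load fails loudly.
- Component networks are stored sparsely; dense materialization is
  refused above 5000 nodes.

### Diffusion state and PPMI

The transition matrix divides each entry of G by the weighted degree of
the source node, A[i,j] = G[i,j] / Σ_k G[k,i].  For a symmetric G that
normalizer is simultaneously the row and the column sum of node i; the
resulting A is stochastic along rows, so every diffusion-state row is a
probability distribution.  Isolated nodes get a unit self-probability,
which keeps A stochastic without coupling them to anything.

The restart walk iterates P_k = α·P_{k−1}·A + (1−α)·P₀ with P₀ = I.
Note the parameterization: α multiplies the walk term, so 1−α is the
restart weight; at the operating point α = 0.5 the two readings
coincide.  Defaults: α = 0.5, convergence when the largest per-row L1
change falls below 1e−6, at most 100 iterations.  The iteration
contracts at rate α, so the fixed point (1−α)·P₀·(I−αA)⁻¹ is reached
quickly for moderate α; the implementation is checked against that
closed form in the tests.  Two state modes exist: `converged` (the
plateau distribution, the default) and `accumulated` (the sum of the
per-step matrices, the construction some network-embedding stacks use);
which to prefer is an open modeling choice, so both are first-class.

PPMI re-weights the diffusion state entrywise:
X[i,j] = max(0, log(P[i,j]·ΣP / (r_i·c_j))) with row/column marginals r
and c.  This damps hub rows/columns that dominate raw diffusion mass.
Zeros of P map to zeros of X, and X is invariant to positive scaling of
P.  Natural log by default; the log base only rescales X and never
changes its zero set.

### Stacked denoising autoencoder

PPMI rows are one-per-node and n-dimensional, so they are compressed
with a stack of denoising autoencoders trained greedily: stage k maps
the layer-(k−1) representation to width M[k] by minimizing the squared
reconstruction error of the *clean* input from a *corrupted* copy
(masking noise: entries independently zeroed).  Hidden activations are
logistic sigmoids; the reconstruction output is linear, which pairs
naturally with the squared loss on unbounded PPMI values.  Optimization
is minibatch Adam.  Defaults: corruption 0.2, 100 epochs per stage,
learning rate 1e−3, batch 32.  An optional end-to-end fine-tuning pass
through the whole stack exists and is off by default; optional
per-column min-max input scaling is available because sigmoid
saturation on large PPMI values is a real risk on some inputs.

The published full-scale layer configuration
[36863, 10000, 3000, 1000, 512] is representable but never exercised
here; tests and the bundled experiments use reduced widths (input,
48, 16) matching their ~100-node networks.  All randomness (init,
shuffling, masks) derives from the configured seed, making embeddings
bit-reproducible.

### Per-term SVM transfer

Proteins whose only annotations carry the IEA evidence code are removed:
IEA is the one GO evidence code never assigned by a curator, and
training on it would teach the classifier the electronic pipeline rather
than the biology.  A protein with at least one manual code keeps all its
records.  Optional true-path propagation (annotating each protein to all
is_a/part_of ancestors of its terms) is provided but off by default.

For each GO term with at least `min_positives` (default 10) annotated
proteins, the training set is all positives plus an equal-size uniform
sample (without replacement) of embedded, un-annotated proteins.
Classifier: RBF-kernel SVM, C = 1, kernel width by the median heuristic
(γ = 1 / median squared pairwise distance of the training features),
with Platt sigmoid calibration on internal cross-validation folds so
every emitted score is a probability in [0, 1].  lncRNAs never enter any
training set; they are only ever scored.

### Fmax evaluation

At threshold t, lncRNA i predicts P_i(t) = {terms with score ≥ t}
("greater than or equal", so boundary scores are included).  Per-gene
precision |P∩T|/|P| is undefined on an empty prediction set, which is
exactly why the protocol averages precision only over the m(t) lncRNAs
with at least one score ≥ t, while recall |P∩T|/|T| averages over all N
evaluated lncRNAs with empty predictions contributing 0.  Fmax scans a
grid of 101 evenly spaced thresholds (configurable); thresholds with
m(t) = 0 are excluded, ties resolve to the lowest threshold, and
F = 0 where Pr + Rc = 0.  Truth and predictions are compared as flat
term sets — no ontology-aware partial credit.  "Coverage" counts
lncRNAs with ≥ 1 true-positive term at the Fmax threshold; the
threshold is exposed because the criterion is a convention, not a
derivation.  A permuted-truth baseline (mean Fmax after randomly
re-assigning the truth sets among the evaluated lncRNAs) estimates the
chance level implied by the term frequencies.

## Synthetic data

The generator plants a partition: each entity belongs to one of g
groups, and every component network draws an edge with probability p_in
within groups and p_out between (weights 0.5 + Gaussian noise of scale
0.1, clipped to (0, 1]; an NPinter-like binary mode exists for LP).
Each group owns `terms_per_group` GO terms; all proteins are annotated
with their group's terms (evidence EXP), and a held-out fraction
(default 50%) of lncRNAs contribute their group terms to the truth set.
Every group is guaranteed at least one lncRNA and one protein.

Defaults (30 lncRNAs, 60 proteins, 10 miRNAs, 3 groups, p_in = 0.3,
p_out = 0.02) give a ~100-node network with clear but noisy modular
structure — small enough that the whole pipeline runs in seconds, large
enough that each group's diffusion profile is identifiable.  What the
generator does **not** emulate: heavy-tailed degree distributions,
hierarchical and power-law-frequency GO terms, mixed evidence codes,
or inter-source inconsistency.  Passing tests therefore demonstrate
that the machinery is correct and recovers planted signal under the
stated noise model, not that any particular Fmax will be reached on
real annotation corpora.

## Numerical and design choices

- One global seed; each stochastic stage mixes the stage name (CRC32)
  into its own sub-seed, so toggling one stage (e.g. the miRNA
  ablation) leaves the other stages' randomness untouched.  Per-term
  negative-sampling seeds additionally mix the term id.
- The miRNA ablation removes the miRNA rows/columns from the assembled
  G by slicing, guaranteeing the remaining blocks are bit-identical to
  the full network's.
- Degenerate inputs fail loudly: zero-variance expression rows (PCC
  undefined), all-zero matrices into PPMI, all-identical feature rows
  into the SVM, non-finite autoencoder losses (cited with stage and
  epoch), cyclic ontologies, malformed edge lines (cited with line
  number), unknown ids (all listed).
- Isolated nodes are handled, not rejected, at the transition-matrix
  stage; an all-isolated graph still yields the identity walk.

## Limitations

- The SDAE is a plain NumPy implementation tuned for the package's
  problem sizes (thousands of nodes); the full-scale published widths
  would require a GPU framework and are out of scope here.
- No ontology-aware evaluation (Smin, weighted Fmax, partial credit)
  and no term-hierarchy-aware training; terms are independent
  classifiers.
- Upstream data curation (sequence clustering of redundant proteins,
  source-database parsing) is assumed done; the package consumes
  pre-extracted ID lists, edge lists and annotation tables.
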