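# lncgo

Predicting Gene Ontology (GO) functions for long non-coding RNAs
(lncRNAs) by annotation transfer over a global heterogeneous network.

Most lncRNAs have no experimentally characterized function, while
protein-coding genes are densely annotated with GO terms.  `lncgo`
exploits guilt by association: molecules that interact or are
co-expressed tend to share function, so annotations can flow from
proteins to lncRNAs through a network that connects them.

## Method

1. **Global network.** Six component networks — lncRNA co-expression
   similarities *L*, protein–protein interactions *P*, miRNA
   co-expression *M*, and the bipartite associations *LP*, *LM*, *PM* —
   are assembled into one symmetric nonnegative block matrix

   ```
       [ L    LP   LM ]
   G = [ LPᵀ  P    PM ]
       [ LMᵀ  PMᵀ  M  ]
   ```

   Co-expression similarities are Pearson correlations (negative values
   dropped); multi-source lncRNA–protein correlations are fused with the
   noisy-OR rule S = 1 − Π(1 − Sₙ) over the positive source scores, and
   curated interactions are binarized to 1.

2. **Diffusion features.** A random walk with restart
   P_k = α·P_{k−1}·A + (1−α)·P₀ (restart probability at the operating
   point α = 0.5, A the degree-normalized transition matrix, P₀ = I) is
   iterated to its plateau, the *diffusion state*; it is re-weighted
   entrywise into a positive pointwise mutual information (PPMI)
   matrix, X_ij = max(0, log(P_ij·ΣP / (r_i·c_j))).

3. **Embedding.** A stacked denoising autoencoder (greedy layer-wise
   training, masking noise, squared reconstruction loss) compresses each
   node's PPMI row; the bottleneck layer is the node's feature vector.

4. **Annotation transfer.** For every GO term with enough curated
   protein annotations (IEA-only proteins removed), a balanced training
   set is drawn — all annotated proteins as positives, an equal-size
   random sample of un-annotated proteins as negatives — and an RBF-SVM
   with Platt-calibrated probabilities is fitted on the protein
   embeddings, then applied to the lncRNA embeddings.

5. **Evaluation.** The CAFA-style Fmax protocol: per-lncRNA precision
   and recall at each threshold t, precision averaged over the m(t)
   lncRNAs with at least one score ≥ t, recall averaged over all N
   evaluated lncRNAs, and Fmax = max_t 2·Pr(t)·Rc(t)/(Pr(t)+Rc(t)).

A seeded synthetic-data generator plants group structure (entities in
the same function group connect with probability p_in, others with
p_out, and groups own disjoint GO term sets) so the whole pipeline can
be exercised and falsified without any external downloads.

## Worked example

`examples/` contains one narrative script per capability.  The full
pipeline on a planted-structure bundle
(`python examples/04_full_pipeline.py`) prints:

```
bundle: 100 nodes, 180 protein annotations, 15 held-out lncRNAs
  build     {'nodes': 100, 'edges': 569}
  diffuse   {'n_iter': 15, 'converged': True}
  embed     {'dim': 16, 'final_loss': 0.048794414701884926}
  train     {'terms_modeled': 9, 'proteins': 60}
  predict   {'lncrnas_scored': 30}
  evaluate  {'n_test': 15}
pipeline Fmax          = 1.000
permuted-truth baseline = 0.520
gap                     = 0.480
```

The pipeline recovers every held-out lncRNA's planted GO terms
(Fmax = 1.0), while randomly re-assigning the truth sets among the
lncRNAs caps Fmax at the chance level 0.52 implied by the three-group
term frequencies; the 0.48 gap is the recovered signal.  The same run is
available from the shell:

```bash
lncgo simulate --out-dir bundle --seed 7
lncgo run-all --bundle-dir bundle --out-dir run --seed 7
```

and per-stage subcommands (`build-network`, `diffuse`, `embed`, `train`,
`predict`, `evaluate`) expose each intermediate artifact as MTX/TSV.

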