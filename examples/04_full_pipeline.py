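"""Run the whole pipeline on a synthetic planted-module bundle.

Thirty lncRNAs, sixty proteins and ten miRNAs fall into three function
groups; edges are dense within groups and sparse between them.  The
pipeline embeds the network (restart walk -> PPMI -> denoising autoencoder),
trains one SVM per GO term on the proteins, scores the lncRNAs and
evaluates Fmax on the held-out lncRNA truth set.  The permuted-truth
baseline shows the chance level the signal has to clear.
"""

from lncgo import (PipelineConfig, SynthConfig, generate,
                   permutation_baseline, run_pipeline)

bundle = generate(SynthConfig(n_l=30, n_p=60, n_m=10, g=3,
                              p_in=0.3, p_out=0.02, seed=7))
print(f"bundle: {bundle.index.n_total} nodes, "
      f"{len(bundle.annotations)} protein annotations, "
      f"{bundle.truth.n_test} held-out lncRNAs")

manifest = run_pipeline(PipelineConfig(hidden_widths=(48, 16), seed=7),
                        bundle=bundle)
for stage, info in manifest.stages.items():
    counts = {k: v for k, v in info.items() if k != "seconds"}
    print(f"  {stage:9s} {counts}")

baseline = permutation_baseline(manifest.predictions, bundle.truth,
                                n_permutations=20, seed=7)
print(f"pipeline Fmax          = {manifest.summary['fmax']:.3f}")
print(f"permuted-truth baseline = {baseline:.3f}")
print(f"gap                     = {manifest.summary['fmax'] - baseline:.3f}")
print("a large gap means the pipeline recovered the planted group structure,"
      "\nnot just the truth-set term frequencies")
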