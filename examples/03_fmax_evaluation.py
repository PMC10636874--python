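"""Evaluate a small prediction matrix with the Fmax protocol.

Precision at each threshold is averaged only over the m(t) lncRNAs that
still predict something; recall is averaged over all N evaluated lncRNAs.
Fmax is the best harmonic mean of the two along the threshold grid.
"""

import numpy as np
import pandas as pd

from lncgo import TruthSet, evaluate_predictions

scores = pd.DataFrame(
    {"GO:0000001": [0.9, 0.4, 0.2],
     "GO:0000002": [0.3, 0.8, 0.1],
     "GO:0000003": [0.1, 0.2, 0.7]},
    index=["lncA", "lncB", "lncC"])
truth = TruthSet({"lncA": {"GO:0000001"},
                  "lncB": {"GO:0000002", "GO:0000003"},
                  "lncC": {"GO:0000003"}})

summary, curve = evaluate_predictions(scores, truth)
print(f"Fmax      = {summary.fmax:.3f} at threshold t* = {summary.t_star:.2f}")
print(f"precision = {summary.precision:.3f} (mean over the m(t*) lncRNAs"
      " that predict something)")
print(f"recall    = {summary.recall:.3f} (mean over all N = "
      f"{truth.n_test} lncRNAs)")
print(f"coverage  = {summary.coverage} of {truth.n_test} lncRNAs get"
      " at least one correct term at t*")

mask = ~np.isnan(curve.precision)
print("\nthreshold  m  precision  recall")
for t, m, p, r in zip(curve.thresholds[mask][::20], curve.m[mask][::20],
                      curve.precision[mask][::20], curve.recall[mask][::20]):
    print(f"  {t:.2f}     {m}    {p:.3f}     {r:.3f}")
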