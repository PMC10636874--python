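"""CAFA-style evaluation of lncRNA function predictions.

For a score threshold t, the prediction set of lncRNA i is
P_i(t) = {terms with score >= t} and its truth set is T_i (manually curated
GO terms).  Per-gene precision and recall are set overlaps:

    Pr_i(t) = |P_i(t) & T_i| / |P_i(t)|       Rc_i(t) = |P_i(t) & T_i| / |T_i|

Averaging follows the m(t)/N convention: precision is averaged only over the
m(t) lncRNAs that have at least one score >= t (per-gene precision is
undefined on an empty prediction set), while recall is averaged over all N
evaluated lncRNAs, an empty prediction set contributing 0.  Fmax is the
maximum over thresholds of the harmonic mean of the two averages; "coverage"
counts the lncRNAs with at least one correctly predicted term at the Fmax
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class TruthSet:
    """Experimentally verified GO term sets per lncRNA; every set nonempty."""

    terms_by_gene: dict[str, set[str]]

    def __post_init__(self):
        self.terms_by_gene = {g: set(t) for g, t in self.terms_by_gene.items()}
        empty = [g for g, t in self.terms_by_gene.items() if not t]
        if empty:
            raise ValueError(f"empty truth set for lncRNAs: {sorted(empty)}")

    @property
    def n_test(self) -> int:
        return len(self.terms_by_gene)

    def genes(self) -> list[str]:
        return sorted(self.terms_by_gene)


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray  # NaN where m(t) == 0
    recall: np.ndarray
    m: np.ndarray


@dataclass
class EvaluationSummary:
    fmax: float
    t_star: float
    precision: float
    recall: float
    coverage: int | None = None


def default_grid(n: int = 101) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def per_gene_pr(predicted: set[str], truth: set[str]) -> tuple[float | None, float]:
    """Per-gene precision and recall at one threshold.

    Precision is None (undefined) when the prediction set is empty; an empty
    truth set is an error.
    """
    if not truth:
        raise ValueError("truth set must be nonempty")
    tp = len(predicted & truth)
    recall = tp / len(truth)
    if not predicted:
        return None, recall
    return tp / len(predicted), recall


def _predicted_sets(predictions: pd.DataFrame, gene: str, t: float) -> set[str]:
    if gene not in predictions.index:
        return set()
    row = predictions.loc[gene]
    return set(row.index[row.to_numpy(dtype=float) >= t])


def pr_curve(predictions: pd.DataFrame, truth: TruthSet,
             grid: np.ndarray | None = None) -> PRCurve:
    """Averaged precision/recall over a threshold grid.

    ``predictions`` is an (lncRNA x term) score matrix; rows missing for a
    truth lncRNA count as empty prediction sets.  Scores exactly equal to
    the threshold are included ("greater than or equal").
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > 1):
        raise ValueError("threshold grid values must lie in [0, 1]")
    genes = truth.genes()
    n = truth.n_test
    prec = np.full(grid.shape, np.nan)
    rec = np.zeros(grid.shape)
    m = np.zeros(grid.shape, dtype=int)
    for k, t in enumerate(grid):
        prec_sum, m_t, rec_sum = 0.0, 0, 0.0
        for g in genes:
            p_set = _predicted_sets(predictions, g, t)
            p_i, r_i = per_gene_pr(p_set, truth.terms_by_gene[g])
            rec_sum += r_i
            if p_i is not None:
                prec_sum += p_i
                m_t += 1
        m[k] = m_t
        rec[k] = rec_sum / n
        if m_t > 0:
            prec[k] = prec_sum / m_t
    return PRCurve(thresholds=grid, precision=prec, recall=rec, m=m)


def fmax(curve: PRCurve) -> EvaluationSummary:
    """Maximum harmonic mean of averaged precision and recall over the grid.

    Thresholds where precision is undefined (m(t) = 0) are excluded; ties
    resolve to the lowest threshold.  F is 0 where Pr + Rc = 0.
    """
    defined = ~np.isnan(curve.precision)
    if not defined.any():
        raise ValueError("no threshold with defined precision")
    pr = curve.precision[defined]
    rc = curve.recall[defined]
    ts = curve.thresholds[defined]
    denom = pr + rc
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, 2.0 * pr * rc / np.where(denom > 0, denom, 1.0), 0.0)
    best = int(np.argmax(f))
    return EvaluationSummary(fmax=float(f[best]), t_star=float(ts[best]),
                             precision=float(pr[best]), recall=float(rc[best]))


def count_correct(predictions: pd.DataFrame, truth: TruthSet, t: float) -> int:
    """Number of lncRNAs with at least one true-positive term at threshold t."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return sum(
        1 for g in truth.genes()
        if _predicted_sets(predictions, g, t) & truth.terms_by_gene[g])


def evaluate_predictions(predictions: pd.DataFrame, truth: TruthSet,
                         grid: np.ndarray | None = None
                         ) -> tuple[EvaluationSummary, PRCurve]:
    """Full protocol: PR curve, Fmax, and coverage at the Fmax threshold."""
    curve = pr_curve(predictions, truth, grid)
    summary = fmax(curve)
    summary.coverage = count_correct(predictions, truth, summary.t_star)
    return summary, curve


def permutation_baseline(predictions: pd.DataFrame, truth: TruthSet,
                         n_permutations: int = 20, seed: int = 0,
                         grid: np.ndarray | None = None) -> float:
    """Chance-level Fmax: mean Fmax after randomly re-assigning the truth
    sets among the evaluated lncRNAs (scores untouched)."""
    rng = np.random.default_rng(seed)
    genes = truth.genes()
    vals = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(genes))
        shuffled = TruthSet({genes[i]: truth.terms_by_gene[genes[int(j)]]
                             for i, j in enumerate(perm)})
        summary, _ = evaluate_predictions(predictions, shuffled, grid)
        vals.append(summary.fmax)
    return float(np.mean(vals))
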