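"""Annotation transfer: per-GO-term SVMs trained on protein embeddings.

Proteins carry curated GO annotations; lncRNAs do not.  Because all nodes
share the embedding space learned from the global network, a classifier
trained to recognize proteins annotated to a GO term can score lncRNAs for
that same term (guilt by association).  For each modeled term, positives are
the annotated proteins and negatives are an equal-size uniform sample of
un-annotated proteins; an RBF support-vector machine with Platt-calibrated
probability output gives scores in [0, 1].

Proteins whose only annotations carry the IEA evidence code ("inferred from
electronic annotation" — the one GO code never assigned by a curator) are
removed before training.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import pairwise_distances
from sklearn.svm import SVC

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationTable:
    """Records of (protein id, GO term, evidence code).

    Exact duplicate records are dropped on construction; malformed GO ids
    raise.
    """

    records: pd.DataFrame

    COLUMNS = ("protein_id", "go_term", "evidence")

    def __post_init__(self):
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        bad = [t for t in df["go_term"].unique() if not _GO_RE.match(str(t))]
        if bad:
            raise ValueError(f"malformed GO term ids: {sorted(bad)[:10]}")
        self.records = df.drop_duplicates(ignore_index=True)

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str]]) -> "AnnotationTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def proteins(self) -> list[str]:
        return sorted(self.records["protein_id"].unique())

    def terms(self) -> list[str]:
        return sorted(self.records["go_term"].unique())

    def annotated_to(self, term: str) -> set[str]:
        return set(self.records.loc[self.records["go_term"] == term, "protein_id"])

    def __len__(self) -> int:
        return len(self.records)


def filter_non_iea(table: AnnotationTable) -> AnnotationTable:
    """Drop proteins that lack any manually assigned (non-IEA) annotation.

    A protein with at least one non-IEA record keeps *all* of its records,
    including the IEA ones.
    """
    df = table.records
    if df.empty:
        return AnnotationTable(df.copy())
    has_manual = df.groupby("protein_id")["evidence"].transform(
        lambda ev: (ev != "IEA").any())
    return AnnotationTable(df[has_manual].reset_index(drop=True))


def propagate_annotations(table: AnnotationTable, ontology: nx.DiGraph | None,
                          enabled: bool = False) -> AnnotationTable:
    """True-path propagation: annotate each protein to all ancestors of its
    terms along is_a/part_of edges (child -> parent orientation).

    Disabled by default, leaving the table unchanged.  Propagated records
    inherit the evidence code of the record they came from.
    """
    if not enabled:
        return table
    if ontology is None:
        raise ValueError("propagation enabled but no ontology provided")
    if not nx.is_directed_acyclic_graph(ontology):
        raise ValueError("ontology graph contains a cycle")
    rows = []
    for protein, term, ev in table.records.itertuples(index=False):
        rows.append((protein, term, ev))
        if term in ontology:
            for anc in nx.descendants(ontology, term):  # child->parent edges
                rows.append((protein, anc, ev))
    return AnnotationTable.from_records(rows)


@dataclass
class TermTrainingSet:
    term: str
    positives: list[str]
    negatives: list[str]
    X: np.ndarray
    y: np.ndarray
    seed: int

    def __post_init__(self):
        if len(self.positives) != len(self.negatives):
            raise ValueError("training set must be class-balanced")
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")


def build_term_training_set(term: str, table: AnnotationTable,
                            embeddings: pd.DataFrame, seed: int,
                            min_positives: int = 10) -> TermTrainingSet | None:
    """Balanced training set for one GO term, or None when the term is skipped.

    Positives are the proteins annotated to the term; negatives are drawn
    uniformly without replacement, in equal number, from embedded proteins
    not annotated to it.  Returns None when there are fewer than
    ``min_positives`` positives or not enough negative candidates.
    """
    positives = sorted(table.annotated_to(term))
    missing = [p for p in positives if p not in embeddings.index]
    if missing:
        raise ValueError(f"no embedding for annotated proteins: {missing[:10]}")
    if len(positives) < min_positives:
        return None
    pool = sorted(set(embeddings.index) - set(positives))
    if len(pool) < len(positives):
        return None
    rng = np.random.default_rng(seed)
    negatives = sorted(rng.choice(pool, size=len(positives), replace=False))
    ids = positives + list(negatives)
    X = embeddings.loc[ids].to_numpy(dtype=float)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    return TermTrainingSet(term=term, positives=positives, negatives=list(negatives),
                           X=X, y=y, seed=seed)


@dataclass
class SVMConfig:
    C: float = 1.0
    gamma: float | None = None  # None -> median heuristic
    seed: int = 0


@dataclass
class TermClassifier:
    term: str
    model: CalibratedClassifierCV
    n_positives: int
    n_features: int
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        pos_col = int(np.flatnonzero(self.model.classes_ == 1)[0])
        return self.model.predict_proba(X)[:, pos_col]


def _median_gamma(X: np.ndarray) -> float:
    """RBF width by the median heuristic: gamma = 1 / median squared
    pairwise distance (falls back to 1/d on degenerate geometry)."""
    d2 = pairwise_distances(X, metric="sqeuclidean")
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0 or not np.isfinite(med):
        return 1.0 / X.shape[1]
    return 1.0 / med


def train_term_classifier(ts: TermTrainingSet,
                          config: SVMConfig | None = None) -> TermClassifier:
    """Fit the calibrated RBF-SVM for one term.

    Probability calibration is Platt sigmoid fitting on internal
    cross-validation folds, so emitted scores are always in [0, 1].
    """
    config = config or SVMConfig()
    if not np.all(np.isfinite(ts.X)):
        raise ValueError(f"non-finite features in training set for {ts.term}")
    if np.allclose(ts.X, ts.X[0]):
        raise ValueError(f"degenerate features for {ts.term}: all rows identical")
    gamma = config.gamma if config.gamma is not None else _median_gamma(ts.X)
    svm = SVC(kernel="rbf", C=config.C, gamma=gamma, random_state=config.seed)
    cv = max(2, min(5, len(ts.positives)))
    model = CalibratedClassifierCV(svm, method="sigmoid", cv=cv, ensemble=False)
    model.fit(ts.X, ts.y)
    return TermClassifier(term=ts.term, model=model,
                          n_positives=len(ts.positives),
                          n_features=ts.X.shape[1], seed=config.seed)


def train_term_classifiers(table: AnnotationTable, embeddings: pd.DataFrame,
                           seed: int = 0, min_positives: int = 10,
                           config: SVMConfig | None = None) -> list[TermClassifier]:
    """Train one classifier per modeled GO term (terms with too few positives
    or candidates are skipped).  Per-term sampling seeds derive from the
    global seed and the term id so term sets are independent of each other."""
    classifiers = []
    for term in table.terms():
        term_seed = (seed * 1000003 + hash_term(term)) % (2 ** 31)
        ts = build_term_training_set(term, table, embeddings, seed=term_seed,
                                     min_positives=min_positives)
        if ts is None:
            continue
        cfg = SVMConfig(**{**(config.__dict__ if config else {}), "seed": term_seed}) \
            if config else SVMConfig(seed=term_seed)
        classifiers.append(train_term_classifier(ts, cfg))
    return classifiers


def hash_term(term: str) -> int:
    """Stable (process-independent) small hash of a GO term id."""
    import zlib
    return zlib.crc32(term.encode()) % (2 ** 31)


def predict_lncrna_functions(classifiers: Iterable[TermClassifier],
                             lncrna_embeddings: pd.DataFrame) -> pd.DataFrame:
    """Score every lncRNA for every modeled term.

    Returns a (lncRNA x term) DataFrame of calibrated scores in [0, 1];
    with no trained classifiers the matrix is empty.
    """
    classifiers = list(classifiers)
    X = lncrna_embeddings.to_numpy(dtype=float)
    out = pd.DataFrame(index=lncrna_embeddings.index.copy())
    for clf in classifiers:
        if X.shape[1] != clf.n_features:
            raise ValueError(
                f"embedding width {X.shape[1]} does not match training width "
                f"{clf.n_features}")
        out[clf.term] = clf.predict_proba(X) if len(X) else np.zeros(0)
    return out
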