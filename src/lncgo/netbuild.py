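"""Construction of the global heterogeneous lncRNA–protein–miRNA network.

The global network is a symmetric nonnegative block matrix over three node
kinds, assembled from six component networks: three intra-kind similarity
networks (lncRNA co-expression ``L``, protein–protein interactions ``P``,
miRNA co-expression ``M``) and three inter-kind association networks
(``LP``, ``LM``, ``PM``)::

        [ L    LP   LM ]
    G = [ LP'  P    PM ]
        [ LM'  PM'  M  ]

Similarity weights are confidence-like scores in (0, 1]; associations from
interaction databases are binarized to 1.  Co-expression similarities from
several sources are fused with a noisy-OR rule over the positive scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

KINDS = ("lncrna", "protein", "mirna")

#: duplicate undirected edge records must agree in weight to this tolerance
DUPLICATE_WEIGHT_TOL = 1e-9

#: below this node count matrices may be materialized dense
DENSE_THRESHOLD = 5000


class EntityIndex:
    """Row/column layout of the global network.

    Node kinds are laid out in fixed block order lncRNA -> protein -> miRNA;
    the global index of an entity is its kind's offset plus its within-kind
    position.  Identifiers must be unique across all kinds.
    """

    def __init__(self, lncrnas: Sequence[str], proteins: Sequence[str],
                 mirnas: Sequence[str] = ()):
        self.ids_by_kind: dict[str, tuple[str, ...]] = {
            "lncrna": tuple(lncrnas),
            "protein": tuple(proteins),
            "mirna": tuple(mirnas),
        }
        all_ids = [i for ids in self.ids_by_kind.values() for i in ids]
        if len(set(all_ids)) != len(all_ids):
            seen, dups = set(), set()
            for i in all_ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate entity ids across kinds: {sorted(dups)}")
        self.offsets: dict[str, int] = {}
        off = 0
        for kind in KINDS:
            self.offsets[kind] = off
            off += len(self.ids_by_kind[kind])
        self.n_total = off
        self._pos: dict[str, tuple[str, int]] = {}
        for kind in KINDS:
            for j, i in enumerate(self.ids_by_kind[kind]):
                self._pos[i] = (kind, j)

    def __len__(self) -> int:
        return self.n_total

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._pos

    def kind_of(self, entity_id: str) -> str:
        return self._pos[entity_id][0]

    def global_index(self, entity_id: str) -> int:
        kind, j = self._pos[entity_id]
        return self.offsets[kind] + j

    def n_of(self, kind: str) -> int:
        return len(self.ids_by_kind[kind])

    def ids(self) -> list[str]:
        """All identifiers in global (block) order."""
        return [i for kind in KINDS for i in self.ids_by_kind[kind]]

    def kinds(self) -> list[str]:
        return [kind for kind in KINDS for _ in self.ids_by_kind[kind]]

    def without_kind(self, kind: str) -> "EntityIndex":
        kept = {k: (() if k == kind else self.ids_by_kind[k]) for k in KINDS}
        return EntityIndex(kept["lncrna"], kept["protein"], kept["mirna"])

    def __eq__(self, other) -> bool:
        return isinstance(other, EntityIndex) and self.ids_by_kind == other.ids_by_kind


@dataclass
class ExpressionMatrix:
    """Entity-by-sample expression levels (arbitrary units)."""

    entity_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.entity_ids = tuple(self.entity_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids in expression matrix")
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ValueError("expression value shape does not match id lists")


class ComponentNetwork:
    """Sparse weighted network between two entity kinds.

    Intra-kind networks (``kind_a == kind_b``) are undirected with no
    self-edges; edges are stored under a canonical (sorted) key.  Duplicate
    records for the same undirected pair must agree in weight within
    ``DUPLICATE_WEIGHT_TOL`` or a ``ValueError`` is raised.
    """

    def __init__(self, kind_a: str, kind_b: str, allow_negative: bool = False):
        if kind_a not in KINDS or kind_b not in KINDS:
            raise ValueError(f"unknown kind pair ({kind_a}, {kind_b})")
        self.kind_a = kind_a
        self.kind_b = kind_b
        self.allow_negative = allow_negative
        self.weights: dict[tuple[str, str], float] = {}

    @property
    def intra_kind(self) -> bool:
        return self.kind_a == self.kind_b

    def _key(self, a: str, b: str) -> tuple[str, str]:
        if self.intra_kind:
            return (a, b) if a <= b else (b, a)
        return (a, b)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        weight = float(weight)
        if not self.allow_negative and weight <= 0:
            raise ValueError(f"edge ({a}, {b}) has non-positive weight {weight}")
        if self.intra_kind and a == b:
            raise ValueError(f"self-edge on {a} not allowed in intra-kind network")
        key = self._key(a, b)
        if key in self.weights:
            if abs(self.weights[key] - weight) > DUPLICATE_WEIGHT_TOL:
                raise ValueError(
                    f"conflicting duplicate edge ({a}, {b}): "
                    f"{self.weights[key]} vs {weight}")
            return
        self.weights[key] = weight

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.weights.get(self._key(a, b), default)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), w in self.weights.items():
            yield a, b, w

    def n_edges(self) -> int:
        return len(self.weights)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ComponentNetwork)
                and (self.kind_a, self.kind_b) == (other.kind_a, other.kind_b)
                and self.weights.keys() == other.weights.keys()
                and all(abs(self.weights[k] - other.weights[k]) <= DUPLICATE_WEIGHT_TOL
                        for k in self.weights))


@dataclass
class FusionConfig:
    """Per-source co-expression score tables to be fused with the noisy-OR rule.

    Each source maps an (lncRNA, protein) pair to a correlation-like score
    in [-1, 1]; negative scores are discarded before fusion.
    """

    sources: Sequence[Mapping[tuple[str, str], float]]

    def __post_init__(self):
        if len(self.sources) < 1:
            raise ValueError("at least one score source required")


@dataclass
class GlobalNetwork:
    """Assembled symmetric nonnegative block adjacency matrix."""

    index: EntityIndex
    matrix: sp.csr_matrix

    def block(self, kind_a: str, kind_b: str) -> sp.csr_matrix:
        ra = self.index.offsets[kind_a]
        rb = self.index.offsets[kind_b]
        na = self.index.n_of(kind_a)
        nb = self.index.n_of(kind_b)
        return self.matrix[ra:ra + na, rb:rb + nb]

    def drop_kind(self, kind: str) -> "GlobalNetwork":
        """Remove all rows/columns of one kind; remaining blocks are untouched."""
        keep = np.array([k != kind for k in self.index.kinds()])
        sub = self.matrix[np.ix_(keep, keep)].tocsr()
        return GlobalNetwork(self.index.without_kind(kind), sub)

    def toarray(self) -> np.ndarray:
        if self.index.n_total > DENSE_THRESHOLD:
            raise ValueError(
                f"refusing dense materialization above {DENSE_THRESHOLD} nodes")
        return self.matrix.toarray()


def pcc_similarity(expr: ExpressionMatrix, clip_negative: bool = True,
                   kind: str = "lncrna") -> ComponentNetwork:
    """Pairwise Pearson co-expression similarity network.

    With ``clip_negative`` (the default) pairs with PCC <= 0 are absent, so
    the network is nonnegative as the diffusion step requires.  The diagonal
    is always excluded.

    Raises
    ------
    ValueError
        If fewer than 2 entities or samples, or a row has zero variance
        (PCC undefined); the error names the offending entity.
    """
    if len(expr.entity_ids) < 2:
        raise ValueError("need at least 2 entities for pairwise correlation")
    if len(expr.sample_ids) < 2:
        raise ValueError("need at least 2 samples for correlation")
    stds = expr.values.std(axis=1)
    for eid, s in zip(expr.entity_ids, stds):
        if s == 0:
            raise ValueError(f"zero-variance expression row for entity {eid!r}")
    corr = np.corrcoef(expr.values)
    net = ComponentNetwork(kind, kind, allow_negative=not clip_negative)
    n = len(expr.entity_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(corr[i, j])
            if clip_negative and w <= 0:
                continue
            if w != 0:
                net.add_edge(expr.entity_ids[i], expr.entity_ids[j], w)
    return net


def fuse_scores(cfg: FusionConfig) -> dict[tuple[str, str], float]:
    """Fuse per-source correlation scores with the noisy-OR rule.

    For each pair, negative (and zero) source scores are discarded; if no
    positive score remains the pair is absent.  Otherwise

        S = 1 - prod_n (1 - S_n)    over the positive S_n,

    which lies in (0, 1] and never decreases when a positive source is added.

    Raises
    ------
    ValueError
        If any source score exceeds 1 (scores must be probability-like).
    """
    pooled: dict[tuple[str, str], list[float]] = {}
    for src in cfg.sources:
        for pair, s in src.items():
            if s > 1:
                raise ValueError(f"score {s} > 1 for pair {pair}; "
                                 "probability-like scores required")
            pooled.setdefault(pair, []).append(float(s))
    fused: dict[tuple[str, str], float] = {}
    for pair, scores in pooled.items():
        pos = [s for s in scores if s > 0]
        if not pos:
            continue
        fused[pair] = 1.0 - float(np.prod([1.0 - s for s in pos]))
    return fused


def binarize_interactions(pairs: Iterable[tuple[str, str]], index: EntityIndex,
                          kind_a: str, kind_b: str) -> ComponentNetwork:
    """Binary interaction network: listed pairs get weight 1, others are absent.

    Duplicate listings collapse to a single edge.  Pairs referencing ids not
    present in ``index`` raise, listing every offending id.
    """
    pairs = list(pairs)
    unknown = sorted({i for pair in pairs for i in pair if i not in index})
    if unknown:
        raise ValueError(f"unknown entity ids in interaction pairs: {unknown}")
    net = ComponentNetwork(kind_a, kind_b)
    for a, b in pairs:
        net.add_edge(a, b, 1.0)
    return net


def merge_max(a: ComponentNetwork, b: ComponentNetwork) -> ComponentNetwork:
    """Combine two evidence networks over the same kinds, taking the larger
    weight when a pair occurs in both (both are confidence-like in [0, 1])."""
    if (a.kind_a, a.kind_b) != (b.kind_a, b.kind_b):
        raise ValueError("cannot merge networks over different kind pairs")
    out = ComponentNetwork(a.kind_a, a.kind_b)
    merged: dict[tuple[str, str], float] = dict(a.weights)
    for key, w in b.weights.items():
        merged[key] = max(merged.get(key, 0.0), w)
    out.weights = merged
    return out


_EXPECTED_KINDS = {
    "L": ("lncrna", "lncrna"), "P": ("protein", "protein"),
    "M": ("mirna", "mirna"), "LP": ("lncrna", "protein"),
    "LM": ("lncrna", "mirna"), "PM": ("protein", "mirna"),
}


def assemble_global(L: ComponentNetwork, P: ComponentNetwork,
                    M: ComponentNetwork, LP: ComponentNetwork,
                    LM: ComponentNetwork, PM: ComponentNetwork,
                    index: EntityIndex) -> GlobalNetwork:
    """Assemble the six component networks into the global block matrix.

    Each off-diagonal block is mirrored by its transpose so the result is
    exactly symmetric; all weights must be nonnegative and every edge
    endpoint must resolve in ``index``.
    """
    components = {"L": L, "P": P, "M": M, "LP": LP, "LM": LM, "PM": PM}
    rows, cols, vals = [], [], []
    for name, net in components.items():
        expected = _EXPECTED_KINDS[name]
        if (net.kind_a, net.kind_b) != expected:
            raise ValueError(
                f"component {name} has kinds ({net.kind_a}, {net.kind_b}), "
                f"expected {expected}")
        for a, b, w in net.edges():
            if w < 0:
                raise ValueError(f"negative weight {w} on edge ({a}, {b})")
            unknown = [i for i in (a, b) if i not in index]
            if unknown:
                raise ValueError(f"edge ({a}, {b}) references unknown ids: {unknown}")
            ia, ib = index.global_index(a), index.global_index(b)
            rows.extend((ia, ib))
            cols.extend((ib, ia))
            vals.extend((w, w))
    n = index.n_total
    G = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return GlobalNetwork(index, G)
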