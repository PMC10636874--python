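"""Readers and writers for the pipeline's file dialects.

All dialects are plain text: ID lists (one identifier per line), 3-column
edge-list TSVs (``id_a  id_b  weight``, '#' comments allowed), annotation
TSVs (``protein_id  go_term  evidence``), truth TSVs (``lncrna_id
go_term``), embeddings as TSV (id + one column per dimension), and square
matrices as MatrixMarket (MTX) with a sidecar index TSV mapping row number
to (kind, id).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .annotate import AnnotationTable
from .evaluate import TruthSet
from .netbuild import KINDS, ComponentNetwork, EntityIndex, ExpressionMatrix


def read_id_list(path: str | Path) -> list[str]:
    """Plain text, one identifier per line, no header; blank lines skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s:
                out.append(s)
    return out


def write_id_list(path: str | Path, ids: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_edge_list(path: str | Path, index: EntityIndex,
                   kind_a: str, kind_b: str) -> ComponentNetwork:
    """3-column TSV (id_a, id_b, weight); '#'-prefixed lines are comments.

    Malformed lines raise with the line number; ids not in ``index`` raise
    listing every offending id.  Symmetric duplicates must agree in weight.
    """
    net = ComponentNetwork(kind_a, kind_b)
    unknown: set[str] = set()
    records = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.lstrip().startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {ln}: expected 3 tab-separated columns, "
                    f"got {len(parts)}")
            a, b, w_str = parts
            try:
                w = float(w_str)
            except ValueError:
                raise ValueError(f"{path}: line {ln}: bad weight {w_str!r}") from None
            for i in (a, b):
                if i not in index:
                    unknown.add(i)
            records.append((a, b, w))
    if unknown:
        raise ValueError(f"{path}: unknown entity ids: {sorted(unknown)}")
    for a, b, w in records:
        net.add_edge(a, b, w)
    return net


def write_edge_list(path: str | Path, net: ComponentNetwork) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV with a header row of sample ids; first column is the entity id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(entity_ids=tuple(df.index.astype(str)),
                            sample_ids=tuple(df.columns.astype(str)),
                            values=df.to_numpy(dtype=float))


def write_expression(path: str | Path, expr: ExpressionMatrix) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.entity_ids),
                      columns=list(expr.sample_ids))
    df.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> AnnotationTable:
    """3-column TSV: protein_id, go_term, evidence_code (no header)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.lstrip().startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {ln}: expected 3 columns")
            rows.append(tuple(parts))
    return AnnotationTable.from_records(rows)


def write_annotations(path: str | Path, table: AnnotationTable) -> None:
    table.records.to_csv(path, sep="\t", header=False, index=False)


def read_truth(path: str | Path) -> TruthSet:
    """2-column TSV: lncrna_id, go_term (no header)."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.lstrip().startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 columns")
            terms.setdefault(parts[0], set()).add(parts[1])
    return TruthSet(terms)


def write_truth(path: str | Path, truth: TruthSet) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in truth.genes():
            for t in sorted(truth.terms_by_gene[g]):
                fh.write(f"{g}\t{t}\n")


def save_matrix(path: str | Path, matrix, index: EntityIndex) -> None:
    """Persist a square node matrix as MTX plus a ``<path>.index.tsv``
    sidecar mapping row number -> (kind, id)."""
    path = Path(path)
    M = sp.coo_matrix(np.asarray(matrix)) if not sp.issparse(matrix) else matrix.tocoo()
    sio.mmwrite(str(path), M)
    with open(str(path) + ".index.tsv", "w", encoding="utf-8") as fh:
        for row, (kind, i) in enumerate(zip(index.kinds(), index.ids())):
            fh.write(f"{row}\t{kind}\t{i}\n")


def load_matrix(path: str | Path) -> tuple[sp.csr_matrix, EntityIndex]:
    path = Path(path)
    mtx_path = path if path.exists() else path.with_suffix(path.suffix + ".mtx")
    M = sp.csr_matrix(sio.mmread(str(mtx_path)))
    ids_by_kind: dict[str, list[str]] = {k: [] for k in KINDS}
    with open(str(path) + ".index.tsv", encoding="utf-8") as fh:
        for line in fh:
            _, kind, i = line.rstrip("\n").split("\t")
            ids_by_kind[kind].append(i)
    index = EntityIndex(ids_by_kind["lncrna"], ids_by_kind["protein"],
                        ids_by_kind["mirna"])
    return M, index


def write_embeddings(path: str | Path, node_ids: Sequence[str],
                     matrix: np.ndarray) -> None:
    df = pd.DataFrame(matrix, index=list(node_ids))
    df.columns = [f"d{j}" for j in range(matrix.shape[1])]
    df.to_csv(path, sep="\t", index_label="id")

def read_embeddings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_predictions(path: str | Path, predictions: pd.DataFrame) -> None:
    """Long-form TSV: lncrna_id, go_term, score."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in predictions.index:
            for term in predictions.columns:
                fh.write(f"{gene}\t{term}\t{float(predictions.loc[gene, term])!r}\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["lncrna_id", "go_term", "score"])
    return df.pivot(index="lncrna_id", columns="go_term", values="score").fillna(0.0)


def read_obo(path: str | Path):
    """Minimal ontology load: [Term] stanzas, keeping only is_a and part_of
    relationships, as a child -> parent directed graph."""
    import networkx as nx
    import obonet

    raw = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    dag.add_nodes_from(raw.nodes)
    for child, parent, key in raw.edges(keys=True):
        if key in ("is_a", "part_of"):
            dag.add_edge(child, parent)
    return dag
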