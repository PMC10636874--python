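"""Seeded synthetic heterogeneous networks with planted functional modules.

The generator emulates the statistical structure the real inputs assume —
interacting or co-expressed molecules tend to share function — with a planted
partition: every entity (lncRNA, protein, miRNA) is assigned to one of g
function groups, and each of the six component networks draws an edge with
probability p_in between same-group nodes and p_out otherwise.  Each group
owns a few GO terms; every protein is annotated with its group's terms
(evidence EXP), while a held-out fraction of lncRNAs contribute their group
terms to a truth set that is never written to the annotation table.  With
p_in >> p_out the pipeline should recover the groups; with p_in == p_out the
labels carry no signal and performance must fall to the permutation
baseline.

Real datasets differ in ways the generator deliberately ignores: degree
distributions are heavy-tailed, GO terms are hierarchically nested and
wildly uneven in frequency, and annotation evidence is mixed.  The bundle is
a statistical test harness, not a data mimic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as lio
from .annotate import AnnotationTable
from .evaluate import TruthSet
from .netbuild import KINDS, ComponentNetwork, EntityIndex


@dataclass
class SynthConfig:
    n_l: int = 30
    n_p: int = 60
    n_m: int = 10
    g: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    weight_noise: float = 0.1
    terms_per_group: int = 3
    holdout_fraction: float = 0.5
    seed: int = 0
    binary_lp: bool = False  # NPinter-like binary lncRNA-protein edges

    def __post_init__(self):
        if not (0 <= self.p_out <= 1 and 0 <= self.p_in <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.p_in < self.p_out:
            raise ValueError("p_in must be >= p_out")
        if min(self.n_l, self.n_p) < 1 or self.n_m < 0:
            raise ValueError("need at least one lncRNA and one protein")
        if not 1 <= self.g <= min(self.n_l, self.n_p):
            raise ValueError("g must satisfy 1 <= g <= min(n_l, n_p)")
        if not 0 < self.holdout_fraction <= 1:
            raise ValueError("holdout fraction must lie in (0, 1]")


@dataclass
class SynthBundle:
    index: EntityIndex
    networks: dict[str, ComponentNetwork]  # keys L P M LP LM PM
    annotations: AnnotationTable
    truth: TruthSet
    groups: dict[str, int]
    config: SynthConfig


def group_terms(cfg: SynthConfig) -> dict[int, list[str]]:
    """GO term ids owned by each group (flat mapping, no hierarchy)."""
    return {j: [f"GO:{j * cfg.terms_per_group + k + 1:07d}"
                for k in range(cfg.terms_per_group)]
            for j in range(cfg.g)}


def _sample_edges(rng: np.random.Generator, ids_a, ids_b, groups, cfg: SynthConfig,
                  kind_a: str, kind_b: str, binary: bool = False) -> ComponentNetwork:
    net = ComponentNetwork(kind_a, kind_b)
    intra = kind_a == kind_b
    for i, a in enumerate(ids_a):
        bs = ids_b[i + 1:] if intra else ids_b
        for b in bs:
            p = cfg.p_in if groups[a] == groups[b] else cfg.p_out
            if rng.random() < p:
                if binary:
                    w = 1.0
                else:
                    w = float(np.clip(0.5 + cfg.weight_noise * rng.standard_normal(),
                                      0.01, 1.0))
                net.add_edge(a, b, w)
    return net


def generate(cfg: SynthConfig) -> SynthBundle:
    """Generate a bundle; identical configs (including seed) give identical
    bundles."""
    rng = np.random.default_rng(cfg.seed)
    lncrnas = tuple(f"L{i:04d}" for i in range(cfg.n_l))
    proteins = tuple(f"P{i:04d}" for i in range(cfg.n_p))
    mirnas = tuple(f"M{i:04d}" for i in range(cfg.n_m))
    index = EntityIndex(lncrnas, proteins, mirnas)

    groups: dict[str, int] = {}
    # every group gets at least one lncRNA and one protein so that truth and
    # annotations are never vacuous; remaining entities are uniform
    for kind_ids, guarantee in ((lncrnas, True), (proteins, True), (mirnas, False)):
        ids = list(kind_ids)
        if guarantee and ids:
            for j in range(cfg.g):
                groups[ids[j]] = j
            ids = ids[cfg.g:]
        for i in ids:
            groups[i] = int(rng.integers(cfg.g))

    networks = {
        "L": _sample_edges(rng, lncrnas, lncrnas, groups, cfg, "lncrna", "lncrna"),
        "P": _sample_edges(rng, proteins, proteins, groups, cfg, "protein", "protein"),
        "M": _sample_edges(rng, mirnas, mirnas, groups, cfg, "mirna", "mirna"),
        "LP": _sample_edges(rng, lncrnas, proteins, groups, cfg, "lncrna", "protein",
                            binary=cfg.binary_lp),
        "LM": _sample_edges(rng, lncrnas, mirnas, groups, cfg, "lncrna", "mirna"),
        "PM": _sample_edges(rng, proteins, mirnas, groups, cfg, "protein", "mirna"),
    }

    terms = group_terms(cfg)
    ann_rows = [(p, t, "EXP") for p in proteins for t in terms[groups[p]]]
    annotations = AnnotationTable.from_records(ann_rows)

    n_held = max(1, round(cfg.holdout_fraction * cfg.n_l))
    held = rng.choice(np.array(lncrnas), size=n_held, replace=False)
    truth = TruthSet({l: set(terms[groups[l]]) for l in sorted(held)})

    return SynthBundle(index=index, networks=networks, annotations=annotations,
                       truth=truth, groups=groups, config=cfg)


_NET_FILES = {"L": "L.tsv", "P": "P.tsv", "M": "M.tsv",
              "LP": "LP.tsv", "LM": "LM.tsv", "PM": "PM.tsv"}
_ID_FILES = {"lncrna": "lncrna_ids.txt", "protein": "protein_ids.txt",
             "mirna": "mirna_ids.txt"}


def write_bundle(bundle: SynthBundle, directory: str | Path) -> dict:
    """Write the bundle in the pipeline's input dialects and return the
    manifest (also saved as manifest.json)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for kind, fname in _ID_FILES.items():
        lio.write_id_list(d / fname, bundle.index.ids_by_kind[kind])
        paths[f"ids_{kind}"] = fname
    for key, fname in _NET_FILES.items():
        lio.write_edge_list(d / fname, bundle.networks[key])
        paths[f"net_{key}"] = fname
    lio.write_annotations(d / "annotations.tsv", bundle.annotations)
    paths["annotations"] = "annotations.tsv"
    lio.write_truth(d / "truth.tsv", bundle.truth)
    paths["truth"] = "truth.tsv"
    with open(d / "groups.tsv", "w") as fh:
        for i in bundle.index.ids():
            fh.write(f"{i}\t{bundle.groups[i]}\n")
    paths["groups"] = "groups.tsv"
    manifest = {"seed": bundle.config.seed, "config": asdict(bundle.config),
                "paths": paths}
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_bundle(directory: str | Path) -> SynthBundle:
    """Read a written bundle back; round-trips ``write_bundle`` exactly."""
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = SynthConfig(**manifest["config"])
    ids = {kind: lio.read_id_list(d / fname) for kind, fname in _ID_FILES.items()}
    index = EntityIndex(ids["lncrna"], ids["protein"], ids["mirna"])
    kinds = {"L": ("lncrna", "lncrna"), "P": ("protein", "protein"),
             "M": ("mirna", "mirna"), "LP": ("lncrna", "protein"),
             "LM": ("lncrna", "mirna"), "PM": ("protein", "mirna")}
    networks = {key: lio.read_edge_list(d / fname, index, *kinds[key])
                for key, fname in _NET_FILES.items()}
    annotations = lio.read_annotations(d / "annotations.tsv")
    truth = lio.read_truth(d / "truth.tsv")
    groups = {}
    with open(d / "groups.tsv") as fh:
        for line in fh:
            i, g = line.rstrip("\n").split("\t")
            groups[i] = int(g)
    return SynthBundle(index=index, networks=networks, annotations=annotations,
                       truth=truth, groups=groups, config=cfg)
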