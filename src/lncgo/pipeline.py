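"""End-to-end pipeline: network assembly -> diffusion -> PPMI -> SDAE ->
per-term SVMs -> prediction -> Fmax evaluation.

One global seed drives the run; each stochastic stage receives a seed
derived from it by mixing in the stage name, so turning one stage on or off
(e.g. the miRNA ablation) does not silently reshuffle the randomness of the
others.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .annotate import (SVMConfig, filter_non_iea, predict_lncrna_functions,
                       propagate_annotations, train_term_classifiers)
from .diffuse import DiffusionConfig, ppmi, rwr, transition_matrix
from .embed import SDAEConfig, encode, train_sdae
from .evaluate import default_grid, evaluate_predictions
from .netbuild import GlobalNetwork, assemble_global
from .synthdata import SynthBundle, read_bundle


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    bundle_dir: str | Path | None = None
    out_dir: str | Path | None = None
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    hidden_widths: tuple[int, ...] = (48, 16)  # appended after the input width
    corruption: float = 0.2
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    fine_tune: bool = False
    svm_c: float = 1.0
    min_positives: int = 10
    propagate: bool = False
    obo_path: str | Path | None = None
    grid_size: int = 101
    seed: int = 0
    drop_mirna: bool = False


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict]
    summary: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages,
                       "summary": self.summary}, fh, indent=2, sort_keys=True,
                      default=str)


def build_global_network(bundle: SynthBundle,
                         drop_mirna: bool = False) -> GlobalNetwork:
    nets = bundle.networks
    G = assemble_global(nets["L"], nets["P"], nets["M"], nets["LP"],
                        nets["LM"], nets["PM"], bundle.index)
    if drop_mirna:
        G = G.drop_kind("mirna")
    return G


def run_pipeline(cfg: PipelineConfig, bundle: SynthBundle | None = None) -> RunManifest:
    """Run every stage in order on a bundle (loaded from ``cfg.bundle_dir``
    when not supplied); persists stage outputs when ``cfg.out_dir`` is set.

    Returns the manifest with per-stage wall-clock, counts, and the final
    evaluation summary.
    """
    if bundle is None:
        if cfg.bundle_dir is None:
            raise ValueError("either a bundle or bundle_dir is required")
        bundle = read_bundle(cfg.bundle_dir)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def _stage(name):
        t0 = time.perf_counter()
        return t0, stages.setdefault(name, {})

    try:
        t0, info = _stage("build")
        G = build_global_network(bundle, drop_mirna=cfg.drop_mirna)
        info.update(nodes=G.index.n_total, edges=int(G.matrix.nnz // 2),
                    seconds=time.perf_counter() - t0)
        if out:
            lio.save_matrix(out / "global.mtx", G.matrix, G.index)

        t0, info = _stage("diffuse")
        A = transition_matrix(G)
        state = rwr(A, cfg.diffusion)
        X = ppmi(state)
        info.update(n_iter=state.n_iter, converged=bool(state.converged),
                    seconds=time.perf_counter() - t0)
        if out:
            lio.save_matrix(out / "ppmi.mtx", X.matrix, G.index)

        t0, info = _stage("embed")
        widths = [G.index.n_total] + [min(w, G.index.n_total)
                                      for w in cfg.hidden_widths]
        sdae_cfg = SDAEConfig(widths=widths, corruption=cfg.corruption,
                              epochs=cfg.epochs, learning_rate=cfg.learning_rate,
                              batch_size=cfg.batch_size,
                              seed=stage_seed(cfg.seed, "embed"),
                              fine_tune=cfg.fine_tune)
        enc = train_sdae(X, sdae_cfg)
        emb = encode(enc, X, node_ids=G.index.ids())
        emb_df = pd.DataFrame(emb.matrix, index=list(emb.node_ids))
        info.update(dim=enc.bottleneck_width,
                    final_loss=enc.loss_traces[-1][-1],
                    seconds=time.perf_counter() - t0)
        if out:
            lio.write_embeddings(out / "embeddings.tsv", emb.node_ids, emb.matrix)

        t0, info = _stage("train")
        table = filter_non_iea(bundle.annotations)
        if cfg.propagate:
            dag = lio.read_obo(cfg.obo_path) if cfg.obo_path else None
            table = propagate_annotations(table, dag, enabled=True)
        prot_emb = emb_df.loc[list(G.index.ids_by_kind["protein"])]
        classifiers = train_term_classifiers(
            table, prot_emb, seed=stage_seed(cfg.seed, "train"),
            min_positives=cfg.min_positives, config=SVMConfig(C=cfg.svm_c))
        info.update(terms_modeled=len(classifiers),
                    proteins=len(prot_emb), seconds=time.perf_counter() - t0)

        t0, info = _stage("predict")
        lnc_emb = emb_df.loc[list(G.index.ids_by_kind["lncrna"])]
        predictions = predict_lncrna_functions(classifiers, lnc_emb)
        info.update(lncrnas_scored=len(predictions),
                    seconds=time.perf_counter() - t0)
        if out:
            lio.write_predictions(out / "predictions.tsv", predictions)

        t0, info = _stage("evaluate")
        summary, curve = evaluate_predictions(predictions, bundle.truth,
                                              default_grid(cfg.grid_size))
        info.update(n_test=bundle.truth.n_test, seconds=time.perf_counter() - t0)
        if out:
            pd.DataFrame({"threshold": curve.thresholds, "m": curve.m,
                          "precision": curve.precision,
                          "recall": curve.recall}).to_csv(
                out / "curve.tsv", sep="\t", index=False)
    except Exception as exc:
        failed = [n for n, s in stages.items() if "seconds" not in s]
        stage_name = failed[0] if failed else "unknown"
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest = RunManifest(
        config={**{k: v for k, v in asdict(cfg).items() if k != "diffusion"},
                "diffusion": asdict(cfg.diffusion)},
        stages=stages,
        summary={"fmax": summary.fmax, "t_star": summary.t_star,
                 "precision": summary.precision, "recall": summary.recall,
                 "coverage": summary.coverage})
    manifest.predictions = predictions  # kept in memory for callers
    if out:
        with open(out / "evaluation.json", "w") as fh:
            json.dump(manifest.summary, fh, indent=2, sort_keys=True)
        manifest.save(out / "manifest.json")
    return manifest
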