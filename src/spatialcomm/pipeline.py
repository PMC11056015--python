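"""Config-driven orchestration of the full inference workflow.

Stages run in order: load (or simulate) -> per-type HVG slices ->
neighbor scores -> per-type PLS fit with cross-validated component
selection -> two-stage coefficient filter -> gene clustering -> MIMO
graph (aggregate, threshold, attenuate) -> export; keyword labeling plus
MLP classification is appended when annotations are configured. Every
stage's outputs are written under the output directory and a run manifest
(config hash, seeds, package version, per-stage timings) is emitted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import build_gene_features, label_genes_by_keywords, load_annotations, train_eval_mlp
from .clustering import cluster_hvgs
from .exceptions import ValidationError
from .filtering import CoefficientFilter
from .graph import build_communication_graph, cluster_coefficient_matrix, export_graph
from .hvg import hvg_overlap_ratio, split_by_cell_type
from .io import load_dataset, write_json, write_matrix_tsv, write_table_tsv
from .neighbors import neighbor_score_matrix
from .pls import PLS2Regression
from .simulate import SimulationSpec, simulate_dataset, write_simulation

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "hvg": {"n_top": 2000, "loess_span": 0.3, "min_cells_per_type": 10,
            "overlap_mode": "ordered_fraction"},
    "neighbor": {"kernel": "log10_ratio", "jitter": False, "jitter_seed": 0},
    "pls": {"c_max": None, "folds": 10, "seed": 0},
    "filter": {"delta": 0.05},
    "cluster": {"k_min": 2, "k_max": 15, "seed": 0, "restarts": 10},
    "graph": {"k_min_override": None},
    "classify": {"annotations": None, "folds": 10, "seed": 0, "hidden_units": 64},
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping or a YAML path")
    return _merge(DEFAULT_CONFIG, config)


def _check_inputs(cfg: dict) -> None:
    inp = cfg.get("input")
    if inp:
        for key in ("expression", "coordinates", "labels"):
            p = inp.get(key)
            if p is None:
                raise ValidationError(f"input.{key} missing from config")
            if not Path(p).exists():
                raise FileNotFoundError(f"input.{key}: {p}")
    elif "simulate" not in cfg:
        raise ValidationError("config needs an 'input' or 'simulate' section")


def run_pipeline(config, out_dir=None) -> dict:
    """Run all stages; returns the manifest (also written to out_dir)."""
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "spatialcomm_run"))
    out.mkdir(parents=True, exist_ok=True)
    _check_inputs(cfg)
    from . import __version__ as version

    manifest = {
        "version": version,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": {
            "pls": cfg["pls"]["seed"],
            "cluster": cfg["cluster"]["seed"],
            "classify": cfg["classify"]["seed"],
            "simulate": cfg.get("simulate", {}).get("seed"),
        },
        "stages": [],
    }
    timings = {}
    state = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed: {exc}; check the config section and inputs for this stage"
            ) from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        manifest["stages"].append(name)
        logger.info("stage %s done in %.2fs", name, timings[name])

    # -- load / simulate ---------------------------------------------------
    def _load():
        if "input" in cfg and cfg["input"]:
            inp = cfg["input"]
            state["dataset"] = load_dataset(
                inp["expression"], inp["coordinates"], inp["labels"],
                format=inp.get("format"), orientation=inp.get("orientation"),
            )
        else:
            spec = SimulationSpec(**cfg["simulate"])
            dataset, truth = simulate_dataset(spec)
            state["dataset"], state["truth"] = dataset, truth
            write_simulation(dataset, truth, out / "simulated_input")
        ds = state["dataset"]
        write_json({"n_cells": ds.n_cells, "n_genes": ds.n_genes,
                    "n_types": ds.n_types,
                    "cell_types": list(ds.cell_types)}, out / "dataset_summary.json")

    stage("load", _load)

    # -- per-type HVG slices ----------------------------------------------
    def _hvg():
        h = cfg["hvg"]
        slices = split_by_cell_type(
            state["dataset"], n_top=h["n_top"], loess_span=h["loess_span"],
            min_cells=h["min_cells_per_type"],
        )
        state["slices"] = slices
        rows = [{"cell_type": s.cell_type, "gene": g}
                for s in slices for g in s.hvg_ids]
        write_table_tsv(pd.DataFrame(rows, columns=["cell_type", "gene"]),
                        out / "hvgs.tsv")
        if len(slices) >= 2:
            ratio = hvg_overlap_ratio([s.hvg_ids for s in slices],
                                      mode=h["overlap_mode"])
            write_json({"hvg_overlap_ratio": ratio, "mode": h["overlap_mode"]},
                       out / "hvg_overlap.json")

    stage("hvg", _hvg)

    # -- neighbor scores ---------------------------------------------------
    def _scores():
        n = cfg["neighbor"]
        scores = neighbor_score_matrix(
            state["dataset"], kernel=n["kernel"], jitter=n["jitter"],
            jitter_seed=n["jitter_seed"],
        )
        state["scores"] = scores
        write_matrix_tsv(scores.zscored, state["dataset"].cell_ids,
                         scores.type_order, out / "neighbor_scores.tsv")

    stage("scores", _scores)

    # -- per-type PLS fits -------------------------------------------------
    def _fit():
        p = cfg["pls"]
        fits, chosen = {}, {}
        for s in state["slices"]:
            f = state["scores"].zscored[s.cell_index]
            model = PLS2Regression(
                n_components="cv", max_components=p["c_max"],
                cv_folds=p["folds"], random_state=p["seed"],
            ).fit(f, s.expression)
            fits[s.cell_type] = model
            chosen[s.cell_type] = model.n_components_
            write_matrix_tsv(model.coef_, state["scores"].type_order, s.hvg_ids,
                             out / f"coefficients_raw_{s.cell_type}.tsv")
        state["fits"] = fits
        write_json({"n_components": chosen}, out / "pls_components.json")

    stage("fit", _fit)

    # -- two-stage filter --------------------------------------------------
    def _filter():
        delta = cfg["filter"]["delta"]
        filtered, rows = {}, []
        for s in state["slices"]:
            f = state["scores"].zscored[s.cell_index]
            filt = CoefficientFilter(delta=delta).fit(state["fits"][s.cell_type],
                                                      f, s.expression)
            filtered[s.cell_type] = filt
            for b, sender in enumerate(state["scores"].type_order):
                for h, gene in enumerate(s.hvg_ids):
                    if filt.coef_[b, h] != 0:
                        rows.append({
                            "cell_type": s.cell_type, "neighbor_type": sender,
                            "gene": gene, "coefficient": filt.coef_[b, h],
                            "q_pair": filt.q_pair_[b, h],
                        })
        state["filtered"] = filtered
        write_table_tsv(
            pd.DataFrame(rows, columns=["cell_type", "neighbor_type", "gene",
                                        "coefficient", "q_pair"]),
            out / "coefficients_filtered.tsv")

    stage("filter", _filter)

    # -- gene clustering ---------------------------------------------------
    def _cluster():
        c = cfg["cluster"]
        clusters, rows = {}, []
        for s in state["slices"]:
            coef = state["filtered"][s.cell_type].coef_
            try:
                res = cluster_hvgs(coef.T, s.hvg_ids, k_min=c["k_min"],
                                   k_max=c["k_max"], seed=c["seed"],
                                   n_init=c["restarts"], cell_type=s.cell_type)
            except ValidationError as exc:
                logger.warning("clustering skipped for %s: %s", s.cell_type, exc)
                continue
            clusters[s.cell_type] = res
            rows.extend({"cell_type": s.cell_type, "gene": g, "cluster": int(a)}
                        for g, a in zip(res.gene_ids, res.assignments))
        if not clusters:
            raise ValidationError("no cell type had enough filtered genes to cluster")
        state["clusters"] = clusters
        write_table_tsv(pd.DataFrame(rows, columns=["cell_type", "gene", "cluster"]),
                        out / "gene_clusters.tsv")

    stage("cluster", _cluster)

    # -- MIMO graph --------------------------------------------------------
    def _graph():
        matrices = {}
        for cell_type, res in state["clusters"].items():
            filt = state["filtered"][cell_type]
            pos = {g: i for i, g in enumerate(
                state["slices"][[s.cell_type for s in state["slices"]].index(cell_type)].hvg_ids)}
            cols = [pos[g] for g in res.gene_ids]
            matrices[cell_type] = cluster_coefficient_matrix(
                filt.coef_[:, cols].T, res.assignments)
        graph = build_communication_graph(
            matrices, state["scores"].type_order,
            k_min=cfg["graph"]["k_min_override"])
        state["graph"] = graph

    stage("graph", _graph)

    # -- export ------------------------------------------------------------
    def _export():
        export_graph(state["graph"], out / "graph")
        manifest["timings"] = timings
        write_json(manifest, out / "manifest.json")

    stage("export", _export)

    # -- optional classification ------------------------------------------
    if cfg["classify"].get("annotations"):
        def _classify():
            cc = cfg["classify"]
            annotations = load_annotations(cc["annotations"])
            labels_df = label_genes_by_keywords(annotations)
            write_table_tsv(labels_df, out / "gene_labels.tsv")
            genes = [g for g in labels_df["gene"]
                     if g in set(state["dataset"].gene_ids)]
            labels = labels_df.set_index("gene").loc[genes, "label"].to_numpy()
            feats = build_gene_features(
                state["dataset"],
                {t: f.coef_ for t, f in state["filtered"].items()},
                {s.cell_type: s.hvg_ids for s in state["slices"]},
                genes,
            )
            report = train_eval_mlp(feats, labels, folds=cc["folds"],
                                    seed=cc["seed"], hidden_units=cc["hidden_units"])
            write_json(report.to_dict(), out / "classifier_report.json")

        stage("classify", _classify)
        manifest["timings"] = timings
        write_json(manifest, out / "manifest.json")

    return manifest
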