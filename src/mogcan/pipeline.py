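"""End-to-end orchestration: preprocess -> per-omics graphs and GCNs ->
latent concatenation -> SNF fusion -> GAT classification -> evaluation.

The test partition is transductive: test samples are present in every
graph and forward pass but never contribute to any loss. All randomness
fans out from a single seed through per-stage derived seeds, so stages
can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import affinity_graph as ag
from . import gat_classifier as gat
from . import gcn_features as gcn
from . import io_preprocess as iop
from . import snf_fusion as snf
from ._nn import stage_seed

__all__ = ["PipelineParams", "RunRecord", "preprocess", "run_pipeline_data",
           "run_pipeline", "sweep_edge_retention", "load_config"]


@dataclass
class PipelineParams:
    """Hyperparameters for one pipeline run (defaults follow the printed
    case-study settings)."""

    mu: float = 0.5
    k_neighbors: int = 20
    p0: float = 0.01
    step: float = 0.005
    kernel_distance_convention: str = "paper_literal"
    gcn: gcn.GCNConfig = field(default_factory=gcn.GCNConfig)
    latent_layer: int | str = 1
    selection_rule: str = "margin"
    selection_margin: float = 0.15
    selection_top_k: int | None = None
    snf_iterations: int = 20
    gat: gat.GATConfig = field(default_factory=gat.GATConfig)
    train_fraction: float = 0.75
    max_na_fraction: float = 0.10
    fixed_retention: float | None = None  # bypass dynamic threshold search
    standardize_latents: bool = True      # z-score latents before the GAT


@dataclass
class RunRecord:
    """Everything needed to audit or re-run one pipeline execution."""

    params: dict
    seed: int
    n_samples: int
    classes: list[str]
    per_omics: dict
    selected_omics: list[str]
    fused_retention: float | None
    metrics: dict
    confusion: list[list[int]] | None
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    timestamps: dict
    loss_traces: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _params_snapshot(params: PipelineParams) -> dict:
    snap = dataclasses.asdict(params)
    return snap


def preprocess(omics: list[iop.OmicsMatrix], labels: iop.LabelTable,
               params: PipelineParams
               ) -> tuple[list[iop.OmicsMatrix], iop.LabelTable]:
    """Deduplicate, align across views/labels, then NA-filter each view.

    NA fractions are computed over the retained (aligned) samples.
    """
    deduped = [iop.deduplicate_samples(m) for m in omics]
    aligned, aligned_labels = iop.align_samples(deduped, labels)
    cleaned = [iop.filter_missing_features(m, params.max_na_fraction)
               for m in aligned]
    return cleaned, aligned_labels


def _sparsify_matrix(A: np.ndarray, params: PipelineParams
                     ) -> tuple[float, np.ndarray, np.ndarray]:
    """Dynamic threshold selection, or a fixed retention override."""
    if params.fixed_retention is not None:
        A_sparse, _, _ = ag.sparsify(A, params.fixed_retention)
        D, L = ag.degree_and_laplacian(A_sparse)  # may raise Singular...
        return params.fixed_retention, A_sparse, L
    return ag.dynamic_threshold_select(A, params.p0, params.step)


def run_pipeline_data(omics: list[iop.OmicsMatrix], labels: iop.LabelTable,
                      params: PipelineParams | None = None, seed: int = 0,
                      outdir: str | None = None) -> RunRecord:
    """Run the full two-stage pipeline on in-memory data."""
    params = params or PipelineParams()
    t_start = time.time()

    omics, labels = preprocess(omics, labels, params)
    y = labels.class_indices()
    n = len(y)
    split = iop.stratified_split(labels, params.train_fraction,
                                 seed=stage_seed(seed, "split"))

    per_omics: dict = {}
    loss_traces: dict = {}
    graphs: dict[str, ag.AffinityGraph] = {}
    latents: dict[str, gcn.LatentEmbedding] = {}
    val_acc: dict[str, float] = {}
    for m in omics:
        stage = f"graph:{m.name}"
        graph = ag.build_affinity(
            m.values, k_neighbors=params.k_neighbors, mu=params.mu,
            kernel_distance_convention=params.kernel_distance_convention,
            name=m.name)
        p_star, A_sparse, L = _sparsify_matrix(graph.A, params)
        graph.A_sparse, graph.L = A_sparse, L
        graph.retained_fraction = p_star
        graphs[m.name] = graph

        cfg = dataclasses.replace(params.gcn,
                                  seed=stage_seed(seed, f"gcn:{m.name}"))
        model, history = gcn.train_gcn(m.values, L, y,
                                       split.train_indices, cfg)
        proba = gcn.predict_proba(m.values, L, model)
        test_pred = proba[split.test_indices].argmax(axis=1)
        test_acc = float(np.mean(test_pred == y[split.test_indices]))
        latents[m.name] = gcn.extract_latent(
            m.values, L, model, layer=params.latent_layer,
            source_omics=m.name)
        val_acc[m.name] = history["val_accuracy"]
        per_omics[m.name] = {
            "p_star": p_star,
            "val_accuracy": history["val_accuracy"],
            "test_accuracy": test_acc,
            "n_features": m.n_features,
        }
        loss_traces[stage] = history["train_loss"]

    selected = gcn.select_omics(val_acc, rule=params.selection_rule,
                                margin=params.selection_margin,
                                top_k=params.selection_top_k)
    H = gcn.concatenate_latents([latents[o] for o in selected])
    if params.standardize_latents:
        H = (H - H.mean(axis=0)) / np.maximum(H.std(axis=0), 1e-8)

    if len(selected) >= 2:
        fused = snf.fuse([graphs[o].A for o in selected],
                         k_neighbors=params.k_neighbors,
                         iterations=params.snf_iterations)
        P_fused = fused.P_fused
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            P_fused = snf.normalize_similarity(graphs[selected[0]].A)
    fused_p, P_sparse, _ = _sparsify_matrix(P_fused, params)

    gat_cfg = dataclasses.replace(params.gat, seed=stage_seed(seed, "gat"))
    gat_model, gat_history = gat.train_gat(H, P_sparse, y,
                                           split.train_indices, gat_cfg)
    prediction = gat.predict(H, P_sparse, gat_model)
    metrics = gat.evaluate(prediction, y, split.test_indices,
                           n_classes=labels.n_classes)
    loss_traces["gat"] = gat_history["train_loss"]

    record = RunRecord(
        params=_params_snapshot(params),
        seed=seed,
        n_samples=n,
        classes=list(labels.classes),
        per_omics=per_omics,
        selected_omics=selected,
        fused_retention=fused_p,
        metrics=metrics,
        confusion=prediction.confusion.tolist(),
        train_sample_ids=[labels.sample_ids[i] for i in split.train_indices],
        test_sample_ids=[labels.sample_ids[i] for i in split.test_indices],
        timestamps={"started": t_start, "finished": time.time()},
        loss_traces=loss_traces,
    )
    if outdir:
        _write_outputs(outdir, record, labels, prediction, P_fused, latents)
    return record


def _write_outputs(outdir: str, record: RunRecord, labels: iop.LabelTable,
                   prediction: gat.SubtypePrediction, P_fused: np.ndarray,
                   latents: dict[str, gcn.LatentEmbedding]) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "run_record.json"), "w") as fh:
        fh.write(record.to_json())
    with open(os.path.join(outdir, "metrics.json"), "w") as fh:
        json.dump(record.metrics, fh, indent=2)
    with open(os.path.join(outdir, "predictions.tsv"), "w") as fh:
        classes = record.classes
        fh.write("sample_id\tpredicted_label\t"
                 + "\t".join(f"p_{c}" for c in classes) + "\n")
        for i, sid in enumerate(labels.sample_ids):
            probs = "\t".join(f"{p:.6g}" for p in prediction.probabilities[i])
            fh.write(f"{sid}\t{classes[prediction.hard_labels[i]]}\t"
                     f"{probs}\n")
    np.savetxt(os.path.join(outdir, "confusion.tsv"),
               np.asarray(record.confusion), fmt="%d", delimiter="\t")
    np.savetxt(os.path.join(outdir, "fused_network.tsv"), P_fused,
               delimiter="\t")
    lat_dir = os.path.join(outdir, "latents")
    os.makedirs(lat_dir, exist_ok=True)
    for name, lat in latents.items():
        np.savetxt(os.path.join(lat_dir, f"{name}.tsv"), lat.values,
                   delimiter="\t")


def sweep_edge_retention(omics: list[iop.OmicsMatrix],
                         labels: iop.LabelTable,
                         p_values: list[float],
                         params: PipelineParams | None = None,
                         seed: int = 0) -> list[dict]:
    """Re-run the graph-dependent stages at fixed retention fractions.

    Each row reports the test accuracy at one retention level; retention
    levels below the singularity minimum come back as failed rows rather
    than raising.
    """
    params = params or PipelineParams()
    rows: list[dict] = []
    for p in p_values:
        run_params = dataclasses.replace(params, fixed_retention=float(p))
        try:
            record = run_pipeline_data(omics, labels, run_params, seed=seed)
        except (ag.SingularDegreeError, ValueError) as err:
            rows.append({"p": float(p), "status": "failed",
                         "error": str(err), "test_accuracy": None})
            continue
        rows.append({"p": float(p), "status": "ok",
                     "test_accuracy": record.metrics["accuracy"],
                     "macro_f1": record.metrics["macro_f1"]})
    return rows


# -- config-file front end ---------------------------------------------------

_GCN_KEYS = {f.name for f in dataclasses.fields(gcn.GCNConfig)}
_GAT_KEYS = {f.name for f in dataclasses.fields(gat.GATConfig)}


def load_config(path: str) -> dict:
    """Load and validate a YAML pipeline config; returns a dict with
    'omics' (name -> path), 'labels', 'seed', 'outdir', 'delimiter',
    'samples_as' and a PipelineParams under 'params'."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("omics", "labels"):
        if key not in raw:
            raise ValueError(f"{path}: missing required key {key!r}")
    if "seed" not in raw:
        raise ValueError(f"{path}: a seed is required (no unseeded runs)")
    omics_paths = dict(raw["omics"])
    for name, p in omics_paths.items():
        if not os.path.exists(p):
            raise FileNotFoundError(f"omics {name!r}: no such file {p}")
    if not os.path.exists(raw["labels"]):
        raise FileNotFoundError(f"labels: no such file {raw['labels']}")

    params = PipelineParams()
    simple = {"mu", "k_neighbors", "p0", "step",
              "kernel_distance_convention", "latent_layer",
              "selection_rule", "selection_margin", "selection_top_k",
              "snf_iterations", "train_fraction", "max_na_fraction",
              "fixed_retention", "standardize_latents"}
    for key in simple & raw.keys():
        setattr(params, key, raw[key])
    if "gcn" in raw:
        bad = set(raw["gcn"]) - _GCN_KEYS
        if bad:
            raise ValueError(f"unknown gcn option(s): {sorted(bad)}")
        params.gcn = dataclasses.replace(params.gcn, **raw["gcn"])
    if "gat" in raw:
        bad = set(raw["gat"]) - _GAT_KEYS
        if bad:
            raise ValueError(f"unknown gat option(s): {sorted(bad)}")
        params.gat = dataclasses.replace(params.gat, **raw["gat"])

    return {
        "omics": omics_paths,
        "labels": raw["labels"],
        "seed": int(raw["seed"]),
        "outdir": raw.get("outdir", "mogcan_run"),
        "delimiter": raw.get("delimiter", ","),
        "samples_as": raw.get("samples_as", "rows"),
        "params": params,
    }


def run_pipeline(config_path: str) -> RunRecord:
    """Run the pipeline from a YAML config file."""
    cfg = load_config(config_path)
    omics = [iop.read_omics_matrix(path, delimiter=cfg["delimiter"],
                                   samples_as=cfg["samples_as"], name=name)
             for name, path in cfg["omics"].items()]
    labels = iop.read_label_table(cfg["labels"], delimiter=cfg["delimiter"])
    return run_pipeline_data(omics, labels, cfg["params"],
                             seed=cfg["seed"], outdir=cfg["outdir"])
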