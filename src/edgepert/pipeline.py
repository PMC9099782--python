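"""End-to-end orchestration: network → perturbation → subtypes → subtype networks.

Every stage writes its outputs to the run directory so any downstream stage
can be resumed from disk without recomputation, and a manifest records
parameters, seed, input checksums and stage dimensions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import io as eio
from .network import degree_powerlaw_fit, filter_to_genes, load_edge_list, write_edge_list
from .perturbation import (
    benchmark_vector,
    delta_rank,
    dispersion_report,
    edge_perturbation,
    rank_transform,
)
from .subnet import cluster_edges, perturbed_clusters, top_degree_genes, zscore_rows
from .subtyping import consensus_cluster, select_feature_edges

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (paths + per-stage parameters)."""

    network_path: str
    normal_expr_path: str
    tumor_expr_path: str
    outdir: str
    top_k: int = 30000
    alpha: float = 0.05
    adjust_pvalues: bool = True
    k_min: int = 2
    k_max: int = 10
    n_resamples: int = 1000
    sample_fraction: float = 0.8
    elbow_threshold: float = 0.1
    k_override: int | None = None
    n_clusters: int = 100
    min_edges: int = 30
    z_cut: float = 0.5
    edge_frac: float = 0.70
    n_sample_edges: int = 1000
    n_hub_genes: int = 10
    seed: int = 0
    true_labels_path: str | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("network_path", "normal_expr_path", "tumor_expr_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator adding stage-name context to errors and timing logs."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the manifest dictionary.

    With ``resume=True``, stages whose outputs already exist in ``outdir``
    are loaded from disk instead of recomputed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "inputs": {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in ("network_path", "normal_expr_path", "tumor_expr_path")
        },
        "stages": {},
    }

    normal_expr = eio.read_expression(config.normal_expr_path)
    tumor_expr = eio.read_expression(config.tumor_expr_path)
    if set(normal_expr.index) != set(tumor_expr.index):
        raise ValueError("normal and tumor expression matrices have different gene sets")
    tumor_expr = tumor_expr.reindex(normal_expr.index)

    net = _network_stage(config, outdir, manifest, normal_expr, resume)
    pert, groups = _perturb_stage(config, outdir, manifest, net, normal_expr, tumor_expr, resume)
    cancer_matrix, labels, result_meta = _subtype_stage(config, outdir, manifest, pert, groups, resume)
    _subnet_stage(config, outdir, manifest, cancer_matrix, labels)

    if config.true_labels_path:
        truth = eio.read_labels(config.true_labels_path).reindex(labels.index)
        manifest["ground_truth_ari"] = float(
            adjusted_rand_score(truth.to_numpy(), labels.to_numpy())
        )
    manifest["n_subtypes"] = int(result_meta["chosen_k"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


@_stage("network")
def _network_stage(config, outdir, manifest, normal_expr, resume):
    net_path = outdir / "background_network.tsv"
    if resume and net_path.exists():
        net = load_edge_list(net_path)
    else:
        raw = load_edge_list(config.network_path)
        net = filter_to_genes(raw, set(normal_expr.index))
        write_edge_list(net, net_path)
    fit = degree_powerlaw_fit(net)
    pd.DataFrame({"degree": fit.degree_values, "count": fit.counts}).to_csv(
        outdir / "degree_distribution.tsv", sep="\t", index=False
    )
    diag = {"n_edges": net.n_edges, "n_genes": net.n_genes, "r_squared": fit.r_squared}
    (outdir / "network_diagnostics.json").write_text(json.dumps(diag, indent=1))
    manifest["stages"]["network"] = diag
    return net


@_stage("perturb")
def _perturb_stage(config, outdir, manifest, net, normal_expr, tumor_expr, resume):
    groups = pd.Series(
        ["normal"] * normal_expr.shape[1] + ["tumor"] * tumor_expr.shape[1],
        index=list(normal_expr.columns) + list(tumor_expr.columns),
        name="group",
    )
    pert_path = outdir / "edge_perturbation.tsv"
    if resume and pert_path.exists():
        pert = eio.read_matrix(pert_path)
    else:
        expr = pd.concat([normal_expr, tumor_expr], axis=1)
        ranks = rank_transform(expr)
        delta = delta_rank(ranks, net)
        bench = benchmark_vector(normal_expr, net)
        pert = edge_perturbation(delta, bench)
        eio.write_matrix(pert, pert_path, index_label="edge_id")
        bench.rename_axis("edge_id").to_frame().to_csv(outdir / "benchmark.tsv", sep="\t")
    n_edges = pert.shape[0]
    report, sampled = dispersion_report(
        pert,
        groups,
        n_sample_edges=min(config.n_sample_edges, n_edges),
        seed=config.seed,
        return_sampled=True,
    )
    (outdir / "dispersion.json").write_text(report.to_json())
    sampled.to_csv(outdir / "sampled_perturbations.tsv", sep="\t", index=False)
    groups.rename_axis("sample_id").to_frame().to_csv(outdir / "groups.tsv", sep="\t")
    if config.plots:
        from .plotting import plot_dispersion_violin

        plot_dispersion_violin(sampled, outdir / "dispersion_violin.png")
    manifest["stages"]["perturb"] = {
        "n_edges": int(pert.shape[0]),
        "n_samples": int(pert.shape[1]),
        **json.loads(report.to_json()),
    }
    return pert, groups


@_stage("subtype")
def _subtype_stage(config, outdir, manifest, pert, groups, resume):
    labels_path = outdir / "subtype_labels.tsv"
    cancer_path = outdir / "cancer_matrix.tsv"
    meta_path = outdir / "subtype_metadata.json"
    if resume and labels_path.exists() and cancer_path.exists() and meta_path.exists():
        labels = eio.read_labels(labels_path)
        cancer_matrix = eio.read_matrix(cancer_path)
        meta = json.loads(meta_path.read_text())
        manifest["stages"]["subtype"] = meta
        return cancer_matrix, labels, meta

    selection = select_feature_edges(
        pert, groups, top_k=config.top_k, alpha=config.alpha, adjust=config.adjust_pvalues
    )
    cancer_matrix = selection.cancer_matrix
    eio.write_matrix(cancer_matrix, cancer_path, index_label="edge_id")
    stats_table = pd.DataFrame(
        {
            "kw_pvalue": selection.kw_pvalues,
            "adjusted_pvalue": selection.adjusted_pvalues,
            "tumor_sd": selection.sds,
            "selected": selection.kw_pvalues.index.isin(selection.selected_edges),
        }
    )
    stats_table.rename_axis("edge_id").to_csv(outdir / "feature_edges.tsv", sep="\t")

    result = consensus_cluster(
        cancer_matrix,
        k_min=config.k_min,
        k_max=config.k_max,
        n_resamples=config.n_resamples,
        sample_fraction=config.sample_fraction,
        seed=config.seed,
        elbow_threshold=config.elbow_threshold,
        k=config.k_override,
    )
    for kk, cm in result.consensus_matrices.items():
        eio.write_matrix(cm, outdir / f"consensus_k{kk}.tsv", index_label="sample_id")
    result.summary_table().to_csv(outdir / "cdf_delta_area.tsv", sep="\t", index=False)
    labels = result.labels
    eio.write_labels(labels, labels_path)
    meta = {
        "seed": config.seed,
        "n_feature_edges": int(cancer_matrix.shape[0]),
        "n_tumor_samples": int(cancer_matrix.shape[1]),
        "chosen_k": int(result.chosen_k),
        "subtype_sizes": {str(k): int(v) for k, v in result.subtype_sizes.items()},
        "delta_area": {str(k): result.delta_area[k] for k in result.k_values},
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    if config.plots:
        from .plotting import plot_consensus_cdf, plot_delta_area

        plot_consensus_cdf(result, outdir / "consensus_cdf.png")
        plot_delta_area(result, outdir / "delta_area.png")
    manifest["stages"]["subtype"] = meta
    return cancer_matrix, labels, meta


@_stage("subnet")
def _subnet_stage(config, outdir, manifest, cancer_matrix, labels):
    z = zscore_rows(cancer_matrix)
    n_clusters = min(config.n_clusters, z.shape[0])
    clusters = cluster_edges(z, n_clusters=n_clusters, min_edges=config.min_edges)
    clusters.cluster_ids.rename_axis("edge_id").to_frame().to_csv(
        outdir / "edge_clusters.tsv", sep="\t"
    )
    summary = {}
    for subtype in sorted(labels.unique()):
        snet = perturbed_clusters(
            z, clusters, labels, subtype, z_cut=config.z_cut, edge_frac=config.edge_frac
        )
        prefix = outdir / f"subtype_{subtype}"
        with open(f"{prefix}_network.tsv", "w") as fh:
            for eid in snet.edges:
                a, b = eid.split("|", 1)
                fh.write(f"{a}\t{b}\n")
        snet.degrees.rename_axis("gene").to_frame().to_csv(f"{prefix}_degrees.tsv", sep="\t")
        hubs = top_degree_genes(snet, config.n_hub_genes) if snet.n_edges else []
        summary[str(subtype)] = {
            "n_edges": snet.n_edges,
            "n_genes": len(snet.genes),
            "perturbed_clusters": list(snet.perturbed_cluster_ids),
            "hub_genes": hubs,
        }
    (outdir / "subtype_networks.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest["stages"]["subnet"] = {
        "n_retained_clusters": len(clusters.retained_ids),
        "networks": summary,
    }
    return summary
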