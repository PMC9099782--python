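"""Synthetic cohorts with known subtype ground truth.

The generator emulates the statistical structure the edge-perturbation
analysis assumes: a scale-free background network (preferential
attachment), a normal cohort whose within-sample gene ranking is stable up
to small noise around a shared base profile, and a tumor cohort with larger
rank noise plus K planted subtypes.  Each subtype owns a disjoint block of
edges; the subtype's samples receive systematic log-scale shifts on the
block's anchor genes so the relative ordering of the block's gene pairs is
flipped, which is exactly the signal the perturbation statistic measures.

Blocks are built as *all* edges incident to a claimed set of anchor genes,
with gene neighbourhoods disjoint across subtypes; every edge that can
perturb under one subtype's shifts therefore belongs to that subtype's
block, making precision/recall of network recovery well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import BackgroundNetwork, write_edge_list

__all__ = ["CohortParams", "SyntheticCohort", "generate_network", "generate_cohort", "write_cohort"]


def generate_network(n_genes: int, attach_m: int = 2, seed: int | None = None) -> BackgroundNetwork:
    """Scale-free background network via preferential attachment.

    Nodes are labelled G0001.. in construction order; with ``attach_m=1``
    the result is a tree on ``n_genes`` nodes (n_genes − 1 edges).
    """
    if not (n_genes > attach_m >= 1):
        raise ValueError(f"need n_genes > attach_m >= 1, got {n_genes}, {attach_m}")
    graph = nx.barabasi_albert_graph(n_genes, attach_m, seed=seed)
    width = max(4, len(str(n_genes)))
    names = {i: f"G{i + 1:0{width}d}" for i in graph.nodes}
    return BackgroundNetwork.from_pairs(
        (names[a], names[b]) for a, b in graph.edges
    )


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration.

    Noise SDs and the perturbation shift are on the log2-expression scale.
    Defaults reflect the study conditions the package is validated under:
    a ~2000-edge scale-free network over 1000 genes, 60 normal samples with
    small rank noise, and 4 tumor subtypes of 20 samples each whose edge
    blocks are shifted by 1.5 log2 units against tumor noise of 1.0.
    """

    n_genes: int = 1000
    attach_m: int = 2
    n_normal: int = 60
    k_subtypes: int = 4
    n_per_subtype: int = 20
    normal_noise_sd: float = 0.3
    tumor_noise_sd: float = 1.0
    perturb_shift: float = 1.5
    block_edges: int = 80
    base_loc: float = 6.0
    base_df: float = 3.0
    seed: int = 0


@dataclass
class SyntheticCohort:
    """A generated study: network, cohorts, and planted ground truth."""

    network: BackgroundNetwork
    normal_expr: pd.DataFrame  # genes × samples
    tumor_expr: pd.DataFrame  # genes × samples
    true_labels: pd.Series  # tumor sample -> subtype 1..K
    true_perturbed_edges: dict[int, tuple[str, ...]]
    params: CohortParams = field(default_factory=CohortParams)

    @property
    def groups(self) -> pd.Series:
        """Per-sample 'normal'/'tumor' labels over both cohorts."""
        g = {s: "normal" for s in self.normal_expr.columns}
        g.update({s: "tumor" for s in self.tumor_expr.columns})
        return pd.Series(g, name="group")

    @property
    def expression(self) -> pd.DataFrame:
        return pd.concat([self.normal_expr, self.tumor_expr], axis=1)


def _plant_edge_blocks(
    net: BackgroundNetwork,
    k_subtypes: int,
    block_edges: int,
    rng: np.random.Generator,
    degree_cap: int = 6,
) -> tuple[list[set[str]], list[list[str]], list[set[tuple[str, str]]]]:
    """Pick per-subtype core gene sets and their incident-edge blocks.

    Every gene in a subtype's core receives the log-scale shift; the
    subtype's block is *all* edges incident to its core, so the set of
    edges that can perturb under the shifts coincides with the block.
    Cores of different subtypes are kept non-adjacent (a gene and its
    neighbours are claimed once), which makes the blocks edge-disjoint.
    Low-degree genes are preferred as core seeds: a block anchored on a
    hub would rise and fall with a single gene's rank, whereas many small
    cores give the subtype a signature spread over many genes.
    """
    adj: dict[str, set[str]] = {g: set() for g in net.genes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)

    shuffled = list(rng.permutation(np.array(net.genes, dtype=object)))
    order = sorted(shuffled, key=lambda g: len(adj[g]))
    claimed: set[str] = set()  # foreign cores plus their neighbour rings
    cores: list[set[str]] = []
    anchor_lists: list[list[str]] = []
    blocks: list[set[tuple[str, str]]] = []
    for _ in range(k_subtypes):
        core: set[str] = set()
        block: set[tuple[str, str]] = set()
        anchors: list[str] = []
        for g in order:
            if len(block) >= block_edges:
                break
            cand = {g} | adj[g]
            if cand & claimed:
                continue
            if max(len(adj[c]) for c in cand) > degree_cap:
                continue  # hubs stay out of cores: one hub rank would drive a whole block
            anchors.append(g)
            core |= cand
            for c in cand:
                for nbr in adj[c]:
                    if nbr in core or c in core:
                        block.add((c, nbr) if c < nbr else (nbr, c))
        if len(block) < block_edges:
            raise ValueError(
                f"cannot plant {k_subtypes} disjoint blocks of {block_edges} "
                f"edges in a {net.n_edges}-edge network"
            )
        # re-derive the block as all edges incident to the final core
        block = {
            (c, n) if c < n else (n, c) for c in core for n in adj[c]
        }
        claimed |= core | {n for c in core for n in adj[c]}
        cores.append(core)
        anchor_lists.append(anchors)
        blocks.append(block)
    return cores, anchor_lists, blocks


def generate_cohort(params: CohortParams | None = None, **overrides) -> SyntheticCohort:
    """Generate a full synthetic study from a single seed."""
    if params is None:
        params = CohortParams(**overrides)
    elif overrides:
        params = CohortParams(**{**asdict(params), **overrides})
    p = params
    if p.k_subtypes < 2:
        raise ValueError("k_subtypes must be >= 2")
    if p.n_per_subtype < 5:
        raise ValueError("n_per_subtype must be >= 5")
    if p.perturb_shift < 0:
        raise ValueError("perturb_shift must be >= 0")

    rng = np.random.default_rng(p.seed)
    net_seed = int(rng.integers(2**31))
    net = generate_network(p.n_genes, p.attach_m, seed=net_seed)
    genes = list(net.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    cores, anchor_lists, blocks = _plant_edge_blocks(net, p.k_subtypes, p.block_edges, rng)

    # heavy-tailed base log2-expression profile shared by all samples
    base = p.base_loc + rng.standard_t(df=p.base_df, size=len(genes))

    # per-subtype shift vectors: each anchor moves toward (past) the median
    # of its neighbours and the neighbours move the opposite way, so the
    # endpoints of a block edge are displaced against each other by twice
    # the shift and their relative ordering flips
    adj: dict[str, set[str]] = {g: set() for g in genes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    shift_vecs = np.zeros((p.k_subtypes, len(genes)))
    for k, (core, anchors) in enumerate(zip(cores, anchor_lists)):
        directions: dict[str, float] = {}
        for g in anchors:
            nbr_base = np.array([base[gene_pos[n]] for n in adj[g]])
            d = 1.0 if base[gene_pos[g]] < np.median(nbr_base) else -1.0
            directions.setdefault(g, d)
            for x in adj[g]:
                directions.setdefault(x, -d)
        for g in sorted(core):
            shift_vecs[k, gene_pos[g]] = directions.get(g, 0.0) * p.perturb_shift

    def _tpm_like(log2_matrix: np.ndarray) -> np.ndarray:
        expr = np.power(2.0, log2_matrix)
        return expr * (1e6 / expr.sum(axis=0, keepdims=True))

    n_width = max(3, len(str(p.n_normal)))
    normal_ids = [f"N{i + 1:0{n_width}d}" for i in range(p.n_normal)]
    normal_log = base[:, None] + rng.normal(0.0, p.normal_noise_sd, (len(genes), p.n_normal))
    normal_expr = pd.DataFrame(_tpm_like(normal_log), index=genes, columns=normal_ids)

    n_tumor = p.k_subtypes * p.n_per_subtype
    t_width = max(3, len(str(n_tumor)))
    tumor_ids = [f"T{i + 1:0{t_width}d}" for i in range(n_tumor)]
    labels = np.repeat(np.arange(1, p.k_subtypes + 1), p.n_per_subtype)
    tumor_log = base[:, None] + rng.normal(0.0, p.tumor_noise_sd, (len(genes), n_tumor))
    for s in range(n_tumor):
        tumor_log[:, s] += shift_vecs[labels[s] - 1]
    tumor_expr = pd.DataFrame(_tpm_like(tumor_log), index=genes, columns=tumor_ids)

    true_labels = pd.Series(labels, index=tumor_ids, name="subtype")
    true_edges = {
        k + 1: tuple(sorted(f"{a}|{b}" for a, b in blocks[k]))
        for k in range(p.k_subtypes)
    }
    return SyntheticCohort(
        network=net,
        normal_expr=normal_expr,
        tumor_expr=tumor_expr,
        true_labels=true_labels,
        true_perturbed_edges=true_edges,
        params=p,
    )


def generate_planted_perturbations(
    n_edges: int = 1400,
    k_subtypes: int = 4,
    n_per_subtype: int = 20,
    block_edges: int = 100,
    shift: float = 1.5,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[int, tuple[str, ...]]]:
    """Perturbation-space benchmark for subtype-network extraction.

    Returns an edges × tumor-samples matrix of planted perturbations: unit
    Gaussian noise with each subtype's edge block shifted by ``shift``
    standard deviations in that subtype's samples, plus the sample labels
    and the planted block membership.  The default dimensions mirror a
    selected feature-edge matrix of ~1400 rows, where a 100-cluster cut
    with a 30-edge retention rule is meaningful (about 14 edges per
    cluster).
    """
    if block_edges * k_subtypes > n_edges:
        raise ValueError("planted blocks exceed available edges")
    rng = np.random.default_rng(seed)
    n_samples = k_subtypes * n_per_subtype
    labels = pd.Series(
        np.repeat(np.arange(1, k_subtypes + 1), n_per_subtype),
        index=[f"T{i + 1:03d}" for i in range(n_samples)],
        name="subtype",
    )
    width = len(str(n_edges))
    edge_ids = [f"GA{i + 1:0{width}d}|GB{i + 1:0{width}d}" for i in range(n_edges)]
    values = rng.normal(0.0, noise_sd, (n_edges, n_samples))
    blocks: dict[int, tuple[str, ...]] = {}
    for k in range(1, k_subtypes + 1):
        rows = np.arange((k - 1) * block_edges, k * block_edges)
        cols = np.flatnonzero(labels.to_numpy() == k)
        values[np.ix_(rows, cols)] += shift * noise_sd
        blocks[k] = tuple(edge_ids[i] for i in rows)
    matrix = pd.DataFrame(values, index=edge_ids, columns=labels.index)
    return matrix, labels, blocks


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the TSV/JSON formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "normal_expr": outdir / "normal_expr.tsv",
        "tumor_expr": outdir / "tumor_expr.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.json",
    }
    write_edge_list(cohort.network, paths["network"])
    cohort.normal_expr.to_csv(paths["normal_expr"], sep="\t", float_format="%.6g")
    cohort.tumor_expr.to_csv(paths["tumor_expr"], sep="\t", float_format="%.6g")
    cohort.groups.rename_axis("sample_id").to_frame().to_csv(paths["groups"], sep="\t")
    truth = {
        "labels": cohort.true_labels.to_dict(),
        "perturbed_edges": {str(k): list(v) for k, v in cohort.true_perturbed_edges.items()},
        "params": asdict(cohort.params),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
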