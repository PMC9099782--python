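"""Subtype-specific perturbed networks and hub genes.

Feature-edge perturbations are row-standardised (Z-scores), edges are
grouped by complete-linkage hierarchical clustering, and a cluster counts as
perturbed for a subtype when a large majority of its edges have a strong
mean standardised perturbation in that subtype's samples.  The union of
perturbed clusters' edges is the subtype-specific network; its highest-
degree genes are the subtype's hub (feature) genes.  An optional local
hypergeometric test scores gene-set enrichment of those genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscore_rows",
    "cluster_edges",
    "EdgeClusterSet",
    "perturbed_clusters",
    "SubtypeNetwork",
    "top_degree_genes",
    "hypergeometric_enrichment",
    "read_gmt",
]


def zscore_rows(cancer_matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each row to mean 0, variance 1 (population SD).

    Constant rows carry no perturbation contrast and are set to all zeros
    (with a warning) rather than dividing by zero.
    """
    if cancer_matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = cancer_matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) set to all-zero z-scores",
            stacklevel=2,
        )
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=cancer_matrix.index, columns=cancer_matrix.columns)


@dataclass(frozen=True)
class EdgeClusterSet:
    """Flat clustering of feature edges with size-filtered retention."""

    cluster_ids: pd.Series  # edge_id -> cluster label (1..n_clusters)
    retained_ids: tuple[int, ...]
    min_edges: int

    def members(self, cluster_id: int) -> list[str]:
        return list(self.cluster_ids.index[self.cluster_ids == cluster_id])


def cluster_edges(
    z: pd.DataFrame, n_clusters: int = 100, min_edges: int = 30
) -> EdgeClusterSet:
    """Complete-linkage clustering of Z-score rows into flat edge clusters.

    Euclidean distance on standardised rows; the tree is cut into
    ``n_clusters`` flat clusters and only clusters with strictly more than
    ``min_edges`` edges are retained for the perturbed-cluster rule.
    """
    if z.shape[0] < n_clusters:
        raise ValueError(
            f"need at least n_clusters={n_clusters} feature edges, got {z.shape[0]}"
        )
    tree = linkage(z.to_numpy(float), method="complete", metric="euclidean")
    flat = fcluster(tree, t=n_clusters, criterion="maxclust")
    cluster_ids = pd.Series(flat, index=z.index, name="cluster")
    sizes = cluster_ids.value_counts()
    retained = tuple(sorted(int(c) for c in sizes.index[sizes > min_edges]))
    return EdgeClusterSet(cluster_ids=cluster_ids, retained_ids=retained, min_edges=min_edges)


def _edge_endpoints(edge_id: str) -> tuple[str, str]:
    a, b = edge_id.split("|", 1)
    return a, b


@dataclass(frozen=True)
class SubtypeNetwork:
    """Perturbed-edge network specific to one subtype."""

    subtype: int | str
    edges: tuple[str, ...]
    genes: tuple[str, ...]
    degrees: pd.Series  # gene -> degree within this network
    perturbed_cluster_ids: tuple[int, ...]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def perturbed_clusters(
    z: pd.DataFrame,
    clusters: EdgeClusterSet,
    labels: pd.Series,
    subtype: int | str,
    z_cut: float = 0.5,
    edge_frac: float = 0.70,
) -> SubtypeNetwork:
    """Extract the subtype-specific network from retained edge clusters.

    For each retained cluster, the mean Z over the subtype's samples is
    taken per edge; the cluster is perturbed for the subtype when the
    fraction of its edges with |mean Z| > ``z_cut`` strictly exceeds
    ``edge_frac``.  All edges of all perturbed clusters form the network.
    """
    labels = labels.reindex(z.columns)
    sub_cols = labels.index[labels == subtype]
    if len(sub_cols) == 0:
        raise ValueError(f"subtype {subtype!r} not present in labels")
    if len(sub_cols) < 2:
        raise ValueError(f"subtype {subtype!r} has <2 samples; mean unstable")

    mean_z = z[sub_cols].mean(axis=1)
    perturbed: list[int] = []
    edge_ids: list[str] = []
    for cid in clusters.retained_ids:
        members = clusters.members(cid)
        frac = float((mean_z.loc[members].abs() > z_cut).mean())
        if frac > edge_frac:
            perturbed.append(cid)
            edge_ids.extend(members)

    edge_ids = sorted(edge_ids)
    deg: dict[str, int] = {}
    for eid in edge_ids:
        a, b = _edge_endpoints(eid)
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    genes = tuple(sorted(deg))
    degrees = pd.Series(deg, name="degree").sort_index() if deg else pd.Series(
        dtype=int, name="degree"
    )
    return SubtypeNetwork(
        subtype=subtype,
        edges=tuple(edge_ids),
        genes=genes,
        degrees=degrees,
        perturbed_cluster_ids=tuple(perturbed),
    )


def top_degree_genes(snet: SubtypeNetwork, n: int = 10) -> list[str]:
    """Hub genes: the ``n`` highest-degree genes of a subtype network.

    Sorted by degree descending, ties broken lexicographically.
    """
    if snet.n_edges == 0:
        raise ValueError("subtype network is empty")
    order = sorted(snet.degrees.index, key=lambda g: (-int(snet.degrees[g]), g))
    return order[:n]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <TAB> description <TAB> genes..."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            gene_sets[fields[0]] = {g for g in fields[2:] if g}
    return gene_sets


def hypergeometric_enrichment(
    genes: list[str] | set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric gene-set enrichment with BH correction.

    For each set, P(X >= overlap) where X ~ Hypergeom(N=|background|,
    K=|set ∩ background|, n=|query|).  Query genes must lie within the
    background; gene sets are intersected with it.  Returns a table sorted
    by p-value with columns set, set_size, overlap, pvalue, qvalue.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    query = set(genes)
    outside = query - background
    if outside:
        raise ValueError(
            f"{len(outside)} query gene(s) not in background, e.g. "
            f"{sorted(outside)[:5]}"
        )
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        members = members & background
        overlap = len(query & members)
        # survival function at overlap-1 gives P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_query))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"])
    if len(table):
        table["qvalue"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["pvalue", "set"], kind="stable").reset_index(drop=True)
    else:
        table["qvalue"] = []
    return table
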