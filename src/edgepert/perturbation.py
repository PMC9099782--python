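"""Rank transforms, delta ranks, and the edge-perturbation matrix.

The core per-sample statistic.  Within each sample, genes are ranked by
expression (rank 1 = lowest, average ranks on ties).  For an edge e = (i, j)
in canonical orientation, the delta rank in sample s is

    delta[e, s] = r[i, s] - r[j, s]

The benchmark delta-rank vector is the delta rank of the ranking of the
*mean* normal expression profile; the edge perturbation is the zero-centred
deviation from it:

    pert[e, s] = delta[e, s] - benchmark[e]

A sample whose gene ranking reproduces the benchmark ranking on every edge
has an all-zero perturbation column.  Because ranks are invariant under any
strictly increasing within-sample transform, the whole pipeline is
insensitive to monotone rescaling such as TPM normalisation constants.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .network import BackgroundNetwork

__all__ = [
    "rank_transform",
    "delta_rank",
    "benchmark_vector",
    "edge_perturbation",
    "dispersion_report",
    "DispersionReport",
    "EdgePerturbation",
]


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if not expr.index.is_unique:
        raise ValueError("gene identifiers are not unique")
    if not expr.columns.is_unique:
        raise ValueError("sample identifiers are not unique")


def rank_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Within-sample rank matrix of a genes × samples expression matrix.

    Ranks ascend with expression (lowest value → rank 1, highest → G);
    ties receive the average of their would-be ranks, so each column sums
    to G(G+1)/2 regardless of ties.
    """
    _check_expression(expr)
    if expr.shape[0] < 2:
        raise ValueError("rank transform needs at least 2 genes")
    ranks = stats.rankdata(expr.to_numpy(float), method="average", axis=0)
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def _edge_indices(net: BackgroundNetwork, gene_index: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in net.genes if g not in gene_index]
    if missing:
        shown = ", ".join(missing[:10])
        more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
        raise ValueError(f"network genes missing from expression matrix: {shown}{more}")
    pos = {g: k for k, g in enumerate(gene_index)}
    ii = np.fromiter((pos[a] for a, _ in net.edges), dtype=np.intp, count=net.n_edges)
    jj = np.fromiter((pos[b] for _, b in net.edges), dtype=np.intp, count=net.n_edges)
    return ii, jj


def delta_rank(ranks: pd.DataFrame, net: BackgroundNetwork) -> pd.DataFrame:
    """Delta-rank matrix (edges × samples): r_i − r_j per canonical edge."""
    ii, jj = _edge_indices(net, ranks.index)
    r = ranks.to_numpy(float)
    delta = r[ii, :] - r[jj, :]
    return pd.DataFrame(delta, index=net.edge_ids, columns=ranks.columns)


def benchmark_vector(normal_expr: pd.DataFrame, net: BackgroundNetwork) -> pd.Series:
    """Benchmark delta-rank vector from a normal reference cohort.

    The per-gene mean expression over normal samples is ranked (same tie
    convention as :func:`rank_transform`) and the delta rank of that single
    reference ranking is taken per edge.
    """
    _check_expression(normal_expr)
    if normal_expr.shape[1] < 1:
        raise ValueError("benchmark needs at least one normal sample")
    mean_expr = normal_expr.mean(axis=1)
    ref_rank = stats.rankdata(mean_expr.to_numpy(float), method="average")
    ii, jj = _edge_indices(net, normal_expr.index)
    bench = ref_rank[ii] - ref_rank[jj]
    return pd.Series(bench, index=net.edge_ids, name="benchmark")


def edge_perturbation(delta: pd.DataFrame, bench: pd.Series) -> pd.DataFrame:
    """Edge-perturbation matrix: delta rank minus the benchmark, per edge."""
    if delta.shape[0] != len(bench):
        raise ValueError(
            f"edge count mismatch: delta has {delta.shape[0]} rows, "
            f"benchmark has {len(bench)}"
        )
    if not np.array_equal(delta.index.to_numpy(), bench.index.to_numpy()):
        raise ValueError("edge order of delta matrix and benchmark differ")
    return delta.sub(bench, axis=0)


@dataclass(frozen=True)
class DispersionReport:
    """Normal-vs-tumor perturbation dispersion summary.

    ``frac_edges_more_dispersed_in_tumor`` counts edges whose group-size-
    normalised sum of |perturbation| is strictly larger in the tumor group.
    ``sampled_edge_test_p`` is a two-sided Wilcoxon rank-sum p-value on the
    pooled |perturbation| values of ``n_sampled_edges`` randomly sampled
    edges.
    """

    mean_abs_normal: float
    mean_abs_tumor: float
    frac_edges_more_dispersed_in_tumor: float
    sampled_edge_test_p: float
    n_sampled_edges: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def dispersion_report(
    pert: pd.DataFrame,
    groups: pd.Series,
    n_sample_edges: int = 1000,
    seed: int | None = None,
    return_sampled: bool = False,
):
    """Compare perturbation dispersion between normal and tumor cohorts.

    Parameters
    ----------
    pert : DataFrame, edges × samples
    groups : Series indexed by sample id with values 'normal' / 'tumor'
    n_sample_edges : number of edges sampled (without replacement) for the
        rank-sum test; capped at the number of edges.
    seed : RNG seed for edge sampling.
    return_sampled : also return a DataFrame of log2(|Δ|+1)-transformed
        sampled values (columns: edge_id, sample_id, group, log2_abs_pert)
        for plotting.
    """
    groups = groups.reindex(pert.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    normal_cols = groups[groups == "normal"].index
    tumor_cols = groups[groups == "tumor"].index
    if len(normal_cols) == 0 or len(tumor_cols) == 0:
        raise ValueError("both normal and tumor groups must be nonempty")
    if n_sample_edges > pert.shape[0]:
        raise ValueError(
            f"cannot sample {n_sample_edges} edges from {pert.shape[0]}"
        )

    abs_n = pert[normal_cols].abs().to_numpy()
    abs_t = pert[tumor_cols].abs().to_numpy()
    mean_abs_normal = float(abs_n.mean())
    mean_abs_tumor = float(abs_t.mean())
    # per-edge dispersion, normalised by group size so unequal cohort sizes
    # cannot drive the comparison
    disp_n = abs_n.sum(axis=1) / abs_n.shape[1]
    disp_t = abs_t.sum(axis=1) / abs_t.shape[1]
    frac = float(np.mean(disp_t > disp_n))

    rng = np.random.default_rng(seed)
    idx = rng.choice(pert.shape[0], size=n_sample_edges, replace=False)
    idx = np.sort(idx)
    pooled_n = abs_n[idx, :].ravel()
    pooled_t = abs_t[idx, :].ravel()
    # Wilcoxon rank-sum with tie correction (perturbations are rank
    # differences, hence heavily tied)
    p = float(stats.mannwhitneyu(pooled_t, pooled_n, alternative="two-sided").pvalue)

    report = DispersionReport(
        mean_abs_normal=mean_abs_normal,
        mean_abs_tumor=mean_abs_tumor,
        frac_edges_more_dispersed_in_tumor=frac,
        sampled_edge_test_p=p,
        n_sampled_edges=int(n_sample_edges),
    )
    if not return_sampled:
        return report

    edge_ids = pert.index.to_numpy()[idx]
    frames = []
    for cols, arr, label in ((normal_cols, abs_n, "normal"), (tumor_cols, abs_t, "tumor")):
        sub = np.log2(arr[idx, :] + 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "edge_id": np.repeat(edge_ids, len(cols)),
                    "sample_id": np.tile(cols.to_numpy(), len(idx)),
                    "group": label,
                    "log2_abs_pert": sub.ravel(),
                }
            )
        )
    return report, pd.concat(frames, ignore_index=True)


class EdgePerturbation(TransformerMixin, BaseEstimator):
    """Transformer computing edge perturbations against a normal reference.

    Follows the sklearn convention: X is samples × genes.  ``fit`` learns
    the benchmark delta-rank vector from a normal reference cohort;
    ``transform`` maps any cohort to its samples × edges perturbation
    matrix.

    Parameters
    ----------
    network : BackgroundNetwork
        Background gene-interaction network (canonical edges).

    Attributes
    ----------
    benchmark_ : ndarray of shape (n_edges,)
        Benchmark delta-rank vector.
    edge_ids_ : list of str
        Edge identifiers, ``GENEI|GENEJ``.
    feature_names_in_ : ndarray
        Gene symbols seen in fit.
    """

    def __init__(self, network: BackgroundNetwork):
        self.network = network

    def fit(self, X: pd.DataFrame, y=None) -> "EdgePerturbation":
        X = self._as_frame(X)
        bench = benchmark_vector(X.T, self.network)
        self.benchmark_ = bench.to_numpy()
        self.edge_ids_ = list(bench.index)
        self.feature_names_in_ = X.columns.to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "benchmark_"):
            raise RuntimeError("EdgePerturbation must be fitted before transform")
        X = self._as_frame(X)
        ranks = rank_transform(X.T)
        delta = delta_rank(ranks, self.network)
        pert = delta.sub(pd.Series(self.benchmark_, index=self.edge_ids_), axis=0)
        return pert.T

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.edge_ids_, dtype=object)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError(
            "EdgePerturbation expects a samples × genes DataFrame with gene "
            "symbols as columns"
        )
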