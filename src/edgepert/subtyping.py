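"""Feature-edge selection and consensus-clustering subtype discovery.

Feature edges are those whose perturbation values differ between tumor and
normal cohorts (Kruskal–Wallis test, BH-adjusted), ranked by the standard
deviation of their tumor-sample perturbations.  Tumor samples are then
partitioned by consensus clustering of the selected-edge submatrix: repeated
subsampling of samples, hierarchical clustering of each subsample, and a
consensus matrix recording how often each pair of samples co-clusters when
co-subsampled.  The number of subtypes k is chosen from the CDF of consensus
values via the relative change in its area (delta area).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis_rows",
    "select_feature_edges",
    "FeatureSelectionResult",
    "KruskalWallisEdgeSelector",
    "consensus_cluster",
    "ConsensusResult",
    "ConsensusClustering",
]


def kruskal_wallis_rows(values: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Row-wise two-group Kruskal–Wallis p-values, vectorised.

    ``values`` is edges × samples; ``group_mask`` a boolean vector marking
    one group.  Uses the tie-corrected H statistic against the chi-squared
    distribution with 1 degree of freedom (the scipy.stats.kruskal
    convention).  Rows where every value is tied get p = 1.
    """
    values = np.asarray(values, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    n = values.shape[1]
    n1 = int(group_mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")

    ranks = stats.rankdata(values, method="average", axis=1)
    r1 = ranks[:, group_mask].sum(axis=1)
    r2 = ranks[:, ~group_mask].sum(axis=1)
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / n2) - 3.0 * (n + 1)

    # tie correction per row: 1 - sum(t^3 - t) / (n^3 - n)
    srt = np.sort(values, axis=1)
    new_run = np.ones_like(srt, dtype=bool)
    new_run[:, 1:] = srt[:, 1:] != srt[:, :-1]
    tie_term = np.empty(values.shape[0])
    for i in range(values.shape[0]):  # run-length encode each sorted row
        starts = np.flatnonzero(new_run[i])
        t = np.diff(np.append(starts, n)).astype(float)
        tie_term[i] = np.sum(t**3 - t)
    correction = 1.0 - tie_term / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = h / correction
    pvals = stats.chi2.sf(h, df=1)
    pvals[correction <= 0] = 1.0  # fully tied row: no evidence
    return pvals


@dataclass(frozen=True)
class FeatureSelectionResult:
    """Outcome of Kruskal–Wallis + SD feature-edge selection."""

    selected_edges: tuple[str, ...]
    kw_pvalues: pd.Series
    adjusted_pvalues: pd.Series
    sds: pd.Series
    cancer_matrix: pd.DataFrame  # selected edges × tumor samples


def select_feature_edges(
    pert: pd.DataFrame,
    groups: pd.Series,
    top_k: int = 30000,
    alpha: float = 0.05,
    adjust: bool = True,
) -> FeatureSelectionResult:
    """Select tumor-discriminative, high-variance feature edges.

    Per edge, a Kruskal–Wallis test compares tumor vs normal perturbation
    values; p-values are BH-adjusted across edges (set ``adjust=False`` to
    filter on raw p).  Among edges significant at ``alpha``, the ``top_k``
    with the largest standard deviation of tumor perturbations are kept
    (ties broken lexicographically by edge id for determinism).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    groups = groups.reindex(pert.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    tumor_mask = (groups == "tumor").to_numpy()
    if tumor_mask.sum() == 0 or (~tumor_mask).sum() == 0:
        raise ValueError("both normal and tumor groups must be nonempty")

    values = pert.to_numpy(float)
    pvals = pd.Series(kruskal_wallis_rows(values, tumor_mask), index=pert.index)
    if adjust:
        adj = pd.Series(
            multipletests(pvals.to_numpy(), method="fdr_bh")[1], index=pert.index
        )
    else:
        adj = pvals.copy()
    sds = pd.Series(values[:, tumor_mask].std(axis=1, ddof=0), index=pert.index)

    significant = adj.index[adj < alpha]
    if len(significant) == 0:
        raise ValueError(
            "no edges pass the significance filter; consider raising alpha "
            "or disabling adjustment"
        )
    order = sorted(significant, key=lambda e: (-sds[e], e))
    selected = tuple(order[:top_k])
    tumor_cols = pert.columns[tumor_mask]
    cancer_matrix = pert.loc[list(selected), tumor_cols]
    return FeatureSelectionResult(
        selected_edges=selected,
        kw_pvalues=pvals,
        adjusted_pvalues=adj,
        sds=sds,
        cancer_matrix=cancer_matrix,
    )


class KruskalWallisEdgeSelector(BaseEstimator):
    """Sklearn-style selector wrapping :func:`select_feature_edges`.

    X is samples × edges (the transposed perturbation matrix); y is the
    per-sample group label ('normal' / 'tumor').  ``transform`` returns the
    tumor rows restricted to the selected edges.
    """

    def __init__(self, top_k: int = 30000, alpha: float = 0.05, adjust: bool = True):
        self.top_k = top_k
        self.alpha = alpha
        self.adjust = adjust

    def fit(self, X: pd.DataFrame, y=None) -> "KruskalWallisEdgeSelector":
        if y is None:
            raise ValueError("KruskalWallisEdgeSelector requires group labels y")
        groups = pd.Series(np.asarray(y), index=X.index)
        result = select_feature_edges(
            X.T, groups, top_k=self.top_k, alpha=self.alpha, adjust=self.adjust
        )
        self.result_ = result
        self.selected_edges_ = list(result.selected_edges)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_edges_"):
            raise RuntimeError("selector must be fitted before transform")
        return X[self.selected_edges_]


@dataclass
class ConsensusResult:
    """Consensus-clustering output across the scanned k range."""

    k_values: tuple[int, ...]
    consensus_matrices: dict[int, pd.DataFrame]
    cdf_grid: np.ndarray
    cdfs: dict[int, np.ndarray]
    area_under_cdf: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int
    labels: pd.Series
    labels_per_k: dict[int, pd.Series] = field(default_factory=dict)

    @property
    def subtype_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.k_values),
                "area_under_cdf": [self.area_under_cdf[k] for k in self.k_values],
                "delta_area": [self.delta_area[k] for k in self.k_values],
                "pac": [self.pac[k] for k in self.k_values],
            }
        )


def _pearson_distance(columns: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation distance between columns (samples)."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(columns, rowvar=False)
    corr = np.nan_to_num(np.clip(corr, -1.0, 1.0), nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return dist


def _hier_labels(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    cancer_matrix: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    n_resamples: int = 1000,
    sample_fraction: float = 0.8,
    seed: int | None = None,
    linkage_method: str = "ward",
    elbow_threshold: float = 0.1,
    elbow_rel: float = 0.0,
    k: int | None = None,
) -> ConsensusResult:
    """Consensus clustering of samples (columns) of a feature matrix.

    For each candidate k, ``n_resamples`` subsamples of
    ``ceil(sample_fraction × n_samples)`` columns are clustered by
    hierarchical clustering (1 − Pearson correlation distance,
    ``linkage_method`` linkage; Ward by default, since average linkage
    peels outlier samples off as singletons at the k-cut and merges true
    groups) cut at k.  The consensus matrix entry for a
    sample pair is the fraction of co-subsampled runs in which the pair
    co-clusters.

    k is chosen by an automatic elbow rule: the largest k that (a) adds
    substantial CDF area — delta area above ``max(elbow_threshold,
    elbow_rel x max delta area over k >= 3)`` — and (b) does not increase
    clustering ambiguity, measured by the proportion of ambiguous
    consensus values PAC(k) = CDF(0.9) - CDF(0.1).  Splitting below the
    true cluster number resolves mixed clusters, so ambiguity falls and
    the area gain is large; splitting beyond it cuts a homogeneous
    cluster arbitrarily, which either adds little area (large true k) or
    raises ambiguity (small true k).  Requiring both conditions reads the
    elbow a delta-area plot shows visually.  Falls back to the delta-area
    maximiser for k >= 3 if nothing qualifies; pass ``k`` to override.
    Final labels come from hierarchical clustering of 1 - consensus at
    the chosen k.
    """
    n_samples = cancer_matrix.shape[1]
    if n_samples < k_max + 1:
        raise ValueError(
            f"need at least k_max+1={k_max + 1} samples, got {n_samples}"
        )
    if not np.isfinite(cancer_matrix.to_numpy(float)).all():
        raise ValueError("cancer matrix contains non-finite values")
    values = cancer_matrix.to_numpy(float)
    sample_ids = cancer_matrix.columns
    n_sub = int(np.ceil(sample_fraction * n_samples))
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 101)

    k_values = tuple(range(k_min, k_max + 1))
    consensus_matrices: dict[int, pd.DataFrame] = {}
    cdfs: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    labels_per_k: dict[int, pd.Series] = {}

    pac: dict[int, float] = {}
    for kk in k_values:
        together = np.zeros((n_samples, n_samples))
        co_sampled = np.zeros((n_samples, n_samples))
        for _ in range(n_resamples):
            if n_sub >= n_samples:
                idx = np.arange(n_samples)
            else:
                idx = np.sort(rng.choice(n_samples, size=n_sub, replace=False))
            sub = values[:, idx]
            labels = _hier_labels(_pearson_distance(sub), kk, linkage_method)
            ix = np.ix_(idx, idx)
            co_sampled[ix] += 1.0
            same = labels[:, None] == labels[None, :]
            together[ix] += same
        if np.any(co_sampled == 0):
            raise ValueError(
                "some sample pair was never co-subsampled; increase "
                "n_resamples or sample_fraction"
            )
        consensus = together / co_sampled
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        consensus_matrices[kk] = pd.DataFrame(
            consensus, index=sample_ids, columns=sample_ids
        )
        tri = consensus[np.triu_indices(n_samples, k=1)]
        cdf = np.array([(tri <= t).mean() for t in grid])
        cdfs[kk] = cdf
        areas[kk] = float(np.trapezoid(cdf, grid))
        pac[kk] = float(((tri > 0.1) & (tri < 0.9)).mean())
        labels_per_k[kk] = pd.Series(
            _hier_labels(1.0 - consensus, kk, linkage_method),
            index=sample_ids,
            name="subtype",
        )

    delta_area: dict[int, float] = {}
    for kk in k_values:
        if kk == k_values[0]:
            delta_area[kk] = areas[kk]
        else:
            prev = areas[kk - 1]
            delta_area[kk] = (areas[kk] - prev) / prev if prev > 0 else 0.0

    if k is not None:
        if k not in k_values:
            raise ValueError(f"override k={k} outside scanned range {k_values}")
        chosen = k
    else:
        high_k = [kk for kk in k_values if kk >= 3]
        rel_part = elbow_rel * max((delta_area[kk] for kk in high_k), default=0.0)
        threshold = max(elbow_threshold, rel_part)
        qualifying = [
            kk
            for kk in k_values
            if delta_area[kk] > threshold
            and (kk == k_values[0] or pac[kk] <= pac[kk - 1] + 1e-2)
        ]
        if qualifying:
            chosen = max(qualifying)
        else:
            candidates = high_k or list(k_values)
            chosen = max(candidates, key=lambda kk: delta_area[kk])

    return ConsensusResult(
        k_values=k_values,
        consensus_matrices=consensus_matrices,
        cdf_grid=grid,
        cdfs=cdfs,
        area_under_cdf=areas,
        delta_area=delta_area,
        pac=pac,
        chosen_k=chosen,
        labels=labels_per_k[chosen],
        labels_per_k=labels_per_k,
    )


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Sklearn-style consensus clusterer over samples.

    X is samples × features (e.g. tumor samples × selected edges).  After
    ``fit``, ``labels_`` holds the subtype of each sample, ``chosen_k_``
    the selected number of subtypes, and ``result_`` the full
    :class:`ConsensusResult` (consensus matrices, CDFs, delta areas).
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 10,
        n_resamples: int = 1000,
        sample_fraction: float = 0.8,
        linkage_method: str = "ward",
        elbow_threshold: float = 0.1,
        elbow_rel: float = 0.0,
        k: int | None = None,
        random_state: int | None = None,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_resamples = n_resamples
        self.sample_fraction = sample_fraction
        self.linkage_method = linkage_method
        self.elbow_threshold = elbow_threshold
        self.elbow_rel = elbow_rel
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None) -> "ConsensusClustering":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        result = consensus_cluster(
            X.T,
            k_min=self.k_min,
            k_max=self.k_max,
            n_resamples=self.n_resamples,
            sample_fraction=self.sample_fraction,
            seed=self.random_state,
            linkage_method=self.linkage_method,
            elbow_threshold=self.elbow_threshold,
            elbow_rel=self.elbow_rel,
            k=self.k,
        )
        self.result_ = result
        self.chosen_k_ = result.chosen_k
        self.labels_ = result.labels.to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
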