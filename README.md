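# edgepert

Sample-specific perturbation of gene–gene interaction edges, and
network-based tumor subtyping built on it.

Bulk expression values drift with time, batch and condition, but the
*relative ordering* of genes inside one sample is comparatively stable in
normal tissue and systematically disturbed in tumors.  `edgepert` measures
that disturbance per sample and per interaction: for each edge *e = (i, j)*
of a background gene-interaction network and each sample *s*,

    δ[e,s] = r[i,s] − r[j,s]          (within-sample rank difference)
    Δ[e,s] = δ[e,s] − δ̄[e]            (deviation from the normal benchmark)

where r[i,s] is the expression rank of gene *i* in sample *s* and δ̄ is the
delta rank of the ranking of mean normal expression.  The edges × samples
matrix Δ is a single-sample network-perturbation profile: zero wherever a
sample preserves the reference gene ordering, large where interactions are
rewired.  On top of Δ the package provides

- **network_io** — loading/merging/filtering SIF or two-column TSV edge
  lists into a canonical undirected network, with scale-free degree
  diagnostics (log-log OLS R²);
- **perturbation** — rank transform, benchmark, Δ, and normal-vs-tumor
  dispersion statistics (mean |Δ|, per-edge dispersion comparison,
  sampled-edge Wilcoxon rank-sum test);
- **subtyping** — Kruskal–Wallis + SD feature-edge selection and consensus
  clustering of tumor samples with automatic choice of the cluster number
  from the consensus CDF (delta-area + PAC elbow rule);
- **subtype networks** — row z-scoring, complete-linkage edge clustering,
  the |mean Z| > 0.5 / 70 % perturbed-cluster rule, per-subtype networks,
  hub genes, and local hypergeometric gene-set enrichment (GMT);
- **synthetic data** — a seeded generator producing scale-free networks
  and normal/tumor cohorts with planted subtypes and known perturbed edge
  blocks, for validation with ground truth.

It is written for computational biologists who want to reproduce or adapt
rank-based edge-perturbation subtyping on their own cohorts.  Estimator
classes (`EdgePerturbation`, `KruskalWallisEdgeSelector`,
`ConsensusClustering`) follow scikit-learn conventions and compose with
sklearn pipelines; module-level functions expose the same operations on
genes × samples DataFrames.

## Worked example

```python
import edgepert as ep
from sklearn.metrics import adjusted_rand_score

cohort = ep.generate_cohort(seed=7)           # 1000 genes, 60 normals, 4x20 tumors
net = cohort.network
print(f"network: {net.n_edges} edges over {net.n_genes} genes, "
      f"degree-fit R^2 = {ep.degree_powerlaw_fit(net).r_squared:.3f}")

ranks = ep.rank_transform(cohort.expression)
bench = ep.benchmark_vector(cohort.normal_expr, net)
pert = ep.edge_perturbation(ep.delta_rank(ranks, net), bench)
report = ep.dispersion_report(pert, cohort.groups, n_sample_edges=1000, seed=7)
print(f"mean |perturbation|: normal {report.mean_abs_normal:.1f}, "
      f"tumor {report.mean_abs_tumor:.1f}; "
      f"{100*report.frac_edges_more_dispersed_in_tumor:.1f}% of edges more "
      f"dispersed in tumor (rank-sum p = {report.sampled_edge_test_p:.2e})")

selection = ep.select_feature_edges(pert, cohort.groups)
result = ep.consensus_cluster(selection.cancer_matrix, n_resamples=100, seed=7)
ari = adjusted_rand_score(cohort.true_labels.to_numpy(), result.labels.to_numpy())
print(f"{len(selection.selected_edges)} feature edges; "
      f"consensus clustering chose k = {result.chosen_k}; "
      f"subtype sizes {result.subtype_sizes}; ARI vs planted truth = {ari:.3f}")
```

prints

```
network: 1996 edges over 1000 genes, degree-fit R^2 = 0.861
mean |perturbation|: normal 78.2, tumor 225.1; 100.0% of edges more dispersed in tumor (rank-sum p = 0.00e+00)
844 feature edges; consensus clustering chose k = 4; subtype sizes {1: 20, 2: 20, 3: 18, 4: 22}; ARI vs planted truth = 0.934
```

Read: the generated background network is scale-free (R² 0.86); tumor
samples perturb interaction edges about three times as strongly as normal
samples and essentially every edge is more dispersed in tumors; consensus
clustering of the 844 selected edges finds exactly the four planted
subtypes, with near-perfect agreement (ARI 0.93) against the generator's
hidden labels.

## Command line

The same pipeline is available as a CLI with per-stage subcommands:

```sh
edgepert simulate --genes 1000 --normals 60 --subtypes 4 --per-subtype 20 \
         --shift 1.5 --seed 7 --out data/
edgepert run-all --network data/network.tsv --normal data/normal_expr.tsv \
         --tumor data/tumor_expr.tsv --truth data/true_labels.tsv \
         --reps 100 --seed 7 --out run/
```

`run-all` writes every intermediate matrix (edge perturbations, feature
edges, per-k consensus matrices, CDF/delta-area table, labels, per-subtype
networks) plus a `manifest.json` with parameters, seed and input
checksums; reruns with the same config are byte-identical.  `network`,
`perturb`, `subtype`, `subnet` and `enrich` run individual stages from the
files a previous stage wrote.

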