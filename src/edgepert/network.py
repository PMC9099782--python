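"""Background gene-interaction networks.

A background network is the union of pathway-derived gene–gene interaction
edges on which per-sample edge perturbations are evaluated.  Edges are
undirected and unweighted; each unordered gene pair is stored once, in
canonical orientation (lexicographically smaller symbol first).  The sign of
a delta rank depends on edge orientation, so canonicalization is applied
everywhere to keep results orientation-stable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundNetwork",
    "DegreeDistribution",
    "load_edge_list",
    "merge_networks",
    "filter_to_genes",
    "degree_powerlaw_fit",
    "write_edge_list",
]


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class BackgroundNetwork:
    """Canonical undirected edge set over gene symbols.

    Attributes
    ----------
    edges : tuple of (str, str)
        Edges in canonical orientation (first symbol lexicographically
        smaller), sorted for determinism.
    genes : tuple of str
        Sorted gene symbols; every gene participates in at least one edge.
    """

    edges: tuple[tuple[str, str], ...]
    genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.genes:
            gene_set = sorted({g for e in self.edges for g in e})
            object.__setattr__(self, "genes", tuple(gene_set))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "BackgroundNetwork":
        """Build a network from raw gene pairs, dropping self-loops and
        collapsing duplicates after canonicalization."""
        seen: set[tuple[str, str]] = set()
        n_loops = 0
        for a, b in pairs:
            if a == b:
                n_loops += 1
                continue
            seen.add(_canonical(a, b))
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        return cls(edges=tuple(sorted(seen)))

    @property
    def edge_index(self) -> dict[tuple[str, str], int]:
        """Mapping canonical pair -> row position."""
        return {e: i for i, e in enumerate(self.edges)}

    @property
    def edge_ids(self) -> list[str]:
        """Edge identifiers of the form ``GENEI|GENEJ``."""
        return [f"{a}|{b}" for a, b in self.edges]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {g: 0 for g in self.genes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BackgroundNetwork):
            return NotImplemented
        return self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)


@dataclass(frozen=True)
class DegreeDistribution:
    """Node-degree histogram with the scale-free diagnostic.

    ``r_squared`` is the determination coefficient of an ordinary
    least-squares fit of log10(count) on log10(degree) — the visual
    convention of degree-distribution plots.  Values close to 1 indicate a
    power-law (scale-free) degree distribution.
    """

    degree_values: tuple[int, ...]
    counts: tuple[int, ...]
    r_squared: float
    slope: float
    intercept: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_degrees": len(self.degree_values),
                "n_nodes": int(sum(self.counts)),
                "r_squared": self.r_squared,
                "slope": self.slope,
            }
        )


def load_edge_list(path: str | Path, format: str = "tsv") -> BackgroundNetwork:
    """Load a background network from a two-column TSV or SIF file.

    TSV records are ``gene_i<TAB>gene_j`` (whitespace also accepted; an
    optional ``gene`` header row is skipped).  SIF records are
    ``gene_i<TAB>relation<TAB>gene_j``; the relation is ignored because the
    network is undirected and unweighted.  Self-loops are dropped (a delta
    rank is undefined for a gene paired with itself) and duplicate unordered
    pairs collapse to one edge.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "sif":
                if len(fields) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 SIF fields, got {len(fields)}"
                    )
                pairs.append((fields[0], fields[2]))
            else:
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                    )
                if lineno == 1 and fields[0].lower() in ("gene", "gene_i", "source"):
                    continue
                pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    return BackgroundNetwork.from_pairs(pairs)


def write_edge_list(net: BackgroundNetwork, path: str | Path) -> None:
    """Write the canonical edge list as two-column TSV."""
    with open(path, "w") as fh:
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")


def merge_networks(nets: Sequence[BackgroundNetwork]) -> BackgroundNetwork:
    """Union a collection of networks into one background network."""
    if len(nets) == 0:
        raise ValueError("merge_networks requires at least one network")
    edges: set[tuple[str, str]] = set()
    for net in nets:
        edges.update(net.edges)
    return BackgroundNetwork(edges=tuple(sorted(edges)))


def filter_to_genes(net: BackgroundNetwork, present: Iterable[str]) -> BackgroundNetwork:
    """Restrict a network to edges whose BOTH endpoints are in ``present``.

    Genes left with no edge are dropped.  Raises if nothing survives, which
    almost always means the expression matrix and network use different
    identifier schemes.
    """
    present = set(present)
    kept = tuple(e for e in net.edges if e[0] in present and e[1] in present)
    if not kept:
        raise ValueError(
            "no edges left after filtering; check that the network and the "
            "expression matrix use the same gene symbols"
        )
    return BackgroundNetwork(edges=kept)


def degree_powerlaw_fit(net: BackgroundNetwork) -> DegreeDistribution:
    """Fit a power law to the degree distribution and report R².

    Fits OLS on (log10 degree, log10 count) over observed degrees (count
    ≥ 1); R² is the squared Pearson correlation of the log-log points.  A
    fit needs at least 3 distinct degree values.
    """
    deg = np.array(sorted(net.degrees().values()))
    values, counts = np.unique(deg, return_counts=True)
    if len(values) < 3:
        raise ValueError(
            f"degree power-law fit needs >=3 distinct degrees, got {len(values)}"
        )
    x = np.log10(values.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    if math.isnan(r2):  # all counts equal -> zero variance in y
        r2 = 0.0
    return DegreeDistribution(
        degree_values=tuple(int(v) for v in values),
        counts=tuple(int(c) for c in counts),
        r_squared=r2,
        slope=float(slope),
        intercept=float(intercept),
    )
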