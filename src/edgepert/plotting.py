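"""Minimal diagnostic figures (CDF / delta-area curves, dispersion violins)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .subtyping import ConsensusResult

__all__ = ["plot_consensus_cdf", "plot_delta_area", "plot_dispersion_violin"]


def plot_consensus_cdf(result: ConsensusResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for k in result.k_values:
        ax.plot(result.cdf_grid, result.cdfs[k], label=f"k={k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_delta_area(result: ConsensusResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ks = list(result.k_values)
    ax.plot(ks, [result.delta_area[k] for k in ks], marker="o")
    ax.axvline(result.chosen_k, color="red", ls="--", lw=1)
    ax.set_xlabel("k")
    ax.set_ylabel("relative change in area under CDF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dispersion_violin(sampled: pd.DataFrame, path: str | Path) -> None:
    """Violin of log2(|perturbation|+1) for sampled edges, by group."""
    fig, ax = plt.subplots(figsize=(4, 4))
    groups = ["normal", "tumor"]
    data = [sampled.loc[sampled["group"] == g, "log2_abs_pert"] for g in groups]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks([1, 2], groups)
    ax.set_ylabel("log2(|perturbation| + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
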