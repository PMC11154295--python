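"""PCA scatterplots, Manhattan plots, and Q-Q plots for simulated GWAS data.

Each plotting function first builds the coordinate table it will draw and
returns that table alongside the rendered file, writing it as a TSV sidecar;
the tables, not the pixels, are the reproducible surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import SummaryStats, genomic_inflation
from .genotypes import GenotypeMatrix
from .ldtools import ClumpSet, ld_prune


@dataclass
class PcaResult:
    """First four principal components of the (pruned, standardized) dosages."""

    coordinates: np.ndarray  # (N, 4)
    explained_fraction: np.ndarray  # (4,)
    sample_labels: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_fraction) > 1e-12):
            raise ValueError("components must be ordered by decreasing explained fraction")


def pca_genotypes(
    genotypes: GenotypeMatrix,
    prune_params: tuple[int, int, float] | None = (50, 5, 0.2),
    labels: list[str] | None = None,
) -> PcaResult:
    """PCA of column-standardized dosages after optional LD pruning.

    Monomorphic columns are dropped; at least 2 polymorphic variants and 5
    samples are required. Components come from the SVD of the standardized
    matrix, so coordinates equal those of a direct eigendecomposition of the
    sample covariance up to per-component sign.
    """
    if genotypes.n_samples < 5:
        raise ValueError("PCA needs at least 5 samples")
    if prune_params is not None:
        window, step, r2_max = prune_params
        kept = ld_prune(genotypes, window=window, step=step, r2_max=r2_max)
        idx = {v: i for i, v in enumerate(genotypes.variants["id"])}
        cols = np.array([idx[v] for v in kept])
        X = genotypes.dosages[:, cols].astype(np.float64)
    else:
        X = genotypes.dosages.astype(np.float64)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic variants after pruning")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    n_comp = min(4, len(s))
    coords = u[:, :n_comp] * s[:n_comp]
    if n_comp < 4:
        coords = np.pad(coords, ((0, 0), (0, 4 - n_comp)))
    eig = s**2
    frac = np.zeros(4)
    frac[:n_comp] = eig[:n_comp] / eig.sum()
    return PcaResult(
        coordinates=coords,
        explained_fraction=frac,
        sample_labels=labels if labels is not None else list(genotypes.sample_ids),
    )


def pca_plot(pca: PcaResult, out: str) -> str:
    """Scatterplots of the first four components (PC1-PC2, PC3-PC4)."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    groups = pd.Series(pca.sample_labels)
    unique = groups.unique()
    for g in unique:
        mask = (groups == g).to_numpy()
        axes[0].scatter(pca.coordinates[mask, 0], pca.coordinates[mask, 1], s=4, label=str(g))
        axes[1].scatter(pca.coordinates[mask, 2], pca.coordinates[mask, 3], s=4)
    for ax, (a, b) in zip(axes, [(0, 1), (2, 3)]):
        ax.set_xlabel(f"PC{a + 1} ({100 * pca.explained_fraction[a]:.1f}%)")
        ax.set_ylabel(f"PC{b + 1} ({100 * pca.explained_fraction[b]:.1f}%)")
    if len(unique) > 1 and len(unique) <= 10:
        axes[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    table = pd.DataFrame(pca.coordinates, columns=["PC1", "PC2", "PC3", "PC4"])
    table.insert(0, "sample", pca.sample_labels)
    table.to_csv(Path(out).with_suffix(".tsv"), sep="\t", index=False)
    return out


def manhattan_table(
    stats: SummaryStats,
    clumps: ClumpSet | None = None,
    suggestive_p: float = 1e-4,
    genomewide_p: float = 5e-8,
) -> pd.DataFrame:
    """Coordinate table behind the Manhattan plot."""
    t = stats.table
    chroms = list(dict.fromkeys(t["chrom"]))
    offset = 0.0
    cum = np.empty(len(t))
    for c in chroms:
        mask = (t["chrom"] == c).to_numpy()
        pos = t.loc[mask, "pos"].to_numpy().astype(float)
        cum[mask] = pos + offset
        offset += pos.max() + 1.0
    p = t["p"].to_numpy()
    highlight = np.where(p < genomewide_p, "genomewide", np.where(p < suggestive_p, "suggestive", "none"))
    index_ids = {c.index_id for c in clumps.clumps} if clumps is not None else set()
    return pd.DataFrame(
        {
            "id": t["id"],
            "chrom": t["chrom"],
            "pos": t["pos"],
            "cum_pos": cum,
            "neglog10_p": -np.log10(p),
            "highlight": highlight,
            "is_clump_index": t["id"].isin(index_ids),
        }
    )


def manhattan_plot(
    stats: SummaryStats,
    clumps: ClumpSet | None = None,
    suggestive_p: float = 1e-4,
    genomewide_p: float = 5e-8,
    out: str = "manhattan.png",
) -> pd.DataFrame:
    """Render the Manhattan plot; returns (and writes) its coordinate table."""
    if len(stats) == 0:
        raise ValueError("empty summary statistics")
    table = manhattan_table(stats, clumps, suggestive_p, genomewide_p)
    fig, ax = plt.subplots(figsize=(10, 4))
    chroms = list(dict.fromkeys(table["chrom"]))
    for i, c in enumerate(chroms):
        sub = table[(table["chrom"] == c) & (table["highlight"] == "none")]
        ax.scatter(sub["cum_pos"], sub["neglog10_p"], s=3,
                   color="#4d4d4d" if i % 2 == 0 else "#9e9e9e")
    sug = table[table["highlight"] == "suggestive"]
    ax.scatter(sug["cum_pos"], sug["neglog10_p"], s=5, color="green")
    gw = table[table["highlight"] == "genomewide"]
    ax.scatter(gw["cum_pos"], gw["neglog10_p"], s=5, color="red")
    idxs = table[table["is_clump_index"]]
    for row in idxs.itertuples(index=False):
        ax.annotate(row.id, (row.cum_pos, row.neglog10_p), fontsize=5, rotation=45)
    ax.axhline(-np.log10(suggestive_p), color="green", lw=0.5, ls="--")
    ax.axhline(-np.log10(genomewide_p), color="red", lw=0.5, ls="--")
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    table.to_csv(Path(out).with_suffix(".tsv"), sep="\t", index=False)
    return table


def qq_table(stats: SummaryStats) -> pd.DataFrame:
    """Observed vs expected -log10 p under uniform order statistics i/(M+1)."""
    p = np.sort(stats.table["p"].to_numpy())
    m = len(p)
    expected = np.arange(1, m + 1) / (m + 1)
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )


def qq_plot(stats: SummaryStats, out: str = "qq.png") -> pd.DataFrame:
    """Render the Q-Q plot with a genomic-inflation annotation."""
    if len(stats) == 0:
        raise ValueError("empty summary statistics")
    table = qq_table(stats)
    lam = genomic_inflation(stats)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(table["expected_neglog10"], table["observed_neglog10"], s=4, color="#2b6aa3")
    lim = max(table["expected_neglog10"].max(), table["observed_neglog10"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.text(0.05, 0.95, f"$\\lambda$ = {lam:.3f}", transform=ax.transAxes, va="top")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    table.to_csv(Path(out).with_suffix(".tsv"), sep="\t", index=False)
    return table
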