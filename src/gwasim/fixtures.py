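"""Synthetic reference panels, gene annotations, and gene sets.

The fixture generator makes the whole pipeline testable offline. Panels are
built from LD blocks: each block carries one deep two-lineage split (every
"divergent" site tags the same haplotype partition, whose frequency is drawn
per block), overlaid with per-site mutation noise. This yields strong
within-block LD, near-zero between-block LD, and an allele-frequency
spectrum mixing common partition-tagging variants with rare mutation-derived
ones. Gene intervals tile the variant span so every gene covers at least one
variant; gene sets include three calibrated sets of 17, 69 and 199 genes
(small/medium/big pathways) plus random sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneInterval, GeneSetCollection
from .genotypes import HaplotypePanel, write_panel_vcf

CALIBRATED_SETS = {
    "FIXTURE_SMALL_PATHWAY": 17,
    "FIXTURE_MEDIUM_PATHWAY": 69,
    "FIXTURE_BIG_PATHWAY": 199,
}


@dataclass
class FixtureConfig:
    """Sizes and rates of the synthetic inputs."""

    n_diploids: int = 100
    n_snps: int = 2000
    n_blocks: int = 50
    mutation_rate: float = 0.005
    n_genes: int = 300
    n_sets: int = 8
    genes_per_set: tuple[int, int] = (5, 40)
    seed: int = 0
    chrom: str = "1"
    spacing_bp: int = 150
    diverged_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in ("n_diploids", "n_snps", "n_blocks", "n_genes", "n_sets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_blocks > self.n_snps:
            raise ValueError("n_blocks cannot exceed n_snps")
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5]")


def make_panel(config: FixtureConfig, out_vcf: str | None = None) -> HaplotypePanel:
    """Generate a phased fixture panel; optionally write it as VCF.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical VCF. Sites monomorphic after generation are dropped.
    """
    rng = np.random.default_rng(config.seed)
    h = 2 * config.n_diploids
    m = config.n_snps

    block_edges = np.linspace(0, m, config.n_blocks + 1).astype(int)
    haps = np.zeros((h, m), dtype=np.uint8)
    for b in range(config.n_blocks):
        lo, hi = block_edges[b], block_edges[b + 1]
        if hi <= lo:
            continue
        width = hi - lo
        # deep split: every haplotype joins lineage 1 with per-block frequency q
        q = rng.uniform(0.05, 0.95)
        lineage = rng.random(h) < q
        diverged = rng.random(width) < config.diverged_fraction
        # which lineage carries the alt allele varies per site
        alt_on_lineage1 = rng.random(width) < 0.5
        block = np.zeros((h, width), dtype=np.uint8)
        block[np.ix_(lineage, diverged & alt_on_lineage1)] = 1
        block[np.ix_(~lineage, diverged & ~alt_on_lineage1)] = 1
        # per-site mutation noise on every haplotype
        flips = rng.random((h, width)) < config.mutation_rate
        block ^= flips.astype(np.uint8)
        haps[:, lo:hi] = block

    pos = 1000 + config.spacing_bp * np.arange(m, dtype=np.int64)
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "id": [f"rs{i + 1}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    counts = haps.sum(axis=0, dtype=np.int64)
    poly = (counts > 0) & (counts < h)
    haps = haps[:, poly]
    variants = variants.loc[poly].reset_index(drop=True)
    freq = haps.sum(axis=0, dtype=np.int64) / h
    variants["maf"] = np.minimum(freq, 1.0 - freq)

    panel = HaplotypePanel(
        variants=variants,
        haplotypes=haps,
        sample_ids=[f"ref{i + 1:04d}" for i in range(config.n_diploids)],
    )
    if out_vcf is not None:
        write_panel_vcf(panel, out_vcf)
    return panel


def make_annotation(
    config: FixtureConfig,
    panel: HaplotypePanel,
    out_genes: str | None = None,
    out_gmt: str | None = None,
) -> tuple[list[GeneInterval], GeneSetCollection]:
    """Tile gene intervals over the panel variants and build gene sets.

    Genes are non-overlapping and each covers at least one variant. The
    collection always contains the three calibrated sets (17, 69, 199 genes)
    plus ``config.n_sets`` random sets with sizes drawn from
    ``config.genes_per_set``. Optionally writes a GTF-style gene file and a
    GMT file.
    """
    from .annotation import write_gene_gtf, write_gmt

    m = panel.n_variants
    if config.n_genes > m:
        raise ValueError(f"n_genes={config.n_genes} exceeds the {m} tileable variants")
    rng = np.random.default_rng(config.seed + 1)

    genes: list[GeneInterval] = []
    gid = 0
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        n_here = max(1, round(config.n_genes * len(pos) / m))
        edges = np.linspace(0, len(pos), n_here + 1).astype(int)
        for g in range(n_here):
            lo, hi = edges[g], edges[g + 1]
            if hi <= lo:
                continue
            gid += 1
            genes.append(
                GeneInterval(
                    gene_id=f"GENE{gid:05d}",
                    chrom=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    strand="+" if gid % 2 else "-",
                )
            )
    gene_ids = [g.gene_id for g in genes]
    largest = max(CALIBRATED_SETS.values())
    if len(gene_ids) < largest:
        raise ValueError(f"need at least {largest} genes for the calibrated sets")

    sets: dict[str, list[str]] = {}
    for name, size in CALIBRATED_SETS.items():
        picked = rng.choice(len(gene_ids), size=size, replace=False)
        sets[name] = [gene_ids[i] for i in sorted(picked)]
    lo, hi = config.genes_per_set
    for s in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(gene_ids))
        picked = rng.choice(len(gene_ids), size=size, replace=False)
        sets[f"RANDOM_SET_{s + 1:02d}"] = [gene_ids[i] for i in sorted(picked)]
    collection = GeneSetCollection(sets=sets)

    if out_genes is not None:
        write_gene_gtf(genes, out_genes)
    if out_gmt is not None:
        write_gmt(collection, out_gmt, description="synthetic fixture set")
    return genes, collection


def write_sample_list(panel: HaplotypePanel, path: str, fraction: float = 1.0) -> list[str]:
    """Write a plain-text sample keep-list (one id per line)."""
    n = max(1, int(round(fraction * len(panel.sample_ids))))
    kept = panel.sample_ids[:n]
    with open(path, "w") as fh:
        fh.write("\n".join(kept) + "\n")
    return kept
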