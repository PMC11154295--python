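"""Nearest-gene annotation of variants and causal-candidate pool definition.

Every variant is assigned the gene whose interval is closest on the same
chromosome (distance 0 when the position falls inside the interval, otherwise
the base-pair gap to the nearer boundary; ties go to the gene with the
smaller start, then the lexicographically smaller id). The causal-candidate
pool is the set of variants whose sample MAF lies strictly inside a window,
(0.05, 0.5) by default, so rare and perfectly balanced variants are never
picked as causal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 1-based inclusive genomic interval; strand is informational."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class SnpGeneMap:
    """Variant id -> (nearest gene id or None, distance in bp or None)."""

    entries: dict[str, tuple[str | None, int | None]]

    def gene_of(self, variant_id: str) -> str | None:
        return self.entries[variant_id][0]

    def variants_of_genes(self, gene_ids: Sequence[str]) -> dict[str, list[str]]:
        """Invert the map for a set of genes: gene id -> mapped variant ids."""
        wanted = set(gene_ids)
        out: dict[str, list[str]] = {g: [] for g in gene_ids}
        for vid, (gid, _) in self.entries.items():
            if gid in wanted:
                out[gid].append(vid)
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> non-empty gene-id list."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)


def nearest_gene(variants: pd.DataFrame, genes: Sequence[GeneInterval]) -> SnpGeneMap:
    """Map each variant to its nearest gene on the same chromosome.

    Variants on chromosomes without genes get a ``(None, None)`` entry and are
    counted in the log. The assignment equals an all-pairs minimum-distance
    search with the deterministic tie rule (smaller start, then gene id).
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    entries: dict[str, tuple[str | None, int | None]] = {}
    n_unmapped = 0
    for chrom, sub in variants.groupby("chrom", sort=False):
        glist = by_chrom.get(chrom)
        vids = sub["id"].to_numpy()
        if not glist:
            for vid in vids:
                entries[vid] = (None, None)
            n_unmapped += len(vids)
            continue
        # deterministic tie-break: order genes by (start, gene_id); argmin picks first
        glist = sorted(glist, key=lambda g: (g.start, g.gene_id))
        starts = np.array([g.start for g in glist])
        ends = np.array([g.end for g in glist])
        pos = sub["pos"].to_numpy()
        # distance(pos, interval): 0 inside, else gap to the nearer boundary
        dist = np.maximum.reduce(
            [starts[None, :] - pos[:, None], pos[:, None] - ends[None, :], np.zeros((len(pos), len(glist)), dtype=np.int64)]
        )
        best = dist.argmin(axis=1)
        for vid, b, d in zip(vids, best, dist[np.arange(len(pos)), best]):
            entries[vid] = (glist[b].gene_id, int(d))
    if n_unmapped:
        logger.warning("nearest_gene: %d variants on chromosomes without genes", n_unmapped)
    return SnpGeneMap(entries=entries)


def candidate_pool(
    genotypes: GenotypeMatrix, min_maf: float = 0.05, max_maf: float = 0.5
) -> list[str]:
    """Variant ids whose sample MAF lies strictly inside (min_maf, max_maf)."""
    if not (0.0 <= min_maf < max_maf <= 0.5):
        raise ValueError(f"need 0 <= min_maf < max_maf <= 0.5, got ({min_maf}, {max_maf})")
    maf = genotypes.sample_maf()
    mask = (maf > min_maf) & (maf < max_maf)
    if not mask.any():
        qs = np.quantile(maf, [0.0, 0.25, 0.5, 0.75, 1.0])
        raise ValueError(
            f"empty causal-candidate pool for MAF window ({min_maf}, {max_maf}); "
            f"sample MAF quantiles (min/q1/median/q3/max): {np.round(qs, 4).tolist()}"
        )
    return genotypes.variants.loc[mask, "id"].tolist()


def read_gmt(path: str) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, gene1...geneG)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str, description: str = "gwasim") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gene_intervals(path: str) -> list[GeneInterval]:
    """Read gene intervals from GTF ('gene' features) or BED (4+ columns).

    Coordinates are normalized to 1-based inclusive; BED's 0-based half-open
    convention is converted on read. Format is chosen by extension (.bed vs
    .gtf/.gff).
    """
    lower = path.lower()
    genes: list[GeneInterval] = []
    if lower.endswith(".bed"):
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: BED gene line needs >= 4 columns")
                strand = f[5] if len(f) > 5 else "+"
                genes.append(
                    GeneInterval(gene_id=f[3], chrom=f[0], start=int(f[1]) + 1, end=int(f[2]), strand=strand)
                )
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ValueError(f"{path}:{lineno}: GTF line needs 9 columns")
                if f[2] != "gene":
                    continue
                m = _GTF_GENE_ID.search(f[8])
                if not m:
                    raise ValueError(f"{path}:{lineno}: gene feature without gene_id attribute")
                genes.append(
                    GeneInterval(gene_id=m.group(1), chrom=f[0], start=int(f[3]), end=int(f[4]), strand=f[6])
                )
    if not genes:
        raise ValueError(f"{path}: no gene intervals found")
    return genes


def write_gene_gtf(genes: Sequence[GeneInterval], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tgwasim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
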