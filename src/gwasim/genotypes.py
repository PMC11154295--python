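"""Reference-panel handling and haplotype-mosaic genotype simulation.

A phased reference panel (``HaplotypePanel``) is loaded from VCF, optionally
filtered on minor-allele frequency and a sample keep-list, and expanded to an
arbitrary simulated sample size. Simulated haplotypes are mosaics of panel
haplotypes: each starts as a copy of a uniformly chosen panel haplotype and,
between consecutive variants, switches to a new uniformly chosen haplotype
with a constant probability. Two independent mosaic haplotypes are summed to
an unphased dosage in {0, 1, 2}. This preserves local linkage disequilibrium
while producing an effectively homogeneous sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of the variant metadata table carried by panels and genotype matrices
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "maf"]

# chunk of simulated haplotypes processed at once (bounds peak memory)
_SIM_CHUNK = 2000


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with its panel minor-allele frequency."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.id}: maf must lie in [0, 0.5], got {self.maf}")


def _check_variant_table(variants: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if variants["id"].duplicated().any():
        dups = variants.loc[variants["id"].duplicated(), "id"].tolist()[:5]
        raise ValueError(f"duplicate variant ids: {dups}")


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes: an H x M binary allele matrix.

    ``variants`` is a DataFrame with columns ``chrom, pos, id, ref, alt, maf``
    ordered by (chromosome first-appearance, position); ``haplotypes`` holds
    one row per haplotype (two consecutive rows per diploid sample).
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray  # (H, M) uint8
    sample_ids: list[str]

    def __post_init__(self) -> None:
        _check_variant_table(self.variants)
        h, m = self.haplotypes.shape
        if h % 2 != 0:
            raise ValueError(f"haplotype count must be even, got {h}")
        if h != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must equal 2 x number of samples")
        if m != len(self.variants):
            raise ValueError("haplotype columns must align with the variant table")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class GenotypeMatrix:
    """Unphased dosage matrix: N individuals x M variants with entries in {0,1,2}."""

    variants: pd.DataFrame
    dosages: np.ndarray  # (N, M) int8
    sample_ids: list[str]

    def __post_init__(self) -> None:
        _check_variant_table(self.variants)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows must equal number of samples")
        if m != len(self.variants):
            raise ValueError("dosage columns must align with the variant table")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant id."""
        idx = self._id_index().get(variant_id)
        if idx is None:
            raise KeyError(f"variant {variant_id!r} not present")
        return self.dosages[:, idx]

    def _id_index(self) -> dict[str, int]:
        cached = getattr(self, "_id_index_cache", None)
        if cached is None or len(cached) != self.n_variants:
            cached = {v: i for i, v in enumerate(self.variants["id"])}
            object.__setattr__(self, "_id_index_cache", cached)
        return cached

    def sample_maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency recomputed from the dosages."""
        freq = self.dosages.mean(axis=0, dtype=np.float64) / 2.0
        return np.minimum(freq, 1.0 - freq)


def _folded_maf(alt_count: np.ndarray, n_alleles: int) -> np.ndarray:
    freq = alt_count / n_alleles
    return np.minimum(freq, 1.0 - freq)


def load_panel(vcf_path: str) -> HaplotypePanel:
    """Load a phased reference panel from a VCF file.

    Only biallelic SNP records with fully phased, non-missing genotypes are
    kept; anything else is skipped and counted. Records at a (chrom, pos)
    already seen are skipped as duplicates. Raises ``ValueError`` when no
    usable record remains.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{vcf_path}: VCF contains no samples")

    columns: list[np.ndarray] = []
    rows: list[tuple] = []
    skipped = 0
    seen_pos: set[tuple[str, int]] = set()
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        alleles = np.empty(2 * len(gts), dtype=np.int16)
        ok = True
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0:
                ok = False
                break
            alleles[2 * i] = g[0]
            alleles[2 * i + 1] = g[1]
        if not ok:
            skipped += 1
            continue
        key = (rec.CHROM, rec.POS)
        if key in seen_pos:
            skipped += 1
            continue
        seen_pos.add(key)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        columns.append(alleles.astype(np.uint8))
        rows.append((rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0]))
    if skipped:
        logger.info("load_panel: skipped %d unusable records in %s", skipped, vcf_path)
    if not rows:
        raise ValueError(f"{vcf_path}: no usable phased biallelic SNP records")

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    haps = np.ascontiguousarray(np.stack(columns, axis=1))
    # sort by (chromosome first-appearance, position)
    chrom_rank = {c: i for i, c in enumerate(variants["chrom"].unique())}
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].map(chrom_rank).to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    haps = np.ascontiguousarray(haps[:, order])
    variants["maf"] = _folded_maf(haps.sum(axis=0, dtype=np.int64), haps.shape[0])
    panel = HaplotypePanel(variants=variants, haplotypes=haps, sample_ids=sample_ids)
    panel.n_skipped_records = skipped  # type: ignore[attr-defined]
    return panel


def load_genotypes(vcf_path: str) -> GenotypeMatrix:
    """Load a genotype matrix from a VCF (phased or unphased GT accepted).

    Used on the simulation-skip path where the user supplies genotypes
    directly. Biallelic SNP records with non-missing genotypes are kept;
    others are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{vcf_path}: VCF contains no samples")
    columns: list[np.ndarray] = []
    rows: list[tuple] = []
    skipped = 0
    seen_pos: set[tuple[str, int]] = set()
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = rec.genotypes
        dos = np.empty(len(gts), dtype=np.int8)
        ok = True
        for i, g in enumerate(gts):
            if g[0] < 0 or g[1] < 0:
                ok = False
                break
            dos[i] = g[0] + g[1]
        key = (rec.CHROM, rec.POS)
        if not ok or key in seen_pos:
            skipped += 1
            continue
        seen_pos.add(key)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        columns.append(dos)
        rows.append((rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0]))
    if skipped:
        logger.info("load_genotypes: skipped %d unusable records in %s", skipped, vcf_path)
    if not rows:
        raise ValueError(f"{vcf_path}: no usable biallelic SNP records")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = np.ascontiguousarray(np.stack(columns, axis=1))
    chrom_rank = {c: i for i, c in enumerate(variants["chrom"].unique())}
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].map(chrom_rank).to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = np.ascontiguousarray(dosages[:, order])
    freq = dosages.mean(axis=0, dtype=np.float64) / 2.0
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(variants=variants, dosages=dosages, sample_ids=sample_ids)


def filter_panel(
    panel: HaplotypePanel,
    min_maf: float = 0.0,
    keep_ids: Sequence[str] | None = None,
) -> HaplotypePanel:
    """Filter a panel by (inclusive) MAF threshold and an optional keep-list.

    When ``keep_ids`` is given only the listed samples are retained and MAF is
    recomputed on the retained haplotypes before the MAF filter is applied.
    """
    if not (0.0 <= min_maf < 0.5):
        raise ValueError(f"min_maf must lie in [0, 0.5), got {min_maf}")

    haps = panel.haplotypes
    samples = list(panel.sample_ids)
    if keep_ids is not None:
        keep = [s for s in samples if s in set(keep_ids)]
        if not keep:
            raise ValueError("keep-list shares no samples with the panel")
        idx = np.array(
            [j for s in keep for j in (2 * samples.index(s), 2 * samples.index(s) + 1)]
        )
        haps = haps[idx]
        samples = keep

    variants = panel.variants.copy()
    variants["maf"] = _folded_maf(haps.sum(axis=0, dtype=np.int64), haps.shape[0])
    mask = variants["maf"].to_numpy() >= min_maf
    return HaplotypePanel(
        variants=variants.loc[mask].reset_index(drop=True),
        haplotypes=haps[:, mask],
        sample_ids=samples,
    )


def _mosaic_sources(
    rng: np.random.Generator,
    n_haps: int,
    n_panel: int,
    chrom_start: np.ndarray,
    switch_rate: float,
) -> np.ndarray:
    """Panel-haplotype source index for each (simulated haplotype, variant)."""
    m = chrom_start.shape[0]
    draws = rng.integers(0, n_panel, size=(n_haps, m), dtype=np.int32)
    switch = rng.random((n_haps, m)) < switch_rate
    switch[:, chrom_start] = True  # mosaic restarts at each chromosome
    keep = np.where(switch, np.arange(m, dtype=np.int32), np.int32(0))
    last = np.maximum.accumulate(keep, axis=1)
    return np.take_along_axis(draws, last, axis=1)


def simulate_genotypes(
    panel: HaplotypePanel,
    n_individuals: int,
    switch_rate: float = 0.002,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate ``n_individuals`` diploid genotypes by haplotype-mosaic resampling.

    Each of the 2N simulated haplotypes starts from a uniformly chosen panel
    haplotype; between consecutive variants it switches to a new uniformly
    chosen panel haplotype with probability ``switch_rate``. Switching resets
    at chromosome boundaries. Deterministic given ``seed``.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not (0.0 <= switch_rate <= 1.0):
        raise ValueError("switch_rate must lie in [0, 1]")
    if panel.n_variants == 0 or panel.n_haplotypes == 0:
        raise ValueError("cannot simulate from an empty panel")

    m = panel.n_variants
    chroms = panel.variants["chrom"].to_numpy()
    chrom_start = np.zeros(m, dtype=bool)
    chrom_start[0] = True
    chrom_start[1:] = chroms[1:] != chroms[:-1]

    rng = np.random.default_rng(seed)
    dosages = np.empty((n_individuals, m), dtype=np.int8)
    col_idx = np.arange(m)
    done = 0
    while done < n_individuals:
        chunk = min(_SIM_CHUNK, n_individuals - done)
        acc = np.zeros((chunk, m), dtype=np.int8)
        for _ in range(2):  # two independent haplotypes per individual
            src = _mosaic_sources(rng, chunk, panel.n_haplotypes, chrom_start, switch_rate)
            acc += panel.haplotypes[src, col_idx]
        dosages[done : done + chunk] = acc
        done += chunk

    sample_ids = [f"sim{i + 1:06d}" for i in range(n_individuals)]
    return GenotypeMatrix(variants=panel.variants.copy(), dosages=dosages, sample_ids=sample_ids)


def _natural_chrom_key(label: str):
    stripped = label[3:] if label.lower().startswith("chr") else label
    try:
        return (0, int(stripped), "")
    except ValueError:
        return (1, 0, stripped)


def merge_panels(parts: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge per-chromosome genotype matrices over identical samples.

    Parts must carry identical sample ids and disjoint chromosome sets; the
    merged variant table is re-sorted by (natural chromosome order, position),
    so the result is invariant to the order in which parts are given.
    """
    if not parts:
        raise ValueError("no parts to merge")
    ref_samples = parts[0].sample_ids
    chrom_seen: set[str] = set()
    for p in parts:
        if p.sample_ids != ref_samples:
            raise ValueError("sample ids differ between parts")
        these = set(p.variants["chrom"])
        if these & chrom_seen:
            raise ValueError(f"chromosome overlap between parts: {these & chrom_seen}")
        chrom_seen |= these

    variants = pd.concat([p.variants for p in parts], ignore_index=True)
    if variants["id"].duplicated().any():
        dups = variants.loc[variants["id"].duplicated(), "id"].tolist()[:5]
        raise ValueError(f"duplicate variant ids across parts: {dups}")
    dosages = np.concatenate([p.dosages for p in parts], axis=1)
    keys = variants["chrom"].map(_natural_chrom_key)
    order = np.lexsort((variants["pos"].to_numpy(), keys.rank(method="dense").to_numpy()))
    return GenotypeMatrix(
        variants=variants.iloc[order].reset_index(drop=True),
        dosages=dosages[:, order],
        sample_ids=list(ref_samples),
    )


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write a panel as a phased VCF (text, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gwasim\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        haps = panel.haplotypes
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}" for i in range(len(panel.sample_ids))
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def write_genotype_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write simulated genotypes as an unphased VCF (0/0, 0/1, 1/1)."""
    codes = ("0/0", "0/1", "1/1")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gwasim\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.sample_ids) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            gts = "\t".join(codes[d] for d in genotypes.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def write_dosage_matrix(genotypes: GenotypeMatrix, path: str, sidecar_path: str) -> None:
    """Write a samples x variants dosage TSV plus a variant-metadata sidecar."""
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.sample_ids, columns=genotypes.variants["id"]
    )
    df.index.name = "IID"
    df.to_csv(path, sep="\t")
    meta = genotypes.variants.rename(
        columns={"chrom": "CHROM", "pos": "POS", "id": "ID", "ref": "REF", "alt": "ALT", "maf": "MAF"}
    )
    meta.to_csv(sidecar_path, sep="\t", index=False)
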