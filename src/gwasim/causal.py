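"""Selection of causal variants, optionally anchored in a named gene set.

Pathway mode draws k causal variants from genes of a chosen set (one variant
per selected gene while genes last, round-robin with per-gene counts differing
by at most one otherwise) and tops up with K - k variants whose nearest gene
lies outside the set. Explicit mode intersects a user-supplied id list with
the genotype data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneSetCollection, SnpGeneMap
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

ORIGINS = ("pathway", "random", "explicit")


@dataclass(frozen=True)
class CausalEntry:
    variant_id: str
    origin: str  # pathway | random | explicit
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class CausalSpec:
    """The K selected causal variants with per-variant provenance."""

    entries: list[CausalEntry]
    target_set: str | None = None

    def __post_init__(self) -> None:
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("causal variant ids must be unique")

    @property
    def variant_ids(self) -> list[str]:
        return [e.variant_id for e in self.entries]

    @property
    def k_pathway(self) -> int:
        return sum(e.origin == "pathway" for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ID": self.variant_ids,
                "ORIGIN": [e.origin for e in self.entries],
                "GENE": [e.gene_id or "." for e in self.entries],
            }
        )
        if genotypes is not None:
            meta = genotypes.variants.set_index("id")
            df["CHROM"] = meta.loc[df["ID"], "chrom"].to_numpy()
            df["POS"] = meta.loc[df["ID"], "pos"].to_numpy()
            maf = pd.Series(genotypes.sample_maf(), index=genotypes.variants["id"])
            df["MAF"] = maf.loc[df["ID"]].to_numpy()
        return df

    def to_tsv(self, path: str, genotypes: GenotypeMatrix | None = None) -> None:
        self.to_frame(genotypes).to_csv(path, sep="\t", index=False)


def select_from_pathway(
    gene_map: SnpGeneMap,
    pool: list[str],
    sets: GeneSetCollection,
    set_name: str,
    K: int,
    k: int,
    seed: int = 0,
) -> CausalSpec:
    """Select K causal variants, k of them anchored in ``set_name``.

    Eligible genes are set members with at least one pool variant mapped to
    them. When k <= n' (eligible genes) k genes are sampled without
    replacement and one mapped pool variant is drawn uniformly per gene; when
    k > n', extra picks are assigned round-robin (a fresh uniform permutation
    of the genes per cycle) so per-gene counts differ by at most one. The
    remaining K - k variants are drawn uniformly from pool variants whose
    nearest gene is NOT in the set. Deterministic given ``seed``.
    """
    if k > K:
        raise ValueError(f"k ({k}) cannot exceed K ({K})")
    if set_name not in sets:
        raise ValueError(f"gene set {set_name!r} not found")
    if not pool:
        raise ValueError("causal-candidate pool is empty")

    rng = np.random.default_rng(seed)
    set_genes = sets[set_name]
    by_gene = gene_map.variants_of_genes(set_genes)
    # keep pool variants only, preserving pool order for determinism
    pool_set = set(pool)
    by_gene = {g: [v for v in vs if v in pool_set] for g, vs in by_gene.items()}
    eligible = [g for g in set_genes if by_gene.get(g)]
    n_mapped = sum(len(by_gene[g]) for g in eligible)
    if n_mapped < k:
        raise ValueError(
            f"gene set {set_name!r} has only {n_mapped} pool variants mapped; k={k} requested"
        )

    entries: list[CausalEntry] = []
    if k > 0:
        counts = {g: 0 for g in eligible}
        capacity = {g: len(by_gene[g]) for g in eligible}
        assigned = 0
        if k <= len(eligible):
            chosen = rng.choice(len(eligible), size=k, replace=False)
            for i in chosen:
                counts[eligible[i]] = 1
            assigned = k
        else:
            for g in eligible:
                counts[g] = 1
            assigned = len(eligible)
            # round-robin over fresh permutations until k picks are assigned,
            # skipping genes whose mapped variants are exhausted
            while assigned < k:
                perm = rng.permutation(len(eligible))
                progressed = False
                for i in perm:
                    g = eligible[i]
                    if counts[g] < capacity[g]:
                        counts[g] += 1
                        assigned += 1
                        progressed = True
                        if assigned == k:
                            break
                if not progressed:
                    raise ValueError("insufficient mapped variants to reach k")  # pragma: no cover
        for g in eligible:
            c = counts[g]
            if c == 0:
                continue
            vs = by_gene[g]
            picked = rng.choice(len(vs), size=c, replace=False)
            for i in sorted(picked):
                entries.append(CausalEntry(variant_id=vs[i], origin="pathway", gene_id=g))

    n_random = K - k
    if n_random > 0:
        set_gene_ids = set(set_genes)
        chosen_ids = {e.variant_id for e in entries}
        off_set = [
            v
            for v in pool
            if v not in chosen_ids and gene_map.entries.get(v, (None, None))[0] not in set_gene_ids
        ]
        if len(off_set) < n_random:
            raise ValueError(
                f"only {len(off_set)} off-set pool variants available; K-k={n_random} requested"
            )
        picked = rng.choice(len(off_set), size=n_random, replace=False)
        for i in picked:
            vid = off_set[i]
            entries.append(
                CausalEntry(variant_id=vid, origin="random", gene_id=gene_map.entries[vid][0])
            )

    return CausalSpec(entries=entries, target_set=set_name)


def select_explicit(ids: list[str], genotypes: GenotypeMatrix) -> CausalSpec:
    """Causal spec from an explicit id list, intersected with the genotype data."""
    if not ids:
        raise ValueError("explicit causal id list is empty")
    present = set(genotypes.variants["id"])
    kept = [v for v in ids if v in present]
    missing = [v for v in ids if v not in present]
    if missing:
        logger.warning(
            "select_explicit: %d ids absent from genotype data: %s", len(missing), missing
        )
    if not kept:
        raise ValueError("none of the explicit causal ids are present in the genotype data")
    return CausalSpec(
        entries=[CausalEntry(variant_id=v, origin="explicit") for v in kept], target_set=None
    )


def extract_causal_genotypes(genotypes: GenotypeMatrix, spec: CausalSpec) -> GenotypeMatrix:
    """N x K submatrix of the causal variants, columns in spec order."""
    idx_map = {v: i for i, v in enumerate(genotypes.variants["id"])}
    missing = [v for v in spec.variant_ids if v not in idx_map]
    if missing:
        raise ValueError(f"causal variants absent from genotype data: {missing}")
    cols = np.array([idx_map[v] for v in spec.variant_ids])
    return GenotypeMatrix(
        variants=genotypes.variants.iloc[cols].reset_index(drop=True),
        dosages=genotypes.dosages[:, cols],
        sample_ids=list(genotypes.sample_ids),
    )
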