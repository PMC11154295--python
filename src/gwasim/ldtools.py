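"""LD computation, greedy clumping of summary statistics, and LD pruning.

LD is the squared Pearson correlation (r^2) of dosage columns. Clumping
follows the classic greedy scheme: variants passing the index p-value
threshold are taken best-first; each index absorbs, as members, unassigned
same-chromosome variants within the kb window that pass the member threshold
and exceed the r^2 threshold with the index. Pruning slides a window over
each chromosome and removes, from the worst remaining pair, the variant with
the smaller MAF until no retained in-window pair exceeds the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import SummaryStats
from .genotypes import GenotypeMatrix

#: genome-wide significance threshold used when evaluating "significant loci"
GENOMEWIDE_P = 5e-8


@dataclass(frozen=True)
class ClumpParams:
    """Clumping thresholds; defaults mirror the standard clump defaults."""

    p1: float = 1e-4
    p2: float = 1e-2
    r2: float = 0.5
    kb: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1 and 0 < self.p2 <= 1):
            raise ValueError("p1 and p2 must lie in (0, 1]")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")
        if self.kb <= 0:
            raise ValueError("kb must be positive")


@dataclass(frozen=True)
class Clump:
    index_id: str
    index_p: float
    member_ids: tuple[str, ...]

    @property
    def all_ids(self) -> tuple[str, ...]:
        return (self.index_id, *self.member_ids)


@dataclass
class ClumpSet:
    clumps: list[Clump]
    params: ClumpParams

    def __len__(self) -> int:
        return len(self.clumps)

    def assigned_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.clumps:
            out.update(c.all_ids)
        return out

    def to_tsv(self, path: str) -> None:
        """Write a .clumped-style report: CHR SNP BP P TOTAL SP2."""
        import pandas as pd

        rows = []
        for c in self.clumps:
            rows.append(
                {
                    "SNP": c.index_id,
                    "P": c.index_p,
                    "TOTAL": len(c.member_ids),
                    "SP2": ",".join(c.member_ids) if c.member_ids else "NONE",
                }
            )
        pd.DataFrame(rows, columns=["SNP", "P", "TOTAL", "SP2"]).to_csv(path, sep="\t", index=False)


def _r2_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of column x against each column of Y."""
    x = x.astype(np.float64)
    Y = Y.astype(np.float64)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = float(xc @ xc)
    sy = (Yc * Yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (xc @ Yc) ** 2 / (sx * sy)
    r2[~np.isfinite(r2)] = 0.0
    return r2


def ld_r2(genotypes: GenotypeMatrix, id_a: str, id_b: str) -> float:
    """Squared Pearson correlation of the two dosage columns."""
    x = genotypes.column(id_a).astype(np.float64)
    y = genotypes.column(id_b).astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("LD undefined for monomorphic variants")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(stats: SummaryStats, genotypes: GenotypeMatrix, params: ClumpParams | None = None) -> ClumpSet:
    """Greedy LD clumping of summary statistics.

    Index candidates are variants with p < p1, processed in ascending p (ties
    by chromosome order, then position). Each index absorbs unassigned
    variants with p < p2, on the same chromosome, within kb of the index, and
    with r^2 >= params.r2 against the index.
    """
    params = params or ClumpParams()
    t = stats.table
    ids = t["id"].to_numpy()
    gmap = {v: i for i, v in enumerate(genotypes.variants["id"])}
    if not all(v in gmap for v in ids):
        raise ValueError("summary statistics contain variants absent from the genotype data")
    p = t["p"].to_numpy()
    pos = t["pos"].to_numpy()
    chrom = t["chrom"].to_numpy()
    chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(chrom))}
    crank = np.array([chrom_rank[c] for c in chrom])

    cand = np.flatnonzero(p < params.p1)
    order = cand[np.lexsort((pos[cand], crank[cand], p[cand]))]
    member_ok = p < params.p2
    window = params.kb * 1000.0

    assigned = np.zeros(len(t), dtype=bool)
    clumps: list[Clump] = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        near = np.flatnonzero(
            member_ok
            & ~assigned
            & (crank == crank[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        members: list[str] = []
        if near.size:
            x = genotypes.dosages[:, gmap[ids[i]]]
            Y = genotypes.dosages[:, [gmap[v] for v in ids[near]]]
            r2 = _r2_columns(x, Y)
            hit = near[r2 >= params.r2]
            assigned[hit] = True
            members = [ids[j] for j in hit]
        clumps.append(Clump(index_id=ids[i], index_p=float(p[i]), member_ids=tuple(members)))
    return ClumpSet(clumps=clumps, params=params)


def ld_prune(
    genotypes: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list[str]:
    """Sliding-window greedy LD pruning; returns retained variant ids.

    Within each window, while any retained pair exceeds ``r2_max``, the
    member of the worst (highest-r^2) pair with the smaller sample MAF is
    removed (ties: the later position goes). The window slides by ``step``
    variants per chromosome. Deterministic.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not (1 <= step <= window):
        raise ValueError("step must lie in [1, window]")
    ids = genotypes.variants["id"].to_numpy()
    chrom = genotypes.variants["chrom"].to_numpy()
    maf = genotypes.sample_maf()
    retained = np.ones(len(ids), dtype=bool)

    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            live = win[retained[win]]
            while live.size >= 2:
                X = genotypes.dosages[:, live].astype(np.float64)
                Xc = X - X.mean(axis=0)
                ss = np.sqrt((Xc * Xc).sum(axis=0))
                poly = ss > 0
                with np.errstate(divide="ignore", invalid="ignore"):
                    R = (Xc.T @ Xc) / np.outer(ss, ss)
                R2 = R * R
                R2[~np.isfinite(R2)] = 0.0
                R2[~poly, :] = 0.0
                R2[:, ~poly] = 0.0
                np.fill_diagonal(R2, 0.0)
                worst = np.unravel_index(np.argmax(R2), R2.shape)
                if R2[worst] <= r2_max:
                    break
                a, b = live[worst[0]], live[worst[1]]
                if maf[a] < maf[b]:
                    drop = a
                elif maf[b] < maf[a]:
                    drop = b
                else:
                    drop = max(a, b)  # tie: later position
                retained[drop] = False
                live = win[retained[win]]
            if start + window >= len(idx):
                break
            start += step
    return [ids[i] for i in np.flatnonzero(retained)]
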