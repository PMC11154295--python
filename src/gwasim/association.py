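"""Per-variant association testing producing GWAS summary statistics.

Quantitative traits use per-SNP simple linear regression (intercept +
dosage): the reported effect is the OLS slope, the statistic the Wald t with
N - 2 degrees of freedom and a two-sided t-tail p-value. Binary traits use
the allelic 1-df chi-square test on the 2x2 case/control x ref/alt allele
table, with the log odds ratio (Haldane-Anscombe corrected when a cell is
zero) as the effect column. Monomorphic variants keep their row (p = 1,
beta = 0, se/stat undefined) so row order stays aligned with the genotype
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix
from .phenotype import PhenotypeVector

# chunk of variants per vectorized regression pass
_ASSOC_CHUNK = 4096

_P_FLOOR = np.finfo(np.float64).tiny  # keep p strictly positive

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(sps.chi2.ppf(0.5, df=1))


@dataclass
class SummaryStats:
    """Per-variant association results, row-aligned with the genotype matrix."""

    table: pd.DataFrame  # chrom, pos, id, a1, beta, se, stat, p, n [, odds_ratio]
    trait_type: str  # "quantitative" | "binary"

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy()
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        se = self.table["se"].to_numpy()
        if np.any(se[np.isfinite(se)] < 0):
            raise ValueError("standard errors must be positive where defined")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str) -> None:
        """Write qassoc-style columns: CHR SNP BP A1 BETA SE STAT P NMISS [OR]."""
        out = pd.DataFrame(
            {
                "CHR": self.table["chrom"],
                "SNP": self.table["id"],
                "BP": self.table["pos"],
                "A1": self.table["a1"],
                "BETA": self.table["beta"],
                "SE": self.table["se"],
                "STAT": self.table["stat"],
                "P": self.table["p"],
                "NMISS": self.table["n"],
            }
        )
        if "odds_ratio" in self.table.columns:
            out["OR"] = self.table["odds_ratio"]
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _align_phenotype(genotypes: GenotypeMatrix, sample_ids: list[str], values: np.ndarray) -> np.ndarray:
    if list(sample_ids) == list(genotypes.sample_ids):
        return values
    pos = {s: i for i, s in enumerate(sample_ids)}
    try:
        order = [pos[s] for s in genotypes.sample_ids]
    except KeyError as e:
        raise ValueError(f"sample id mismatch between genotypes and phenotype: {e}") from None
    return values[np.array(order)]


def assoc_quantitative(genotypes: GenotypeMatrix, pheno: PhenotypeVector) -> SummaryStats:
    """Per-variant simple linear regression of the trait on dosage."""
    n = genotypes.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for association testing")
    y = _align_phenotype(genotypes, pheno.sample_ids, pheno.values).astype(np.float64)
    yc = y - y.mean()
    syy = float(yc @ yc)

    m = genotypes.n_variants
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    p = np.ones(m)
    for start in range(0, m, _ASSOC_CHUNK):
        X = genotypes.dosages[:, start : start + _ASSOC_CHUNK].astype(np.float64)
        xm = X.mean(axis=0)
        sxx = (X * X).sum(axis=0) - n * xm**2
        sxy = X.T @ yc  # yc is centered, so no mean cross-term
        poly = sxx > 0
        b = np.zeros(X.shape[1])
        b[poly] = sxy[poly] / sxx[poly]
        rss = np.maximum(syy - b * sxy, 0.0)
        sigma2 = rss / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(sigma2 / sxx)
            t = b / s
        pv = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        sl = slice(start, start + X.shape[1])
        beta[sl] = b
        se[sl] = np.where(poly, s, np.nan)
        stat[sl] = np.where(poly, t, np.nan)
        p[sl] = np.where(poly & np.isfinite(t), np.clip(pv, _P_FLOOR, 1.0), 1.0)
        # perfect fit (zero residual, nonzero slope): infinite t, p at the floor;
        # a NaN t (zero-variance response) stays at the p = 1 convention
        p[sl] = np.where(poly & np.isinf(t), _P_FLOOR, p[sl])

    table = pd.DataFrame(
        {
            "chrom": genotypes.variants["chrom"],
            "pos": genotypes.variants["pos"],
            "id": genotypes.variants["id"],
            "a1": genotypes.variants["alt"],
            "beta": beta,
            "se": se,
            "stat": stat,
            "p": p,
            "n": n,
        }
    )
    return SummaryStats(table=table, trait_type="quantitative")


def assoc_binary(genotypes: GenotypeMatrix, labels: np.ndarray) -> SummaryStats:
    """Allelic 1-df chi-square test on case/control x ref/alt allele counts.

    ``labels`` uses PLINK coding: 1 = control, 2 = case. The beta column is
    the log odds ratio with a 0.5 continuity correction when any cell is 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != genotypes.n_samples:
        raise ValueError("labels length must equal the number of samples")
    cases = labels == 2
    controls = labels == 1
    n_case, n_ctrl = int(cases.sum()), int(controls.sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both case and control classes must be non-empty")

    D = genotypes.dosages
    a = D[cases].sum(axis=0, dtype=np.int64).astype(np.float64)  # case alt alleles
    c = D[controls].sum(axis=0, dtype=np.int64).astype(np.float64)  # control alt alleles
    b = 2.0 * n_case - a  # case ref
    d = 2.0 * n_ctrl - c  # control ref

    total = a + b + c + d
    alt_tot = a + c
    ref_tot = b + d
    chi2 = np.zeros_like(a)
    poly = (alt_tot > 0) & (ref_tot > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = total * (a * d - b * c) ** 2
        den = alt_tot * ref_tot * (a + b) * (c + d)
        chi2[poly] = num[poly] / den[poly]
    p = np.where(poly, np.clip(sps.chi2.sf(chi2, df=1), _P_FLOOR, 1.0), 1.0)

    zero_cell = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa = np.where(zero_cell, a + 0.5, a)
    bb = np.where(zero_cell, b + 0.5, b)
    cc = np.where(zero_cell, c + 0.5, c)
    dd = np.where(zero_cell, d + 0.5, d)
    odds_ratio = (aa * dd) / (bb * cc)
    log_or = np.log(odds_ratio)
    se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)

    table = pd.DataFrame(
        {
            "chrom": genotypes.variants["chrom"],
            "pos": genotypes.variants["pos"],
            "id": genotypes.variants["id"],
            "a1": genotypes.variants["alt"],
            "beta": np.where(poly, log_or, 0.0),
            "se": np.where(poly, se, np.nan),
            "stat": np.where(poly, chi2, np.nan),
            "p": p,
            "n": genotypes.n_samples,
            "odds_ratio": np.where(poly, odds_ratio, np.nan),
        }
    )
    return SummaryStats(table=table, trait_type="binary")


def genomic_inflation(stats: SummaryStats) -> float:
    """Genomic inflation factor: median observed chi-square / null median."""
    if len(stats) < 1:
        raise ValueError("need at least one variant")
    chi2 = sps.chi2.isf(stats.table["p"].to_numpy(), df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)
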