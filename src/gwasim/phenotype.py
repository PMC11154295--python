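"""Variance-partition phenotype simulation from causal genotypes.

The quantitative trait is built from empirically standardized components so
the realized variance split equals the requested one exactly:

    y = sqrt(h2) * g + sqrt(1 - h2) * e

where g is the (unit-variance) genetic score and e is unit-variance Gaussian
noise residualized against g. The genetic score itself splits as
sqrt(hs2) * g_causal + sqrt(1 - hs2) * g_background, with the background a
polygenic score over B background variants with i.i.d. Normal(0, 1/B)
effects, orthogonalized against the causal score. Effect sizes are drawn from
Normal(m_beta, sd_beta^2); an optional sign flip randomizes direction.

The shared-effect parameters theta and alpha and the fixed-effect parameters
p_indep and phi only matter for multi-trait simulation; for a single trait
they must hold their inert defaults (0, 0, 1, 1) and any other value is
rejected loudly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class PhenotypeParams:
    """Variance-partition parameters; defaults are the validated single-trait set."""

    m_beta: float = 0.05
    sd_beta: float = 0.001
    h2: float = 0.1
    hs2: float = 1.0
    theta: float = 0.0
    p_indep: float = 1.0
    phi: float = 1.0
    alpha: float = 0.0
    random_sign: bool = False

    def validate(self) -> None:
        for name in ("h2", "hs2", "phi"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sd_beta < 0:
            raise ValueError(f"sd_beta must be >= 0, got {self.sd_beta}")
        # multi-trait machinery is out of scope: the four shared/fixed-effect
        # parameters must hold their single-trait inert values
        inert = {"theta": 0.0, "alpha": 0.0, "p_indep": 1.0, "phi": 1.0}
        for name, expect in inert.items():
            if getattr(self, name) != expect:
                raise ValueError(
                    f"{name}={getattr(self, name)} is only meaningful for multi-trait "
                    f"simulation (not implemented); single-trait runs require {name}={expect}"
                )


@dataclass
class PhenotypeVector:
    """Simulated trait values with their genetic and noise components."""

    sample_ids: list[str]
    values: np.ndarray
    genetic: np.ndarray
    noise: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")
        if not np.allclose(self.genetic + self.noise, self.values, atol=1e-12):
            raise ValueError("components must sum to the trait values")

    @property
    def n(self) -> int:
        return len(self.values)

    def genetic_variance_fraction(self) -> float:
        """Realized var(genetic component) / var(values)."""
        return float(np.var(self.genetic) / np.var(self.values))

    def to_tsv(self, path: str) -> None:
        """PLINK-style phenotype file: FID, IID, PHENO."""
        with open(path, "w") as fh:
            fh.write("FID\tIID\tPHENO\n")
            for sid, v in zip(self.sample_ids, self.values):
                fh.write(f"{sid}\t{sid}\t{v:.10g}\n")


def draw_effects(K: int, params: PhenotypeParams, seed: int = 0) -> np.ndarray:
    """Draw K effect sizes: Normal(m_beta, sd_beta^2), optionally sign-flipped."""
    if K < 1:
        raise ValueError("K must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    beta = rng.normal(params.m_beta, params.sd_beta, size=K)
    if params.random_sign:
        beta *= rng.choice([-1.0, 1.0], size=K)
    return beta


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def _residualize(x: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Remove the empirical projection of x onto (centered) ``against``."""
    x = x - x.mean()
    denom = float(against @ against)
    if denom == 0:
        return x
    return x - (float(x @ against) / denom) * against


def simulate_quantitative(
    causal_genotypes: GenotypeMatrix,
    beta: np.ndarray,
    params: PhenotypeParams,
    background_genotypes: GenotypeMatrix | None = None,
    seed: int = 0,
) -> PhenotypeVector:
    """Simulate a quantitative trait from causal genotypes.

    The causal score is the beta-weighted sum of column-standardized dosages,
    rescaled to unit empirical variance. Noise (and the hs2 < 1 background
    score) is residualized against the genetic score before standardization,
    so var(genetic part) / var(values) equals h2 up to floating error.
    """
    params.validate()
    X = causal_genotypes.dosages
    n, K = X.shape
    if len(beta) != K:
        raise ValueError(f"effect vector length {len(beta)} != K={K}")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if params.hs2 < 1.0 and background_genotypes is None:
        raise ValueError("hs2 < 1 requires background_genotypes")

    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = causal_genotypes.variants.loc[np.flatnonzero(sd == 0), "id"].tolist()
        raise ValueError(f"zero-variance causal variant(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    g = _standardize(Z @ beta)

    rng = np.random.default_rng(seed)
    if params.hs2 < 1.0:
        assert background_genotypes is not None
        B = background_genotypes.dosages
        bsd = B.std(axis=0)
        keep = bsd > 0
        Zb = (B[:, keep] - B[:, keep].mean(axis=0)) / bsd[keep]
        bg_beta = rng.normal(0.0, 1.0 / np.sqrt(Zb.shape[1]), size=Zb.shape[1])
        bg = _standardize(_residualize(Zb @ bg_beta, g))
        genetic = np.sqrt(params.hs2) * g + np.sqrt(1.0 - params.hs2) * bg
    else:
        genetic = g

    if params.h2 == 1.0:
        values = genetic
        noise_part = np.zeros(n)
    else:
        eps = rng.standard_normal(n)
        eps = _standardize(_residualize(eps, genetic))
        values = np.sqrt(params.h2) * genetic + np.sqrt(1.0 - params.h2) * eps
        noise_part = np.sqrt(1.0 - params.h2) * eps
    genetic_part = np.sqrt(params.h2) * genetic

    return PhenotypeVector(
        sample_ids=list(causal_genotypes.sample_ids),
        values=values,
        genetic=genetic_part,
        noise=noise_part,
    )


def binarize(pheno: PhenotypeVector, prevalence: float, seed: int = 0) -> np.ndarray:
    """Liability-threshold case/control labels (1=control, 2=case).

    Cases are the individuals whose trait value lies above the empirical
    (1 - prevalence) quantile: exactly round(prevalence * N) cases, ties
    broken by sample order. The ``seed`` argument is accepted for interface
    symmetry with the other simulation steps but the thresholding itself is
    deterministic.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    n = pheno.n
    n_cases = int(round(prevalence * n))
    if n_cases < 1:
        raise ValueError(f"prevalence {prevalence} yields no cases at N={n}")
    # stable sort on descending value keeps earlier samples first among ties
    order = np.argsort(-pheno.values, kind="stable")
    labels = np.ones(n, dtype=np.int64)
    labels[order[:n_cases]] = 2
    return labels
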