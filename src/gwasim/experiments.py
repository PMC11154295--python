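"""Replicate experiments over the full simulation pipeline.

These helpers bundle the per-replicate chain (causal selection -> phenotype
-> association -> clumping -> scoring) that both the parameter grid search
and the validation experiments repeat many times on a fixed genotype dataset.
Genotypes are simulated once per bundle and reused across replicates, with
per-replicate seeds derived from a master seed; each replicate redraws the
causal set, the effect sizes, and the noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotation, causal, fixtures, phenotype
from .association import SummaryStats, assoc_quantitative, genomic_inflation
from .annotation import GeneSetCollection, SnpGeneMap
from .evaluation import EvalMetrics, precision_recall_f1
from .genotypes import GenotypeMatrix, simulate_genotypes
from .ldtools import GENOMEWIDE_P, ClumpParams, ClumpSet, clump
from .pipeline import derive_seeds


@dataclass
class SimulationInputs:
    """Fixed inputs shared by all replicates of an experiment."""

    genotypes: GenotypeMatrix
    gene_map: SnpGeneMap
    gene_sets: GeneSetCollection
    pool: list[str]

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples


def build_inputs(
    seed: int,
    n_individuals: int,
    config: fixtures.FixtureConfig | None = None,
    switch_rate: float = 0.002,
) -> SimulationInputs:
    """Generate a fixture panel, expand it to N individuals, and annotate.

    One bundle per (seed, config): the panel, the simulated genotype matrix,
    the nearest-gene map, the gene sets, and the causal-candidate pool.
    """
    config = config or fixtures.FixtureConfig(seed=derive_seeds(seed, "panel"))
    panel = fixtures.make_panel(config)
    genotypes = simulate_genotypes(
        panel, n_individuals, switch_rate=switch_rate, seed=derive_seeds(seed, "genotypes")
    )
    genes, sets = fixtures.make_annotation(config, panel)
    gene_map = annotation.nearest_gene(genotypes.variants, genes)
    pool = annotation.candidate_pool(genotypes)
    return SimulationInputs(genotypes=genotypes, gene_map=gene_map, gene_sets=sets, pool=pool)


#: study conditions of the default-parameter validation experiments: a
#: 200-haplotype panel over 20,000 SNPs in 2,000 LD blocks, expanded to
#: N = 10,000 individuals
VALIDATION_FIXTURE = dict(n_diploids=100, n_snps=20000, n_blocks=2000, n_genes=600)
VALIDATION_N = 10000
VALIDATION_SET = "FIXTURE_MEDIUM_PATHWAY"


def validation_inputs(seed: int) -> SimulationInputs:
    """Build the fixed inputs of the default-parameter validation experiments."""
    config = fixtures.FixtureConfig(**VALIDATION_FIXTURE, seed=derive_seeds(seed, "panel"))
    return build_inputs(seed, VALIDATION_N, config=config)


@dataclass
class ReplicateResult:
    metrics: EvalMetrics
    clumps: ClumpSet
    spec: causal.CausalSpec
    stats: SummaryStats | None = None


def run_replicate(
    inputs: SimulationInputs,
    set_name: str,
    K: int,
    k: int,
    params: phenotype.PhenotypeParams,
    clump_params: ClumpParams | None = None,
    seed: int = 0,
    keep_stats: bool = False,
) -> ReplicateResult:
    """One full pathway-anchored simulation replicate, scored against truth."""
    clump_params = clump_params or ClumpParams(p1=GENOMEWIDE_P)
    spec = causal.select_from_pathway(
        inputs.gene_map,
        inputs.pool,
        inputs.gene_sets,
        set_name,
        K=K,
        k=k,
        seed=derive_seeds(seed, "causal"),
    )
    causal_geno = causal.extract_causal_genotypes(inputs.genotypes, spec)
    beta = phenotype.draw_effects(K, params, seed=derive_seeds(seed, "effects"))
    pheno = phenotype.simulate_quantitative(
        causal_geno, beta, params, seed=derive_seeds(seed, "phenotype")
    )
    stats = assoc_quantitative(inputs.genotypes, pheno)
    clumps = clump(stats, inputs.genotypes, clump_params)
    metrics = precision_recall_f1(clumps, spec)
    return ReplicateResult(
        metrics=metrics, clumps=clumps, spec=spec, stats=stats if keep_stats else None
    )


def replicate_metrics(
    inputs: SimulationInputs,
    set_name: str,
    K: int,
    k: int,
    params: phenotype.PhenotypeParams,
    n_replicates: int,
    seed: int = 0,
    clump_params: ClumpParams | None = None,
) -> pd.DataFrame:
    """Precision/recall/F1 for ``n_replicates`` seeded replicates."""
    rows = []
    for rep in range(n_replicates):
        res = run_replicate(
            inputs, set_name, K, k, params,
            clump_params=clump_params, seed=derive_seeds(seed, "replicate", rep),
        )
        rows.append(
            {"replicate": rep, **res.metrics.to_dict()}
        )
    return pd.DataFrame(rows)


def null_calibration(
    inputs: SimulationInputs,
    set_name: str,
    n_seeds: int = 10,
    seed: int = 0,
    K: int = 10,
    k: int = 5,
) -> pd.DataFrame:
    """Null (h2 = 0) calibration: per-seed p<0.05 fraction and genomic lambda.

    The p<0.05 fraction is evaluated on an LD-pruned (approximately
    independent) variant subset: the binomial reference band assumes
    independent tests, which variants inside an LD block are not. Genomic
    lambda, a median-based statistic, is computed on the same subset.
    """
    from .ldtools import ld_prune

    geno = inputs.genotypes
    # prune on a sample subset: r^2 estimates for thresholding need far fewer
    # individuals than association does
    n_sub = min(1000, geno.n_samples)
    sub = GenotypeMatrix(
        variants=geno.variants, dosages=geno.dosages[:n_sub],
        sample_ids=list(geno.sample_ids[:n_sub]),
    )
    kept = set(ld_prune(sub, window=50, step=5, r2_max=0.1))
    keep_mask = geno.variants["id"].isin(kept).to_numpy()

    params = phenotype.PhenotypeParams(h2=0.0)
    rows = []
    for rep in range(n_seeds):
        rep_seed = derive_seeds(seed, "null", rep)
        spec = causal.select_from_pathway(
            inputs.gene_map, inputs.pool, inputs.gene_sets, set_name,
            K=K, k=k, seed=derive_seeds(rep_seed, "causal"),
        )
        causal_geno = causal.extract_causal_genotypes(inputs.genotypes, spec)
        beta = phenotype.draw_effects(K, params, seed=derive_seeds(rep_seed, "effects"))
        pheno = phenotype.simulate_quantitative(
            causal_geno, beta, params, seed=derive_seeds(rep_seed, "phenotype")
        )
        stats = assoc_quantitative(inputs.genotypes, pheno)
        p = stats.table.loc[keep_mask, "p"].to_numpy()
        pruned = SummaryStats(
            table=stats.table.loc[keep_mask].reset_index(drop=True),
            trait_type=stats.trait_type,
        )
        rows.append(
            {
                "replicate": rep,
                "frac_p_below_05": float(np.mean(p < 0.05)),
                "lambda_gc": genomic_inflation(pruned),
                "n_variants": len(p),
            }
        )
    return pd.DataFrame(rows)
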