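"""Scoring of simulations against ground truth, and enrichment-benchmark rates.

Precision is the fraction of clumps that contain at least one predefined
causal variant (as index or member); recall is the fraction of the K causal
variants captured by any clump; F1 is their harmonic mean. For enrichment
benchmarking, TPR is the fraction of causal-design simulations in which the
target gene set is significantly enriched after multiple-testing correction,
and FPR the fraction of null-design simulations with at least one significant
set; both carry Wilson score intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .causal import CausalSpec
from .ldtools import ClumpSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalMetrics:
    precision: float
    recall: float
    f1: float
    n_clumps: int
    n_causal: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_clumps": self.n_clumps,
            "n_causal": self.n_causal,
        }


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 / (1.0 / precision + 1.0 / recall) if precision > 0 and recall > 0 else 0.0


def precision_recall_f1(
    clumps: ClumpSet, spec: CausalSpec, count_members: bool = True
) -> EvalMetrics:
    """Score clumps against the known causal variants.

    ``count_members=True`` (the primary definition) counts a causal variant
    as recovered whether it is a clump's index or one of its members;
    ``count_members=False`` restricts to index variants only.
    """
    causal = set(spec.variant_ids)
    n_clumps = len(clumps)
    if n_clumps == 0:
        return EvalMetrics(0.0, 0.0, 0.0, 0, len(causal))
    hit_clumps = 0
    covered: set[str] = set()
    for c in clumps.clumps:
        ids = set(c.all_ids) if count_members else {c.index_id}
        inter = ids & causal
        if inter:
            hit_clumps += 1
            covered |= inter
    precision = hit_clumps / n_clumps
    recall = len(covered) / len(causal) if causal else 0.0
    return EvalMetrics(precision, recall, _f1(precision, recall), n_clumps, len(causal))


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError("successes must lie in [0, n]")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    z = sps.norm.ppf((1.0 + confidence) / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    spread = (z / denom) * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    # the closed form hits the boundaries exactly at 0 or n successes;
    # pin them so floating round-off cannot move them inward
    low = 0.0 if successes == 0 else float(max(0.0, center - spread))
    high = 1.0 if successes == n else float(min(1.0, center + spread))
    return (low, high)


@dataclass(frozen=True)
class BenchmarkRates:
    tpr: float
    fpr: float
    n_causal_sims: int
    n_null_sims: int
    tpr_ci: tuple[float, float]
    fpr_ci: tuple[float, float]
    confidence: float


def tpr_fpr(
    results: pd.DataFrame,
    target_set: str,
    alpha: float = 0.05,
    multiple_testing: str = "bonferroni",
) -> BenchmarkRates:
    """Benchmark rates from a per-simulation enrichment result table.

    ``results`` needs columns ``sim`` (simulation id), ``set`` (gene set
    name), ``p`` (enrichment p-value), and ``design`` ("causal" or "null").
    Per simulation, the multiple-testing procedure (none | bonferroni |
    benjamini-hochberg) is applied over its tested sets at level ``alpha``.
    """
    required = {"sim", "set", "p", "design"}
    if not required.issubset(results.columns):
        raise ValueError(f"results table needs columns {sorted(required)}")
    if target_set not in set(results["set"]):
        raise ValueError(f"target set {target_set!r} absent from the results table")
    if multiple_testing not in ("none", "bonferroni", "benjamini-hochberg"):
        raise ValueError(f"unknown multiple-testing procedure {multiple_testing!r}")

    def significant(group: pd.DataFrame) -> pd.Series:
        p = group["p"].to_numpy()
        if multiple_testing == "none":
            return pd.Series(p < alpha, index=group.index)
        if multiple_testing == "bonferroni":
            return pd.Series(p * len(p) < alpha, index=group.index)
        from statsmodels.stats.multitest import multipletests

        rej, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        return pd.Series(rej, index=group.index)

    tp = 0
    n_causal = 0
    fp = 0
    n_null = 0
    for (sim, design), group in results.groupby(["sim", "design"], sort=False):
        sig = significant(group)
        if design == "causal":
            n_causal += 1
            hit = group.loc[sig, "set"].eq(target_set).any()
            tp += int(hit)
        elif design == "null":
            n_null += 1
            fp += int(sig.any())
        else:
            raise ValueError(f"unknown design label {design!r} (expected 'causal' or 'null')")

    tpr = tp / n_causal if n_causal else float("nan")
    fpr = fp / n_null if n_null else float("nan")
    tpr_ci = wilson_interval(tp, n_causal) if n_causal else (float("nan"), float("nan"))
    fpr_ci = wilson_interval(fp, n_null) if n_null else (float("nan"), float("nan"))
    return BenchmarkRates(
        tpr=tpr,
        fpr=fpr,
        n_causal_sims=n_causal,
        n_null_sims=n_null,
        tpr_ci=tpr_ci,
        fpr_ci=fpr_ci,
        confidence=0.95,
    )


def read_enrichment_table(path: str) -> pd.DataFrame:
    """Adapter for external enrichment-tool output: TSV with sim/set/p/design."""
    df = pd.read_csv(path, sep="\t")
    required = {"sim", "set", "p", "design"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: enrichment table needs columns {sorted(required)}")
    return df


def grid_search(
    param_grid: Sequence[dict],
    n_replicates: int,
    base_inputs,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean precision/recall/F1 per parameter set, ranked by mean F1.

    ``param_grid`` is a sequence of dictionaries, each with keys ``set_name``,
    ``K``, ``k``, and optional phenotype-parameter overrides (``m_beta``,
    ``sd_beta``, ``h2``, ...); ``base_inputs`` is an
    :class:`~gwasim.experiments.SimulationInputs` bundle whose genotypes are
    reused across all grid points. A failing replicate is recorded as zero
    metrics with a logged diagnostic. The returned table has one row per grid
    point, ranked by mean F1 descending, ties by mean recall descending.
    """
    if not param_grid:
        raise ValueError("parameter grid is empty")
    from .experiments import run_replicate  # local import: experiments builds on this module
    from .phenotype import PhenotypeParams
    from .pipeline import derive_seeds

    structural = {"set_name", "K", "k"}
    rows = []
    for gi, point in enumerate(param_grid):
        pheno_params = PhenotypeParams(**{k: v for k, v in point.items() if k not in structural})
        metrics = []
        for rep in range(n_replicates):
            rep_seed = derive_seeds(seed, f"grid{gi}", rep)
            try:
                res = run_replicate(
                    base_inputs, point["set_name"], point["K"], point["k"],
                    pheno_params, seed=rep_seed,
                )
                metrics.append(res.metrics)
            except Exception as exc:  # noqa: BLE001 - survey must not crash
                logger.warning("grid point %d replicate %d failed: %s", gi, rep, exc)
                metrics.append(EvalMetrics(0.0, 0.0, 0.0, 0, 0))
        row = dict(point)
        row["mean_precision"] = float(np.mean([m.precision for m in metrics]))
        row["mean_recall"] = float(np.mean([m.recall for m in metrics]))
        row["mean_f1"] = float(np.mean([m.f1 for m in metrics]))
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_f1", "mean_recall"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
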