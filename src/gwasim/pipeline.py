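"""End-to-end orchestration of the three-stage simulation workflow.

Stage 1 simulates (or ingests) genotypes from a phased reference panel,
stage 2 selects causal variants and simulates the trait, stage 3 runs the
association scan, clumping, evaluation and plotting. Every run writes a JSON
manifest recording parameters, derived seeds, package version, and SHA-256
checksums of all outputs, so any artifact can be regenerated from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__ as _version
from . import annotation, causal, genotypes, ldtools, phenotype, viz
from .association import assoc_binary, assoc_quantitative, genomic_inflation
from .evaluation import precision_recall_f1
from .phenotype import PhenotypeParams

logger = logging.getLogger(__name__)

_SEED_SPACE = 2**31


def derive_seeds(master_seed: int, stage: str, replicate: int = 0) -> int:
    """Deterministic, collision-resistant per-stage/replicate seed derivation."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{replicate}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _SEED_SPACE


@dataclass
class RunConfig:
    """All inputs and parameters of a pipeline run."""

    out_prefix: str
    seed: int = 0
    # stage 1: genotypes (either simulate from a panel VCF or load directly)
    vcf: list[str] = field(default_factory=list)
    genotype_vcf: str | None = None  # skip simulation, use these genotypes
    keep: str | None = None
    maf: float = 0.05
    n_individuals: int | None = None
    switch_rate: float = 0.002
    # stage 2: causal selection + phenotype
    causal_maf_min: float = 0.05
    causal_maf_max: float = 0.5
    k_total: int = 10
    k_pathway: int = 5
    gmt: str | None = None
    gene_set: str | None = None
    causal_ids: str | None = None  # file with explicit ids, one per line
    annotation_file: str | None = None
    params: PhenotypeParams = field(default_factory=PhenotypeParams)
    trait: str = "quant"  # quant | binary
    prevalence: float = 0.1
    # stage 3: clumping / pruning / plots
    clump: ldtools.ClumpParams = field(default_factory=ldtools.ClumpParams)
    eval_clump_p1: float = ldtools.GENOMEWIDE_P
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    suggestive_p: float = 1e-4
    genomewide_p: float = 5e-8

    def validate(self) -> None:
        pathway_mode = self.gene_set is not None
        explicit_mode = self.causal_ids is not None
        if pathway_mode == explicit_mode:
            raise ValueError("exactly one of gene_set or causal_ids must be given")
        if pathway_mode and (self.gmt is None or self.annotation_file is None):
            raise ValueError("pathway mode requires gmt and annotation_file")
        if self.genotype_vcf is None:
            if not self.vcf:
                raise ValueError("either panel vcf(s) or genotype_vcf must be given")
            if self.n_individuals is None:
                raise ValueError("n_individuals is required when simulating genotypes")
        if self.trait not in ("quant", "binary"):
            raise ValueError(f"trait must be 'quant' or 'binary', got {self.trait!r}")
        for p in [*self.vcf, self.genotype_vcf, self.keep, self.gmt, self.causal_ids,
                  self.annotation_file]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        params = PhenotypeParams(**raw.pop("params", {}))
        clump_kwargs = raw.pop("clump", {})
        return cls(params=params, clump=ldtools.ClumpParams(**clump_kwargs), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the manifest dictionary.

    Writes, under ``config.out_prefix``: genotypes (VCF + dosage TSV +
    variant sidecar), the causal-variant table, the phenotype file, summary
    statistics, the clump report, evaluation metrics, plots with their
    coordinate sidecars, and the JSON manifest. On stage failure the partial
    outputs are retained and the manifest records the failure point.
    """
    config.validate()
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "outputs": {},
        "failed_stage": None,
    }
    manifest_path = Path(f"{prefix}.manifest.json")

    def finish(stage: str, exc: Exception) -> dict:
        logger.error("stage %s failed: %s", stage, exc)
        manifest["failed_stage"] = {"stage": stage, "error": str(exc)}
        _write_manifest(manifest, manifest_path, prefix)
        raise exc

    t0 = time.time()
    # ---- stage 1: genotypes ------------------------------------------------
    try:
        if config.genotype_vcf is not None:
            # simulation-skip path: user-supplied genotypes, phased or not
            geno = genotypes.load_genotypes(config.genotype_vcf)
        else:
            parts = []
            for v in config.vcf:
                panel = genotypes.load_panel(v)
                keep_ids = None
                if config.keep:
                    keep_ids = [s for s in Path(config.keep).read_text().split() if s]
                panel = genotypes.filter_panel(panel, min_maf=config.maf, keep_ids=keep_ids)
                parts.append(
                    genotypes.simulate_genotypes(
                        panel,
                        config.n_individuals,
                        switch_rate=config.switch_rate,
                        seed=derive_seeds(config.seed, f"genotypes:{v}"),
                    )
                )
            geno = parts[0] if len(parts) == 1 else genotypes.merge_panels(parts)
        genotypes.write_genotype_vcf(geno, f"{prefix}.genotypes.vcf")
        genotypes.write_dosage_matrix(
            geno, f"{prefix}.dosages.tsv", f"{prefix}.variants.tsv"
        )
        manifest["stages"]["genotypes"] = {
            "n_samples": geno.n_samples, "n_variants": geno.n_variants,
            "elapsed_s": round(time.time() - t0, 3),
        }
    except Exception as exc:  # noqa: BLE001
        return finish("genotypes", exc)

    # ---- stage 2: causal selection + phenotype -----------------------------
    t1 = time.time()
    try:
        if config.causal_ids is not None:
            ids = [s for s in Path(config.causal_ids).read_text().split() if s]
            spec = causal.select_explicit(ids, geno)
        else:
            genes = annotation.read_gene_intervals(config.annotation_file)
            gene_map = annotation.nearest_gene(geno.variants, genes)
            sets = annotation.read_gmt(config.gmt)
            pool = annotation.candidate_pool(
                geno, min_maf=config.causal_maf_min, max_maf=config.causal_maf_max
            )
            spec = causal.select_from_pathway(
                gene_map, pool, sets, config.gene_set,
                K=config.k_total, k=config.k_pathway,
                seed=derive_seeds(config.seed, "causal"),
            )
        spec.to_tsv(f"{prefix}.causal.tsv", geno)
        causal_geno = causal.extract_causal_genotypes(geno, spec)
        beta = phenotype.draw_effects(
            len(spec), config.params, seed=derive_seeds(config.seed, "effects")
        )
        pheno = phenotype.simulate_quantitative(
            causal_geno, beta, config.params, seed=derive_seeds(config.seed, "phenotype")
        )
        labels = None
        if config.trait == "binary":
            labels = phenotype.binarize(
                pheno, config.prevalence, seed=derive_seeds(config.seed, "binarize")
            )
            with open(f"{prefix}.pheno.tsv", "w") as fh:
                fh.write("FID\tIID\tPHENO\n")
                for sid, lab in zip(pheno.sample_ids, labels):
                    fh.write(f"{sid}\t{sid}\t{lab}\n")
        else:
            pheno.to_tsv(f"{prefix}.pheno.tsv")
        manifest["stages"]["phenotype"] = {
            "K": len(spec), "k_pathway": spec.k_pathway,
            "elapsed_s": round(time.time() - t1, 3),
        }
    except Exception as exc:  # noqa: BLE001
        return finish("phenotype", exc)

    # ---- stage 3: association, clumping, evaluation, plots -----------------
    t2 = time.time()
    try:
        if labels is not None:
            stats = assoc_binary(geno, labels)
        else:
            stats = assoc_quantitative(geno, pheno)
        stats.to_tsv(f"{prefix}.assoc.tsv")
        clumps = ldtools.clump(stats, geno, config.clump)
        clumps.to_tsv(f"{prefix}.clumped.tsv")
        eval_clumps = ldtools.clump(
            stats, geno,
            ldtools.ClumpParams(
                p1=config.eval_clump_p1, p2=config.clump.p2,
                r2=config.clump.r2, kb=config.clump.kb,
            ),
        )
        metrics = precision_recall_f1(eval_clumps, spec)
        metrics_dict = metrics.to_dict()
        metrics_dict["lambda_gc"] = genomic_inflation(stats)
        with open(f"{prefix}.metrics.json", "w") as fh:
            json.dump(metrics_dict, fh, indent=2)
        viz.manhattan_plot(
            stats, clumps=eval_clumps, suggestive_p=config.suggestive_p,
            genomewide_p=config.genomewide_p, out=f"{prefix}.manhattan.png",
        )
        viz.qq_plot(stats, out=f"{prefix}.qq.png")
        try:
            pca = viz.pca_genotypes(
                geno, prune_params=(config.prune_window, config.prune_step, config.prune_r2)
            )
            viz.pca_plot(pca, out=f"{prefix}.pca.png")
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)
        manifest["stages"]["association"] = {
            "n_clumps": len(clumps), "metrics": metrics_dict,
            "elapsed_s": round(time.time() - t2, 3),
        }
    except Exception as exc:  # noqa: BLE001
        return finish("association", exc)

    _write_manifest(manifest, manifest_path, prefix)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _write_manifest(manifest: dict, manifest_path: Path, prefix: Path) -> None:
    outputs = {}
    for f in sorted(prefix.parent.glob(f"{prefix.name}.*")):
        if f == manifest_path:
            continue
        outputs[f.name] = _sha256(f)
    manifest["outputs"] = outputs
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
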