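#!/usr/bin/env bash
# The same workflow from the shell: write synthetic inputs, then run the
# three-stage pipeline end to end (genotypes -> phenotype -> association,
# clumping, evaluation, plots) with one seed controlling everything.
set -euo pipefail

out=example_output/cli
mkdir -p "$out"

gwasim make-fixtures --n-diploids 80 --n-snps 2000 --n-blocks 200 \
    --n-genes 300 --seed 5 --out "$out/fx"

gwasim run-all \
    --vcf "$out/fx.panel.vcf" \
    --gmt "$out/fx.sets.gmt" \
    --annotation "$out/fx.genes.gtf" \
    --gene-set FIXTURE_MEDIUM_PATHWAY \
    --n-individuals 1000 \
    --k-total 8 --k-pathway 4 \
    --h2 0.3 \
    --seed 5 \
    --out "$out/run"

echo "metrics:"
cat "$out/run.metrics.json"
echo
echo "artifacts:"
ls -1 "$out" | sed 's/^/  /'
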