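"""Benchmark-rate bookkeeping for enrichment tools (TPR/FPR with Wilson CIs).

Enrichment analysis itself happens in external tools; their per-simulation
result tables (simulation id, gene set, p-value, design) are consumed here.
This example fabricates such a table for a tool with 80% power at alpha=0.05
after Bonferroni correction and a mild false-positive tendency, then computes
the rates the way a benchmarking study would report them.
"""

import numpy as np
import pandas as pd

from gwasim import tpr_fpr, wilson_interval

rng = np.random.default_rng(31)
sets = [f"PATHWAY_{i:02d}" for i in range(20)]
target = "PATHWAY_00"

rows = []
for sim in range(30):  # causal-design simulations: target truly enriched
    for s in sets:
        if s == target:
            p = 10 ** rng.uniform(-8, -3) if rng.random() < 0.8 else rng.uniform(0.01, 1)
        else:
            p = rng.uniform()
        rows.append({"sim": f"causal{sim}", "set": s, "p": p, "design": "causal"})
for sim in range(30):  # null-design simulations: no set enriched
    for s in sets:
        p = rng.uniform() if rng.random() > 0.004 else rng.uniform(0, 0.002)
        rows.append({"sim": f"null{sim}", "set": s, "p": p, "design": "null"})
results = pd.DataFrame(rows)

rates = tpr_fpr(results, target_set=target, alpha=0.05, multiple_testing="bonferroni")
print(f"TPR = {rates.tpr:.3f}  (Wilson 95% CI {rates.tpr_ci[0]:.3f}-{rates.tpr_ci[1]:.3f}, "
      f"n = {rates.n_causal_sims} simulations)")
print(f"FPR = {rates.fpr:.3f}  (Wilson 95% CI {rates.fpr_ci[0]:.3f}-{rates.fpr_ci[1]:.3f}, "
      f"n = {rates.n_null_sims} simulations)")
# TPR: fraction of causal-design simulations where the target pathway was
# significant after correction; FPR: fraction of null-design simulations
# with any significant pathway.
print("Wilson interval for 15/30:", wilson_interval(15, 30, 0.95))
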