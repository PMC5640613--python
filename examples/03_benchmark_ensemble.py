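"""Evaluate rankings against a gold standard and ensemble them.

Builds the method's ranking on a spiked cohort plus two deliberately
degraded rankings, scores each with precision/recall/F-score curves
against the true driver list, and combines them with a truncated Borda
count. Also reproduces a Fisher's exact enrichment test comparing the
rate of a gene category between two gene sets.
"""

import numpy as np

from clonedriver import (
    SimulationConfig,
    analyze_cohort,
    borda_ensemble,
    enrichment_test,
    precision_recall_fscore,
    simulate_cohort,
)

cohort, truth, context = simulate_cohort(SimulationConfig(), seed=5)
analysis = analyze_cohort(cohort, context, truth["driver_genes"], seed=5)
ranking = analysis.results.sort_values("rank")["gene"].tolist()
gold = truth["driver_genes"]

rng = np.random.default_rng(0)
noisy_a = list(rng.permutation(ranking[:40])) + ranking[40:]  # scrambled head
noisy_b = list(rng.permutation(ranking))  # random ordering

for name, lst in [("full model", ranking), ("scrambled head", noisy_a), ("random", noisy_b)]:
    curve = precision_recall_fscore(lst, gold)
    print(f"{name:15s} peak F = {curve.peak_fscore:.3f} at rank {curve.peak_rank}")

combined = borda_ensemble([ranking, noisy_a, noisy_b], truncation=2 * len(gold), top_n_methods=2)
curve = precision_recall_fscore(combined, gold)
print(f"{'Borda ensemble':15s} peak F = {curve.peak_fscore:.3f} at rank {curve.peak_rank}")

# enrichment of a category between two gene sets, e.g. 18/63 of one list
# vs 78/504 of a reference list carrying some annotation:
p = enrichment_test(18, 63, 78, 504)
print(f"\nFisher enrichment 18/63 vs 78/504: p = {p:.4f}")
# The ensemble tracks the best constituent ranking; a category hit rate of
# 29% vs 15% in these set sizes is significant at p ~ 0.0125.
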