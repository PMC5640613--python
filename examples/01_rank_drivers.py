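"""Rank driver genes in a simulated tumor cohort.

Generates a 1000-gene, 200-patient cohort with 10 injected driver genes,
runs the full analysis (CCF/damage derivation, dual background models,
both Bayesian posteriors, resampling FDR cutoff) and prints the top of
the ranking. Genes above the suggested rank cutoff are called significant
at an estimated false discovery rate of 10%.
"""

from clonedriver import SimulationConfig, analyze_cohort, simulate_cohort

cohort, truth, context = simulate_cohort(SimulationConfig(), seed=1)
analysis = analyze_cohort(cohort, context, truth["driver_genes"], seed=1)

print(f"cohort: {cohort['patient'].nunique()} patients, {len(cohort)} mutations")
print(f"clonal background rate r = {analysis.background.r:.2f} mutations/patient")
print(f"suggested rank cutoff (FDR 10%): {analysis.cutoff}\n")

top = analysis.results.sort_values("rank").head(12)
print(top[["rank", "gene", "m", "posterior_hazard", "posterior_driver", "fdr"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4f}"))

called = set(analysis.results.loc[analysis.results["significant"], "gene"])
hits = called & set(truth["driver_genes"])
print(f"\n{len(hits)} of {len(truth['driver_genes'])} true drivers called significant;"
      f" {len(called) - len(hits)} false calls")
# m is the per-gene evidence mass (sum over patients of CCF x damage for the
# best mutation); the posteriors separate true drivers (near 1) from the
# passenger background (near 0) by several orders of magnitude.
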