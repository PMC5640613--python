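"""Compare cancer-cell-fraction distributions of four mutation groups.

Splits the mutations of a simulated cohort into nonsilent/silent x
driver-gene/passenger-gene groups and tests every pair with a two-sided
Wilcoxon-Mann-Whitney rank-sum test. In a cohort under positive
selection, nonsilent mutations in driver genes are clonal (CCF near 1)
while the other three groups share the neutral, mostly subclonal CCF
spectrum.
"""

from clonedriver import (
    SimulationConfig,
    annotate_cohort,
    ccf_group_comparison,
    simulate_cohort,
)

cohort, truth, _ = simulate_cohort(SimulationConfig(), seed=3)
cohort = annotate_cohort(cohort)
gc = ccf_group_comparison(cohort, truth["driver_genes"])

print("group medians (CCF) and sizes:")
for g, med in gc.medians.items():
    print(f"  {g:22s} median {med:.3f}  (n = {gc.counts[g]})")

print("\npairwise rank-sum tests:")
print(gc.pairwise.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# Only pairs involving the nonsilent-driver group separate (p << 0.01);
# the remaining groups are draws from the same neutral CCF distribution.
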