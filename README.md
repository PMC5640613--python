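# clonedriver

Bayesian prioritization of positively selected cancer driver genes from
cohort somatic-mutation data.

Tumor sequencing studies need to separate the handful of *driver* genes —
genes whose mutations confer a selective advantage to tumor cells — from
the thousands of genes that accumulate *passenger* mutations neutrally.
Recurrence alone is a weak signal: long genes and mutation-prone genomic
contexts collect passengers too. `clonedriver` combines three orthogonal
signatures of positive selection into a single per-gene score:

* **recurrence** across patients,
* **clonality** — the cancer cell fraction (CCF) of each mutation, since
  selected mutations tend to be clonal (CCF ≈ 1) while neutral ones
  accumulate subclonally,
* **functional impact** — a CADD-like raw score squashed into a damage
  probability by a logistic sigmoid (midpoint μ = 15, scale 2).

It is aimed at computational cancer-genomics practitioners with a cohort
MAF of somatic calls plus per-mutation VAF, purity and ploidy annotations.

## Model

**CCF.** For a mutation of multiplicity 1, `CCF = VAF · (p·CN + 2(1−p)) / p`
with purity `p` and local total copy number `CN` (diploid case: `2·VAF/p`),
clipped to [0, 1]. Precomputed CCFs (e.g. from subclonal deconvolution) are
accepted as-is.

**Foreground evidence.** For gene *g*, each patient contributes its single
highest-CCF nonsilent mutation, and

```
m_g = Σ_{i=1..n} CCF_i · damage_i        (0 for unmutated patients)
```

over the full cohort of `n` patients.

**Background (bmp).** Two neutral models are averaged. The CCF-adjusted
Ka/Ks model predicts the expected nonsilent count from the gene's own
silent mutations, `n̂_a = n_s′ · N_a / N_s`, where `n_s′` floors the
CCF-weighted silent count at `N_s/N_a` so a single nonsilent hit cannot
look selected. The ncmr model uses an externally measured non-coding
mutation rate: `n̂_a = ncmr · L / (1 + N_s/N_a)`. Each expectation vector
is normalized to per-gene probabilities `p_g` and converted to the chance
a patient has ≥ 1 nonsilent mutation in the gene,
`bmp_g = 1 − (1 − p_g)^r`, with `r` the cohort-average per-patient count
of clonal (CCF ≥ 0.85) nonsilent SNVs.

**Posteriors.** The *cancer-hazard* model scores
`P(cancer | ns) = Lπ / (Lπ + bmp·(1−π))` with likelihood `L = m/n` and
incidence prior π. The *driver-inference* model treats the `m` patients
with evidence and `n−m` without as Bernoulli outcomes with success rate
`P(ns|driver)` (estimated from a known-driver list as
`#driver mutations / (#patients · #drivers)`) versus `bmp` under the
passenger hypothesis, with prior `#drivers / #genes`; evaluated in log
space with real-valued exponents.

**Significance.** Gene labels are resampled i.i.d. from the bmp vector
(100 replicates), both models are re-scored, and the FDR at rank *k* is
the median null exceedance count of the observed *k*-th posterior divided
by *k*. The suggested cutoff is the floored mean of the two models'
largest ranks with FDR ≤ 10%.

## Worked example

```
python examples/01_rank_drivers.py
```

simulates a 200-patient cohort (1000 genes, 10 injected drivers) and runs
the full pipeline:

```
cohort: 200 patients, 2214 mutations
clonal background rate r = 2.66 mutations/patient
suggested rank cutoff (FDR 10%): 10

 rank  gene       m  posterior_hazard  posterior_driver    fdr
    1 G0825 22.2351            0.9246            1.0000 0.0000
    2 G0145 26.0175            0.9135            1.0000 0.0000
    ...
   10 G0931 24.3122            0.8255            1.0000 0.0000
   11 G0370  4.2125            0.0811            0.0000 0.6364

10 of 10 true drivers called significant; 0 false calls
```

`m` is the clonality- and impact-weighted recurrence; the ten injected
drivers carry `m ≈ 16–26` against a passenger background of `m ≲ 4`, the
driver posterior saturates for them, and the resampling cutoff lands at
rank 10 exactly. `examples/02_ccf_groups.py` reproduces the four-group CCF
comparison (nonsilent driver-gene mutations are clonal, median CCF 0.94
vs ≈ 0.33 for all other groups), and `examples/03_benchmark_ensemble.py`
shows precision/recall/F-score evaluation, truncated Borda-count
ensembling and Fisher enrichment testing.

The same pipeline is scriptable from the shell:

```
clonedriver simulate --outdir sim --genes 1000 --patients 200 --drivers 10 --seed 1
clonedriver run --maf sim/cohort.maf.tsv --gene-context sim/gene_context.tsv \
    --driver-list sim/true_drivers.txt --outdir out --seed 1
clonedriver benchmark --ranking out/results.tsv --gold sim/true_drivers.txt
```

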