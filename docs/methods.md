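# Methods

## Scope and data model

`clonedriver` ranks genes by evidence of positive somatic selection in a
tumor cohort. Input is an extended MAF v2.4 table (tab-separated, one row
per somatic mutation) with mandatory `Hugo_Symbol`,
`Tumor_Sample_Barcode`, `Variant_Classification` and `VAF` columns and
optional `purity`, `ploidy`, `CNV_CCF` and `CADD` columns, plus a
per-gene context table of nonsynonymous sites `N_a`, synonymous sites
`N_s`, coding length and non-coding mutation rate `ncmr`. Variant
classes are mapped onto {indel, missense, nonsense, splice, TSS,
nonstop, silent}; standard non-coding MAF classes (Intron, UTRs, Flanks,
IGR, RNA, …) are dropped with a logged count, and any other string is a
hard error. Missing purity defaults to 1 (no correction) and missing
ploidy to 2 (diploid), both logged. Genes absent from the context table
cannot enter either background model and are excluded from ranking with
a warning. Upstream steps — variant calling, effect annotation,
expression filtering — are out of scope.

## CCF estimation

Assuming mutation multiplicity 1, a mutation present in a fraction `CCF`
of tumor cells with purity `p` at total copy number `CN` is expected at
`VAF = CCF·p / (p·CN + 2(1−p))`; we invert this and clip to [0, 1] as the
last step. When the CCF of an overlapping CNV is given and below 1, the
effective copy number is the mixture `2(1−w) + CN·w`. The diploid pure
case reduces to `CCF = 2·VAF`. The package equally accepts precomputed
per-mutation CCFs (columns preserved on input unless recomputation is
requested); no clustering of mutations into clones is attempted.

Raw functional-impact scores on a phred-like CADD scale are transformed
to damage probabilities with the logistic `1/(1 + exp(−(x − μ)/s))`,
μ = 15, s = 2. The midpoint sits where CADD separates likely-benign from
likely-damaging coding variants; the logistic is the simplest sigmoid
parameterized by a mean and scale. Mutations without a score get
damage 0 (they then contribute recurrence only through the clonal rate
and background counts).

## Background mutation probability

Two independent neutral expectations per gene are averaged:

* **CCF-adjusted Ka/Ks.** `n_s^CCF` and `n_a^CCF` are sums of CCF over
  silent and nonsilent mutations (all mutations, no per-patient
  collapse — the selection statistic is defined over mutations, not
  patients). Under neutrality (Ka/Ks = 1) the expected nonsilent count is
  `n̂ = n_s′ · N_a/N_s` with `n_s′ = max(n_s^CCF, N_s/N_a)`. The floor is
  the silent mass at which exactly one nonsilent mutation is expected, so
  genes with zero silent mutations do not flag a single nonsilent hit as
  selection.
* **ncmr.** `n̂_t = ncmr · length` total expected mutations, of which the
  nonsilent share is `n̂ = n̂_t / (1 + N_s/N_a)`.

Each model's expectations are normalized to `p_g = n̂_g / Σ n̂` (sums to 1
by construction, asserted to 1e−12) and converted to the probability that
one patient carries ≥ 1 nonsilent mutation in the gene via a binomial
with `r` trials: `bmp_g = 1 − (1 − p_g)^r`. `r` is the cohort-average
per-patient count of clonal nonsilent SNVs (CCF ≥ 0.85, indels excluded
by default, switchable), a proxy for the somatic load acquired before
transformation; it is a cohort mean and is used directly as a real
exponent. The final `bmp` is the arithmetic mean of the two models'.

## Bayesian models

Per-gene foreground evidence collapses each patient to their single
highest-CCF nonsilent mutation (ties: higher damage, then position
string, then input order) and sums `m = Σ CCF_i·damage_i` over the full
cohort of `n` patients, zeros for unmutated patients. `m` is kept
real-valued throughout; no binomial coefficient appears in the posterior
(it would cancel between hypotheses anyway).

* **Cancer-hazard model**: `P(cancer|ns) = Lπ / (Lπ + bmp(1−π))`,
  `L = m/n`, π the population incidence of the tumor type (user prior,
  default 0.1; it scales all genes monotonically and does not affect the
  ranking). `L = bmp = 0` is defined as posterior 0.
* **Driver-inference model**: two-channel Bernoulli likelihood with
  exponents `m` and `n − m`; driver channel `P(ns|d)` estimated as
  `#nonsilent mutations in known drivers / (#patients · #drivers)`
  (capped at 1; user-overridable), passenger channel `bmp_g`; prior
  `#known drivers / 20,000` protein-coding genes. Evaluated in log space;
  probabilities at exactly 0/1 clamped to [1e−12, 1−1e−12].

Note the posterior is decreasing in `bmp` only while `m/n > bmp`; below
that the passenger channel explains the data better as `bmp` grows and
the posterior rises. This is a property of the formula, not a bug.

Default ranking is by the driver posterior (ties: hazard posterior, then
`m`, then gene symbol — a deterministic total order); `hazard` and
`average` rankings are exposed as options.

## Null model and FDR cutoff

Under the no-selection null, every mutation keeps its CCF, damage,
classification and patient but its gene label is redrawn i.i.d. with
probability proportional to `bmp`. Each of 100 replicates (one RNG
stream per replicate spawned from a master seed) is re-scored with both
models and sorted. The observed background (bmp, r) is reused for the
null posteriors: the labels are drawn *from* bmp, and re-deriving the
background per replicate would let the null adapt to its own noise; this
is the main interpretive choice of the implementation. FDR at rank k is
the median over replicates of the count of null posteriors ≥ the
observed k-th posterior, divided by k, capped at 1 and monotonized by
cumulative maximum. Per model the cutoff is the largest rank with
FDR ≤ α (default 0.1), and the suggested combined cutoff is the floored
mean of the two — floored because a rank is an integer and rounding down
is conservative.

## Synthetic cohorts

The generator emulates the clonal-architecture contrast the method
exploits, with ground-truth labels for every mutation. Defaults, chosen
once as a realistic mid-sized exome cohort: 1000 genes, 200 patients, 10
drivers. Passengers arrive per gene and patient as Poisson counts with a
cohort mean of 10 coding mutations/patient and per-gene rate
heterogeneity `length × lognormal(σ = 1)`; their CCFs mix a 25% clonal
component Beta(25, 1.8) (pre-transformation hitchhikers) with 75%
subclonal Beta(1.5, 4), and impacts are Gamma(2, 6) on the CADD scale
(mostly benign). Silent status is assigned with probability
`N_s/(N_a+N_s)` = 0.25. Each driver gene is hit in 12% of patients —
recurrence typical of real drivers below the TP53 tier — with clonal
Beta(25, 1.8) CCFs and damaging Normal(32, 4) impacts, on top of its
passenger background. Purity is Beta(6, 2) clipped to [0.25, 1]; loci
are diploid, and VAF is back-computed from CCF so the estimator recovers
CCFs exactly. The context table's `ncmr` is the true per-gene rate with
lognormal(σ = 0.3) noise, so the ncmr background is informative but
imperfect, as in real data.

What the simulator does not model: non-diploid loci and CNV overlap
(exercised in unit tests only), multiplicity > 1, sequencing-depth noise
in VAF, clustered hotspot positions, inter-patient mutation-load
variation beyond Poisson, and correlated gene sets. Passing tests
therefore demonstrate correct inference under the stated generative
assumptions, not performance on any particular tumor type.

## Numerical and design choices

* Posteriors in log space via `expit` of log-likelihood differences;
  naive arithmetic agrees to 1e−9 relative wherever it does not
  underflow (n ≤ 50, verified in tests).
* Rank-sum tests via `scipy.stats.mannwhitneyu` (two-sided, exact for
  small untied samples, midrank normal approximation with continuity
  correction otherwise); Fisher's exact test two-sided by
  minimum-likelihood summation (scipy), one-sided by flag. Comparison
  groups with < 2 mutations yield NaN p-values rather than errors.
* Clipping CCF to [0, 1] happens after the CNV adjustment.
* Borda ensembling treats genes beyond the truncation rank, or absent
  from a list, as rank `truncation + 1` (score 0) and sums positional
  scores over each gene's best `top_n_methods` lists; ties alphabetical.
* The pipeline is a pure function of (input files, configuration, seed);
  replicate RNG streams are spawned from the master seed so results are
  order-independent.

## Problem sizes

The test suite and the acceptance script use 50 replicates of the
default 1000-gene × 200-patient cohort for the distribution-level
claims (clonality signal, driver recovery, null calibration), with the
100-replicate resampling null inside each run; the vectorized
evidence-mass kernel makes a full analysis run ≈ 0.15 s. Smaller
fixtures (150 genes × 60 patients, 5 drivers at 25% recurrence) back the
file-level and CLI tests.

## Limitations

* CCF estimation assumes mutation multiplicity 1; amplified early
  mutations are underestimated.
* The driver-model likelihood assumes all known drivers are equally
  likely to be hit; the override exists because this is the weakest
  assumption in the chain.
* The empirical FDR is resampling-based only; with few mutations or few
  genes the per-rank medians are coarse.
* Genes are scored independently; no pathway or covariate sharing.
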