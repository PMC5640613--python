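"""Synthetic tumor-cohort generator with known driver/passenger truth.

The generator emulates the clonal architecture signal the ranking method
exploits: driver genes accumulate recurrent, clonal (CCF near 1), highly
damaging nonsilent mutations across patients, while passenger mutations
arrive as a neutral Poisson background whose CCF spectrum mixes a small
clonal component (hitchhikers present in the tumor's founding clone) with
a dominant subclonal tail, and whose impact scores are broad and mostly
benign. Silent mutations arise from the same background in proportion to
each gene's synonymous site share. CCFs are drawn directly — no read
counts or clonal phylogenies are simulated — and VAFs are back-computed
from CCF, purity and diploid copy number so the CCF-estimation step
recovers them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cd_io

#: nonsilent classes drawn for generated mutations, with probabilities
NONSILENT_CLASS_PROBS = {
    "missense": 0.80,
    "nonsense": 0.07,
    "splice": 0.05,
    "indel": 0.08,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator parameters.

    Defaults describe a mid-sized exome cohort: 200 patients, a
    1000-gene universe containing 10 drivers, ~10 somatic coding
    mutations per patient, and per-gene mutation-rate heterogeneity with
    lognormal dispersion sigma = 1. Driver hits occur independently in
    12% of patients per driver gene with clonal CCF ~ Beta(25, 1.8)
    (median ~0.95) and raw impact ~ Normal(32, 4) on the CADD-like scale;
    passenger CCFs mix 25% clonal draws with 75% subclonal Beta(1.5, 4)
    (median ~0.24), and passenger impact ~ Gamma(2, 6).
    """

    n_genes: int = 1000
    n_patients: int = 200
    n_drivers: int = 10
    driver_genes: tuple[str, ...] | None = None
    driver_hit_prob: float = 0.12
    driver_ccf_beta: tuple[float, float] = (25.0, 1.8)
    driver_impact: tuple[float, float] = (32.0, 4.0)  # normal mean, sd
    passenger_rate_mean: float = 10.0  # coding mutations per patient
    rate_dispersion: float = 1.0  # lognormal sigma of per-gene rates
    passenger_clonal_weight: float = 0.25
    passenger_clonal_beta: tuple[float, float] = (25.0, 1.8)
    passenger_subclonal_beta: tuple[float, float] = (1.5, 4.0)
    passenger_impact_gamma: tuple[float, float] = (2.0, 6.0)  # shape, scale
    purity_beta: tuple[float, float] = (6.0, 2.0)
    nonsyn_site_fraction: float = 0.75  # N_a / (N_a + N_s)
    ncmr_noise_sigma: float = 0.3

    def __post_init__(self) -> None:
        n_drv = len(self.driver_genes) if self.driver_genes else self.n_drivers
        if n_drv > self.n_genes:
            raise ValueError("more driver genes than genes in the universe")
        if not 0 <= self.passenger_clonal_weight <= 1:
            raise ValueError("passenger_clonal_weight must be a probability")


#: reduced-size configuration used for quick fixtures and docs examples
SMALL_CONFIG = SimulationConfig(
    n_genes=150, n_patients=60, n_drivers=5, driver_hit_prob=0.25, passenger_rate_mean=8.0
)


def _draw_classes(rng: np.random.Generator, n: int) -> np.ndarray:
    names = list(NONSILENT_CLASS_PROBS)
    probs = np.array([NONSILENT_CLASS_PROBS[c] for c in names])
    return np.array(names, dtype=object)[rng.choice(len(names), size=n, p=probs)]


def simulate_cohort(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Generate a cohort, its ground truth and a matching gene-context table.

    Returns ``(cohort, truth, context)`` where ``cohort`` is a canonical
    mutation DataFrame (``ccf``/``damage`` left underived), ``truth`` has
    keys ``driver_genes`` (list) and ``origin`` (per-mutation Series with
    values ``driver``/``passenger``), and ``context`` is the gene-indexed
    site/rate table. Deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:04d}" for i in range(config.n_genes)], dtype=object)
    patients = np.array([f"P{i:03d}" for i in range(config.n_patients)], dtype=object)

    # gene universe: lengths, site counts, heterogeneous neutral rates
    lengths = np.clip(rng.lognormal(np.log(1500.0), 0.5, config.n_genes), 300, 15000).round()
    n_a_sites = config.nonsyn_site_fraction * lengths
    n_s_sites = (1.0 - config.nonsyn_site_fraction) * lengths
    weights = lengths * rng.lognormal(0.0, config.rate_dispersion, config.n_genes)
    lam = config.passenger_rate_mean * weights / weights.sum()  # per patient, per gene
    ncmr = lam / lengths * rng.lognormal(0.0, config.ncmr_noise_sigma, config.n_genes)
    context = pd.DataFrame(
        {
            "n_sites_nonsyn": n_a_sites,
            "n_sites_syn": n_s_sites,
            "length": lengths,
            "ncmr": ncmr,
        },
        index=pd.Index(genes, name="gene"),
    )

    if config.driver_genes is not None:
        driver_genes = list(config.driver_genes)
    else:
        driver_genes = sorted(rng.choice(genes, size=config.n_drivers, replace=False))
    driver_idx = {g: True for g in driver_genes}

    purity = np.clip(rng.beta(*config.purity_beta, config.n_patients), 0.25, 1.0)

    # neutral passenger background, Poisson per (gene, patient)
    counts = rng.poisson(np.repeat(lam, config.n_patients))
    gene_i = np.repeat(np.arange(config.n_genes), config.n_patients)
    pat_i = np.tile(np.arange(config.n_patients), config.n_genes)
    gene_p = np.repeat(gene_i, counts)
    pat_p = np.repeat(pat_i, counts)
    n_pass = len(gene_p)
    silent_frac = 1.0 - config.nonsyn_site_fraction
    is_silent = rng.random(n_pass) < silent_frac
    clonal = rng.random(n_pass) < config.passenger_clonal_weight
    ccf_p = np.where(
        clonal,
        rng.beta(*config.passenger_clonal_beta, n_pass),
        rng.beta(*config.passenger_subclonal_beta, n_pass),
    )
    impact_p = rng.gamma(config.passenger_impact_gamma[0], config.passenger_impact_gamma[1], n_pass)
    class_p = np.where(is_silent, "silent", _draw_classes(rng, n_pass))

    # driver foreground: extra clonal, damaging nonsilent hits
    drv_rows = []
    if driver_genes:
        dmask = rng.random((len(driver_genes), config.n_patients)) < config.driver_hit_prob
        dg, dp = np.nonzero(dmask)
        n_drv = len(dg)
        ccf_d = rng.beta(*config.driver_ccf_beta, n_drv)
        impact_d = np.clip(rng.normal(*config.driver_impact, n_drv), 0.0, None)
        class_d = _draw_classes(rng, n_drv)
        drv_gene_names = np.array(driver_genes, dtype=object)[dg]
        drv_pat = dp
    else:
        drv_gene_names = np.array([], dtype=object)
        drv_pat = np.array([], dtype=int)
        ccf_d = impact_d = np.array([])
        class_d = np.array([], dtype=object)

    all_gene = np.concatenate([genes[gene_p], drv_gene_names])
    all_pat_i = np.concatenate([pat_p, drv_pat]).astype(int)
    all_ccf = np.concatenate([ccf_p, ccf_d])
    all_impact = np.concatenate([impact_p, impact_d])
    all_class = np.concatenate([class_p, class_d])
    origin = np.concatenate(
        [np.repeat("passenger", n_pass), np.repeat("driver", len(drv_gene_names))]
    )

    pur = purity[all_pat_i]
    vaf = all_ccf * pur / 2.0  # inverse of the diploid CCF estimate

    cohort = pd.DataFrame(
        {
            "gene": all_gene,
            "patient": patients[all_pat_i],
            "classification": all_class,
            "vaf": vaf,
            "purity": pur,
            "copy_number": 2.0,
            "cnv_ccf": np.nan,
            "impact_raw": all_impact,
            "ccf": np.nan,
            "damage": np.nan,
        }
    )
    truth = {
        "driver_genes": list(driver_genes),
        "origin": pd.Series(origin, index=cohort.index, name="origin"),
        "true_ccf": pd.Series(all_ccf, index=cohort.index, name="true_ccf"),
        "passenger_rate": pd.Series(lam, index=pd.Index(genes, name="gene"), name="passenger_rate"),
    }
    return cohort, truth, context


TOY_MAF = """Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tVAF\tpurity\tploidy\tCNV_CCF\tCADD
TP53\tPAT1\tMissense_Mutation\t0.42\t0.9\t2\t\t28.4
TP53\tPAT2\tNonsense_Mutation\t0.35\t0.8\t2\t\t36.0
KRAS\tPAT1\tSilent\t0.12\t0.9\t2\t\t3.1
"""


def write_fixture_suite(outdir: str | PathLike, seed: int = 0) -> list[Path]:
    """Write the canonical small fixtures used by tests and examples.

    Emits a 3-row toy MAF, a neutral (driver-free) cohort, a driver-spiked
    cohort with its gene-context table, truth labels and gold-standard
    list. All files are plain TSV/text.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    toy = outdir / "toy.maf.tsv"
    toy.write_text(TOY_MAF)
    written.append(toy)

    neutral_cfg = replace(SMALL_CONFIG, n_drivers=0)
    neutral, _, neutral_ctx = simulate_cohort(neutral_cfg, seed)
    cd_io.write_maf(neutral, outdir / "neutral_cohort.maf.tsv")
    cd_io.write_gene_context(neutral_ctx, outdir / "neutral_gene_context.tsv")
    written += [outdir / "neutral_cohort.maf.tsv", outdir / "neutral_gene_context.tsv"]

    spiked, truth, ctx = simulate_cohort(SMALL_CONFIG, seed + 1)
    cd_io.write_maf(spiked, outdir / "spiked_cohort.maf.tsv")
    cd_io.write_gene_context(ctx, outdir / "spiked_gene_context.tsv")
    truth_df = pd.DataFrame({"origin": truth["origin"]})
    truth_df.to_csv(outdir / "spiked_truth.tsv", sep="\t", index_label="row")
    gold = outdir / "gold_standard.txt"
    gold.write_text("\n".join(truth["driver_genes"]) + "\n")
    written += [
        outdir / "spiked_cohort.maf.tsv",
        outdir / "spiked_gene_context.tsv",
        outdir / "spiked_truth.tsv",
        gold,
    ]
    return written
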