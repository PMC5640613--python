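"""End-to-end wiring: cohort table -> derived CCF/damage -> background ->
posteriors -> resampling FDR cutoff -> ranked results."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import background as bg
from . import bayes, fdr
from . import impact
from . import io as cd_io

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one cohort."""

    results: pd.DataFrame
    cutoff: int
    background: bg.CohortBackground
    null_model: fdr.NullModel
    params: bayes.BayesParams


def analyze_cohort(
    cohort: pd.DataFrame,
    context: pd.DataFrame,
    driver_genes,
    incidence: float = 0.1,
    n_genes_total: int = 20_000,
    impact_params: impact.ImpactParams = impact.DEFAULT_IMPACT,
    clonal_threshold: float = bg.DEFAULT_CLONAL_THRESHOLD,
    alpha: float = fdr.DEFAULT_ALPHA,
    n_reps: int = fdr.DEFAULT_N_REPS,
    seed: int = 0,
    n_patients: int | None = None,
    recompute_ccf: bool = False,
    rank_by: str = "driver",
    p_ns_given_d_override: float | None = None,
) -> AnalysisResult:
    """Run the full analysis on an in-memory cohort.

    ``driver_genes`` is the known-driver list feeding the driver model's
    prior and likelihood. ``n_patients`` defaults to the number of
    distinct patients in the table.
    """
    if n_patients is None:
        n_patients = cohort["patient"].nunique()
    cohort = impact.annotate_cohort(cohort, impact_params, recompute=recompute_ccf)
    backgr = bg.compute_background(
        cohort, context, n_patients=n_patients, clonal_threshold=clonal_threshold
    )
    params = bayes.BayesParams(
        incidence=incidence,
        n_genes=n_genes_total,
        driver_genes=tuple(driver_genes),
        p_ns_given_d_override=p_ns_given_d_override,
    )
    results = bayes.score_genes(cohort, backgr, params, n_patients=n_patients, rank_by=rank_by)
    null = fdr.null_rank_profile(
        cohort, backgr, params, n_reps=n_reps, seed=seed, n_patients=n_patients
    )
    results, cutoff = fdr.annotate_significance(results, null, alpha=alpha)
    return AnalysisResult(
        results=results, cutoff=cutoff, background=backgr, null_model=null, params=params
    )


@dataclass
class RunConfig:
    """File-level pipeline configuration (CLI / YAML surface)."""

    maf: str
    gene_context: str
    driver_list: str
    outdir: str = "clonedriver_out"
    incidence: float = 0.1
    n_genes_total: int = 20_000
    impact_mu: float = 15.0
    impact_scale: float = 2.0
    clonal_threshold: float = bg.DEFAULT_CLONAL_THRESHOLD
    alpha: float = fdr.DEFAULT_ALPHA
    n_reps: int = fdr.DEFAULT_N_REPS
    seed: int = 0
    recompute_ccf: bool = False
    rank_by: str = "driver"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Run the file-in/file-out pipeline and write all result tables.

    Writes ``results.tsv`` (ranked genes), ``background.tsv``,
    ``null_fdr.tsv`` (per-rank null medians and FDR) and ``run_log.txt``
    into ``config.outdir``.
    """
    if not (0 < config.alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    for name in ("maf", "gene_context", "driver_list"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = cd_io.read_maf(config.maf)
    context = cd_io.read_gene_context(config.gene_context)
    drivers = cd_io.read_gene_list(config.driver_list)
    analysis = analyze_cohort(
        cohort,
        context,
        drivers,
        incidence=config.incidence,
        n_genes_total=config.n_genes_total,
        impact_params=impact.ImpactParams(config.impact_mu, config.impact_scale),
        clonal_threshold=config.clonal_threshold,
        alpha=config.alpha,
        n_reps=config.n_reps,
        seed=config.seed,
        recompute_ccf=config.recompute_ccf,
        rank_by=config.rank_by,
    )
    cd_io.write_results(analysis.results, outdir / "results.tsv")
    analysis.background.to_tsv(outdir / "background.tsv")

    null_tab = analysis.null_model.to_frame()
    obs = analysis.results.sort_values("rank")
    null_tab["fdr_driver"] = obs["fdr"].to_numpy()
    null_tab.to_csv(outdir / "null_fdr.tsv", sep="\t", index=False)

    log_lines = [
        f"seed: {config.seed}",
        f"patients: {cohort['patient'].nunique()}",
        f"mutations: {len(cohort)}",
        f"genes scored: {len(analysis.results)}",
        f"clonal rate r: {analysis.background.r:.4f}",
        f"incidence prior: {config.incidence}",
        f"driver prior: {bayes.driver_prior(analysis.params):.6f}",
        f"null replicates: {config.n_reps}",
        f"FDR alpha: {config.alpha}",
        f"suggested rank cutoff: {analysis.cutoff}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline finished; cutoff rank %d", analysis.cutoff)
    return analysis
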