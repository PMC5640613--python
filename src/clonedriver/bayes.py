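"""Bayesian gene scoring: cancer-hazard and driver-inference posteriors.

Both models share a foreground evidence term built from the cohort: for
each gene, each patient contributes the product CCF x damage of their
single highest-CCF nonsilent mutation in the gene (zero if unmutated), and
``m`` is the sum of these contributions over the ``n`` patients of the
cohort — a recurrence count softened by clonality and functional impact.

The cancer-hazard model asks "what is the probability a person develops
cancer given this gene is mutated": prior = population incidence,
likelihood P(ns|cancer) = m / n, false-positive channel P(ns|not cancer) =
the gene's background mutation probability (bmp).

The driver-inference model asks "what is the probability this gene is a
driver given the cohort": the m patients with evidence and n - m without
are treated as Bernoulli outcomes with success probability P(ns|driver)
(estimated from a known-driver list) under the driver hypothesis and bmp
under the passenger hypothesis, with prior #drivers / #genes. The
Bernoulli exponents use the real-valued m; posteriors are evaluated in
log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import SILENT_CLASS

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class BayesParams:
    """Priors and likelihood inputs for the two models.

    ``incidence`` is the population incidence of the tumor type (prior of
    the hazard model). ``driver_genes`` is the known-driver list used to
    estimate P(ns|driver); ``n_known_drivers`` defaults to its length.
    ``p_ns_given_d_override`` replaces the estimated P(ns|driver) verbatim
    when the uniform-driver assumption is too weak.
    """

    incidence: float = 0.1
    n_genes: int = 20_000
    driver_genes: Sequence[str] = field(default_factory=tuple)
    n_known_drivers: int | None = None
    p_ns_given_d_override: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.incidence < 1.0):
            raise ValueError("incidence prior must lie strictly in (0, 1)")
        nk = self.n_known_drivers if self.n_known_drivers is not None else len(self.driver_genes)
        if not 0 < nk < self.n_genes:
            raise ValueError("need 0 < n_known_drivers < n_genes")


def evidence_mass_table(
    cohort: pd.DataFrame, genes: pd.Index, n_patients: int
) -> pd.DataFrame:
    """Per-gene evidence mass m = sum_i CCF_i * damage_i (one mutation/patient).

    Patients without a nonsilent mutation in a gene contribute zero;
    ``n_patients`` is the full cohort size including unmutated patients.
    Returns a DataFrame indexed like ``genes`` with columns ``m`` and ``n``.
    """
    ns = cohort[cohort["classification"] != SILENT_CLASS]
    gene_codes, gene_order = pd.factorize(ns["gene"], sort=False)
    pat_codes, _ = pd.factorize(ns["patient"], sort=False)
    m_arr = _evidence_mass_arrays(
        gene_codes,
        pat_codes,
        ns["ccf"].to_numpy(dtype=float),
        ns["damage"].to_numpy(dtype=float),
        len(gene_order),
    )
    m = pd.Series(m_arr, index=gene_order).reindex(genes).fillna(0.0)
    return pd.DataFrame({"m": m, "n": n_patients}, index=genes)


def _evidence_mass_arrays(
    gene_codes: np.ndarray,
    pat_codes: np.ndarray,
    ccf: np.ndarray,
    damage: np.ndarray,
    n_genes: int,
) -> np.ndarray:
    """Vectorized per-(gene, patient) highest-CCF collapse and CCF*damage sum.

    Ties on CCF keep the higher damage. Shared by the observed scoring and
    the label-resampling null, where it runs once per replicate.
    """
    if len(gene_codes) == 0:
        return np.zeros(n_genes)
    order = np.lexsort((-damage, -ccf, pat_codes, gene_codes))
    g = gene_codes[order]
    p = pat_codes[order]
    first = np.ones(len(g), dtype=bool)
    first[1:] = (g[1:] != g[:-1]) | (p[1:] != p[:-1])
    weights = ccf[order][first] * damage[order][first]
    m = np.zeros(n_genes)
    np.add.at(m, g[first], weights)
    return m


def evidence_mass(cohort: pd.DataFrame, gene: str, n_patients: int) -> tuple[float, int]:
    """Evidence mass (m, n) for a single gene."""
    tab = evidence_mass_table(cohort[cohort["gene"] == gene], pd.Index([gene]), n_patients)
    return float(tab.loc[gene, "m"]), int(n_patients)


def hazard_posterior(m, n, bmp, incidence: float):
    """P(cancer | gene mutated), Bayes with likelihood m/n and bmp channel.

    When both the likelihood and bmp are zero there is no evidence either
    way; the posterior is defined as 0.
    """
    m = np.asarray(m, dtype=float)
    bmp_arr = np.asarray(bmp, dtype=float)
    like = m / float(n)
    num = like * incidence
    den = num + bmp_arr * (1.0 - incidence)
    with np.errstate(invalid="ignore"):
        post = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if np.ndim(post) == 0:
        return float(post)
    if isinstance(bmp, pd.Series):
        return pd.Series(post, index=bmp.index)
    return post


def driver_prior(params: BayesParams) -> float:
    """P(driver) = number of known drivers / number of protein-coding genes."""
    nk = params.n_known_drivers if params.n_known_drivers is not None else len(params.driver_genes)
    if nk <= 0:
        raise ValueError("driver prior requires at least one known driver gene")
    if nk >= params.n_genes:
        raise ValueError("known drivers must be fewer than total genes")
    return nk / params.n_genes


def driver_likelihood(cohort: pd.DataFrame, params: BayesParams, n_patients: int) -> float:
    """P(ns | driver): nonsilent mutations in known drivers per patient-driver slot.

    Assumes every known driver is equally likely to be hit; the override in
    ``params`` bypasses the estimate entirely.
    """
    if params.p_ns_given_d_override is not None:
        return float(params.p_ns_given_d_override)
    drivers = list(params.driver_genes)
    if not drivers:
        raise ValueError("driver likelihood needs a driver gene list or an override")
    ns = cohort[cohort["classification"] != SILENT_CLASS]
    count = int(ns["gene"].isin(set(drivers)).sum())
    p = count / (n_patients * len(drivers))
    if count == 0:
        logger.warning("no nonsilent mutations found in the known driver genes; P(ns|d) = 0")
    if p > 1.0:
        logger.warning("P(ns|d) estimate %.3f exceeds 1; capped", p)
        p = 1.0
    return p


def driver_posterior(m, n, p_ns_d: float, bmp, prior_d: float):
    """P(driver | data) via the two-channel Bernoulli likelihood, in log space.

    Probabilities at exactly 0 or 1 are clamped to [1e-12, 1 - 1e-12].
    """
    m = np.asarray(m, dtype=float)
    bmp_arr = np.clip(np.asarray(bmp, dtype=float), EPS, 1.0 - EPS)
    p_d = float(np.clip(p_ns_d, EPS, 1.0 - EPS))
    prior = float(np.clip(prior_d, EPS, 1.0 - EPS))
    n = float(n)
    log_driver = m * np.log(p_d) + (n - m) * np.log1p(-p_d) + np.log(prior)
    log_passg = m * np.log(bmp_arr) + (n - m) * np.log1p(-bmp_arr) + np.log1p(-prior)
    post = expit(log_driver - log_passg)
    if np.ndim(post) == 0:
        return float(post)
    if isinstance(bmp, pd.Series):
        return pd.Series(post, index=bmp.index)
    return post


def rank_genes(results: pd.DataFrame, by: str = "driver") -> pd.DataFrame:
    """Assign ranks 1..G.

    ``by`` selects the primary key: ``driver`` (default) sorts by the
    driver posterior, ``hazard`` by the hazard posterior, ``average`` by
    the mean of the two per-model rank positions. Ties break by the other
    posterior descending, then m descending, then gene symbol.
    """
    df = results.copy()
    if by == "average":
        rd = df["posterior_driver"].rank(ascending=False, method="min")
        rh = df["posterior_hazard"].rank(ascending=False, method="min")
        df["_key"] = (rd + rh) / 2.0
        df = df.sort_values(["_key", "posterior_driver", "posterior_hazard", "m", "gene"],
                            ascending=[True, False, False, False, True], kind="stable")
        df = df.drop(columns="_key")
    else:
        primary, secondary = ("posterior_driver", "posterior_hazard")
        if by == "hazard":
            primary, secondary = secondary, primary
        elif by != "driver":
            raise ValueError(f"unknown ranking key {by!r}")
        df = df.sort_values([primary, secondary, "m", "gene"],
                            ascending=[False, False, False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def score_genes(
    cohort: pd.DataFrame,
    background,
    params: BayesParams,
    n_patients: int | None = None,
    rank_by: str = "driver",
) -> pd.DataFrame:
    """Full per-gene scoring: evidence mass, both posteriors, ranking.

    ``background`` is a :class:`~clonedriver.background.CohortBackground`;
    its gene universe defines which genes are scored.
    """
    if n_patients is None:
        n_patients = cohort["patient"].nunique()
    genes = background.table.index
    cohort = cohort[cohort["gene"].isin(genes)]
    ev = evidence_mass_table(cohort, genes, n_patients)
    bmp = background.bmp
    p_ns_d = driver_likelihood(cohort, params, n_patients)
    prior_d = driver_prior(params)
    res = pd.DataFrame(
        {
            "gene": genes,
            "m": ev["m"].to_numpy(),
            "n": n_patients,
            "posterior_hazard": hazard_posterior(
                ev["m"].to_numpy(), n_patients, bmp.to_numpy(), params.incidence
            ),
            "posterior_driver": driver_posterior(
                ev["m"].to_numpy(), n_patients, p_ns_d, bmp.to_numpy(), prior_d
            ),
        }
    )
    return rank_genes(res, by=rank_by)
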