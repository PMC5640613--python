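"""Per-gene background mutation probability (bmp).

Two independent neutral-expectation models are averaged:

* a CCF-adjusted Ka/Ks model — the gene's own silent mutations, weighted by
  cancer cell fraction, predict the neutrally expected nonsilent count
  ``n_hat = n_s' * N_a / N_s``, with a floor on the silent count so that a
  single nonsilent mutation cannot masquerade as positive selection;
* a non-coding mutation-rate (ncmr) model — an externally measured per-bp
  neutral rate times the coding length gives the expected total count,
  split into the nonsilent share ``n_hat = n_t / (1 + N_s / N_a)``.

Each model's expectations are normalized into per-gene success
probabilities ``p_g`` and turned into the probability that one patient has
at least one nonsilent mutation in the gene via a binomial with ``r``
trials, ``bmp_g = 1 - (1 - p_g)^r``, where ``r`` is the cohort-average
per-patient count of clonal (CCF >= 0.85) nonsilent SNVs — a proxy for the
pre-cancer somatic load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SILENT_CLASS

logger = logging.getLogger(__name__)

DEFAULT_CLONAL_THRESHOLD = 0.85


@dataclass
class CohortBackground:
    """Per-gene background table plus the cohort clonal rate ``r``.

    ``table`` is indexed by gene with columns ``n_a_ccf``, ``n_s_ccf``,
    ``n_s_corrected``, ``expected_nonsilent_kaks``, ``expected_total_ncmr``,
    ``expected_nonsilent_ncmr``, ``p_kaks``, ``p_ncmr``, ``bmp_kaks``,
    ``bmp_ncmr``, ``bmp``.
    """

    table: pd.DataFrame
    r: float
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD

    @property
    def bmp(self) -> pd.Series:
        return self.table["bmp"]

    def to_tsv(self, path) -> None:
        self.table.reset_index(names="gene").to_csv(path, sep="\t", index=False)


def ccf_adjusted_counts(cohort: pd.DataFrame, genes: pd.Index) -> pd.DataFrame:
    """Sum CCF over nonsilent and silent mutations per gene (no collapse).

    Genes without mutations get zeros. Mutations in genes outside ``genes``
    are ignored by the caller's filtering, not here.
    """
    silent = cohort["classification"] == SILENT_CLASS
    n_a = cohort.loc[~silent].groupby("gene")["ccf"].sum()
    n_s = cohort.loc[silent].groupby("gene")["ccf"].sum()
    out = pd.DataFrame(index=genes)
    out["n_a_ccf"] = n_a.reindex(genes).fillna(0.0)
    out["n_s_ccf"] = n_s.reindex(genes).fillna(0.0)
    return out


def correct_silent_counts(n_s_ccf, n_sites_nonsyn, n_sites_syn):
    """Floor the CCF-weighted silent count at ``N_s / N_a``.

    ``N_s / N_a`` is the silent count that, under neutrality, corresponds to
    exactly one expected nonsilent mutation — so a gene with no silent
    mutations is still expected to tolerate one nonsilent hit by chance.
    """
    floor = np.asarray(n_sites_syn, dtype=float) / np.asarray(n_sites_nonsyn, dtype=float)
    return np.maximum(np.asarray(n_s_ccf, dtype=float), floor)


def expected_nonsilent_kaks(n_s_corrected, n_sites_nonsyn, n_sites_syn):
    """Neutral (Ka/Ks = 1) expected nonsilent count: ``n_s' * N_a / N_s``."""
    return (
        np.asarray(n_s_corrected, dtype=float)
        * np.asarray(n_sites_nonsyn, dtype=float)
        / np.asarray(n_sites_syn, dtype=float)
    )


def expected_nonsilent_ncmr(ncmr, length, n_sites_nonsyn, n_sites_syn):
    """Expected nonsilent count from the non-coding rate.

    ``n_t = ncmr * length`` mutations are expected in total; the nonsilent
    share under neutrality is ``n_t / (1 + N_s / N_a)``.
    """
    n_t = np.asarray(ncmr, dtype=float) * np.asarray(length, dtype=float)
    ratio = np.asarray(n_sites_syn, dtype=float) / np.asarray(n_sites_nonsyn, dtype=float)
    return n_t / (1.0 + ratio)


def clonal_mutation_rate(
    cohort: pd.DataFrame,
    n_patients: int | None = None,
    threshold: float = DEFAULT_CLONAL_THRESHOLD,
    include_indels: bool = False,
) -> float:
    """Cohort-average per-patient count of clonal nonsilent mutations.

    A mutation is clonal when its CCF is at or above ``threshold``. By
    default only SNVs count (indels excluded); patients with no clonal
    mutation contribute zero. ``n_patients`` is the full cohort size; when
    omitted it is the number of distinct patients in the table.
    """
    if len(cohort) == 0:
        raise ValueError("cannot compute clonal rate of an empty cohort")
    if n_patients is None:
        n_patients = cohort["patient"].nunique()
    mask = (cohort["classification"] != SILENT_CLASS) & (cohort["ccf"] >= threshold)
    if not include_indels:
        mask &= cohort["classification"] != "indel"
    return float(mask.sum() / n_patients)


def background_probability(expected: np.ndarray | pd.Series, r: float):
    """Binomial chance of >= 1 nonsilent mutation per patient and gene.

    Normalizes the expected counts into success probabilities
    ``p_g = n_hat_g / sum(n_hat)`` and returns ``1 - (1 - p_g)^r``; ``r``
    is used directly as a real-valued exponent.
    """
    exp = np.asarray(expected, dtype=float)
    total = exp.sum()
    if total <= 0:
        raise ValueError("expected-count vector sums to zero; bmp undefined")
    if r < 0:
        raise ValueError("clonal rate r must be nonnegative")
    p = exp / total
    bmp = 1.0 - np.power(1.0 - p, r)
    if isinstance(expected, pd.Series):
        return pd.Series(bmp, index=expected.index)
    return bmp


def combine_bmp(bmp_kaks, bmp_ncmr):
    """Arithmetic mean of the two background probabilities, per gene."""
    if isinstance(bmp_kaks, pd.Series) and isinstance(bmp_ncmr, pd.Series):
        if not bmp_kaks.index.equals(bmp_ncmr.index):
            raise ValueError("bmp vectors cover different gene sets")
    a = np.asarray(bmp_kaks, dtype=float)
    b = np.asarray(bmp_ncmr, dtype=float)
    if a.shape != b.shape:
        raise ValueError("bmp vectors cover different gene sets")
    out = (a + b) / 2.0
    if isinstance(bmp_kaks, pd.Series):
        return pd.Series(out, index=bmp_kaks.index)
    return out


def compute_background(
    cohort: pd.DataFrame,
    context: pd.DataFrame,
    n_patients: int | None = None,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    include_indels_in_r: bool = False,
) -> CohortBackground:
    """Run both background models over the gene universe of ``context``.

    Mutations in genes missing from the context table are excluded from
    the background (and should be excluded from ranking) with a logged
    warning, since the site counts and non-coding rate are undefined there.
    """
    known = cohort["gene"].isin(context.index)
    if (~known).any():
        missing = sorted(cohort.loc[~known, "gene"].unique())
        logger.warning(
            "%d mutations in %d genes absent from the gene-context table were excluded (e.g. %s)",
            int((~known).sum()),
            len(missing),
            missing[:3],
        )
        cohort = cohort[known]

    genes = context.index
    tab = ccf_adjusted_counts(cohort, genes)
    tab["n_s_corrected"] = correct_silent_counts(
        tab["n_s_ccf"], context["n_sites_nonsyn"], context["n_sites_syn"]
    )
    tab["expected_nonsilent_kaks"] = expected_nonsilent_kaks(
        tab["n_s_corrected"], context["n_sites_nonsyn"], context["n_sites_syn"]
    )
    tab["expected_total_ncmr"] = context["ncmr"] * context["length"]
    tab["expected_nonsilent_ncmr"] = expected_nonsilent_ncmr(
        context["ncmr"], context["length"], context["n_sites_nonsyn"], context["n_sites_syn"]
    )
    r = clonal_mutation_rate(
        cohort, n_patients=n_patients, threshold=clonal_threshold, include_indels=include_indels_in_r
    )
    for model in ("kaks", "ncmr"):
        exp = tab[f"expected_nonsilent_{model}"]
        tab[f"p_{model}"] = exp / exp.sum()
        tab[f"bmp_{model}"] = background_probability(exp, r)
    tab["bmp"] = combine_bmp(tab["bmp_kaks"], tab["bmp_ncmr"])
    return CohortBackground(table=tab, r=r, clonal_threshold=clonal_threshold)
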