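"""Resampling null model and empirical FDR rank cutoff.

The null hypothesis is "no gene is under selection": mutations keep their
CCF, damage, classification and patient but lose their gene identity,
which is redrawn i.i.d. from the background mutation probability vector.
Re-scoring each relabeled cohort with both Bayesian models gives, per
replicate, a sorted posterior profile; the per-rank medians describe the
posterior magnitudes expected by chance. The FDR at observed rank k is the
median (over replicates) number of null posteriors at or above the
observed k-th posterior, divided by k, monotonized by cumulative maximum.
The suggested significance cutoff is the floor of the mean of the two
models' largest ranks with FDR below the target (10% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes
from .io import SILENT_CLASS

DEFAULT_ALPHA = 0.1
DEFAULT_N_REPS = 100


@dataclass
class NullModel:
    """Sorted null posterior profiles for both models.

    ``null_hazard`` and ``null_driver`` are (n_reps, G) arrays, each row a
    replicate's posteriors sorted descending. ``median_*`` are the
    per-rank medians across replicates.
    """

    n_reps: int
    seed: int
    genes: pd.Index
    null_hazard: np.ndarray
    null_driver: np.ndarray

    @property
    def median_hazard(self) -> np.ndarray:
        return np.median(self.null_hazard, axis=0)

    @property
    def median_driver(self) -> np.ndarray:
        return np.median(self.null_driver, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "median_null_hazard": self.median_hazard,
                "median_null_driver": self.median_driver,
            }
        )


def sample_null_cohort(cohort: pd.DataFrame, bmp: pd.Series, seed) -> pd.DataFrame:
    """Redraw every mutation's gene label from the bmp vector.

    All per-mutation attributes (CCF, damage, classification, patient, VAF,
    ...) are preserved; only ``gene`` changes. ``seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    probs = bmp.to_numpy(dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ValueError("bmp vector sums to zero; cannot resample labels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rng.choice(len(probs), size=len(cohort), replace=True, p=probs / total)
    out = cohort.copy()
    out["gene"] = bmp.index.to_numpy()[labels]
    return out


def null_rank_profile(
    cohort: pd.DataFrame,
    background,
    params: bayes.BayesParams,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    n_patients: int | None = None,
) -> NullModel:
    """Score ``n_reps`` label-resampled cohorts with both Bayesian models.

    One master seed spawns an independent RNG stream per replicate, so the
    profile is reproducible and independent of evaluation order. The
    background (bmp, r) is the observed one: the null varies only the
    foreground evidence.
    """
    if n_reps < 1:
        raise ValueError("need at least one null replicate")
    if n_patients is None:
        n_patients = cohort["patient"].nunique()
    genes = background.table.index
    bmp_arr = background.bmp.to_numpy(dtype=float)
    probs = bmp_arr / bmp_arr.sum()

    cohort = cohort[cohort["gene"].isin(genes)]
    ns = cohort[cohort["classification"] != SILENT_CLASS]
    pat_codes, _ = pd.factorize(ns["patient"], sort=False)
    ccf = ns["ccf"].to_numpy(dtype=float)
    damage = ns["damage"].to_numpy(dtype=float)
    n_mut_total = len(cohort)
    ns_pos = cohort.index.get_indexer(ns.index)  # positions of nonsilent rows

    p_ns_d = bayes.driver_likelihood(cohort, params, n_patients)
    prior_d = bayes.driver_prior(params)

    G = len(genes)
    null_h = np.empty((n_reps, G))
    null_d = np.empty((n_reps, G))
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        labels_all = rng.choice(G, size=n_mut_total, replace=True, p=probs)
        labels_ns = labels_all[ns_pos]
        m = bayes._evidence_mass_arrays(labels_ns, pat_codes, ccf, damage, G)
        ph = bayes.hazard_posterior(m, n_patients, bmp_arr, params.incidence)
        pdrv = bayes.driver_posterior(m, n_patients, p_ns_d, bmp_arr, prior_d)
        null_h[rep] = np.sort(ph)[::-1]
        null_d[rep] = np.sort(pdrv)[::-1]
    return NullModel(n_reps=n_reps, seed=seed, genes=genes, null_hazard=null_h, null_driver=null_d)


def estimate_fdr(observed_sorted: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    """Per-rank empirical FDR of an observed descending posterior profile.

    ``null_sorted`` is the (n_reps, G) matrix of descending null
    posteriors. FDR(k) = median over replicates of #{null >= observed_k}
    divided by k, capped at 1 and made nondecreasing in k.
    """
    obs = np.asarray(observed_sorted, dtype=float)
    if np.any(np.diff(obs) > 1e-12):
        raise ValueError("observed posteriors must be sorted descending")
    n_reps = null_sorted.shape[0]
    counts = np.empty((n_reps, len(obs)))
    for rep in range(n_reps):
        asc = null_sorted[rep, ::-1]  # ascending
        # count of null values >= obs_k
        counts[rep] = len(asc) - np.searchsorted(asc, obs, side="left")
    med = np.median(counts, axis=0)
    k = np.arange(1, len(obs) + 1)
    fdr = np.minimum(med / k, 1.0)
    return np.maximum.accumulate(fdr)


def optimal_rank(
    fdr_hazard: np.ndarray, fdr_driver: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[int, int, int]:
    """Largest rank with FDR <= alpha per model, and their floored mean.

    Returns ``(cutoff, rank_hazard, rank_driver)``; a model with no rank
    under the threshold contributes 0.
    """
    if len(fdr_hazard) != len(fdr_driver):
        raise ValueError("FDR vectors must have equal length")

    def last_ok(fdr: np.ndarray) -> int:
        ok = np.nonzero(np.asarray(fdr) <= alpha)[0]
        return int(ok[-1] + 1) if len(ok) else 0

    rh, rd = last_ok(fdr_hazard), last_ok(fdr_driver)
    return (rh + rd) // 2, rh, rd


def annotate_significance(
    results: pd.DataFrame,
    null_model: NullModel,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, int]:
    """Attach per-rank FDR and the significance flag to ranked results.

    Results must carry both posteriors and a rank ordering from
    :func:`clonedriver.bayes.rank_genes`. The reported ``fdr`` column is
    the driver-model FDR profile evaluated at each gene's rank;
    ``significant`` marks ranks at or below the combined (both-model)
    cutoff. Returns ``(annotated results, cutoff)``.
    """
    df = results.sort_values("rank").reset_index(drop=True)
    obs_h = np.sort(df["posterior_hazard"].to_numpy())[::-1]
    obs_d = np.sort(df["posterior_driver"].to_numpy())[::-1]
    fdr_h = estimate_fdr(obs_h, null_model.null_hazard)
    fdr_d = estimate_fdr(obs_d, null_model.null_driver)
    cutoff, _, _ = optimal_rank(fdr_h, fdr_d, alpha)
    df["fdr"] = fdr_d[df["rank"].to_numpy() - 1]
    df["significant"] = df["rank"] <= cutoff
    return df, cutoff
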