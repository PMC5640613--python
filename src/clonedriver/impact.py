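"""Per-mutation cancer cell fraction (CCF) and damage probability.

A clonal heterozygous point mutation at a diploid locus in a pure tumor is
expected in half of the reads, so its CCF is twice the variant allele
frequency; impure samples divide by the purity. Non-diploid loci use a
copy-number-aware generalization (see :func:`estimate_ccf`). Raw functional
impact scores on a CADD-like scale are squashed onto [0, 1] by a logistic
sigmoid so they can act as probabilities of a damaging effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import SILENT_CLASS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactParams:
    """Logistic transform of raw impact scores: 1 / (1 + exp(-(x - mu)/scale)).

    ``mu`` is the midpoint (raw score mapping to damage 0.5), ``scale``
    controls the steepness. Defaults are tuned to the phred-scaled CADD
    range, where scores around 15 separate likely-benign from
    likely-damaging variants.
    """

    mu: float = 15.0
    scale: float = 2.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"sigmoid scale must be positive, got {self.scale}")


DEFAULT_IMPACT = ImpactParams()


def damage_score(impact_raw, params: ImpactParams = DEFAULT_IMPACT):
    """Map a raw impact score (scalar or array) to a damage probability."""
    x = np.asarray(impact_raw, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(x - params.mu) / params.scale))
    return float(out) if np.isscalar(impact_raw) else out


def estimate_ccf(vaf, purity=1.0, copy_number=2.0, cnv_ccf=None):
    """Estimate the cancer cell fraction of a mutation from VAF.

    The diploid case is ``ccf = 2 * vaf / purity``. In general, assuming
    mutation multiplicity 1, the expected VAF of a mutation present in a
    fraction ``ccf`` of tumor cells is

        vaf = ccf * purity / (purity * CN + 2 * (1 - purity)),

    which is inverted here. When ``cnv_ccf`` (the fraction of cancer cells
    carrying the overlapping CNV) is given and below 1, the effective copy
    number is the CCF-weighted mixture ``2 * (1 - cnv_ccf) + CN * cnv_ccf``.
    The result is clipped into [0, 1] as the final step.

    Accepts scalars or numpy arrays (broadcast together).
    """
    vaf = np.asarray(vaf, dtype=float)
    purity_arr = np.asarray(purity, dtype=float)
    if np.any(purity_arr <= 0):
        raise ValueError("purity must be > 0")
    cn = np.asarray(copy_number, dtype=float)
    if cnv_ccf is not None:
        w = np.asarray(cnv_ccf, dtype=float)
        cn = np.where(np.isnan(w), cn, 2.0 * (1.0 - w) + cn * w)
    ccf = vaf * (purity_arr * cn + 2.0 * (1.0 - purity_arr)) / purity_arr
    ccf = np.clip(ccf, 0.0, 1.0)
    return float(ccf) if ccf.ndim == 0 else ccf


def annotate_cohort(
    cohort: pd.DataFrame,
    impact_params: ImpactParams = DEFAULT_IMPACT,
    recompute: bool = False,
) -> pd.DataFrame:
    """Fill the derived ``ccf`` and ``damage`` columns of a cohort.

    Values already present on input are preserved unless ``recompute`` is
    true, so precomputed CCFs (e.g. from a subclonal-deconvolution tool)
    can be used as-is.
    """
    out = cohort.copy()
    cn = out["copy_number"].fillna(2.0)
    ccf = estimate_ccf(
        out["vaf"].to_numpy(),
        out["purity"].fillna(1.0).to_numpy(),
        cn.to_numpy(),
        out["cnv_ccf"].to_numpy(),
    )
    dmg = damage_score(out["impact_raw"].to_numpy(), impact_params)
    if recompute:
        out["ccf"] = ccf
        out["damage"] = dmg
    else:
        out["ccf"] = out["ccf"].fillna(pd.Series(ccf, index=out.index))
        out["damage"] = out["damage"].fillna(pd.Series(dmg, index=out.index))
    if out["damage"].isna().any():
        n = int(out["damage"].isna().sum())
        logger.info("%d mutations without impact score; damage set to 0", n)
        out["damage"] = out["damage"].fillna(0.0)
    return out


def collapse_per_patient(mutations: pd.DataFrame) -> pd.DataFrame:
    """Keep, per patient, the single nonsilent mutation with the highest CCF.

    Ties on CCF are broken by higher damage, then by the lexicographically
    smallest position string if a ``position`` column exists, then stably
    by input order. Input rows must all belong to one gene.
    """
    ns = mutations[mutations["classification"] != SILENT_CLASS]
    if ns.empty:
        return ns
    keys: list = [ns["patient"]]
    ascending = [True]
    keys.append(ns["ccf"])
    ascending.append(False)
    keys.append(ns["damage"])
    ascending.append(False)
    if "position" in ns.columns:
        keys.append(ns["position"].astype(str))
        ascending.append(True)
    order = pd.concat(keys, axis=1)
    order.columns = [f"k{i}" for i in range(len(keys))]
    idx = order.sort_values(list(order.columns), ascending=ascending, kind="stable").index
    return ns.loc[idx].drop_duplicates(subset="patient", keep="first")


GROUPS = (
    "nonsilent_driver",
    "nonsilent_passenger",
    "silent_driver",
    "silent_passenger",
)


@dataclass
class GroupComparison:
    """Four-way CCF comparison of (non)silent mutations in driver vs passenger genes."""

    medians: dict[str, float]
    counts: dict[str, int]
    pairwise: pd.DataFrame  # columns group_a, group_b, statistic, p_value

    def p_value(self, a: str, b: str) -> float:
        pw = self.pairwise
        row = pw[((pw.group_a == a) & (pw.group_b == b)) | ((pw.group_a == b) & (pw.group_b == a))]
        return float(row["p_value"].iloc[0])


def ccf_group_comparison(cohort: pd.DataFrame, driver_genes: Iterable[str]) -> GroupComparison:
    """Compare CCF distributions of the four mutation groups.

    Splits mutations by (nonsilent vs silent) x (in a driver gene vs not)
    and runs a two-sided Wilcoxon-Mann-Whitney rank-sum test for every
    unordered pair of groups. Groups with fewer than two mutations yield
    NaN p-values for their pairs rather than raising.
    """
    drivers = set(driver_genes)
    is_silent = cohort["classification"] == SILENT_CLASS
    in_driver = cohort["gene"].isin(drivers)
    values = {
        "nonsilent_driver": cohort.loc[~is_silent & in_driver, "ccf"].dropna().to_numpy(),
        "nonsilent_passenger": cohort.loc[~is_silent & ~in_driver, "ccf"].dropna().to_numpy(),
        "silent_driver": cohort.loc[is_silent & in_driver, "ccf"].dropna().to_numpy(),
        "silent_passenger": cohort.loc[is_silent & ~in_driver, "ccf"].dropna().to_numpy(),
    }
    medians = {g: (float(np.median(v)) if len(v) else float("nan")) for g, v in values.items()}
    counts = {g: int(len(v)) for g, v in values.items()}
    rows = []
    for a, b in combinations(GROUPS, 2):
        if len(values[a]) < 2 or len(values[b]) < 2:
            stat, p = float("nan"), float("nan")
        else:
            res = mannwhitneyu(values[a], values[b], alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_value": p})
    return GroupComparison(medians=medians, counts=counts, pairwise=pd.DataFrame(rows))
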