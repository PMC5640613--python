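"""Evaluation of ranked gene lists: precision/recall/F curves, Borda
ensembling of multiple rankers, and Fisher enrichment of gene categories."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)


@dataclass
class EvaluationCurve:
    """Precision, recall and F-score of a ranking at every cutoff rank."""

    table: pd.DataFrame  # columns rank, precision, recall, fscore
    gold_size: int

    @property
    def peak_fscore(self) -> float:
        return float(self.table["fscore"].max())

    @property
    def peak_rank(self) -> int:
        return int(self.table.loc[self.table["fscore"].idxmax(), "rank"])

    def truncated(self) -> pd.DataFrame:
        """Curve up to twice the gold-standard size, for display."""
        return self.table[self.table["rank"] <= 2 * self.gold_size]


def precision_recall_fscore(
    ranked_genes: Sequence[str], gold_standard: Iterable[str]
) -> EvaluationCurve:
    """Evaluate a best-first gene ranking against a gold-standard set.

    At each rank k: precision = |top-k ∩ GS| / k, recall = |top-k ∩ GS| /
    |GS|, F = their harmonic mean (0 where both vanish).
    """
    gs = set(gold_standard)
    if not gs:
        raise ValueError("gold standard is empty")
    if len(ranked_genes) == 0:
        raise ValueError("ranking is empty")
    hits = np.cumsum([g in gs for g in ranked_genes])
    k = np.arange(1, len(ranked_genes) + 1)
    precision = hits / k
    recall = hits / len(gs)
    denom = precision + recall
    with np.errstate(invalid="ignore", divide="ignore"):
        fscore = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return EvaluationCurve(
        table=pd.DataFrame(
            {"rank": k, "precision": precision, "recall": recall, "fscore": fscore}
        ),
        gold_size=len(gs),
    )


def borda_ensemble(
    rank_lists: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    truncation: int,
    top_n_methods: int = 3,
) -> list[str]:
    """Combine several ranked gene lists by truncated Borda count.

    Ranks beyond ``truncation`` (and genes absent from a list) are set to
    ``truncation + 1``. Each gene scores the sum of ``truncation + 1 -
    rank`` over its ``top_n_methods`` best (lowest) ranks, and genes are
    returned sorted by score descending, ties alphabetical.
    """
    if truncation <= 0:
        raise ValueError("truncation must be positive")
    lists = list(rank_lists.values()) if isinstance(rank_lists, Mapping) else list(rank_lists)
    if len(lists) < top_n_methods:
        logger.warning(
            "only %d rankings given but top_n_methods=%d; using all", len(lists), top_n_methods
        )
        top_n_methods = len(lists)
    floor_rank = truncation + 1
    genes = sorted({g for lst in lists for g in lst})
    scores: dict[str, float] = {}
    for g in genes:
        ranks = []
        for lst in lists:
            try:
                r = lst.index(g) + 1
            except ValueError:
                r = floor_rank
            ranks.append(min(r, floor_rank))
        best = sorted(ranks)[:top_n_methods]
        scores[g] = sum(floor_rank - r for r in best)
    return sorted(genes, key=lambda g: (-scores[g], g))


def enrichment_test(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"
) -> float:
    """Fisher's exact test comparing success rates k1/n1 vs k2/n2.

    Builds the 2x2 table [[k1, n1-k1], [k2, n2-k2]]; two-sided p-values
    sum the probabilities of all tables at most as likely as the observed
    one (scipy's convention). ``alternative`` may be ``greater``/``less``
    for one-sided tests.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if k < 0 or n < 0 or k > n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative=alternative)
    return float(p)
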