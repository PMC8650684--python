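"""Screening enrichment statistics.

The enrichment ratio at a score cutoff c compares the classifier's recall of
known actives against the rate at which it passes compounds overall:

    Ratio_c = P_tpr(c) / random(c) = (N_c / N_total) / (NN_c / N_all)

where N_c counts actives scoring strictly above c, N_total all actives, NN_c
all compounds scoring strictly above c, and N_all all compounds screened.
A ratio of 1 is what a random scorer achieves; the larger the ratio, the
better the enrichment of actives at the top of the ranking. The customary
cutoff for probability-like scores is 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata


class UndefinedRatioError(ZeroDivisionError):
    """No compound passes the cutoff, so the random rate is zero."""


@dataclass(frozen=True)
class EnrichmentResult:
    cutoff: float
    n_c: int        # actives above cutoff
    n_total: int    # all actives
    nn_c: int       # all compounds above cutoff
    n_all: int      # all compounds
    tpr: float
    random_rate: float
    ratio: float


def compute_enrichment(
    scores: Iterable[tuple[str, float, bool]] | Sequence,
    cutoff: float = 0.9,
) -> EnrichmentResult:
    """Compute the enrichment ratio from (id, score, is_active) triples.

    The cutoff comparison is strict ``>``. Raises
    :class:`UndefinedRatioError` when no compound scores above the cutoff,
    and ``ValueError`` on an empty table or one without actives.
    """
    rows = list(scores)
    n_all = len(rows)
    if n_all == 0:
        raise ValueError("empty score table")
    n_total = sum(1 for _, _, active in rows if active)
    if n_total == 0:
        raise ValueError("no active compounds in the table")
    n_c = sum(1 for _, s, active in rows if active and s > cutoff)
    nn_c = sum(1 for _, s, _ in rows if s > cutoff)
    if nn_c == 0:
        raise UndefinedRatioError(
            f"no compound scores above {cutoff}; ratio undefined")
    tpr = n_c / n_total
    random_rate = nn_c / n_all
    return EnrichmentResult(cutoff=cutoff, n_c=n_c, n_total=n_total,
                            nn_c=nn_c, n_all=n_all, tpr=tpr,
                            random_rate=random_rate, ratio=tpr / random_rate)


def auc(scores: Sequence[float], labels: Sequence[bool | int]) -> float:
    """Rank-based (Mann–Whitney) AUC; tied scores contribute 1/2.

    Equals the probability that a random active outranks a random inactive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def enrichment_from_predictions(ids: Sequence[str], scores: Sequence[float],
                                labels: Sequence[bool | int],
                                cutoff: float = 0.9) -> EnrichmentResult:
    return compute_enrichment(
        [(i, float(s), bool(l)) for i, s, l in zip(ids, scores, labels)],
        cutoff=cutoff)
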