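"""Ranking-based evaluation: ROC AUC, rank-recovery curves, fold enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class RecoveryCurve:
    """Cumulative known peptides recovered as a function of prediction rank."""

    ranks: np.ndarray
    cumulative_known: np.ndarray
    baseline_name: str = ""


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2.

    Exact under ties, unlike trapezoidal integration over thresholds.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks under ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rank_recovery(
    labels,
    scores,
    max_rank: int,
    tie_break=None,
    baseline_name: str = "",
) -> RecoveryCurve:
    """Cumulative positives among the top-r predictions for r = 1..max_rank.

    ``tie_break`` optionally supplies a secondary sort array (descending)
    applied within equal scores; remaining ties resolve by input order, so
    the curve is deterministic.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if max_rank > len(labels):
        raise ValueError(f"max_rank {max_rank} exceeds {len(labels)} rows")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if tie_break is None:
        order = np.lexsort((np.arange(len(scores)), -scores))
    else:
        tie_break = np.asarray(tie_break, dtype=float)
        order = np.lexsort((np.arange(len(scores)), -tie_break, -scores))
    hits = np.cumsum(labels[order][:max_rank])
    return RecoveryCurve(
        ranks=np.arange(1, max_rank + 1),
        cumulative_known=hits,
        baseline_name=baseline_name,
    )


def fold_enrichment(hits: int, k: int, positives: int, universe: int) -> float:
    """Enrichment of positives among the top k over the universe base rate."""
    if not 0 <= hits <= k <= universe:
        raise ValueError("need 0 <= hits <= k <= universe")
    if positives < 1 or universe < 1:
        raise ValueError("positives and universe must be >= 1")
    return (hits / k) / (positives / universe)
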