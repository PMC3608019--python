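"""Null-model significance testing of species distribution models.

Model quality is measured by the training AUC — the probability that a
presence cell outscores a background cell, with ties counted half.  Instead
of judging the AUC against an arbitrary threshold, the observed value is
ranked within a null distribution of 99 AUCs from models fitted to the same
number of *random* localities drawn from the genus-accessible region; the
observed AUC is pooled as the 100th value and called significant only when
it strictly exceeds the 95th smallest pooled value (ties count against
significance).  Under the null the observed value is exchangeable with the
replicates, so the test's type-I error is 5% by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .sdm import BackgroundSet, MaxentSDM, fit_entropy_model

__all__ = ["auc", "rank_observed", "NullTestResult", "null_model_test"]


def rank_observed(null_aucs, observed: float) -> tuple[int, bool]:
    """Ascending rank of the observed AUC among the pooled 100 values and the
    significance verdict: strictly greater than the 95th smallest pooled
    value, with ties counting against significance."""
    nulls = np.asarray(null_aucs, dtype=float)
    pooled = np.sort(np.append(nulls, observed))
    rank = 1 + int(np.sum(nulls < observed))
    significant = bool(observed > pooled[94]) if len(pooled) == 100 else bool(
        observed > pooled[int(np.ceil(0.95 * len(pooled))) - 1]
    )
    return rank, significant


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 P(tie), exact over all pairs."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class NullTestResult:
    """Observed AUC ranked against 99 random-locality null AUCs."""

    observed_auc: float
    null_aucs: list[float]
    rank: int          # ascending rank of the observed value among all 100
    significant: bool  # observed strictly above the 95th smallest pooled value
    seed: int
    n_localities: int = 0

    def __post_init__(self) -> None:
        if len(self.null_aucs) != 99:
            raise ValueError("null distribution must hold exactly 99 values")

    def to_dict(self) -> dict:
        return {
            "observed_auc": self.observed_auc,
            "null_aucs": list(self.null_aucs),
            "rank": self.rank,
            "significant": self.significant,
            "seed": self.seed,
            "n_localities": self.n_localities,
        }


def training_auc(model: MaxentSDM, presence_X: np.ndarray, background: BackgroundSet) -> float:
    return auc(model.predict_raw(presence_X), model.predict_raw(background.X))


def null_model_test(
    observed_auc: float,
    n_localities: int,
    candidate_X: np.ndarray,
    background: BackgroundSet,
    n_null: int = 99,
    beta: float = 1.0,
    n_knots: int = 30,
    seed: int = 0,
) -> NullTestResult:
    """Rank an observed training AUC against ``n_null`` random-locality models.

    ``candidate_X`` holds the climate values of every cell random localities
    may be drawn from (the same buffered genus region used for background);
    each replicate draws ``n_localities`` cells uniformly without
    replacement, fits the same hinge-maxent settings against the same
    background, and records its training AUC.
    """
    if n_localities < 5:
        raise ValueError("need at least 5 localities")
    if len(candidate_X) < n_localities:
        raise ValueError(
            f"random-locality pool ({len(candidate_X)}) smaller than n_localities ({n_localities})"
        )
    rng = np.random.default_rng(seed)
    nulls: list[float] = []
    for _ in range(n_null):
        idx = rng.choice(len(candidate_X), size=n_localities, replace=False)
        model = fit_entropy_model(candidate_X[idx], background, beta=beta, n_knots=n_knots)
        nulls.append(training_auc(model, candidate_X[idx], background))
    rank, significant = rank_observed(nulls, observed_auc)
    return NullTestResult(
        observed_auc=float(observed_auc),
        null_aucs=nulls,
        rank=rank,
        significant=significant,
        seed=seed,
        n_localities=n_localities,
    )
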