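"""Cross-validated top@k evaluation: fold splitting and ranking metrics.

The protocol splits *both* users and items into q blocks (default 5): fold f
holds out user-block f and item-block f, the test ratings are those of the
test users on the test items, and everything else trains the CF model.  For
each test user the candidate universe is every test item, rated or not;
relevance is binary (any positive rating is relevant — a count of 5 is not
more relevant than a count of 1; unrated candidates are non-relevant).

Metrics, all in [0, 1], computed per user and macro-averaged (mean over users
within a fold, then mean over folds):

* precision@k = |top-k ∩ relevant| / k
* recall@k    = |top-k ∩ relevant| / |relevant|
* F-measure@k = harmonic mean of the two (0 when both are 0)
* MRR@k       = mean over users of 1/rank of the first relevant item in the
                top-k (0 if none)
* nDCG@k      = DCG@k / iDCG@k with binary gains and log2(rank+1) discounts
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cf import RatingsDataset
from .hybrid import RankedRecommendations

__all__ = [
    "FoldSpec",
    "split_folds",
    "fold_train_test",
    "binarize_relevance",
    "precision_at_k",
    "recall_at_k",
    "f_measure_at_k",
    "mrr_at_k",
    "ndcg_at_k",
    "metrics_for_user",
    "aggregate_users",
    "EvalReport",
]

METRIC_NAMES = ("precision", "recall", "f_measure", "mrr", "ndcg")


@dataclass(frozen=True)
class FoldSpec:
    fold_index: int  # 1..q
    test_users: frozenset[str]
    test_items: frozenset[str]
    q: int
    seed: int


def split_folds(data: RatingsDataset, q: int = 5, seed: int = 0) -> list[FoldSpec]:
    """Seeded paired user/item q-fold split.

    Users and items are independently shuffled and cut into q blocks; fold f
    pairs user-block f with item-block f.  Across folds the user blocks
    partition the user set and the item blocks partition the item set.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    if q > data.n_users or q > data.n_items:
        raise ValueError(
            f"q={q} exceeds n_users={data.n_users} or n_items={data.n_items}"
        )
    rng = np.random.default_rng(seed)
    users = np.array(data.users)
    items = np.array(data.items)
    rng.shuffle(users)
    rng.shuffle(items)
    ublocks = np.array_split(users, q)
    iblocks = np.array_split(items, q)
    return [
        FoldSpec(
            fold_index=i + 1,
            test_users=frozenset(ublocks[i].tolist()),
            test_items=frozenset(iblocks[i].tolist()),
            q=q,
            seed=seed,
        )
        for i in range(q)
    ]


def fold_train_test(
    data: RatingsDataset, fold: FoldSpec
) -> tuple[RatingsDataset, pd.DataFrame]:
    """Train ratings and test ratings for a fold.

    Test ratings are those of test users on test items; the train set is all
    remaining triples (test users keep their ratings on train items — that is
    the profile both CF and ONTO score from).
    """
    t = data.triples
    is_test = t["user"].isin(fold.test_users) & t["item"].isin(fold.test_items)
    train = RatingsDataset.from_triples(t[~is_test])
    return train, t[is_test]


def binarize_relevance(test_ratings: pd.DataFrame) -> set[str]:
    """Relevant items for one user: those with a positive test rating."""
    return set(test_ratings.loc[test_ratings["rating"] > 0, "item"])


def precision_at_k(ranked: RankedRecommendations, relevant: set[str], k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    top = ranked.items()[:k]
    return sum(1 for it in top if it in relevant) / k


def recall_at_k(ranked: RankedRecommendations, relevant: set[str], k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant:
        raise ValueError("recall undefined for a user with no relevant items")
    top = ranked.items()[:k]
    return sum(1 for it in top if it in relevant) / len(relevant)


def f_measure_at_k(p: float, r: float) -> float:
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def reciprocal_rank_at_k(
    ranked: RankedRecommendations, relevant: set[str], k: int
) -> float:
    """1/rank of the first relevant item within the top-k; 0 if none."""
    for pos, it in enumerate(ranked.items()[:k], start=1):
        if it in relevant:
            return 1.0 / pos
    return 0.0


def mrr_at_k(
    ranked_lists: list[RankedRecommendations],
    relevant_sets: list[set[str]],
    k: int,
) -> float:
    """Mean reciprocal rank over users."""
    if not ranked_lists:
        raise ValueError("MRR needs at least one user")
    return sum(
        reciprocal_rank_at_k(rl, rel, k)
        for rl, rel in zip(ranked_lists, relevant_sets)
    ) / len(ranked_lists)


def ndcg_at_k(ranked: RankedRecommendations, relevant: set[str], k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant:
        raise ValueError("nDCG undefined for a user with no relevant items")
    dcg = sum(
        1.0 / math.log2(pos + 1)
        for pos, it in enumerate(ranked.items()[:k], start=1)
        if it in relevant
    )
    ideal_hits = min(k, len(relevant))
    idcg = sum(1.0 / math.log2(pos + 1) for pos in range(1, ideal_hits + 1))
    return dcg / idcg


def metrics_for_user(
    ranked: RankedRecommendations, relevant: set[str], k: int
) -> dict[str, float]:
    """All per-user metrics at one k (MRR contributes its reciprocal rank)."""
    p = precision_at_k(ranked, relevant, k)
    r = recall_at_k(ranked, relevant, k)
    return {
        "precision": p,
        "recall": r,
        "f_measure": f_measure_at_k(p, r),
        "mrr": reciprocal_rank_at_k(ranked, relevant, k),
        "ndcg": ndcg_at_k(ranked, relevant, k),
    }


def aggregate_users(per_user: list[dict[str, float]]) -> dict[str, float]:
    """Macro-average metric dicts over users."""
    if not per_user:
        raise ValueError("no users to aggregate")
    return {
        m: sum(d[m] for d in per_user) / len(per_user) for m in METRIC_NAMES
    }


@dataclass
class EvalReport:
    """Long-format per-(algorithm, fold, k) metric table with cross-fold means."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["algorithm", "fold", "k", *METRIC_NAMES]
        )
    )

    def add(self, algorithm: str, fold: int, k: int, metrics: dict[str, float]) -> None:
        self.rows.loc[len(self.rows)] = {
            "algorithm": algorithm,
            "fold": fold,
            "k": k,
            **metrics,
        }

    def summary(self) -> pd.DataFrame:
        """Cross-fold mean per (algorithm, k)."""
        return (
            self.rows.groupby(["algorithm", "k"])[list(METRIC_NAMES)]
            .mean()
            .reset_index()
        )

    def to_long_csv(self, path) -> None:
        long = self.rows.melt(
            id_vars=["algorithm", "fold", "k"],
            value_vars=list(METRIC_NAMES),
            var_name="metric",
            value_name="value",
        )
        long.to_csv(path, index=False)
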