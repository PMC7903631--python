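"""ONTO: content-based scoring by mean semantic similarity to a user profile.

A candidate (test) item is scored as the arithmetic mean of its semantic
similarities to the ``n`` most similar of the user's training items:

    S_CB(t) = (Sim(t, i_1) + ... + Sim(t, i_m)) / m

with m = min(n, |train|).  Because the score depends only on the ontology and
the user's own history — never on any rating of the candidate itself — a
brand-new item with zero ratings dataset-wide can still be recommended, which
is exactly the cold-start case collaborative filtering cannot handle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simstore import MEASURES, SimilarityStore

__all__ = ["OntoScore", "score_items_onto", "ALL"]

#: sentinel for "use every train item" (no n-most-similar restriction)
ALL: object = "all"


@dataclass(frozen=True)
class OntoScore:
    user_id: str | None
    item_id: str
    measure: str
    n_used: int  # number of train items actually averaged (m)
    score: float


def score_items_onto(
    store: SimilarityStore,
    train_items: list[str],
    test_items: list[str],
    measure: str = "lin",
    n: int | object = 5,
    user_id: str | None = None,
) -> dict[str, OntoScore]:
    """Score each test item against a user's train items.

    For each test item the similarities to all train items are collected from
    the store, sorted descending (ties broken by ascending train-item id so
    the n-cutoff is deterministic), the top ``min(n, |train|)`` kept, and
    their arithmetic mean returned.  ``n=ALL`` (or any non-int) uses every
    train item.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")
    if not train_items:
        raise ValueError("empty train set: ONTO needs at least one train item")
    use_all = not isinstance(n, int)
    if not use_all and n < 1:
        raise ValueError("n must be >= 1 or ALL")

    train = sorted(set(train_items))
    out: dict[str, OntoScore] = {}
    for t in test_items:
        sims = store.get_many([(t, tr) for tr in train], measure)
        # descending similarity, ascending item id on ties
        order = sorted(zip(sims, train), key=lambda p: (-p[0], p[1]))
        m = len(order) if use_all else min(n, len(order))
        kept = [s for s, _ in order[:m]]
        out[t] = OntoScore(
            user_id=user_id,
            item_id=t,
            measure=measure,
            n_used=m,
            score=sum(kept) / m,
        )
    return out
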