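"""Score fusion and ranking for the hybrid recommender.

Two fixed fusion rules combine the collaborative-filtering score S_CF and the
content-based score S_CB per candidate item:

* Metric1 — the product ``S_CF · S_CB``: scale-invariant per side, lets an
  item that is outstanding under either module surface.
* Metric2 — the mean ``(S_CF + S_CB) / 2``: the conventional weighted blend,
  sensitive to score-range mismatch (an unbounded Resnik-based S_CB can
  dominate CF scores below 1).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HybridScore",
    "RankedRecommendations",
    "combine_metric1",
    "combine_metric2",
    "combine_scores",
    "minmax_normalize",
    "rank_items",
]


def minmax_normalize(scores: dict[str, float]) -> dict[str, float]:
    """Rescale scores to [0, 1]; constant inputs map to 0.5 (order-free).

    Optional pre-fusion step for mean fusion when one side's range (e.g.
    Resnik in bits) would otherwise dominate; off by default so the raw
    range mismatch stays observable.
    """
    if not scores:
        return {}
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {k: 0.5 for k in scores}
    return {k: (v - lo) / (hi - lo) for k, v in scores.items()}


def combine_metric1(s_cf: float, s_cb: float) -> float:
    """Product fusion: S_CF × S_CB."""
    return s_cf * s_cb


def combine_metric2(s_cf: float, s_cb: float) -> float:
    """Mean fusion: (S_CF + S_CB) / 2."""
    return (s_cf + s_cb) / 2.0


_METRICS = {"m1": combine_metric1, "m2": combine_metric2}


@dataclass(frozen=True)
class HybridScore:
    user_id: str | None
    item_id: str
    s_cf: float
    s_cb: float
    metric: str  # "m1" | "m2"
    combined: float


@dataclass(frozen=True)
class RankedRecommendations:
    user_id: str | None
    ranking: tuple[tuple[str, float], ...]  # (item_id, score), descending

    def items(self) -> list[str]:
        return [it for it, _ in self.ranking]

    def __len__(self) -> int:
        return len(self.ranking)


def combine_scores(
    cf_scores: dict[str, float],
    cb_scores: dict[str, float],
    metric: str,
    user_id: str | None = None,
    cb_only_fallback: bool = False,
) -> dict[str, HybridScore]:
    """Fuse per-item CF and CB scores.

    Items with only a CB score (e.g. CF-unseen items under the ``exclude``
    policy) are dropped by default — the hybrid inherits CF's cold-start
    limitation — or kept with ``combined = s_cb`` when ``cb_only_fallback``
    is on.  Items with only a CF score are always dropped: ONTO covers every
    ontology item, so a missing CB score signals an item outside the ontology.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    fuse = _METRICS[metric]
    out: dict[str, HybridScore] = {}
    for item, s_cb in cb_scores.items():
        if item in cf_scores:
            s_cf = cf_scores[item]
            combined = fuse(s_cf, s_cb)
        elif cb_only_fallback:
            s_cf = float("nan")
            combined = s_cb
        else:
            continue
        out[item] = HybridScore(user_id, item, s_cf, s_cb, metric, combined)
    return out


def rank_items(
    scores: dict[str, float], user_id: str | None = None
) -> RankedRecommendations:
    """Stable descending sort with ties broken by ascending item id."""
    for item, s in scores.items():
        if s != s or s in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite score for item {item!r}")
    ordered = sorted(scores.items(), key=lambda p: (-p[1], p[0]))
    return RankedRecommendations(user_id=user_id, ranking=tuple(ordered))
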