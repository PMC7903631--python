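"""Synthetic ontologies and ontology-correlated implicit ratings.

Real inputs for this recommender are a chemical ontology (ChEBI-scale: tens
of thousands of terms) and a literature-derived implicit ratings table in
which users are authors, items are ontology terms, every user has rated at
least 20 items, and item popularity is heavily skewed (most items have one or
two raters).  This module emulates that structure at desk scale so every
component is testable without downloads:

* :func:`gen_ontology` grows a single-root random DAG: term t picks 1..
  ``max_parents`` parents among earlier terms, biased toward recent ones so
  the DAG develops depth rather than a star shape.
* :func:`gen_ratings` gives each user an *anchor subtree*; a ``concentration``
  fraction of their items is drawn from that subtree and the rest from a
  power-law popularity pool.  At concentration 1 a user's history is purely
  ontology-driven (strong content-based signal); at 0 it is independent of
  the ontology (negative control for ONTO).

Generation is fully determined by the seed; identical configs yield
byte-identical OBO text and ratings tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cf import RatingsDataset
from .ontology import OntologyGraph, parse_obo

__all__ = [
    "SynthConfig",
    "gen_ontology",
    "to_obo",
    "gen_ratings",
    "gen_rank1_preferences",
    "fixture_toy",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the shape of a literature-derived compound-ratings
    dataset: every user rates at least 20 items, ratings are small positive
    counts (capped at 5), and item popularity follows a power law.
    """

    n_terms: int = 150
    max_parents: int = 2
    n_users: int = 40
    n_items: int = 80  # must be <= n_terms
    min_items_per_user: int = 20
    extra_items_mean: float = 4.0  # Poisson mean on top of the minimum
    popularity_skew: float = 1.0  # power-law exponent on item rank
    concentration: float = 0.9  # fraction of a user's items from their subtree
    rating_probs: tuple[float, ...] = (0.55, 0.2, 0.12, 0.08, 0.05)  # counts 1..5
    seed: int = 0

    def __post_init__(self):
        if self.n_items > self.n_terms:
            raise ValueError("n_items must be <= n_terms")
        if self.min_items_per_user < 1:
            raise ValueError("min_items_per_user must be >= 1")
        if not 0.0 <= self.concentration <= 1.0:
            raise ValueError("concentration must be in [0, 1]")
        if abs(sum(self.rating_probs) - 1.0) > 1e-9:
            raise ValueError("rating_probs must sum to 1")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def gen_ontology(config: SynthConfig) -> tuple[OntologyGraph, str]:
    """Generate a single-root random DAG and its OBO serialization.

    Returns the parsed graph and the OBO text (parsing its own output keeps
    the serializer honest).
    """
    if config.n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = np.random.default_rng(config.seed)
    parents: dict[int, list[int]] = {0: []}
    for t in range(1, config.n_terms):
        k = int(rng.integers(1, config.max_parents + 1))
        k = min(k, t)
        # geometric bias toward recent terms => deeper DAGs
        weights = np.array([0.85 ** (t - 1 - j) for j in range(t)])
        weights /= weights.sum()
        chosen = rng.choice(t, size=k, replace=False, p=weights)
        parents[t] = sorted(int(c) for c in chosen)
    obo = to_obo(parents)
    return parse_obo(obo), obo


def to_obo(parents: dict[int, list[int]]) -> str:
    """Serialize integer-indexed parent lists as a minimal OBO document."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for t in sorted(parents):
        lines.append("[Term]")
        lines.append(f"id: {_term_id(t)}")
        lines.append(f"name: synthetic term {t}")
        for p in parents[t]:
            lines.append(f"is_a: {_term_id(p)}")
        lines.append("")
    return "\n".join(lines)


def _subtree_items(
    graph: OntologyGraph, anchor: str, item_set: set[str]
) -> list[str]:
    """Items of the universe lying in the descendant-or-self set of anchor."""
    down = nx.ancestors(graph.graph, anchor) | {anchor}
    return sorted(down & item_set)


def gen_ratings(graph: OntologyGraph, config: SynthConfig) -> RatingsDataset:
    """Ontology-correlated implicit ratings with a skewed popularity pool.

    Each user draws an anchor term whose subtree holds enough items for their
    concentrated share (anchors are resampled otherwise), then samples
    ``concentration`` of their items from the subtree and the rest from the
    global power-law pool.  Ratings are counts in 1..5.
    """
    rng = np.random.default_rng(config.seed + 1)
    terms = sorted(graph.terms)
    items = sorted(rng.choice(terms, size=config.n_items, replace=False).tolist())
    item_set = set(items)

    # power-law popularity over a random item order
    order = rng.permutation(config.n_items)
    pop = np.empty(config.n_items)
    pop[order] = (np.arange(config.n_items) + 1.0) ** (-config.popularity_skew)
    pop /= pop.sum()

    # anchors: terms whose subtree holds at least ~half the concentrated need
    counts = np.arange(1, 6)
    rows = []
    for u in range(config.n_users):
        n_u = config.min_items_per_user + int(rng.poisson(config.extra_items_mean))
        n_u = min(n_u, config.n_items)
        n_sub = int(round(config.concentration * n_u))
        subtree: list[str] = []
        if n_sub > 0:
            for _ in range(200):
                anchor = terms[int(rng.integers(len(terms)))]
                subtree = _subtree_items(graph, anchor, item_set)
                if len(subtree) >= max(2, n_sub // 2):
                    break
            n_sub = min(n_sub, len(subtree))
        chosen: set[str] = set()
        if n_sub > 0:
            chosen.update(
                rng.choice(subtree, size=n_sub, replace=False).tolist()
            )
        # fill the rest from the popularity pool (rejection on duplicates)
        while len(chosen) < n_u:
            cand = items[int(rng.choice(config.n_items, p=pop))]
            chosen.add(cand)
        for item in sorted(chosen):
            rating = int(rng.choice(counts, p=np.asarray(config.rating_probs)))
            rows.append((f"u{u:04d}", item, rating))

    triples = pd.DataFrame(rows, columns=["user", "item", "rating"])
    return RatingsDataset.from_triples(triples)


def gen_rank1_preferences(
    n_users: int = 30,
    n_items: int = 40,
    n_pos: int = 12,
    seed: int = 7,
) -> tuple[RatingsDataset, np.ndarray]:
    """Implicit ratings driven by a rank-1 preference structure.

    Every item has a latent quality ``q_i``; each user observes the top
    ``n_pos`` items by ``q_i`` plus a small per-user perturbation, so the
    true item ordering is shared across users (a rank-1 preference matrix)
    while observed sets differ slightly.  Returns the dataset and the quality
    vector (the ground truth for ranking checks such as held-out pairwise
    AUC).
    """
    rng = np.random.default_rng(seed)
    quality = rng.uniform(0.5, 1.5, size=n_items)
    rows = []
    for u in range(n_users):
        perturbed = quality + rng.normal(0.0, 0.1, size=n_items)
        chosen = np.argsort(-perturbed)[:n_pos]
        for j in sorted(chosen):
            rows.append((f"u{u:04d}", _term_id(j), int(max(1, round(quality[j] * 2)))))
    data = RatingsDataset.from_triples(
        pd.DataFrame(rows, columns=["user", "item", "rating"])
    )
    return data, quality


_TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: T:R
name: toy root

[Term]
id: T:A
name: toy branch a
is_a: T:R

[Term]
id: T:B
name: toy branch b
is_a: T:R

[Term]
id: T:C
name: toy leaf c
alt_id: T:C9
is_a: T:A

[Term]
id: T:D
name: toy leaf d
is_a: T:A
"""

_TOY_RATINGS = """user,item,rating
alice,T:A,2
alice,T:C,1
alice,T:D,3
bob,T:B,1
bob,T:C,2
carol,T:A,1
carol,T:B,1
carol,T:D,1
"""


def fixture_toy() -> tuple[OntologyGraph, RatingsDataset]:
    """The fixed 5-term diamond-free DAG and 3-user ratings table.

    Structure: root R; A, B is_a R; C, D is_a A.  With N=5 terms the ICs are
    IC(R)=0, IC(A)=log2(5/3), IC(B)=IC(C)=IC(D)=log2(5).  Byte-stable across
    calls.
    """
    import io

    graph = parse_obo(_TOY_OBO)
    data = RatingsDataset.from_triples(pd.read_csv(io.StringIO(_TOY_RATINGS)))
    return graph, data
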