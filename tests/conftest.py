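"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own graph machinery: they
recompute ancestor sets by naive recursion over the parsed parent lists and
information content by counting descendants through those ancestor sets, so
they can serve as an independent cross-check of the production path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ontorec import OntologyGraph, compute_ic, parse_obo
from ontorec.synthetic import fixture_toy


# ---------------------------------------------------------------- oracles


def brute_ancestors_or_self(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Ancestor closure by naive recursion over stored parent lists."""
    out: set[str] = set()

    def walk(t: str) -> None:
        if t in out:
            return
        out.add(t)
        for p in graph.terms[t].parents:
            walk(p)

    walk(term)
    return frozenset(out)


def brute_ic(graph: OntologyGraph) -> dict[str, float]:
    """IC by counting, for each term, how many terms have it as an ancestor."""
    anc = {t: brute_ancestors_or_self(graph, t) for t in graph.terms}
    n = len(graph.terms)
    ic = {}
    for t in graph.terms:
        desc = sum(1 for other in graph.terms if other != t and t in anc[other])
        ic[t] = -math.log2((desc + 1) / n)
    return ic


def brute_similarities(
    graph: OntologyGraph, a: str, b: str
) -> tuple[float, float, float]:
    """(resnik, lin, jc) from fully enumerated ancestor sets and brute IC."""
    ic = brute_ic(graph)
    common = brute_ancestors_or_self(graph, a) & brute_ancestors_or_self(graph, b)
    shared = max((ic[t] for t in common), default=0.0)
    resnik = shared
    denom = ic[a] + ic[b]
    if denom == 0.0:
        lin = 1.0 if a == b else 0.0
    else:
        lin = 2.0 * shared / denom
    jc = 1.0 / (1.0 + ic[a] + ic[b] - 2.0 * shared)
    return resnik, lin, jc


def random_dag(n_terms: int, seed: int, max_parents: int = 3) -> OntologyGraph:
    """Random single-root DAG built directly as OBO text."""
    rng = np.random.default_rng(seed)
    lines = ["format-version: 1.2", "ontology: random-test", ""]
    for t in range(n_terms):
        lines += ["[Term]", f"id: RT:{t:04d}", f"name: term {t}"]
        if t > 0:
            k = min(t, int(rng.integers(1, max_parents + 1)))
            for p in sorted(rng.choice(t, size=k, replace=False)):
                lines.append(f"is_a: RT:{int(p):04d}")
        lines.append("")
    return parse_obo("\n".join(lines))


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def toy():
    """The fixed 5-term DAG (R; A,B is_a R; C,D is_a A) with its IC table."""
    graph, ratings = fixture_toy()
    return graph, compute_ic(graph), ratings


@pytest.fixture(scope="session")
def toy_store(toy, tmp_path_factory):
    from ontorec import build_cache

    graph, ic, ratings = toy
    path = tmp_path_factory.mktemp("store") / "toy.db"
    return build_cache(graph, ic, sorted(graph.terms), path, workers=1)


class DictStore:
    """In-memory stand-in for a SimilarityStore, for tests that need

    hand-chosen similarity values rather than ontology-derived ones."""

    def __init__(self, sims: dict[tuple[str, str], float]):
        self._sims = {}
        for (a, b), v in sims.items():
            self._sims[(min(a, b), max(a, b))] = v

    def get_many(self, pairs, measure):
        return [self._sims[(min(a, b), max(a, b))] for a, b in pairs]


@pytest.fixture
def dict_store_factory():
    return DictStore
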