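"""Ontology parsing, information content, and IC-based semantic similarity.

The ontology is a DAG of terms connected by ``is_a`` edges (ChEBI-style).
Similarity between two terms is grounded in *information content* (IC): the
negative log-probability of a term, where a term's probability is the fraction
of the ontology it subsumes.  Three classic measures are provided:

* Resnik — IC of the most informative common ancestor (MICA); unbounded above.
* Lin — ``2·IC(MICA) / (IC(a) + IC(b))``; range [0, 1].
* Jiang–Conrath — the IC distance ``IC(a) + IC(b) − 2·IC(MICA)`` converted to
  a similarity via ``1 / (1 + d)``; range (0, 1].

All logs are base 2, so IC is measured in bits.  Only ``is_a`` edges are
traversed by default; other relationship types (``has_role`` etc.) may be
enabled via an allow-list at parse time.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

__all__ = [
    "OntologyError",
    "CycleError",
    "UnknownTermError",
    "OntologyTerm",
    "OntologyGraph",
    "parse_obo",
    "compute_ic",
    "shared_ic",
    "shared_ic_dca",
    "sim_resnik",
    "sim_lin",
    "sim_jc",
    "SIM_FUNCTIONS",
]


class OntologyError(ValueError):
    """Malformed ontology input."""


class CycleError(OntologyError):
    """The is_a relation contains a cycle (the graph is not a DAG)."""

    def __init__(self, cycle: list[tuple[str, str]]):
        self.cycle = cycle
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        super().__init__(f"is_a cycle detected: {path}")


class UnknownTermError(KeyError):
    """An identifier that resolves to no term in the ontology."""

    def __init__(self, term_id: str, strict: bool = False):
        self.term_id = term_id
        msg = f"unknown term id: {term_id!r}"
        if strict:
            msg += " (strict mode: secondary ids are not resolved)"
        super().__init__(msg)


@dataclass(frozen=True)
class OntologyTerm:
    primary_id: str
    name: str = ""
    synonyms: tuple[str, ...] = ()
    alt_ids: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """A parsed ontology: terms, is_a edges, and an alt_id resolution map.

    ``graph`` is a :class:`networkx.DiGraph` with edges pointing child→parent,
    so ``nx.descendants(graph, t)`` yields the ancestors of ``t`` and
    ``nx.ancestors(graph, t)`` its descendants.
    """

    terms: dict[str, OntologyTerm]
    graph: nx.DiGraph
    alt_id_map: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False
    )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """is_a edges as (child, parent) pairs."""
        return list(self.graph.edges())

    def roots(self) -> list[str]:
        return sorted(t for t in self.terms if self.graph.out_degree(t) == 0)

    def resolve_id(self, term_id: str, strict: bool = False) -> str:
        """Resolve a primary or secondary accession to its primary id.

        In strict mode secondary ids are treated as unknown, reproducing the
        behaviour of tools that index primary ids only.
        """
        if term_id in self.terms:
            return term_id
        if not strict and term_id in self.alt_id_map:
            return self.alt_id_map[term_id]
        raise UnknownTermError(term_id, strict=strict)

    def ancestors_or_self(self, term_id: str, strict: bool = False) -> frozenset[str]:
        """Reflexive-transitive closure over is_a; always contains the term."""
        primary = self.resolve_id(term_id, strict=strict)
        cached = self._ancestor_cache.get(primary)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, primary)) | {primary}
            self._ancestor_cache[primary] = cached
        return cached

    def descendant_count(self, term_id: str) -> int:
        """Number of strict descendants of a term."""
        return len(nx.ancestors(self.graph, self.resolve_id(term_id)))


_ID_LINE = re.compile(r"^id:\s*(\S+)\s*$", re.MULTILINE)


def parse_obo(
    obo_text: str,
    relationships: tuple[str, ...] = (),
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyGraph`.

    Honours ``id``, ``name``, ``alt_id``, ``synonym``, ``is_a`` and
    ``is_obsolete`` (obsolete terms are dropped); all other tags are ignored.
    ``relationships`` optionally allow-lists additional relationship types
    (e.g. ``("has_role",)``) to traverse besides ``is_a``.

    Raises :class:`OntologyError` on duplicate primary ids and
    :class:`CycleError` if the is_a relation is cyclic.
    """
    # obonet keeps the last stanza for a repeated id; detect duplicates from
    # the raw text so they are rejected rather than silently merged.
    seen: set[str] = set()
    in_term = False
    for line in obo_text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
            continue
        if in_term and line.startswith("id:"):
            tid = line[3:].strip()
            if tid in seen:
                raise OntologyError(f"duplicate primary id: {tid!r}")
            seen.add(tid)

    multi = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=True)

    allowed = {"is_a", *relationships}
    g = nx.DiGraph()
    terms: dict[str, OntologyTerm] = {}
    alt_map: dict[str, str] = {}

    for node, data in multi.nodes(data=True):
        g.add_node(node)
    for node, data in multi.nodes(data=True):
        parents = tuple(
            sorted(
                v
                for _, v, key in multi.out_edges(node, keys=True)
                if key in allowed and v in multi
            )
        )
        term = OntologyTerm(
            primary_id=node,
            name=data.get("name", ""),
            synonyms=tuple(data.get("synonym", ())),
            alt_ids=tuple(data.get("alt_id", ())),
            parents=parents,
        )
        terms[node] = term
        g.add_edges_from((node, p) for p in parents)
        for alt in term.alt_ids:
            if alt in terms or alt in multi:
                raise OntologyError(
                    f"alt_id {alt!r} of {node!r} collides with a primary id"
                )
            alt_map[alt] = node

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError(list(cycle))

    return OntologyGraph(terms=terms, graph=g, alt_id_map=alt_map)


def compute_ic(
    graph: OntologyGraph,
    annotations: dict[str, int] | None = None,
) -> dict[str, float]:
    """Information content per term, in bits.

    Intrinsic (default): ``IC(t) = −log2((desc(t) + 1) / N)`` with ``desc(t)``
    the number of strict descendants of ``t`` and ``N`` the total number of
    terms — a term's probability is the fraction of the ontology it subsumes,
    so a root subsuming everything has IC 0 and leaves carry the most
    information.

    Extrinsic: pass per-term ``annotations`` counts (e.g. corpus mentions);
    a term's frequency is then the annotation mass of its descendant-or-self
    set plus one (Laplace smoothing, so unannotated terms stay finite),
    normalized by the total.
    """
    import math

    n = graph.n_terms
    if n < 1:
        raise OntologyError("empty ontology")
    if annotations is None:
        return {
            t: -math.log2((graph.descendant_count(t) + 1) / n)
            for t in graph.terms
        }
    ann = {t: annotations.get(t, 0) for t in graph.terms}
    unknown = set(annotations) - set(graph.terms)
    if unknown:
        raise UnknownTermError(sorted(unknown)[0])
    mass = {
        t: sum(ann[d] for d in graph.terms if t in graph.ancestors_or_self(d))
        for t in graph.terms
    }
    total = max(mass.values()) + 1
    return {t: -math.log2((mass[t] + 1) / total) for t in graph.terms}


def shared_ic(
    graph: OntologyGraph, ic: dict[str, float], a: str, b: str
) -> float:
    """IC of the most informative common ancestor of ``a`` and ``b``.

    Terms with no common ancestor (disjoint components) share IC 0.
    """
    common = graph.ancestors_or_self(a) & graph.ancestors_or_self(b)
    if not common:
        return 0.0
    return max(ic[t] for t in common)


def shared_ic_dca(
    graph: OntologyGraph, ic: dict[str, float], a: str, b: str
) -> float:
    """Shared IC by disjunctive common ancestors (DiShIn-style).

    Common ancestors are visited in descending IC; an ancestor is
    *disjunctive* if the difference between its path counts to the two terms
    differs from that of every ancestor already selected.  The shared IC is
    the mean IC of the selected ancestors, which softens the winner-takes-all
    behaviour of the MICA convention on multiple-inheritance graphs.
    """
    pa, pb = graph.resolve_id(a), graph.resolve_id(b)
    common = graph.ancestors_or_self(pa) & graph.ancestors_or_self(pb)
    if not common:
        return 0.0
    seen_diffs: set[int] = set()
    selected: list[float] = []
    ordered = sorted(common, key=lambda t: (-ic[t], t))
    for anc in ordered:
        diff = abs(_path_count(graph, pa, anc) - _path_count(graph, pb, anc))
        if diff not in seen_diffs:
            seen_diffs.add(diff)
            selected.append(ic[anc])
    return sum(selected) / len(selected)


def _path_count(graph: OntologyGraph, source: str, target: str) -> int:
    """Number of distinct is_a paths from a term up to an ancestor."""
    if source == target:
        return 1
    total = 0
    for parent in graph.terms[source].parents:
        if target in graph.ancestors_or_self(parent):
            total += _path_count(graph, parent, target)
    return total


def _shared(graph, ic, a, b, shared: str) -> float:
    if shared == "mica":
        return shared_ic(graph, ic, a, b)
    if shared == "dca":
        return shared_ic_dca(graph, ic, a, b)
    raise ValueError("shared must be 'mica' or 'dca'")


def sim_resnik(
    graph: OntologyGraph,
    ic: dict[str, float],
    a: str,
    b: str,
    shared: str = "mica",
) -> float:
    """Resnik similarity: shared IC of the pair. Non-negative, unbounded above."""
    return _shared(graph, ic, a, b, shared)


def sim_lin(
    graph: OntologyGraph,
    ic: dict[str, float],
    a: str,
    b: str,
    shared: str = "mica",
) -> float:
    """Lin similarity in [0, 1].

    When both terms have IC 0 (e.g. two roots) the ratio is undefined; the
    convention is 1 for a term with itself and 0 otherwise.
    """
    pa, pb = graph.resolve_id(a), graph.resolve_id(b)
    denom = ic[pa] + ic[pb]
    if denom == 0.0:
        return 1.0 if pa == pb else 0.0
    return 2.0 * _shared(graph, ic, a, b, shared) / denom


def sim_jc(
    graph: OntologyGraph,
    ic: dict[str, float],
    a: str,
    b: str,
    shared: str = "mica",
) -> float:
    """Jiang–Conrath similarity in (0, 1].

    The JC distance ``IC(a) + IC(b) − 2·sharedIC`` is mapped to a similarity
    via ``1 / (1 + d)``, which is 1 exactly when the distance is 0.
    """
    pa, pb = graph.resolve_id(a), graph.resolve_id(b)
    d = ic[pa] + ic[pb] - 2.0 * _shared(graph, ic, a, b, shared)
    return 1.0 / (1.0 + d)


SIM_FUNCTIONS = {"resnik": sim_resnik, "lin": sim_lin, "jc": sim_jc}
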