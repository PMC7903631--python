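"""Persistent pairwise-similarity store.

Computing IC-based similarities on the fly is the bottleneck of content-based
scoring: every (test item, train item) pair needs an ancestor intersection.
This module precomputes all three measures (Resnik, Lin, Jiang–Conrath) for
every unordered pair of a declared item universe — optionally in parallel —
and serves them from a single-file sqlite database, so downstream scoring is
a lookup, not a graph traversal.

Pairs are canonicalized lexicographically (``item_a <= item_b``) so symmetry
is structural.  Stores built with different worker counts are record-identical
by construction: the pair list is enumerated deterministically, each pair's
floating-point path is worker-independent, and rows are inserted in canonical
order regardless of which worker produced them.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from multiprocessing import get_context
from pathlib import Path

from .ontology import (
    OntologyGraph,
    UnknownTermError,
    sim_jc,
    sim_lin,
    sim_resnik,
)

__all__ = [
    "SimilarityStore",
    "build_cache",
    "MissingPairError",
    "benchmark_speedup",
]

MEASURES = ("resnik", "lin", "jc")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS pair_similarity (
    item_a TEXT NOT NULL,
    item_b TEXT NOT NULL,
    resnik REAL NOT NULL,
    lin REAL NOT NULL,
    jc REAL NOT NULL,
    PRIMARY KEY (item_a, item_b)
) WITHOUT ROWID;
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
"""


class MissingPairError(KeyError):
    """A queried pair is absent from the store (distinct from similarity 0)."""

    def __init__(self, a: str, b: str):
        self.pair = (a, b)
        super().__init__(f"pair ({a!r}, {b!r}) not in similarity store")


@dataclass
class SimilarityStore:
    """Read interface over a built pairwise-similarity database."""

    path: str | Path

    def _connect(self) -> sqlite3.Connection:
        return sqlite3.connect(str(self.path))

    @property
    def items(self) -> list[str]:
        with self._connect() as con:
            row = con.execute(
                "SELECT value FROM meta WHERE key='items'"
            ).fetchone()
        return row[0].split("\n") if row and row[0] else []

    @property
    def include_self_pairs(self) -> bool:
        with self._connect() as con:
            row = con.execute(
                "SELECT value FROM meta WHERE key='include_self_pairs'"
            ).fetchone()
        return bool(row) and row[0] == "1"

    @property
    def n_records(self) -> int:
        with self._connect() as con:
            return con.execute(
                "SELECT COUNT(*) FROM pair_similarity"
            ).fetchone()[0]

    def get(self, a: str, b: str, measure: str) -> float:
        """Stored similarity for an unordered pair; symmetric by construction."""
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")
        lo, hi = (a, b) if a <= b else (b, a)
        with self._connect() as con:
            row = con.execute(
                f"SELECT {measure} FROM pair_similarity "
                "WHERE item_a=? AND item_b=?",
                (lo, hi),
            ).fetchone()
        if row is None:
            raise MissingPairError(a, b)
        return row[0]

    def get_many(self, pairs: list[tuple[str, str]], measure: str) -> list[float]:
        """Batch lookup preserving input order; raises on the first missing pair."""
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")
        out = []
        with self._connect() as con:
            cur = con.cursor()
            for a, b in pairs:
                lo, hi = (a, b) if a <= b else (b, a)
                row = cur.execute(
                    f"SELECT {measure} FROM pair_similarity "
                    "WHERE item_a=? AND item_b=?",
                    (lo, hi),
                ).fetchone()
                if row is None:
                    raise MissingPairError(a, b)
                out.append(row[0])
        return out

    def records(self) -> list[tuple[str, str, float, float, float]]:
        """All records in canonical order (for equality checks)."""
        with self._connect() as con:
            return con.execute(
                "SELECT item_a, item_b, resnik, lin, jc "
                "FROM pair_similarity ORDER BY item_a, item_b"
            ).fetchall()


# Worker-process state, set once per worker by the pool initializer.  Using
# fork inheritance would also work on Linux; an explicit initializer keeps the
# data flow visible and start-method agnostic.
_WORK: dict = {}


def _init_worker(graph: OntologyGraph, ic: dict[str, float]) -> None:
    _WORK["graph"] = graph
    _WORK["ic"] = ic


def _compute_chunk(
    chunk: list[tuple[str, str]],
) -> list[tuple[str, str, float, float, float]]:
    graph, ic = _WORK["graph"], _WORK["ic"]
    return [
        (
            a,
            b,
            sim_resnik(graph, ic, a, b),
            sim_lin(graph, ic, a, b),
            sim_jc(graph, ic, a, b),
        )
        for a, b in chunk
    ]


def build_cache(
    graph: OntologyGraph,
    ic: dict[str, float],
    items: list[str],
    path: str | Path,
    workers: int = 1,
    include_self_pairs: bool = True,
    chunk_size: int = 10_000,
    strict: bool = False,
) -> SimilarityStore:
    """Precompute all pairwise similarities for ``items`` into a sqlite store.

    Unresolvable items are skipped with their ids recorded in store metadata
    (lenient default) or raised as a fatal error (``strict=True``).  The
    resulting store is record-identical for any ``workers`` value.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")

    resolved: list[str] = []
    unknown: list[str] = []
    for it in items:
        try:
            resolved.append(graph.resolve_id(it))
        except UnknownTermError:
            unknown.append(it)
    if unknown and strict:
        raise UnknownTermError(
            ", ".join(sorted(unknown)), strict=False
        )

    universe = sorted(set(resolved))
    pairs = [
        (universe[i], universe[j])
        for i in range(len(universe))
        for j in range(i if include_self_pairs else i + 1, len(universe))
    ]
    chunks = [
        pairs[i : i + chunk_size] for i in range(0, len(pairs), chunk_size)
    ]

    if workers == 1 or len(chunks) <= 1:
        _init_worker(graph, ic)
        results = [_compute_chunk(c) for c in chunks]
    else:
        ctx = get_context()
        with ctx.Pool(
            workers, initializer=_init_worker, initargs=(graph, ic)
        ) as pool:
            results = pool.map(_compute_chunk, chunks)

    path = Path(path)
    if path.exists():
        path.unlink()
    with sqlite3.connect(str(path)) as con:
        con.executescript(_SCHEMA)
        for rows in results:
            con.executemany(
                "INSERT INTO pair_similarity VALUES (?,?,?,?,?)", rows
            )
        con.executemany(
            "INSERT OR REPLACE INTO meta VALUES (?,?)",
            [
                ("items", "\n".join(universe)),
                ("include_self_pairs", "1" if include_self_pairs else "0"),
                ("skipped_items", "\n".join(sorted(unknown))),
            ],
        )
    return SimilarityStore(path)


def benchmark_speedup(latency_baseline: float, latency_new: float) -> float:
    """Latency speedup ratio ``baseline / new`` (both in seconds, > 0)."""
    if latency_baseline <= 0 or latency_new <= 0:
        raise ValueError("latencies must be positive")
    return latency_baseline / latency_new
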