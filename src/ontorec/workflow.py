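"""End-to-end experiment orchestration: split → fit/score → fuse → rank → evaluate.

The algorithm vocabulary covers the CF learners alone (``ALS``, ``BPR``), the
content-based scorer alone (``ONTO_JC``, ``ONTO_LIN``, ``ONTO_RESNIK``), and
the twelve hybrids ``{ALS|BPR}_ONTO_{JC|LIN|RESNIK}_{m1|m2}``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd

from .cf import RatingsDataset, fit_als, fit_bpr, score_items_cf
from .evaluation import (
    EvalReport,
    FoldSpec,
    aggregate_users,
    binarize_relevance,
    fold_train_test,
    metrics_for_user,
    split_folds,
)
from .hybrid import combine_scores, minmax_normalize, rank_items
from .onto import ALL, score_items_onto
from .simstore import SimilarityStore

__all__ = [
    "ALGORITHMS",
    "AlgorithmSpec",
    "parse_algorithm",
    "RunConfig",
    "evaluate_run",
    "run_experiment",
]


@dataclass(frozen=True)
class AlgorithmSpec:
    name: str
    cf: str | None  # "ALS" | "BPR" | None
    measure: str | None  # "resnik" | "lin" | "jc" | None
    metric: str | None  # "m1" | "m2" | None (hybrids only)


def _vocabulary() -> dict[str, AlgorithmSpec]:
    vocab: dict[str, AlgorithmSpec] = {}
    for cf in ("ALS", "BPR"):
        vocab[cf] = AlgorithmSpec(cf, cf, None, None)
    for m in ("JC", "LIN", "RESNIK"):
        vocab[f"ONTO_{m}"] = AlgorithmSpec(f"ONTO_{m}", None, m.lower(), None)
    for cf in ("ALS", "BPR"):
        for m in ("JC", "LIN", "RESNIK"):
            for metric in ("m1", "m2"):
                name = f"{cf}_ONTO_{m}_{metric}"
                vocab[name] = AlgorithmSpec(name, cf, m.lower(), metric)
    return vocab


ALGORITHMS: dict[str, AlgorithmSpec] = _vocabulary()


def parse_algorithm(name: str) -> AlgorithmSpec:
    try:
        return ALGORITHMS[name]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {name!r}; valid names: {', '.join(sorted(ALGORITHMS))}"
        ) from None


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    algorithm: str = "ALS_ONTO_LIN_m2"
    # CF hyperparameters
    f: int = 150
    alpha: float = 40.0
    lam: float = 0.01
    als_iterations: int = 15
    lr: float = 0.01
    bpr_lam: float = 0.0001
    epochs: int = 100
    # CB
    n_most_similar: int | object = 5  # int or onto.ALL
    # evaluation
    q: int = 5
    k_max: int = 20
    seed: int = 0
    # policy flags
    strict_primary: bool = False
    bpr_shift: bool = False
    cb_only_fallback: bool = False
    cf_unseen_policy: str = "exclude"
    normalize: bool = False  # min-max both sides before fusion


def _fit_cf(spec: AlgorithmSpec, train: RatingsDataset, cfg: RunConfig):
    if spec.cf == "ALS":
        return fit_als(
            train,
            f=cfg.f,
            alpha=cfg.alpha,
            lam=cfg.lam,
            iterations=cfg.als_iterations,
            seed=cfg.seed,
        )
    if spec.cf == "BPR":
        return fit_bpr(
            train,
            f=cfg.f,
            lr=cfg.lr,
            lam=cfg.bpr_lam,
            epochs=cfg.epochs,
            seed=cfg.seed,
        )
    return None


def _rank_for_user(
    spec: AlgorithmSpec,
    cfg: RunConfig,
    model,
    store: SimilarityStore | None,
    user: str,
    train_items_user: list[str],
    candidates: list[str],
):
    """Ranked candidate list for one test user, or None if unscorable."""
    cf_scores = None
    if spec.cf is not None:
        cf_scores = score_items_cf(
            model,
            user,
            candidates,
            unseen_policy=cfg.cf_unseen_policy,
            bpr_shift=cfg.bpr_shift,
        )
    cb_scores = None
    if spec.measure is not None:
        if not train_items_user:
            return None  # no profile to score from
        onto = score_items_onto(
            store,
            train_items_user,
            candidates,
            measure=spec.measure,
            n=cfg.n_most_similar,
            user_id=user,
        )
        cb_scores = {it: s.score for it, s in onto.items()}

    if spec.metric is not None:
        if cfg.normalize:
            cf_scores = minmax_normalize(cf_scores)
            cb_scores = minmax_normalize(cb_scores)
        fused = combine_scores(
            cf_scores,
            cb_scores,
            spec.metric,
            user_id=user,
            cb_only_fallback=cfg.cb_only_fallback,
        )
        final = {it: h.combined for it, h in fused.items()}
    elif spec.cf is not None:
        final = cf_scores
    else:
        final = cb_scores
    if not final:
        return None
    return rank_items(final, user_id=user)


def evaluate_run(
    algorithm: str,
    data: RatingsDataset,
    store: SimilarityStore | None,
    config: RunConfig | None = None,
    folds: list[FoldSpec] | None = None,
    collect_recommendations: bool = False,
) -> tuple[EvalReport, pd.DataFrame | None]:
    """Cross-validated evaluation of one algorithm.

    Per fold: fit the CF model on the train ratings (if the algorithm has a
    CF side), score every test item for every test user, fuse, rank, and
    compute all metrics for k = 1..k_max; users with no relevant test item
    are excluded from the averages.  Returns the report and, optionally, the
    per-user recommendation lists as a long DataFrame.
    """
    cfg = config or RunConfig()
    cfg = replace(cfg, algorithm=algorithm)
    spec = parse_algorithm(algorithm)
    if spec.measure is not None and store is None:
        raise ValueError(f"{algorithm} needs a similarity store")
    if folds is None:
        folds = split_folds(data, q=cfg.q, seed=cfg.seed)

    report = EvalReport()
    rec_rows: list[dict] = []
    for fold in folds:
        train, test = fold_train_test(data, fold)
        model = _fit_cf(spec, train, cfg)
        candidates = sorted(fold.test_items)

        ranked_by_user: dict[str, object] = {}
        relevant_by_user: dict[str, set[str]] = {}
        for user in sorted(fold.test_users):
            user_test = test[test["user"] == user]
            relevant = binarize_relevance(user_test)
            if not relevant:
                continue  # denominator-safe exclusion, logged by callers
            if spec.cf is not None and user not in train.user_index:
                continue  # cold-start user under a CF-bearing algorithm
            train_items_user = (
                train.items_of_user(user) if user in train.user_index else []
            )
            ranked = _rank_for_user(
                spec, cfg, model, store, user, train_items_user, candidates
            )
            if ranked is None or len(ranked) == 0:
                continue
            ranked_by_user[user] = ranked
            relevant_by_user[user] = relevant
            if collect_recommendations:
                for rank, (item, score) in enumerate(ranked.ranking, start=1):
                    rec_rows.append(
                        {
                            "user": user,
                            "fold": fold.fold_index,
                            "rank": rank,
                            "item": item,
                            "combined": score,
                            "algorithm": algorithm,
                        }
                    )

        if not ranked_by_user:
            continue
        for k in range(1, cfg.k_max + 1):
            per_user = [
                metrics_for_user(ranked_by_user[u], relevant_by_user[u], k)
                for u in ranked_by_user
            ]
            report.add(algorithm, fold.fold_index, k, aggregate_users(per_user))

    recs = pd.DataFrame(rec_rows) if collect_recommendations else None
    return report, recs


def run_experiment(
    config: RunConfig,
    data: RatingsDataset,
    store: SimilarityStore | None,
    outdir: str | Path,
    ratings_path: str | Path | None = None,
) -> EvalReport:
    """Run one algorithm end to end and persist report, recommendations, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report, recs = evaluate_run(
        config.algorithm, data, store, config, collect_recommendations=True
    )
    report.rows.to_csv(outdir / f"report_{config.algorithm}.csv", index=False)
    report.to_long_csv(outdir / f"report_long_{config.algorithm}.csv")
    report.summary().to_csv(
        outdir / f"summary_{config.algorithm}.csv", index=False
    )
    if recs is not None:
        recs.to_csv(outdir / f"recommendations_{config.algorithm}.csv", index=False)

    manifest = {
        "config": {
            k: (str(v) if not isinstance(v, (int, float, bool, str)) else v)
            for k, v in asdict(config).items()
        },
        "n_users": data.n_users,
        "n_items": data.n_items,
        "n_ratings": int(data.matrix.nnz),
        "ratings_sha256": _sha256_file(ratings_path) if ratings_path else None,
    }
    (outdir / f"manifest_{config.algorithm}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return report


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
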