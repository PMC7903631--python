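"""Implicit-feedback collaborative filtering: confidence-weighted ALS and BPR.

The ratings here are implicit counts (e.g. how many articles an author wrote
about a compound): there are no negative examples, only observed positives.
Two standard latent-factor learners handle this:

* **ALS** (Hu, Koren & Volinsky): every user–item cell gets a binary
  preference ``p_ui = 1[r_ui > 0]`` and a confidence ``c_ui = 1 + alpha·r_ui``;
  user and item factor matrices are updated alternately by closed-form ridge
  solves minimizing ``Σ_ui c_ui (p_ui − x_uᵀ y_i)² + λ(‖X‖² + ‖Y‖²)``.

* **BPR** (Rendle et al.): stochastic gradient ascent on sampled triplets
  (user, observed item, unobserved item), maximizing
  ``Σ ln σ(x̂_ui − x̂_uj) − λ‖Θ‖²`` so observed items outrank unobserved ones.

Both are deterministic given their seed (randomness enters only through
initialization and, for BPR, triplet sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "RatingsDataset",
    "FactorModel",
    "ColdStartError",
    "fit_als",
    "als_objective",
    "fit_bpr",
    "bpr_update",
    "score_items_cf",
]


class ColdStartError(KeyError):
    """A user or item absent from training cannot be scored by CF."""


@dataclass
class RatingsDataset:
    """Sparse user×item implicit ratings with index maps.

    Built from (user, item, rating) triples; ratings must be positive counts
    and each (user, item) pair must appear at most once.
    """

    triples: pd.DataFrame  # columns: user, item, rating
    users: list[str]
    items: list[str]
    user_index: dict[str, int]
    item_index: dict[str, int]
    matrix: sp.csr_matrix  # n_users x n_items, counts

    @classmethod
    def from_triples(cls, triples: pd.DataFrame) -> "RatingsDataset":
        required = {"user", "item", "rating"}
        if not required.issubset(triples.columns):
            raise ValueError(f"ratings table needs columns {sorted(required)}")
        triples = triples.copy()
        triples["user"] = triples["user"].astype(str)
        triples["item"] = triples["item"].astype(str)
        if (triples["rating"] <= 0).any():
            raise ValueError("implicit ratings must be positive counts")
        if triples.duplicated(["user", "item"]).any():
            dup = triples[triples.duplicated(["user", "item"])].iloc[0]
            raise ValueError(
                f"duplicate (user, item) pair: ({dup['user']}, {dup['item']})"
            )
        users = sorted(triples["user"].unique())
        items = sorted(triples["item"].unique())
        uix = {u: i for i, u in enumerate(users)}
        iix = {t: i for i, t in enumerate(items)}
        mat = sp.csr_matrix(
            (
                triples["rating"].to_numpy(dtype=np.float64),
                (
                    triples["user"].map(uix).to_numpy(),
                    triples["item"].map(iix).to_numpy(),
                ),
            ),
            shape=(len(users), len(items)),
        )
        return cls(triples, users, items, uix, iix, mat)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingsDataset":
        return cls.from_triples(pd.read_csv(path, dtype={"user": str, "item": str}))

    def to_csv(self, path: str | Path) -> None:
        self.triples.to_csv(path, index=False)

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def items_of_user(self, user: str) -> list[str]:
        """Items the user has rated, in item-id order."""
        if user not in self.user_index:
            raise ColdStartError(f"unknown user: {user!r}")
        row = self.matrix.getrow(self.user_index[user])
        return [self.items[j] for j in sorted(row.indices)]

    def subset(self, mask: pd.Series) -> "RatingsDataset":
        return RatingsDataset.from_triples(self.triples[mask])


@dataclass
class FactorModel:
    algorithm: str  # "ALS" | "BPR"
    user_factors: np.ndarray  # n_users x f
    item_factors: np.ndarray  # n_items x f
    user_index: dict[str, int]
    item_index: dict[str, int]
    hyperparameters: dict = field(default_factory=dict)
    # items observed at least once in training (columns with a nonzero)
    observed_items: frozenset[str] = frozenset()

    @property
    def f(self) -> int:
        return self.user_factors.shape[1]


def _init_factors(rng: np.random.Generator, n: int, f: int) -> np.ndarray:
    # uniform(0, 1/sqrt(f)) keeps initial dot products O(1)
    return rng.uniform(0.0, 1.0 / np.sqrt(f), size=(n, f))


def als_update_row(
    B: np.ndarray,
    idx: np.ndarray,
    counts: np.ndarray,
    alpha: float,
    lam: float,
    BtB: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form ridge solve for one user (or item) factor row.

    Solves ``(BᵀB + Bᵀ(C−I)B + λI) x = Bᵀ C p`` where ``idx`` are the row's
    observed columns, ``counts`` the raw ratings there, ``c = 1 + alpha·r``
    and ``p = 1`` on observed columns.  A row with no observations is driven
    to the zero vector by the regularizer.
    """
    f = B.shape[1]
    if BtB is None:
        BtB = B.T @ B
    if len(idx) == 0:
        return np.zeros(f)
    conf = 1.0 + alpha * np.asarray(counts, dtype=float)
    Bu = B[idx]
    G = BtB + Bu.T @ ((conf - 1.0)[:, None] * Bu) + lam * np.eye(f)
    rhs = Bu.T @ conf
    return np.linalg.solve(G, rhs)


def fit_als(
    data: RatingsDataset,
    f: int = 150,
    alpha: float = 40.0,
    lam: float = 0.01,
    iterations: int = 15,
    seed: int = 0,
) -> FactorModel:
    """Confidence-weighted implicit ALS.

    Each sweep solves the normal equations
    ``x_u = (YᵀY + Yᵀ(C_u − I)Y + λI)⁻¹ Yᵀ C_u p_u`` for every user and the
    symmetric system for every item.  The ``Yᵀ(C_u − I)Y`` correction touches
    only the user's observed items, so a sweep is linear in the number of
    ratings.
    """
    if f < 1:
        raise ValueError("f must be >= 1")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if data.n_users == 0 or data.matrix.nnz == 0:
        raise ValueError("empty ratings dataset")

    rng = np.random.default_rng(seed)
    X = _init_factors(rng, data.n_users, f)
    Y = _init_factors(rng, data.n_items, f)
    R = data.matrix
    Rt = R.T.tocsr()

    def sweep_side(A: np.ndarray, B: np.ndarray, M: sp.csr_matrix) -> None:
        # update each row of A given fixed B; M rows are the observed counts
        BtB = B.T @ B
        for u in range(A.shape[0]):
            start, end = M.indptr[u], M.indptr[u + 1]
            A[u] = als_update_row(
                B, M.indices[start:end], M.data[start:end], alpha, lam, BtB
            )
            if not np.all(np.isfinite(A[u])):
                raise FloatingPointError(
                    f"non-finite factors in ALS update (row {u})"
                )

    for _ in range(iterations):
        sweep_side(X, Y, R)
        sweep_side(Y, X, Rt)

    observed = frozenset(
        data.items[j] for j in np.unique(R.indices)
    )
    return FactorModel(
        "ALS",
        X,
        Y,
        dict(data.user_index),
        dict(data.item_index),
        {"f": f, "alpha": alpha, "lambda": lam, "iterations": iterations, "seed": seed},
        observed,
    )


def als_objective(
    model: FactorModel, data: RatingsDataset, alpha: float, lam: float
) -> float:
    """Exact confidence-weighted least-squares objective (dense; diagnostic).

    ``Σ_ui c_ui (p_ui − x_uᵀ y_i)² + λ(‖X‖² + ‖Y‖²)`` over *all* user–item
    cells, with c=1, p=0 on unobserved cells.  Intended for the small problem
    sizes used in validation, not production-scale data.
    """
    X, Y = model.user_factors, model.item_factors
    S = X @ Y.T
    R = data.matrix.toarray()
    P = (R > 0).astype(float)
    C = 1.0 + alpha * R
    loss = float(np.sum(C * (P - S) ** 2))
    return loss + lam * (float(np.sum(X**2)) + float(np.sum(Y**2)))


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def bpr_update(
    w_u: np.ndarray,
    h_i: np.ndarray,
    h_j: np.ndarray,
    lr: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One BPR SGD step on a (user, positive, negative) triplet.

    Returns updated copies of the user factor and the two item factors; the
    gradient of ``ln σ(x̂_uij)`` with L2 shrinkage, ``x̂_uij = w·(h_i − h_j)``.
    """
    x_uij = float(w_u @ (h_i - h_j))
    g = _sigmoid(-x_uij)
    w_new = w_u + lr * (g * (h_i - h_j) - lam * w_u)
    hi_new = h_i + lr * (g * w_u - lam * h_i)
    hj_new = h_j + lr * (-g * w_u - lam * h_j)
    return w_new, hi_new, hj_new


def fit_bpr(
    data: RatingsDataset,
    f: int = 150,
    lr: float = 0.01,
    lam: float = 0.0001,
    epochs: int = 100,
    seed: int = 0,
) -> FactorModel:
    """Bayesian Personalized Ranking via seeded SGD on uniform triplets.

    One epoch draws as many triplets as there are observed ratings: a random
    observed (u, i⁺) and a uniform unobserved j⁻ for that user (rejection
    sampling).  Users whose positives cover the whole item universe cannot
    supply a negative and are excluded from sampling with a warning.
    """
    import warnings

    if f < 1:
        raise ValueError("f must be >= 1")
    if data.n_users == 0 or data.matrix.nnz == 0:
        raise ValueError("empty ratings dataset")

    rng = np.random.default_rng(seed)
    W = _init_factors(rng, data.n_users, f)
    H = _init_factors(rng, data.n_items, f)
    R = data.matrix
    n_items = data.n_items

    pos_items = [R.indices[R.indptr[u] : R.indptr[u + 1]] for u in range(data.n_users)]
    pos_sets = [set(p) for p in pos_items]
    full = [u for u, s in enumerate(pos_sets) if len(s) == n_items]
    if full:
        warnings.warn(
            f"{len(full)} user(s) rated every item; excluded from BPR sampling",
            stacklevel=2,
        )
    eligible = np.array(
        [u for u, s in enumerate(pos_sets) if 0 < len(s) < n_items]
    )
    if len(eligible) == 0:
        raise ValueError("no user has both a positive and a negative item")
    # sample (u, i+) proportionally to the user's rating count, matching a
    # uniform draw over observed cells
    weights = np.array([len(pos_sets[u]) for u in eligible], dtype=float)
    weights /= weights.sum()

    n_samples = R.nnz
    for _ in range(epochs):
        us = rng.choice(eligible, size=n_samples, p=weights)
        for u in us:
            i = int(rng.choice(pos_items[u]))
            j = int(rng.integers(n_items))
            while j in pos_sets[u]:
                j = int(rng.integers(n_items))
            W[u], H[i], H[j] = bpr_update(W[u], H[i], H[j], lr, lam)

    observed = frozenset(data.items[j] for j in np.unique(R.indices))
    return FactorModel(
        "BPR",
        W,
        H,
        dict(data.user_index),
        dict(data.item_index),
        {"f": f, "lr": lr, "lambda": lam, "epochs": epochs, "seed": seed},
        observed,
    )


def score_items_cf(
    model: FactorModel,
    user: str,
    candidates: list[str],
    unseen_policy: str = "exclude",
    bpr_shift: bool = False,
) -> dict[str, float]:
    """Dot-product CF scores for a user over candidate items.

    Items never observed in training are dropped (``unseen_policy='exclude'``,
    the CF cold-start limitation) or scored 0 (``'zero'``, which keeps them
    rankable once a content-based score is added).  ``bpr_shift`` adds 1 to
    every BPR score, mirroring implementations that offset ranking scores.
    """
    if user not in model.user_index:
        raise ColdStartError(f"user {user!r} not in the trained model")
    if unseen_policy not in ("exclude", "zero"):
        raise ValueError("unseen_policy must be 'exclude' or 'zero'")
    xu = model.user_factors[model.user_index[user]]
    shift = 1.0 if (bpr_shift and model.algorithm == "BPR") else 0.0
    out: dict[str, float] = {}
    for item in candidates:
        known = item in model.item_index and item in model.observed_items
        if not known:
            if unseen_policy == "exclude":
                continue
            out[item] = 0.0 + shift
            continue
        out[item] = float(xu @ model.item_factors[model.item_index[item]]) + shift
    return out
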