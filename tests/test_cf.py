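"""ALS and BPR contracts: closed-form updates, objective descent, determinism."""

import numpy as np
import pandas as pd
import pytest

from ontorec import (
    ColdStartError,
    RatingsDataset,
    als_objective,
    als_update_row,
    bpr_update,
    fit_als,
    fit_bpr,
    score_items_cf,
)
from ontorec.synthetic import SynthConfig, gen_ontology, gen_rank1_preferences, gen_ratings


def _dataset(rows):
    return RatingsDataset.from_triples(
        pd.DataFrame(rows, columns=["user", "item", "rating"])
    )


class TestRatingsDataset:
    def test_nonpositive_rating_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _dataset([("u", "i", 0)])

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _dataset([("u", "i", 1), ("u", "i", 2)])

    def test_matrix_shape_and_lookup(self):
        d = _dataset([("u1", "a", 2), ("u1", "b", 1), ("u2", "a", 3)])
        assert d.matrix.shape == (2, 2)
        assert d.items_of_user("u1") == ["a", "b"]
        with pytest.raises(ColdStartError):
            d.items_of_user("nobody")


class TestALS:
    def test_scalar_update_matches_closed_form(self):
        # one user, one item, r=1, f=1, item factor held at 1:
        # x = (1 + 40 + 0.1)^-1 * 41 = 41/41.1
        x = als_update_row(
            B=np.array([[1.0]]), idx=np.array([0]), counts=np.array([1.0]),
            alpha=40.0, lam=0.1,
        )
        assert x[0] == pytest.approx(41.0 / 41.1, abs=1e-12)

    def test_row_without_observations_goes_to_zero(self):
        x = als_update_row(
            B=np.arange(6.0).reshape(3, 2), idx=np.array([], dtype=int),
            counts=np.array([]), alpha=40.0, lam=0.1,
        )
        assert np.all(x == 0.0)

    def test_objective_nonincreasing_over_sweeps(self):
        rng = np.random.default_rng(42)
        rows = [
            (f"u{u}", f"i{i}", int(rng.integers(1, 5)))
            for u in range(20)
            for i in rng.choice(30, size=8, replace=False)
        ]
        data = _dataset(rows)
        objs = []
        for it in range(1, 16):
            m = fit_als(data, f=6, alpha=10.0, lam=0.1, iterations=it, seed=1)
            objs.append(als_objective(m, data, alpha=10.0, lam=0.1))
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_determinism(self):
        data = _dataset([("u1", "a", 2), ("u1", "b", 1), ("u2", "b", 3)])
        m1 = fit_als(data, f=4, iterations=3, seed=5)
        m2 = fit_als(data, f=4, iterations=3, seed=5)
        assert np.array_equal(m1.user_factors, m2.user_factors)
        assert np.array_equal(m1.item_factors, m2.item_factors)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_als(_dataset([("u", "i", 1)]).subset(pd.Series([False])), f=2)

    def test_rank1_structure_recovers_item_ordering(self):
        # noiseless rank-1 counts r_ui = a_u * b_i, fully observed: the
        # fitted scores must order items identically to the generating b
        a = [1, 2, 3]
        b = [5, 4, 3, 2, 1]
        rows = [
            (f"u{u}", f"i{i}", a[u] * b[i])
            for u in range(3)
            for i in range(5)
        ]
        data = _dataset(rows)
        m = fit_als(data, f=2, alpha=1.0, lam=0.01, iterations=20, seed=0)
        for u in range(3):
            scores = score_items_cf(m, f"u{u}", [f"i{i}" for i in range(5)])
            order = sorted(scores, key=scores.get, reverse=True)
            assert order == [f"i{i}" for i in range(5)]


class TestBPR:
    def test_single_step_matches_hand_gradient(self):
        # x̂ = 1, σ(−1) = 0.26894...; w ← 1 + 0.1·σ(−1)·(1−0)
        w, hi, hj = bpr_update(
            np.array([1.0]), np.array([1.0]), np.array([0.0]), lr=0.1, lam=0.0
        )
        sig = 1.0 / (1.0 + np.exp(1.0))
        assert w[0] == pytest.approx(1.0 + 0.1 * sig, abs=1e-12)
        assert hi[0] == pytest.approx(1.0 + 0.1 * sig, abs=1e-12)
        assert hj[0] == pytest.approx(-0.1 * sig, abs=1e-12)

    def test_zero_learning_rate_is_identity(self):
        data = _dataset([("u1", "a", 1), ("u1", "b", 2), ("u2", "a", 1), ("u2", "c", 1)])
        m0 = fit_bpr(data, f=3, lr=0.0, epochs=5, seed=9)
        m1 = fit_bpr(data, f=3, lr=0.0, epochs=0, seed=9)
        assert np.array_equal(m0.item_factors, m1.item_factors)
        assert np.array_equal(m0.user_factors, m1.user_factors)

    def test_determinism(self):
        data = _dataset([("u1", "a", 1), ("u1", "b", 2), ("u2", "a", 1), ("u2", "c", 1)])
        m1 = fit_bpr(data, f=3, epochs=4, seed=11)
        m2 = fit_bpr(data, f=3, epochs=4, seed=11)
        assert np.array_equal(m1.user_factors, m2.user_factors)
        assert np.array_equal(m1.item_factors, m2.item_factors)

    def test_user_with_all_items_positive_excluded(self):
        data = _dataset([("full", "a", 1), ("full", "b", 1), ("u2", "a", 1)])
        with pytest.warns(UserWarning, match="every item"):
            fit_bpr(data, f=2, epochs=1, seed=0)

    @staticmethod
    def holdout_auc(seed: int, f: int = 8, epochs: int = 50) -> float:
        """Held-out pairwise AUC on rank-1 preference data, by exhaustive

        enumeration of (held-out positive, never-seen negative) pairs."""
        data, _ = gen_rank1_preferences(n_users=25, n_items=35, n_pos=12, seed=seed)
        rng = np.random.default_rng(seed + 1000)
        test_rows = []
        train_parts = []
        for user, grp in data.triples.groupby("user"):
            idx = rng.permutation(len(grp))
            n_test = max(1, len(grp) // 5)
            test_rows.append(grp.iloc[idx[:n_test]])
            train_parts.append(grp.iloc[idx[n_test:]])
        train = RatingsDataset.from_triples(pd.concat(train_parts))
        test = pd.concat(test_rows)
        model = fit_bpr(train, f=f, epochs=epochs, seed=seed)

        wins = total = 0
        all_items = data.items
        for user, grp in test.groupby("user"):
            if user not in model.user_index:
                continue
            pos_train = set(train.items_of_user(user))
            pos_test = set(grp["item"])
            negatives = [
                i for i in all_items
                if i not in pos_train and i not in pos_test and i in model.item_index
            ]
            scores = score_items_cf(model, user, all_items, unseen_policy="zero")
            for p in pos_test:
                for n in negatives:
                    total += 1
                    if scores.get(p, 0.0) > scores.get(n, 0.0):
                        wins += 1
        return wins / total

    def test_holdout_auc_on_rank1_preferences(self):
        assert self.holdout_auc(seed=7) > 0.8

    def test_training_auc_improves_start_to_end(self):
        data, _ = gen_rank1_preferences(n_users=20, n_items=30, n_pos=10, seed=3)

        def train_auc(model):
            wins = total = 0
            for user in data.users:
                pos = set(data.items_of_user(user))
                scores = score_items_cf(model, user, data.items, unseen_policy="zero")
                for p in pos:
                    for n in data.items:
                        if n in pos:
                            continue
                        total += 1
                        wins += scores[p] > scores[n]
            return wins / total

        m_start = fit_bpr(data, f=6, epochs=0, seed=2)
        m_end = fit_bpr(data, f=6, epochs=30, seed=2)
        assert train_auc(m_end) > train_auc(m_start)


class TestScoreItemsCF:
    def _model(self, algorithm="ALS"):
        from ontorec import FactorModel

        return FactorModel(
            algorithm=algorithm,
            user_factors=np.array([[1.0, 0.0]]),
            item_factors=np.array([[0.5, 2.0]]),
            user_index={"u": 0},
            item_index={"i": 0},
            observed_items=frozenset({"i"}),
        )

    def test_dot_product(self):
        assert score_items_cf(self._model(), "u", ["i"]) == {"i": 0.5}

    def test_bpr_shift_adds_one(self):
        m = self._model("BPR")
        assert score_items_cf(m, "u", ["i"], bpr_shift=True) == {"i": 1.5}

    def test_shift_ignored_for_als(self):
        assert score_items_cf(self._model("ALS"), "u", ["i"], bpr_shift=True) == {
            "i": 0.5
        }

    def test_unseen_item_excluded_by_default(self):
        out = score_items_cf(self._model(), "u", ["i", "new"])
        assert "new" not in out

    def test_unseen_item_zero_policy(self):
        out = score_items_cf(self._model(), "u", ["i", "new"], unseen_policy="zero")
        assert out["new"] == 0.0

    def test_unknown_user_is_cold_start(self):
        with pytest.raises(ColdStartError):
            score_items_cf(self._model(), "stranger", ["i"])
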