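"""Split/balance arithmetic, Boruta, LASSO, clustering, VIF."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from t1tex.selection import (
    boruta_select,
    hierarchical_decorrelate,
    lasso_select,
    select_features,
    split_and_balance,
    vif_check,
)


class TestSplitAndBalance:
    def test_printed_cohort_arithmetic(self):
        # 23 LGE+ / 19 LGE- at 67/33: train 15+/12- -> 24 balanced,
        # test 8+/7- -> 14 balanced
        labels = pd.Series([1] * 23 + [0] * 19, index=[f"c{i}" for i in range(42)])
        train, test = split_and_balance(labels, 0.67, seed=0)
        assert len(train) == 24 and len(test) == 14
        assert labels[train].sum() == 12 and labels[test].sum() == 7

    def test_balanced_input_loses_nothing(self):
        labels = pd.Series([0, 0, 0, 1, 1, 1] * 5, index=[f"c{i}" for i in range(30)])
        train, test = split_and_balance(labels, 0.67, seed=1)
        assert len(train) + len(test) == 30

    def test_same_seed_same_split(self):
        labels = pd.Series([1] * 23 + [0] * 19, index=[f"c{i}" for i in range(42)])
        assert split_and_balance(labels, seed=5) == split_and_balance(labels, seed=5)

    def test_single_class_rejected(self):
        labels = pd.Series([1] * 10, index=[f"c{i}" for i in range(10)])
        with pytest.raises(ValueError):
            split_and_balance(labels)


class TestBoruta:
    def test_informative_feature_confirmed_noise_rejected(self):
        # n large enough that chance noise-label correlations (~1/sqrt(n))
        # stay below what can consistently beat the shadow maximum; Boruta is
        # an in-sample all-relevant selector, so at small n a freak-correlated
        # noise column is legitimately "relevant"
        rng = np.random.default_rng(1)
        n = 300
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            rng.standard_normal((n, 10)), columns=[f"noise_{i}" for i in range(9)] + ["signal"]
        )
        X["signal"] = y + rng.normal(scale=0.05, size=n)
        res = boruta_select(X, y, seed=2, max_iter=40, n_estimators=200)
        assert "signal" in res.confirmed
        assert not any(f.startswith("noise") for f in res.confirmed)

    def test_all_noise_rarely_confirms(self):
        rng = np.random.default_rng(3)
        confirmed_runs = 0
        for rep in range(6):
            y = np.repeat([0, 1], 30)
            X = pd.DataFrame(
                rng.standard_normal((60, 8)), columns=[f"n{i}" for i in range(8)]
            )
            res = boruta_select(X, y, seed=rep, max_iter=25, n_estimators=150)
            confirmed_runs += bool(res.confirmed)
        assert confirmed_runs <= 1

    def test_duplicated_informative_feature_both_confirmed(self):
        # all-relevant selection keeps redundant copies
        rng = np.random.default_rng(4)
        n = 120
        y = np.repeat([0, 1], n // 2)
        sig = y * 2.0 + rng.normal(scale=0.3, size=n)
        X = pd.DataFrame(
            {
                "a_sig": sig,
                "b_sig_copy": sig + rng.normal(scale=0.01, size=n),
                **{f"noise_{i}": rng.standard_normal(n) for i in range(5)},
            }
        )
        res = boruta_select(X, y, seed=0, max_iter=40, n_estimators=200)
        assert {"a_sig", "b_sig_copy"} <= set(res.confirmed)

    def test_nonfinite_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            boruta_select(X, np.array([0, 1, 0]))


class TestLasso:
    def test_informative_among_noise_selected(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            rng.standard_normal((n, 8)), columns=[f"noise_{i}" for i in range(7)] + ["signal"]
        )
        X["signal"] = y * 1.5 + rng.normal(scale=0.8, size=n)
        selected, lam = lasso_select(X, y, seed=1)
        assert "signal" in selected
        assert lam > 0

    def test_duplicated_columns_keep_selection_nonempty(self):
        rng = np.random.default_rng(6)
        n = 150
        y = np.repeat([0, 1], n // 2)
        sig = y * 2.0 + rng.normal(scale=0.5, size=n)
        X = pd.DataFrame({"s1": sig, "s2": sig.copy()})
        selected, _ = lasso_select(X, y, seed=0)
        assert selected  # at least one of the twins survives

    def test_huge_penalty_empties_selection(self):
        # mimic the lambda -> infinity limit by overwhelming noise-only data
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({"a": rng.standard_normal(40) * 1e-8})
        selected, lam = lasso_select(X, y, seed=0)
        assert selected == []


class TestClustering:
    def test_exact_copy_collapses_to_one(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "a_copy": a.copy()})
        clusters, reps = hierarchical_decorrelate(X, ["a", "a_copy"])
        assert len(set(clusters.values())) == 1
        assert len(reps) == 1

    def test_orthogonal_features_stay_separate(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        clusters, reps = hierarchical_decorrelate(X, list("abcd"))
        assert len(reps) == 4

    def test_matches_brute_force_agglomeration(self):
        # fixed toy correlation structure: two tight pairs + two singletons
        rng = np.random.default_rng(10)
        n = 300
        u, v = rng.standard_normal(n), rng.standard_normal(n)
        X = pd.DataFrame(
            {
                "u1": u,
                "u2": u + rng.normal(scale=0.1, size=n),
                "v1": v,
                "v2": -v + rng.normal(scale=0.1, size=n),  # sign flip: |rho| used
                "w": rng.standard_normal(n),
                "z": rng.standard_normal(n),
            }
        )
        clusters, reps = hierarchical_decorrelate(X, list(X.columns), 0.75)
        assert clusters["u1"] == clusters["u2"]
        assert clusters["v1"] == clusters["v2"]
        assert len({clusters["u1"], clusters["v1"], clusters["w"], clusters["z"]}) == 4
        assert len(reps) == 4

    def test_fewer_than_two_passthrough(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        clusters, reps = hierarchical_decorrelate(X, ["a"])
        assert reps == ["a"]


class TestVif:
    def test_orthogonal_features_unit_vif(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        vifs = vif_check(X, list("abc"))
        for v in vifs.values():
            assert v == pytest.approx(1.0, abs=0.1)

    def test_near_duplicate_blows_up(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(100)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(scale=0.01, size=100)})
        vifs = vif_check(X, ["a", "b"])
        assert vifs["a"] > 5 and vifs["b"] > 5

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        X["c"] = 0.7 * X["a"] + rng.normal(scale=0.5, size=80)
        vifs = vif_check(X, list("abc"))
        # direct oracle via lstsq R^2 on standardized data
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        for j, name in enumerate("abc"):
            others = np.delete(Z, j, axis=1)
            A = np.column_stack([np.ones(80), others])
            coef, *_ = np.linalg.lstsq(A, Z[:, j], rcond=None)
            r2 = 1 - ((Z[:, j] - A @ coef) ** 2).sum() / ((Z[:, j] - Z[:, j].mean()) ** 2).sum()
            assert vifs[name] == pytest.approx(1 / (1 - r2), rel=1e-6)


class TestFullCascade:
    def test_recovers_planted_signal(self, feature_frame):
        X, labels = feature_frame
        hits = 0
        reps = 5
        for rep in range(reps):
            res = select_features(
                X,
                labels,
                seed=rep,
                boruta_kwargs={"max_iter": 30, "n_estimators": 150},
            )
            assert set(res.independent) <= set(res.union)
            corr = [
                abs(spearmanr(X.loc[res.train_ids, f], X.loc[res.train_ids, "signal"]).statistic)
                for f in res.independent
            ]
            hits += bool(corr and max(corr) >= 0.7)
            for v in res.vif.values():
                assert v < 5
        assert hits >= 0.8 * reps

    def test_deterministic_given_seed(self, feature_frame):
        X, labels = feature_frame
        kw = {"max_iter": 15, "n_estimators": 100}
        a = select_features(X, labels, seed=3, boruta_kwargs=kw)
        b = select_features(X, labels, seed=3, boruta_kwargs=kw)
        assert a == b
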