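"""Descriptor filtering, Spearman screen, ridge CV, permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiopop.structure_activity import (
    bh_qvalues,
    holm_adjust,
    permutation_significance,
    ridge_cv_predict,
    spearman_screen,
    variation_filter,
)


class TestVariationFilter:
    def test_single_differing_sample_removed(self):
        X = pd.DataFrame({"a": [0] * 9 + [1], "b": range(10)})
        out = variation_filter(X)
        assert "a" not in out.columns and "b" in out.columns

    def test_exactly_two_differing_retained(self):
        X = pd.DataFrame({"a": [0] * 8 + [1, 1], "b": range(10)})
        assert "a" in variation_filter(X).columns

    def test_constant_column_removed(self):
        X = pd.DataFrame({"a": [5.0] * 10, "b": range(10)})
        assert "a" not in variation_filter(X).columns

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.poisson(0.3, size=(20, 15)))
        X.columns = [f"c{i}" for i in range(15)]
        once = variation_filter(X)
        pd.testing.assert_frame_equal(once, variation_filter(once))

    def test_too_few_chemicals_rejected(self):
        with pytest.raises(ValueError):
            variation_filter(pd.DataFrame({"a": [1, 2]}))


class TestSpearmanScreen:
    def test_known_rho_with_one_swap(self):
        # d = (0,0,0,1,1) -> rho = 1 - 6*2/(5*24) = 0.9
        X = pd.DataFrame({"d": [1, 2, 3, 4, 5]}, index=list("abcde"))
        Y = pd.DataFrame({"y": [1, 2, 3, 5, 4]}, index=list("abcde"))
        out = spearman_screen(X, Y)
        assert out["spearman_rho"].iloc[0] == pytest.approx(0.9)

    def test_perfect_anticorrelation(self):
        X = pd.DataFrame({"d": [1, 2, 3, 4, 5]}, index=list("abcde"))
        Y = pd.DataFrame({"y": [5, 4, 3, 2, 1]}, index=list("abcde"))
        out = spearman_screen(X, Y)
        assert out["spearman_rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_scipy_on_random_matrices(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 10)),
                         index=[f"c{i}" for i in range(20)])
        Y = pd.DataFrame(rng.normal(size=(20, 4)),
                         index=[f"c{i}" for i in range(20)])
        out = spearman_screen(X, Y).set_index(["descriptor", "variable"])
        for d in X.columns:
            for v in Y.columns:
                rho, p = stats.spearmanr(X[d], Y[v])
                row = out.loc[(d, v)]
                assert row["spearman_rho"] == pytest.approx(rho, abs=1e-12)
                assert row["p"] == pytest.approx(p, abs=1e-9)

    def test_zero_variance_descriptor_excluded(self, rng):
        X = pd.DataFrame(
            {"flat": [1.0] * 10, "ok": rng.normal(size=10)},
            index=[f"c{i}" for i in range(10)],
        )
        Y = pd.DataFrame({"y": rng.normal(size=10)}, index=X.index)
        out = spearman_screen(X, Y)
        assert set(out["descriptor"]) == {"ok"}
        assert out.attrs["n_excluded_pairs"] == 1


class TestMultipleTesting:
    def test_bh_stepup_bruteforce_example(self):
        # p=(0.01,0.02,0.03,0.04), m=4: q_i = min over j>=i of p_j * m/j
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_holm_stepdown_bruteforce_example(self):
        p_adj = holm_adjust([0.01, 0.04])
        assert np.allclose(p_adj, [0.02, 0.04])

    def test_both_match_bruteforce_on_random_pvalues(self, rng):
        p = rng.uniform(size=25)
        m = p.size
        order = np.argsort(p)
        # brute-force BH step-up
        q_bf = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q_bf[i] = running
        assert np.allclose(bh_qvalues(p), q_bf)
        # brute-force Holm step-down
        h_bf = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order, start=1):
            running = max(running, min(1.0, (m - rank + 1) * p[i]))
            h_bf[i] = running
        assert np.allclose(holm_adjust(p), h_bf)


def _planted(n=56, p=123, snr=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    signal = X @ beta
    noise = rng.normal(size=n) * signal.std() / snr
    return X, signal + noise


class TestRidgeCvPredict:
    def test_planted_signal_recovered(self):
        X, y = _planted(seed=1)
        res = ridge_cv_predict(X, y, seed=0)
        assert res["cv_r"] > 0.5

    def test_null_signal_r_near_zero(self):
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(56, 123))
            y = rng.normal(size=56)
            rs.append(abs(ridge_cv_predict(X, y)["cv_r"]))
        assert np.mean(rs) < 0.2

    def test_constant_phenotype_flagged(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        res = ridge_cv_predict(X, np.ones(10))
        assert res["degenerate"]

    def test_matches_sklearn_ridge_at_fixed_penalty(self):
        # same LOO predictions as sklearn when the penalty grid has one point
        from sklearn.linear_model import Ridge
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15) + X[:, 0]
        lam = 1.7
        res = ridge_cv_predict(X, y, lambda_grid=[lam])
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            sc = StandardScaler().fit(X[tr])
            model = Ridge(alpha=lam).fit(sc.transform(X[tr]), y[tr])
            want = model.predict(sc.transform(X[[i]]))[0]
            assert res["predictions"][i] == pytest.approx(want, rel=1e-8)

    def test_kfold_assignment_seeded(self):
        X, y = _planted(n=30, p=10)
        a = ridge_cv_predict(X, y, n_folds=5, seed=4)
        b = ridge_cv_predict(X, y, n_folds=5, seed=4)
        np.testing.assert_array_equal(a["predictions"], b["predictions"])


class TestPermutationSignificance:
    def test_strong_signal_hits_p_floor(self):
        X, y = _planted(n=40, p=20, snr=5.0)
        idx = [f"c{i}" for i in range(40)]
        res = permutation_significance(
            pd.DataFrame(X, index=idx),
            pd.DataFrame({"y": y}, index=idx),
            n_perm=199, seed=0,
        )
        assert res["empirical_p"].iloc[0] == pytest.approx(1 / 200)

    def test_empirical_p_has_formula_floor(self):
        X, y = _planted(n=25, p=8, snr=10.0)
        idx = [f"c{i}" for i in range(25)]
        res = permutation_significance(
            pd.DataFrame(X, index=idx), pd.DataFrame({"y": y}, index=idx),
            n_perm=999, seed=1,
        )
        assert res["empirical_p"].iloc[0] >= 1 / 1000

    def test_small_n_perm_warns(self):
        X, y = _planted(n=20, p=5)
        idx = [f"c{i}" for i in range(20)]
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_significance(
                pd.DataFrame(X, index=idx),
                pd.DataFrame({"y": y}, index=idx), n_perm=50, seed=0,
            )

    def test_adjusted_columns_bounded(self):
        rng = np.random.default_rng(2)
        idx = [f"c{i}" for i in range(20)]
        X = pd.DataFrame(rng.normal(size=(20, 6)), index=idx)
        Y = pd.DataFrame(rng.normal(size=(20, 5)), index=idx,
                         columns=[f"y{i}" for i in range(5)])
        res = permutation_significance(X, Y, n_perm=199, seed=2)
        ok = res["empirical_p"].notna()
        assert ((res.loc[ok, "p_adj"] >= 0) & (res.loc[ok, "p_adj"] <= 1)).all()
        assert ((res.loc[ok, "q"] >= 0) & (res.loc[ok, "q"] <= 1)).all()
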