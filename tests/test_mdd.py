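import itertools

import numpy as np
import pandas as pd
import pytest

from methscore.io import MethylationMatrix, PhenotypeTable
from methscore.mdd import (
    PenalizedMddScorer,
    delong_test,
    roc_auc,
    split_cohort,
    train_penalized_score,
)


def brute_force_auc(scores, labels):
    """U / (n_cases * n_controls) by explicit pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a, b in itertools.product(pos, neg))
    return u / (len(pos) * len(neg))


class TestSplit:
    @pytest.fixture()
    def pheno(self):
        rng = np.random.default_rng(0)
        n = 100
        return PhenotypeTable(
            pd.DataFrame(
                {"set_label": rng.choice([1, 2], n), "mdd": rng.integers(0, 2, n)},
                index=[f"S{i}" for i in range(n)],
            )
        )

    def test_by_column_partition(self, pheno):
        train, test = split_cohort(pheno, by="set_label")
        counts = pheno.table["set_label"].value_counts()
        assert len(train) == counts[1] and len(test) == counts[2]
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(pheno.sample_ids)

    def test_fraction_deterministic(self, pheno):
        t1 = split_cohort(pheno, fraction=0.5, seed=4)
        t2 = split_cohort(pheno, fraction=0.5, seed=4)
        assert list(t1[0]) == list(t2[0]) and list(t1[1]) == list(t2[1])

    def test_bad_inputs(self, pheno):
        pheno.table["three"] = pheno.table["set_label"].where(
            pheno.table["set_label"] == 1, other=pheno.table.index.str.len()
        )
        with pytest.raises(ValueError):
            split_cohort(pheno, by="three")
        with pytest.raises(ValueError):
            split_cohort(pheno, fraction=1.5)


@pytest.fixture(scope="module")
def sparse_problem():
    rng = np.random.default_rng(7)
    n, p, k = 300, 80, 4
    X = rng.normal(0, 1, (n, p))
    w = np.zeros(p)
    causal = rng.choice(p, k, replace=False)
    w[causal] = rng.choice([-1.5, 1.5], k)
    liab = X @ w
    y = (liab + rng.normal(0, 1, n) > 0).astype(float)
    matrix = MethylationMatrix(
        pd.DataFrame(X, index=[f"S{i}" for i in range(n)], columns=[f"cg{i}" for i in range(p)]),
        "m",
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"mdd": y, "age": rng.normal(50, 10, n), "sex": rng.choice(["F", "M"], n)},
            index=matrix.sample_ids,
        )
    )
    return matrix, pheno, causal


class TestPenalizedScorer:
    def test_extreme_lambda_selects_nothing(self, sparse_problem):
        from sklearn.linear_model import Lasso

        matrix, pheno, _ = sparse_problem
        mdd = pheno.table["mdd"].to_numpy(float)
        resid = mdd - mdd.mean()
        X = matrix.values.to_numpy()
        lam_max = np.max(np.abs(X.T @ resid)) / len(resid)
        model = Lasso(alpha=lam_max * 1.01).fit(X, resid)
        assert np.count_nonzero(model.coef_) == 0

    def test_nonzero_count_monotone_in_lambda(self, sparse_problem):
        from sklearn.linear_model import lasso_path

        matrix, pheno, _ = sparse_problem
        mdd = pheno.table["mdd"].to_numpy(float)
        resid = mdd - mdd.mean()
        alphas, coefs, _ = lasso_path(matrix.values.to_numpy(), resid, alphas=30)
        counts = np.count_nonzero(coefs, axis=0)
        # alphas come out decreasing, so support size must not shrink
        assert (np.diff(counts.astype(int)) >= 0).all()

    def test_fit_recovers_signal_and_is_deterministic(self, sparse_problem):
        matrix, pheno, causal = sparse_problem
        m1 = train_penalized_score(matrix, pheno, ["age", "sex"], folds=5, seed=1)
        m2 = train_penalized_score(matrix, pheno, ["age", "sex"], folds=5, seed=1)
        assert m1.selected_cpgs_ == m2.selected_cpgs_
        assert m1.lambda_chosen_ == m2.lambda_chosen_
        causal_ids = {f"cg{i}" for i in causal}
        assert len(causal_ids & set(m1.selected_cpgs_)) >= 3

    def test_objective_at_solution_beats_truth(self, sparse_problem):
        """Convexity check: the penalized objective at the returned weights
        is no worse than at any other candidate (here: the true support)."""
        rng = np.random.default_rng(11)
        n, p = 50, 20
        X = rng.normal(0, 1, (n, p))
        w_true = np.zeros(p)
        w_true[:3] = [1.0, -1.0, 0.5]
        y = X @ w_true + rng.normal(0, 0.3, n)
        matrix = MethylationMatrix(
            pd.DataFrame(X, index=[f"S{i}" for i in range(n)], columns=[f"cg{i}" for i in range(p)]),
            "m",
        )
        yb = (y > np.median(y)).astype(float)
        pheno = PhenotypeTable(pd.DataFrame({"mdd": yb}, index=matrix.sample_ids))
        model = PenalizedMddScorer(covariates=None, folds=5, seed=0).fit(matrix, pheno)
        resid = yb - yb.mean()
        lam = model.lambda_chosen_

        def objective(w, b):
            r = resid - (X @ w + b)
            return 0.5 * np.mean(r**2) + lam * np.sum(np.abs(w))

        w_hat = np.zeros(p)
        for cpg, wv in model.weights_.items():
            w_hat[int(cpg[2:])] = wv
        assert objective(w_hat, model.intercept_) <= objective(w_true, 0.0) + 1e-6

    def test_predict_is_weighted_sum(self, sparse_problem):
        matrix, pheno, _ = sparse_problem
        model = train_penalized_score(matrix, pheno, ["age"], folds=5, seed=2)
        scores = model.predict(matrix)
        manual = model.intercept_ + matrix.values[
            list(model.weights_.index)
        ].to_numpy() @ model.weights_.to_numpy()
        assert np.allclose(scores.to_numpy(), manual, atol=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_label_inversion_antisymmetry(self):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 1, 60)
        y = rng.integers(0, 2, 60)
        assert roc_auc(s, y) == pytest.approx(1 - roc_auc(s, 1 - y), abs=1e-12)

    def test_all_ties_give_half(self):
        assert roc_auc([5.0] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1
        s = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        assert roc_auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 30)
        s = rng.normal(0, 1, 60)
        res = delong_test(s, s.copy(), y)
        assert res.delong_d == 0.0 and res.p_value == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        a = rng.normal(0, 1, 80)
        b = rng.normal(0, 1, 80)
        base = delong_test(a, b, y)
        warped = delong_test(np.exp(a), b**3 + 5 * b, y)
        assert warped.delong_d == pytest.approx(base.delong_d, abs=1e-10)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-10)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], [0, 1, 1])

    def test_auc_fields_match_roc_auc(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        a = y + rng.normal(0, 1, 100)
        b = y + rng.normal(0, 2, 100)
        res = delong_test(a, b, y)
        assert res.auc_a == pytest.approx(roc_auc(a, y), abs=1e-12)
        assert res.auc_b == pytest.approx(roc_auc(b, y), abs=1e-12)
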