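"""Pruning, splitting, OLS fitting, GA subset search and prediction."""

import json

import numpy as np
import pandas as pd
import pytest

from dpp3qsar.qsar_model import (
    GAConfig,
    MLRModel,
    MODEL1_PUBLISHED,
    MODEL2_PUBLISHED,
    SingularityError,
    SplitResult,
    activity_ranked_split,
    exclude_inactives,
    fit_ols,
    ga_select,
    loo_q2_fast,
    predict,
    prune_descriptors,
)
from dpp3qsar.synthetic_data import RegressionTruth, gen_regression


class TestPruning:
    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"c": np.ones(20), "x": rng.normal(size=20)})
        assert list(prune_descriptors(df).columns) == ["x"]

    def test_correlated_pair_keeps_first(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(scale=0.01, size=200)})
        assert abs(df.corr().iloc[0, 1]) > 0.95
        assert list(prune_descriptors(df).columns) == ["a"]

    def test_synthetic_count_by_construction(self, rng):
        # 10 columns: 2 constants + 1 duplicated pair -> 7 survive
        base = rng.normal(size=(50, 7))
        df = pd.DataFrame(base, columns=[f"v{i}" for i in range(7)])
        df["const1"] = 3.0
        df["const2"] = -1.0
        df["dup_of_v0"] = df["v0"] * 2.0 + 0.1
        assert prune_descriptors(df).shape[1] == 7

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)})
        with pytest.raises(ValueError):
            prune_descriptors(df)


class TestExclusion:
    def test_dataset_counts(self, records):
        part = exclude_inactives(records, n_exclude=8, seed=11)
        assert len(part.excluded_inactive_ids) == 8
        assert len(part.training_ids) == 32

    def test_seed_reproducible(self, records):
        a = exclude_inactives(records, seed=5)
        b = exclude_inactives(records, seed=5)
        assert a.excluded_inactive_ids == b.excluded_inactive_ids

    def test_zero_exclusion_and_overdraw(self, records):
        assert len(exclude_inactives(records, n_exclude=0).training_ids) == 40
        with pytest.raises(ValueError):
            exclude_inactives(records, n_exclude=15)

    def test_only_na_compounds_excluded(self, records):
        part = exclude_inactives(records, seed=3)
        na_ids = {
            r.compound_id
            for r in records
            if r.is_tested and r.inhibition_pct is None
        }
        assert set(part.excluded_inactive_ids) <= na_ids


class TestActivitySplit:
    def test_dataset_sizes(self, rng):
        ids = list(range(1, 33))
        y = rng.normal(size=32)
        split = activity_ranked_split(ids, y, n_groups=5, seed=1)
        assert len(split.test_ids) == 5
        assert len(split.training_ids) == 27

    def test_one_test_compound_per_block(self):
        ids = list(range(10))
        y = [9, 8, 7, 6, 5, 4, 3, 2, 1, 0]
        split = activity_ranked_split(ids, y, n_groups=5, seed=2)
        # descending rank = ids in order; blocks of 2
        for b, block in enumerate([(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]):
            assert len(set(block) & set(split.test_ids)) == 1

    def test_partition_property(self, rng):
        ids = list(range(100, 132))
        y = rng.normal(size=32)
        split = activity_ranked_split(ids, y, seed=9)
        assert set(split.training_ids) | set(split.test_ids) == set(ids)
        assert not set(split.training_ids) & set(split.test_ids)
        again = activity_ranked_split(ids, y, seed=9)
        assert again.test_ids == split.test_ids

    def test_ties_stable_by_id(self):
        ids = [5, 3, 1, 2, 4, 7, 6, 9, 8, 10]
        y = [1.0] * 10  # all tied -> ranking falls back to id order
        split = activity_ranked_split(ids, y, n_groups=5, seed=0)
        blocks = [(1, 2), (3, 4), (5, 6), (7, 8), (9, 10)]
        for block in blocks:
            assert len(set(block) & set(split.test_ids)) == 1

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            activity_ranked_split([1, 2, 3], [1, 2, 3], n_groups=5)

    def test_split_result_disjointness_enforced(self):
        with pytest.raises(ValueError):
            SplitResult(training_ids=(1, 2), test_ids=(2, 3))


class TestFitOLS:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        m = fit_ols(pd.DataFrame({"x": x}), 2 * x)
        assert m.intercept == pytest.approx(0.0, abs=1e-10)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert m.std_coefficients[0] == pytest.approx(1.0, abs=1e-10)

    def test_noiseless_recovery(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = 1.5 - 2.0 * X["a"] + 0.5 * X["b"] + 3.0 * X["c"]
        m = fit_ols(X, y)
        assert np.allclose(m.coefficients, [-2.0, 0.5, 3.0], atol=1e-10)
        assert m.intercept == pytest.approx(1.5, abs=1e-10)

    def test_monte_carlo_unbiased(self):
        """Coefficient estimates are unbiased within 2 standard errors."""
        true = np.array([1.0, -0.7, 0.3])
        coefs = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 3))
            y = X @ true + rng.normal(scale=0.3, size=200)
            coefs.append(fit_ols(X, y).coefficients)
        mean = np.array(coefs).mean(axis=0)
        se = np.array(coefs).std(axis=0) / np.sqrt(300)
        assert np.all(np.abs(mean - true) < 2 * se + 1e-12)

    def test_residual_orthogonality(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        m = fit_ols(X, y)
        resid = y - np.asarray(predict(m, X))
        assert abs(resid.sum()) < 1e-8
        assert np.all(np.abs(X.T @ resid) < 1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        with pytest.raises(SingularityError, match="a"):
            fit_ols(X, rng.normal(size=50))

    def test_too_few_observations(self, rng):
        with pytest.raises(ValueError):
            fit_ols(rng.normal(size=(4, 3)), rng.normal(size=4))


class TestGASelect:
    def test_single_informative_column(self, rng):
        X = pd.DataFrame(
            {"x1": rng.normal(size=50), "x2": rng.normal(size=50)}
        )
        y = 2 * X["x1"].to_numpy()
        res = ga_select(
            X, y, GAConfig(population_size=20, generations=15,
                           subset_size_max=1, seed=0)
        )
        assert res.model.descriptor_names == ("x1",)

    def test_duplicated_column_tie_breaks_low_index(self, rng):
        base = rng.normal(size=60)
        X = pd.DataFrame(
            {
                "n1": rng.normal(size=60),
                "sig_a": base,
                "sig_b": base.copy(),  # exact duplicate -> fitness tie
                "n2": rng.normal(size=60),
            }
        )
        y = 3 * base + rng.normal(scale=0.1, size=60)
        res = ga_select(
            X, y, GAConfig(population_size=30, generations=25, seed=4)
        )
        assert "sig_a" in res.model.descriptor_names
        assert "sig_b" not in res.model.descriptor_names

    def test_fitness_history_monotone(self, rng):
        truth = RegressionTruth(seed=3, noise_sd=0.5)
        X, y, _ = gen_regression(60, 12, truth)
        res = ga_select(X, y, GAConfig(population_size=20, generations=30, seed=3))
        hist = res.fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_reproducible_from_seed(self, rng):
        X, y, _ = gen_regression(60, 15, RegressionTruth(seed=8))
        a = ga_select(X, y, GAConfig(population_size=25, generations=20, seed=42))
        b = ga_select(X, y, GAConfig(population_size=25, generations=20, seed=42))
        assert a.model == b.model
        assert a.fitness_history == b.fitness_history

    def test_planted_subset_recovery_smoke(self):
        hits = 0
        for seed in range(10):
            truth = RegressionTruth(
                true_subset=(2, 7, 11),
                true_coefficients=(1.0, 0.8, 0.6),
                noise_sd=0.88,
                collinearity_rho=0.3,
                seed=seed,
            )
            X, y, _ = gen_regression(100, 20, truth)
            res = ga_select(
                X, y, GAConfig(population_size=40, generations=30, seed=seed)
            )
            if res.selected_columns == (2, 7, 11):
                hits += 1
        assert hits >= 9


class TestPredict:
    def test_published_model_at_origin(self):
        zeros = {"EEig05x": 0.0, "Mor10u": 0.0, "nArOH": 0.0}
        assert predict(MODEL2_PUBLISHED, zeros) == pytest.approx(-4.07)
        assert predict(MODEL1_PUBLISHED, zeros) == pytest.approx(-4.03)

    def test_published_model_at_ones(self):
        ones = {"EEig05x": 1.0, "Mor10u": 1.0, "nArOH": 1.0}
        assert predict(MODEL2_PUBLISHED, ones) == pytest.approx(-0.06)

    def test_linearity(self, rng):
        x = rng.normal(size=3)
        delta = rng.normal(size=3)
        m = MODEL2_PUBLISHED
        lhs = predict(m, x + delta) - predict(m, x)
        assert lhs == pytest.approx(float(np.dot(m.coefficients, delta)))

    def test_dataframe_alignment_and_errors(self):
        df = pd.DataFrame(
            {"Mor10u": [0.0], "EEig05x": [0.0], "nArOH": [0.0]}
        )  # shuffled column order must not matter
        assert predict(MODEL2_PUBLISHED, df)[0] == pytest.approx(-4.07)
        with pytest.raises(KeyError):
            predict(MODEL2_PUBLISHED, {"EEig05x": 0.0})

    def test_json_roundtrip(self, tmp_path, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        m = fit_ols(X, rng.normal(size=20), training_ids=range(20))
        path = tmp_path / "model.json"
        m.to_json(path, provenance={"note": "test"})
        back = MLRModel.from_json(path)
        assert back == m
        assert "provenance" in json.loads(path.read_text())


def test_loo_q2_fast_matches_explicit(rng):
    from dpp3qsar.validation import loo_cv

    X = rng.normal(size=(25, 3))
    y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(scale=0.4, size=25)
    assert loo_q2_fast(X, y) == pytest.approx(
        loo_cv(X, y, method="refit")["Q2_LOO"], abs=1e-10
    )
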