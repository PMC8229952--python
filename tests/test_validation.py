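"""Validation statistics: fit metrics, LOO, Y-scrambling, external
predictivity, applicability domain, and the criteria checklist."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dpp3qsar.qsar_model import fit_ols, predict
from dpp3qsar.validation import (
    ValidationReport,
    ccc,
    check_criteria,
    compute_validation_report,
    external_validation,
    fit_stats,
    k_index,
    kxx_deltak,
    loo_cv,
    rm2_metrics,
    williams,
    y_scramble,
)

# Published improved-model statistics: used to exercise the checklist.
MODEL2_REPORT = ValidationReport(
    N_tr=26, N_ex=5,
    R2=0.796, R2_adj=0.768, s=0.323, F=28.572, Kxx=0.190, dK=0.215,
    RMSE_tr=0.297, MAE_tr=0.253, CCC_tr=0.886,
    Q2_LOO=0.710, RMSE_cv=0.354, MAE_cv=0.302, PRESS_cv=3.258, CCC_cv=0.844,
    R2_Yscr=0.121, Q2_Yscr=-0.244,
    RMSE_ext=0.295, MAE_ext=0.275, R2_ext=0.785, CCC_ext=0.873,
    Q2_F1=0.778, Q2_F2=0.776, Q2_F3=0.798,
    rm2_avg=0.653, rm2_diff=0.174,
)


class TestFitStats:
    def test_perfect_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        y = 1 + 2 * X["a"] - X["b"]
        m = fit_ols(X, y)
        s = fit_stats(m, X, y)
        assert s["R2"] == pytest.approx(1.0)
        assert s["RMSE_tr"] == pytest.approx(0.0, abs=1e-10)
        assert s["MAE_tr"] == pytest.approx(0.0, abs=1e-10)
        assert s["CCC_tr"] == pytest.approx(1.0)

    def test_pure_noise_r2_near_zero(self):
        r2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10_000, 3))
            y = rng.normal(size=10_000)
            m = fit_ols(X, y)
            r2s.append(fit_stats(m, X, y)["R2"])
        assert max(abs(v) for v in r2s) < 0.05

    def test_f_matches_anova_decomposition(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1, 0.5, -1.0]) + rng.normal(size=30)
        m = fit_ols(X, y)
        s = fit_stats(m, X, y)
        yhat = np.asarray(predict(m, X))
        # independent route: explained/residual mean squares
        ess = ((yhat - y.mean()) ** 2).sum()
        rss = ((y - yhat) ** 2).sum()
        f_direct = (ess / 3) / (rss / (30 - 3 - 1))
        assert s["F"] == pytest.approx(f_direct, rel=1e-9)

    def test_ccc_identities(self, rng):
        x = rng.normal(size=40)
        assert ccc(x, x) == pytest.approx(1.0)
        y = 2 * x + rng.normal(size=40)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc(x, y)) <= abs(r) + 1e-12


class TestLOO:
    def test_exact_linear_data(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        y = 3 * X[0] - X[1] + 2
        out = loo_cv(X, y)
        assert out["Q2_LOO"] == pytest.approx(1.0)
        assert out["PRESS_cv"] == pytest.approx(0.0, abs=1e-18)

    def test_hat_shortcut_equals_explicit_refits(self, rng):
        # two independent algorithms must agree to 1e-10
        for n in (6, 12, 30):
            X = rng.normal(size=(n, 2))
            y = X @ np.array([1.0, -0.5]) + rng.normal(scale=0.5, size=n)
            a = loo_cv(X, y, method="refit")
            b = loo_cv(X, y, method="hat")
            for key in a:
                assert a[key] == pytest.approx(b[key], abs=1e-10), key

    def test_noise_descriptor_does_not_help(self):
        """Adding a pure-noise column never improves LOO Q2 in median."""
        deltas = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(26, 2))
            y = X @ np.array([1.0, 0.7]) + rng.normal(scale=0.5, size=26)
            base = loo_cv(X, y, method="hat")["Q2_LOO"]
            Xplus = np.column_stack([X, rng.normal(size=26)])
            plus = loo_cv(Xplus, y, method="hat")["Q2_LOO"]
            deltas.append(plus - base)
        assert np.median(deltas) <= 0

    def test_insufficient_data(self, rng):
        with pytest.raises(ValueError):
            loo_cv(rng.normal(size=(4, 2)), rng.normal(size=4))


class TestExternal:
    def test_perfect_predictions(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = 1 + X["a"] - 2 * X["b"]
        m = fit_ols(X, y)
        X_ext = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        y_ext = 1 + X_ext["a"] - 2 * X_ext["b"]
        out = external_validation(m, X_ext, y_ext, y)
        for key in ("Q2_F1", "Q2_F2", "Q2_F3", "R2_ext", "CCC_ext"):
            assert out[key] == pytest.approx(1.0), key
        avg, diff = rm2_metrics(y_ext, y_ext)
        assert (avg, diff) == (pytest.approx(1.0), pytest.approx(0.0))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_q2f1_dominates_q2f2(self, seed):
        rng = np.random.default_rng(seed)
        n_tr, n_ext = 20, 5
        X = rng.normal(size=(n_tr, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(size=n_tr)
        m = fit_ols(X, y)
        X_ext = rng.normal(size=(n_ext, 2))
        y_ext = X_ext @ np.array([1.0, -1.0]) + rng.normal(size=n_ext)
        out = external_validation(m, X_ext, y_ext, y)
        assert out["Q2_F1"] >= out["Q2_F2"] - 1e-12

    def test_five_point_worked_example(self):
        """Hand-computed spreadsheet-style check of the Q2_F family."""
        y_tr = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # mean 2, TSS 10
        y_ext = np.array([1.0, 2.0, 3.0, 2.5, 0.5])
        yhat = np.array([1.2, 1.8, 3.1, 2.2, 0.9])
        from dpp3qsar.qsar_model import MLRModel

        # identity "model": prediction equals the single descriptor value
        model = MLRModel(("d",), 0.0, (1.0,))
        out = external_validation(model, yhat[:, None], y_ext, y_tr)
        rss = ((y_ext - yhat) ** 2).sum()  # 0.04+0.04+0.01+0.09+0.16 = 0.34
        assert rss == pytest.approx(0.34)
        assert out["Q2_F1"] == pytest.approx(1 - 0.34 / (((y_ext - 2.0) ** 2).sum()), abs=1e-12)
        assert out["Q2_F2"] == pytest.approx(
            1 - 0.34 / (((y_ext - y_ext.mean()) ** 2).sum()), abs=1e-12
        )
        assert out["Q2_F3"] == pytest.approx(1 - (0.34 / 5) / (10.0 / 5), abs=1e-12)
        assert out["RMSE_ext"] == pytest.approx(np.sqrt(0.34 / 5), abs=1e-12)
        assert out["MAE_ext"] == pytest.approx(np.mean([0.2, 0.2, 0.1, 0.3, 0.4]), abs=1e-12)

    def test_too_small_external_set(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        y = rng.normal(size=20)
        m = fit_ols(X, y)
        with pytest.raises(ValueError):
            external_validation(m, X.iloc[:1], y[:1], y)


class TestYScrambling:
    def test_strong_signal_pattern(self, rng):
        X = rng.normal(size=(27, 3))
        beta = np.array([1.0, 0.8, 0.6])
        y = X @ beta + rng.normal(scale=0.5, size=27)
        r2_scr, q2_scr = y_scramble(X, y, n_iter=200, seed=0)
        assert r2_scr < 0.2
        assert q2_scr < r2_scr

    def test_exchangeable_null(self):
        """When y is independent of X, scrambling changes nothing on
        average: mean scrambled R2 tracks the unscrambled R2."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        m = fit_ols(X, y)
        r2 = fit_stats(m, X, y)["R2"]
        r2_scr, _ = y_scramble(X, y, n_iter=500, seed=1)
        assert abs(r2_scr - r2) < 0.05

    def test_deterministic(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        assert y_scramble(X, y, n_iter=1, seed=9) == y_scramble(
            X, y, n_iter=1, seed=9
        )


class TestWilliams:
    def test_warning_leverage_modeled_configuration(self, rng):
        X = rng.normal(size=(27, 3))
        y = X @ np.array([1.0, 1.0, 1.0]) + rng.normal(size=27)
        m = fit_ols(X, y)
        wd = williams(m, X, y)
        assert wd.h_star == pytest.approx(3 * 4 / 27)
        assert round(wd.h_star, 3) == 0.444

    def test_leverages_sum_to_p_prime(self, rng):
        X = rng.normal(size=(27, 3))
        y = rng.normal(size=27)
        m = fit_ols(X, y)
        wd = williams(m, X, y)
        assert wd.leverages.sum() == pytest.approx(4.0, abs=1e-9)
        assert np.all((wd.leverages >= 0) & (wd.leverages <= 1))

    def test_single_predictor_closed_form(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        y = np.array([0.1, 1.2, 1.9, 3.1])
        m = fit_ols(x[:, None], y)
        wd = williams(m, x[:, None], y)
        closed = 1 / 4 + (x - x.mean()) ** 2 / ((x - x.mean()) ** 2).sum()
        assert np.allclose(wd.leverages, closed, atol=1e-12)

    def test_outlier_flagging(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ np.array([2.0, 1.0]) + rng.normal(scale=0.1, size=30)
        y[4] += 5.0  # gross response outlier
        m = fit_ols(X, y)
        wd = williams(m, X, y, ids_tr=list(range(30)))
        assert 4 in wd.outlier_ids

    def test_query_compounds_screened(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(scale=0.2, size=20)
        m = fit_ols(X, y)
        far = np.array([[8.0, -8.0]])  # far outside training space
        wd = williams(m, X, y, X_query=far, ids_tr=range(20), ids_query=["new"])
        assert "new" in wd.outside_domain_ids


class TestKIndex:
    def test_perfectly_collinear_pair(self, rng):
        x = rng.normal(size=100)
        assert k_index(np.column_stack([x, 2 * x])) == pytest.approx(1.0)

    def test_orthogonal_design(self):
        # exactly uncorrelated columns via Helmert-style contrasts
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        assert k_index(X) == pytest.approx(0.0, abs=1e-12)

    def test_kxx_range_random_sweep(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, rng.integers(2, 6)))
            v = k_index(X)
            assert 0.0 <= v <= 1.0 + 1e-12

    def test_delta_k_for_informative_response(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ np.array([1.0, 1.0, 1.0]) + rng.normal(scale=0.3, size=50)
        kxx, dk = kxx_deltak(X, y)
        assert dk > 0.05

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            k_index(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestCriteria:
    def test_published_model2_column_passes(self):
        flags = check_criteria(MODEL2_REPORT)
        assert all(flags.values()), {k: v for k, v in flags.items() if not v}

    def test_boundary_failure(self):
        import dataclasses

        rep = dataclasses.replace(MODEL2_REPORT, Q2_LOO=0.49)
        flags = check_criteria(rep)
        assert not flags["Q2_LOO"]
        assert flags["R2"]

    def test_partial_report_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            check_criteria(ValidationReport())


def test_full_report_assembly(rng):
    X = pd.DataFrame(rng.normal(size=(27, 3)), columns=["a", "b", "c"])
    y = X @ np.array([1.0, 0.8, 0.6]) + rng.normal(scale=0.5, size=27)
    X_ext = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a", "b", "c"])
    y_ext = X_ext @ np.array([1.0, 0.8, 0.6]) + rng.normal(scale=0.5, size=5)
    m = fit_ols(X, y)
    rep = compute_validation_report(m, X, y, X_ext, y_ext, n_yscramble=50)
    d = rep.to_dict()
    assert all(np.isfinite(v) for v in d.values())
    assert rep.N_tr == 27 and rep.N_ex == 5
    assert rep.Q2_F1 >= rep.Q2_F2
    assert rep.PRESS_cv >= 0
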