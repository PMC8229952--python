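"""Model validation: fit statistics, LOO cross-validation, Y-scrambling,
external predictivity, and the leverage-based applicability domain.

All statistics follow the QSAR reporting conventions of the modeling
protocol:

* fit: R2, adjusted R2, regression standard error s, Fisher F, RMSE, MAE
  and Lin's concordance correlation coefficient (CCC);
* internal: leave-one-out Q2, PRESS, cross-validated RMSE/MAE/CCC;
* robustness: mean R2 and Q2 over Y-scrambled refits;
* external: Q2_F1 (training-mean reference), Q2_F2 (external-mean
  reference), Q2_F3 (variance-per-compound reference), external RMSE /
  MAE / R2 / CCC and the rm2 metrics;
* applicability domain: Williams plot data with warning leverage
  h* = 3 p'/n and |standardized residual| > 2 as the outlier rule.

Population variances are used throughout, consistently across metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .qsar_model import MLRModel, fit_ols, predict

__all__ = [
    "ValidationReport",
    "WilliamsData",
    "ccc",
    "fit_stats",
    "loo_cv",
    "external_validation",
    "y_scramble",
    "williams",
    "kxx_deltak",
    "k_index",
    "check_criteria",
    "compute_validation_report",
    "DEFAULT_CRITERIA",
]


def _arr(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    a = np.asarray(x, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient between paired values.

    2*sum((x-xbar)(y-ybar)) / [sum((x-xbar)^2) + sum((y-ybar)^2)
    + n*(xbar-ybar)^2]; equals 1 iff x == y elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    denom = (xc**2).sum() + (yc**2).sum() + n * (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0
    return float(2 * (xc * yc).sum() / denom)


@dataclass
class ValidationReport:
    """Every reported statistic of the modeling protocol, one field each."""

    N_tr: int = 0
    N_ex: int = 0
    R2: float = np.nan
    R2_adj: float = np.nan
    s: float = np.nan
    F: float = np.nan
    Kxx: float = np.nan
    dK: float = np.nan
    RMSE_tr: float = np.nan
    MAE_tr: float = np.nan
    CCC_tr: float = np.nan
    Q2_LOO: float = np.nan
    RMSE_cv: float = np.nan
    MAE_cv: float = np.nan
    PRESS_cv: float = np.nan
    CCC_cv: float = np.nan
    R2_Yscr: float = np.nan
    Q2_Yscr: float = np.nan
    RMSE_ext: float = np.nan
    MAE_ext: float = np.nan
    R2_ext: float = np.nan
    CCC_ext: float = np.nan
    Q2_F1: float = np.nan
    Q2_F2: float = np.nan
    Q2_F3: float = np.nan
    rm2_avg: float = np.nan
    rm2_diff: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path, provenance: Mapping | None = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = dict(provenance)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path, provenance: Mapping | None = None) -> None:
        """Aligned two-column TSV, one statistic per row."""
        with open(path, "w") as fh:
            for key, val in (provenance or {}).items():
                fh.write(f"# {key}: {val}\n")
            fh.write("statistic\tvalue\n")
            for f in fields(self):
                val = getattr(self, f.name)
                if isinstance(val, float):
                    fh.write(f"{f.name}\t{val:.3f}\n")
                else:
                    fh.write(f"{f.name}\t{val}\n")


@dataclass
class WilliamsData:
    """Applicability-domain data behind a Williams plot."""

    ids: tuple = ()
    leverages: np.ndarray = field(default_factory=lambda: np.array([]))
    std_residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    h_star: float = np.nan
    training_mask: np.ndarray = field(default_factory=lambda: np.array([], bool))
    outlier_ids: tuple = ()
    outside_domain_ids: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        flags = []
        for i, cid in enumerate(self.ids):
            f = []
            if cid in self.outlier_ids:
                f.append("outlier")
            if cid in self.outside_domain_ids:
                f.append("outside_domain")
            flags.append("+".join(f) or "ok")
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "set": np.where(self.training_mask, "training", "query"),
                "h": self.leverages,
                "std_residual": self.std_residuals,
                "flag": flags,
            }
        )

    def to_tsv(self, path: str | Path, provenance: Mapping | None = None) -> None:
        with open(path, "w") as fh:
            for key, val in (provenance or {}).items():
                fh.write(f"# {key}: {val}\n")
            fh.write(f"# h_star: {self.h_star:.3f}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.5f")


# ---------------------------------------------------------------------------
# Fit statistics


def fit_stats(model: MLRModel, X_tr, y_tr) -> dict[str, float]:
    """Training-set statistics: R2, R2_adj, s, F, RMSE_tr, MAE_tr, CCC_tr."""
    y = np.asarray(y_tr, dtype=float)
    yhat = np.asarray(predict(model, X_tr), dtype=float)
    n, p = len(y), len(model.coefficients)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 for fit statistics (n={n}, p={p})")
    rss = ((y - yhat) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1 - rss / tss
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    s = float(np.sqrt(rss / (n - p - 1)))
    f_stat = (r2 / p) / ((1 - r2) / (n - p - 1)) if r2 < 1 else np.inf
    return {
        "R2": float(r2),
        "R2_adj": float(r2_adj),
        "s": s,
        "F": float(f_stat),
        "RMSE_tr": float(np.sqrt(rss / n)),
        "MAE_tr": float(np.abs(y - yhat).mean()),
        "CCC_tr": ccc(y, yhat),
    }


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation


def loo_cv(
    X, y, method: str = "refit", return_predictions: bool = False
) -> dict[str, float] | tuple[dict[str, float], np.ndarray]:
    """Leave-one-out CV of the OLS model on (X, y).

    ``method='refit'`` refits n times explicitly; ``method='hat'`` uses the
    algebraically equivalent shortcut e_i / (1 - h_ii).  Returns Q2_LOO,
    PRESS_cv, RMSE_cv, MAE_cv, CCC_cv (and the LOO predictions themselves
    when ``return_predictions`` is set; the rm2 metrics are computed from
    those).
    """
    arr = _arr(X)
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 for LOO (n={n}, p={p})")
    design = np.column_stack([np.ones(n), arr])
    if method == "hat":
        q, r = np.linalg.qr(design)
        coef = np.linalg.solve(r, q.T @ y)
        resid = y - design @ coef
        h = (q**2).sum(axis=1)
        press_resid = resid / (1 - h)
        preds = y - press_resid
    elif method == "refit":
        preds = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            di, yi = design[mask], y[mask]
            try:
                coef, *_ = np.linalg.lstsq(di, yi, rcond=None)
                if np.linalg.matrix_rank(di) < di.shape[1]:
                    raise np.linalg.LinAlgError("rank deficient")
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"LOO refit singular when leaving out index {i}"
                ) from exc
            preds[i] = design[i] @ coef
    else:
        raise ValueError("method must be 'refit' or 'hat'")
    press = ((y - preds) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    stats = {
        "Q2_LOO": float(1 - press / tss),
        "PRESS_cv": float(press),
        "RMSE_cv": float(np.sqrt(press / n)),
        "MAE_cv": float(np.abs(y - preds).mean()),
        "CCC_cv": ccc(y, preds),
    }
    if return_predictions:
        return stats, preds
    return stats


# ---------------------------------------------------------------------------
# External validation


def _r2_with_without_origin(x, y) -> tuple[float, float]:
    """(r2 with intercept, r0.2 through origin) regressing y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = ((y - y.mean()) ** 2).sum()
    if denom == 0:
        return 1.0, 1.0
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r**2)
    k = (x * y).sum() / (x**2).sum()
    r0_2 = float(1 - ((y - k * x) ** 2).sum() / denom)
    return r2, r0_2


def rm2_metrics(y_obs, y_pred) -> tuple[float, float]:
    """Roy's rm2 average and absolute difference between observed and
    predicted values.

    rm2 = r2 * (1 - sqrt(r2 - r0.2)) with r2 the squared correlation with
    intercept and r0.2 the through-origin coefficient, evaluated in both
    regression directions; for this protocol the predictions are the
    leave-one-out ones (rm2 is an internal robustness metric here).
    """

    def _one(x, y) -> float:
        r2, r0_2 = _r2_with_without_origin(x, y)
        return float(r2 * (1 - np.sqrt(max(r2 - r0_2, 0.0))))

    fwd = _one(np.asarray(y_pred, float), np.asarray(y_obs, float))
    rev = _one(np.asarray(y_obs, float), np.asarray(y_pred, float))
    return (fwd + rev) / 2, abs(fwd - rev)


def external_validation(model: MLRModel, X_ext, y_ext, y_tr) -> dict[str, float]:
    """External-set predictivity statistics.

    Q2_F1 references the training mean, Q2_F2 the external mean, Q2_F3 the
    per-compound training variance.  (The rm2 metrics are computed from
    the LOO predictions via :func:`rm2_metrics`, not here.)
    """
    y_ext = np.asarray(y_ext, dtype=float)
    y_tr = np.asarray(y_tr, dtype=float)
    if len(y_ext) < 2:
        raise ValueError("external set needs >= 2 compounds")
    yhat = np.asarray(predict(model, X_ext), dtype=float)
    rss = ((y_ext - yhat) ** 2).sum()
    n_ext, n_tr = len(y_ext), len(y_tr)
    q2f1 = 1 - rss / ((y_ext - y_tr.mean()) ** 2).sum()
    q2f2 = 1 - rss / ((y_ext - y_ext.mean()) ** 2).sum()
    q2f3 = 1 - (rss / n_ext) / (((y_tr - y_tr.mean()) ** 2).sum() / n_tr)
    r = np.corrcoef(y_ext, yhat)[0, 1]
    return {
        "R2_ext": float(r**2),
        "RMSE_ext": float(np.sqrt(rss / n_ext)),
        "MAE_ext": float(np.abs(y_ext - yhat).mean()),
        "CCC_ext": ccc(y_ext, yhat),
        "Q2_F1": float(q2f1),
        "Q2_F2": float(q2f2),
        "Q2_F3": float(q2f3),
    }


# ---------------------------------------------------------------------------
# Y-scrambling


def y_scramble(
    X, y, n_iter: int = 500, seed: int = 0
) -> tuple[float, float]:
    """Mean R2 and Q2_LOO over refits against permuted responses.

    A robust model shows scrambled values near zero and well below the
    unscrambled fit; chance correlation shows up as high scrambled R2.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    arr = _arr(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    design = np.column_stack([np.ones(n), arr])
    q, r = np.linalg.qr(design)
    h = (q**2).sum(axis=1)
    r2s, q2s = [], []
    for _ in range(n_iter):
        yp = y[rng.permutation(n)]
        coef = np.linalg.solve(r, q.T @ yp)
        resid = yp - design @ coef
        tss = ((yp - yp.mean()) ** 2).sum()
        r2s.append(1 - (resid**2).sum() / tss)
        press = ((resid / (1 - h)) ** 2).sum()
        q2s.append(1 - press / tss)
    return float(np.mean(r2s)), float(np.mean(q2s))


# ---------------------------------------------------------------------------
# Applicability domain


def williams(
    model: MLRModel,
    X_tr,
    y_tr,
    X_query=None,
    y_query=None,
    ids_tr: Sequence | None = None,
    ids_query: Sequence | None = None,
    residual_scaling: str = "standardized",
    outlier_threshold: float = 2.0,
) -> WilliamsData:
    """Leverages and standardized residuals for the Williams plot.

    Leverage h_i = x_i (X'X)^-1 x_i' with the intercept column included;
    the warning leverage is h* = 3 p'/n with p' = descriptors + intercept.
    Residuals are scaled by the regression standard error s by default
    (``residual_scaling='studentized'`` divides by s*sqrt(1-h) instead).
    Query compounds (e.g. an external set or new molecules) are screened
    against the training-data hat matrix.
    """
    arr_tr = _arr(X_tr)
    y_tr = np.asarray(y_tr, dtype=float)
    n, p = arr_tr.shape
    p_prime = p + 1
    design = np.column_stack([np.ones(n), arr_tr])
    xtx = design.T @ design
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X'X is singular") from exc
    h_tr = np.einsum("ij,jk,ik->i", design, xtx_inv, design)
    yhat = np.asarray(predict(model, X_tr), dtype=float)
    resid = y_tr - yhat
    s = np.sqrt((resid**2).sum() / (n - p_prime))
    if residual_scaling == "standardized":
        std_resid = resid / s
    elif residual_scaling == "studentized":
        std_resid = resid / (s * np.sqrt(1 - h_tr))
    else:
        raise ValueError("residual_scaling must be standardized|studentized")

    ids_tr = list(ids_tr) if ids_tr is not None else list(range(n))
    ids_all = list(ids_tr)
    h_all = list(h_tr)
    sr_all = list(std_resid)
    train_mask = [True] * n
    if X_query is not None:
        arr_q = _arr(X_query)
        design_q = np.column_stack([np.ones(len(arr_q)), arr_q])
        h_q = np.einsum("ij,jk,ik->i", design_q, xtx_inv, design_q)
        yhat_q = np.asarray(predict(model, X_query), dtype=float)
        if y_query is not None:
            sr_q = (np.asarray(y_query, dtype=float) - yhat_q) / s
        else:
            sr_q = np.full(len(arr_q), np.nan)
        ids_q = (
            list(ids_query)
            if ids_query is not None
            else [f"q{i}" for i in range(len(arr_q))]
        )
        ids_all += ids_q
        h_all += list(h_q)
        sr_all += list(sr_q)
        train_mask += [False] * len(arr_q)

    h_star = 3 * p_prime / n
    h_arr = np.array(h_all)
    sr_arr = np.array(sr_all)
    outliers = tuple(
        cid
        for cid, sr in zip(ids_all, sr_arr)
        if np.isfinite(sr) and abs(sr) > outlier_threshold
    )
    outside = tuple(cid for cid, h in zip(ids_all, h_arr) if h > h_star)
    return WilliamsData(
        ids=tuple(ids_all),
        leverages=h_arr,
        std_residuals=sr_arr,
        h_star=float(h_star),
        training_mask=np.array(train_mask),
        outlier_ids=outliers,
        outside_domain_ids=outside,
    )


# ---------------------------------------------------------------------------
# Multivariate correlation index


def k_index(M: np.ndarray) -> float:
    """Todeschini K index of a variable block from correlation eigenvalues.

    K = sum_j |lambda_j / sum(lambda) - 1/p| / (2 (p-1)/p); 0 for mutually
    uncorrelated variables, 1 for total correlation.
    """
    M = np.asarray(M, dtype=float)
    p = M.shape[1]
    if p < 2:
        raise ValueError("K index needs >= 2 variables")
    sds = M.std(axis=0)
    if (sds == 0).any():
        raise ValueError("constant column: correlation undefined")
    corr = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0, None)
    frac = lam / lam.sum()
    return float(np.abs(frac - 1 / p).sum() / (2 * (p - 1) / p))


def kxx_deltak(X, y) -> tuple[float, float]:
    """Global descriptor correlation Kxx and its increase dK when the
    response is appended; dK well above zero indicates that the response
    adds correlation structure beyond descriptor collinearity."""
    arr = _arr(X)
    y = np.asarray(y, dtype=float)[:, None]
    kxx = k_index(arr)
    kxy = k_index(np.hstack([arr, y]))
    return kxx, kxy - kxx


# ---------------------------------------------------------------------------
# Criteria checklist

DEFAULT_CRITERIA = {
    "R2_min": 0.60,
    "R2_adj_min": 0.60,
    "CCC_tr_min": 0.85,
    "Q2_LOO_min": 0.50,
    "R2_ext_min": 0.60,
    "Q2_F1_min": 0.60,
    "Q2_F2_min": 0.60,
    "Q2_F3_min": 0.60,
    "rm2_avg_min": 0.60,
    "rm2_diff_max": 0.20,
    "Yscr_max": 0.20,
    "dK_min": 0.05,
}


def check_criteria(
    report: ValidationReport, thresholds: Mapping[str, float] | None = None
) -> dict[str, bool]:
    """Named pass/fail flags for the validation-criteria checklist."""
    t = dict(DEFAULT_CRITERIA)
    if thresholds:
        t.update(thresholds)
    needed = [
        "R2", "R2_adj", "CCC_tr", "Q2_LOO", "R2_ext",
        "Q2_F1", "Q2_F2", "Q2_F3", "rm2_avg", "rm2_diff",
        "R2_Yscr", "Q2_Yscr", "dK",
    ]
    missing = [f for f in needed if not np.isfinite(getattr(report, f))]
    if missing:
        raise ValueError(f"validation report missing fields: {missing}")
    return {
        "R2": report.R2 >= t["R2_min"],
        "R2_adj": report.R2_adj >= t["R2_adj_min"],
        "CCC_tr": report.CCC_tr >= t["CCC_tr_min"],
        "Q2_LOO": report.Q2_LOO >= t["Q2_LOO_min"],
        "R2_ext": report.R2_ext >= t["R2_ext_min"],
        "Q2_F1": report.Q2_F1 >= t["Q2_F1_min"],
        "Q2_F2": report.Q2_F2 >= t["Q2_F2_min"],
        "Q2_F3": report.Q2_F3 >= t["Q2_F3_min"],
        "rm2_avg": report.rm2_avg >= t["rm2_avg_min"],
        "rm2_diff": report.rm2_diff <= t["rm2_diff_max"],
        "R2_Yscr": report.R2_Yscr < t["Yscr_max"],
        "Q2_Yscr": report.Q2_Yscr < t["Yscr_max"],
        "Yscr_order": report.R2_Yscr > report.Q2_Yscr,
        "dK": report.dK >= t["dK_min"],
    }


def compute_validation_report(
    model: MLRModel,
    X_tr,
    y_tr,
    X_ext,
    y_ext,
    n_yscramble: int = 500,
    yscramble_seed: int = 0,
) -> ValidationReport:
    """Assemble the full ValidationReport for a fitted model."""
    rep = ValidationReport(N_tr=len(np.asarray(y_tr)), N_ex=len(np.asarray(y_ext)))
    for key, val in fit_stats(model, X_tr, y_tr).items():
        setattr(rep, key, val)
    loo_stats, loo_preds = loo_cv(X_tr, y_tr, return_predictions=True)
    for key, val in loo_stats.items():
        setattr(rep, key, val)
    rep.rm2_avg, rep.rm2_diff = rm2_metrics(np.asarray(y_tr, float), loo_preds)
    for key, val in external_validation(model, X_ext, y_ext, y_tr).items():
        setattr(rep, key, val)
    rep.R2_Yscr, rep.Q2_Yscr = y_scramble(
        X_tr, y_tr, n_iter=n_yscramble, seed=yscramble_seed
    )
    rep.Kxx, rep.dK = kxx_deltak(X_tr, y_tr)
    return rep
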