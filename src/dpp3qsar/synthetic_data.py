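"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without external data:
equicorrelated Gaussian descriptor matrices with a planted linear signal
(for subset-selection and validation recovery tests), and linear
dose-response series with a known IC50 (for the assay arithmetic).  All
generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import DoseResponseSeries
from .qsar_model import SplitResult, activity_ranked_split

__all__ = [
    "RegressionTruth",
    "SyntheticStudy",
    "gen_regression",
    "gen_doseresponse",
    "gen_table2_like_study",
    "DEFAULT_CONCENTRATIONS",
]

#: Assay concentration grid, uM: 0.5-3.5 in 0.5 steps (7 points).
DEFAULT_CONCENTRATIONS = tuple(np.arange(0.5, 3.51, 0.5))


@dataclass(frozen=True)
class RegressionTruth:
    """Ground truth of a planted linear signal in a descriptor matrix."""

    true_subset: tuple[int, ...] = (0, 1, 2)
    true_coefficients: tuple[float, ...] = (1.0, 0.8, 0.6)
    intercept: float = 0.0
    noise_sd: float = 0.5
    collinearity_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_subset) != len(self.true_coefficients):
            raise ValueError("subset and coefficients must pair up")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.collinearity_rho < 1):
            raise ValueError("collinearity_rho must lie in [0, 1)")

    def signal_variance(self) -> float:
        """Var of the planted signal under the equicorrelated design."""
        b = np.asarray(self.true_coefficients)
        rho = self.collinearity_rho
        return float((1 - rho) * (b**2).sum() + rho * b.sum() ** 2)

    def expected_r2(self) -> float:
        v = self.signal_variance()
        return v / (v + self.noise_sd**2)


def gen_regression(
    n: int, p: int, truth: RegressionTruth
) -> tuple[pd.DataFrame, np.ndarray, RegressionTruth]:
    """Descriptor matrix (n x p) with planted linear response.

    Columns are standard Gaussian with pairwise correlation
    ``collinearity_rho`` (one-factor equicorrelation); the response is
    intercept + X[:, subset] @ coefficients + N(0, noise_sd).
    """
    if p < len(truth.true_subset):
        raise ValueError("p smaller than the planted subset")
    if n <= len(truth.true_subset) + 2:
        raise ValueError("n too small for the planted subset")
    if max(truth.true_subset) >= p:
        raise ValueError("true_subset index out of range")
    rng = np.random.default_rng(truth.seed)
    g = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, p))
    rho = truth.collinearity_rho
    X = np.sqrt(rho) * g + np.sqrt(1 - rho) * eps
    y = truth.intercept + X[:, list(truth.true_subset)] @ np.asarray(
        truth.true_coefficients
    )
    if truth.noise_sd > 0:
        y = y + rng.normal(0, truth.noise_sd, size=n)
    cols = [f"D{j + 1:02d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y, truth


def gen_doseresponse(
    ic50_uM: float = 1.10,
    slope_pct_per_uM: float = 20.0,
    noise_sd_pct: float = 2.0,
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS,
    seed: int = 0,
) -> DoseResponseSeries:
    """Linear dose-response series with known IC50.

    inhibition = 50 + slope * (c - ic50) + N(0, noise_sd_pct) at each
    concentration of the assay grid.
    """
    if ic50_uM <= 0:
        raise ValueError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    inh = 50.0 + slope_pct_per_uM * (conc - ic50_uM)
    if noise_sd_pct > 0:
        inh = inh + rng.normal(0, noise_sd_pct, size=len(conc))
    return DoseResponseSeries.from_arrays(conc, inh)


@dataclass
class SyntheticStudy:
    """Bundled synthetic study mirroring the modeled dataset's shape."""

    X: pd.DataFrame
    y: np.ndarray
    truth: RegressionTruth
    split: SplitResult
    ids: tuple[int, ...] = field(default_factory=tuple)

    @property
    def X_train(self) -> pd.DataFrame:
        return self.X.loc[list(self.split.training_ids)]

    @property
    def X_test(self) -> pd.DataFrame:
        return self.X.loc[list(self.split.test_ids)]

    @property
    def y_train(self) -> np.ndarray:
        idx = [self.ids.index(i) for i in self.split.training_ids]
        return self.y[idx]

    @property
    def y_test(self) -> np.ndarray:
        idx = [self.ids.index(i) for i in self.split.test_ids]
        return self.y[idx]


def gen_table2_like_study(seed: int = 0) -> SyntheticStudy:
    """One synthetic study shaped like the modeled dataset.

    32 compounds split 27/5 by activity sampling; 3 informative
    descriptors among 50 equicorrelated columns; noise sized so the
    expected signal fraction (population R2) is 0.8.
    """
    truth = RegressionTruth(
        true_subset=(0, 1, 2),
        true_coefficients=(1.0, 0.8, 0.6),
        intercept=0.5,
        # noise_sd chosen analytically for expected R2 = 0.8:
        # Var(signal) = (1-rho)*sum(b^2) + rho*(sum b)^2 with rho = 0.3
        noise_sd=float(np.sqrt(((1 - 0.3) * 2.0 + 0.3 * 2.4**2) / 4)),
        collinearity_rho=0.3,
        seed=seed,
    )
    X, y, truth = gen_regression(32, 50, truth)
    ids = tuple(range(1, 33))
    X.index = pd.Index(ids, name="id")
    split = activity_ranked_split(ids, y, n_groups=5, seed=seed)
    return SyntheticStudy(X=X, y=y, truth=truth, split=split, ids=ids)
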