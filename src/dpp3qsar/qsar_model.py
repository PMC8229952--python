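"""Descriptor pruning, dataset splitting, GA-MLR model search and prediction.

The modeling protocol: drop (semi-)constant and highly intercorrelated
descriptors, exclude a random subset of the inactive compounds, split the
remainder into training and test sets by activity sampling (rank by
response, bin, draw one test compound per bin), then search descriptor
subsets of size <= 3 with a genetic algorithm scored by leave-one-out Q2,
fitting each candidate by ordinary least squares.

The two published models are shipped as frozen constants
(:data:`MODEL1_PUBLISHED`, :data:`MODEL2_PUBLISHED`) so predictions for
new molecules run without refitting:

    log % inh. = -4.07 + 1.85*EEig05x + 1.60*Mor10u + 0.56*nArOH
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .compound_library import CompoundRecord

__all__ = [
    "MLRModel",
    "SplitResult",
    "GAConfig",
    "GAResult",
    "SingularityError",
    "prune_descriptors",
    "exclude_inactives",
    "activity_ranked_split",
    "fit_ols",
    "ga_select",
    "predict",
    "loo_q2_fast",
    "MODEL1_PUBLISHED",
    "MODEL2_PUBLISHED",
    "PUBLISHED_MODELS",
]


class SingularityError(np.linalg.LinAlgError):
    """Raised when a design matrix is rank deficient."""


@dataclass(frozen=True)
class MLRModel:
    """Multiple linear regression model over named descriptors.

    ``std_coefficients`` are the standardized betas
    beta_j = b_j * sd(x_j) / sd(y) (population sd); for frozen published
    models they are the printed values.
    """

    descriptor_names: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    std_coefficients: tuple[float, ...] | None = None
    training_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise ValueError("descriptor names and coefficients must pair up")
        if self.std_coefficients is not None and len(
            self.std_coefficients
        ) != len(self.coefficients):
            raise ValueError("std_coefficients length mismatch")

    def predict(self, x) -> np.ndarray | float:
        return predict(self, x)

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "std_coefficients": (
                None
                if self.std_coefficients is None
                else list(self.std_coefficients)
            ),
            "training_ids": (
                None if self.training_ids is None else list(self.training_ids)
            ),
        }

    def to_json(self, path: str | Path, provenance: Mapping | None = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = dict(provenance)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "MLRModel":
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            intercept=float(d["intercept"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            std_coefficients=(
                None
                if d.get("std_coefficients") is None
                else tuple(float(c) for c in d["std_coefficients"])
            ),
            training_ids=(
                None
                if d.get("training_ids") is None
                else tuple(int(i) for i in d["training_ids"])
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MLRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Frozen published model 1 (fitted on the full 27-compound training set).
MODEL1_PUBLISHED = MLRModel(
    descriptor_names=("EEig05x", "Mor10u", "nArOH"),
    intercept=-4.03,
    coefficients=(1.82, 1.46, 0.49),
    std_coefficients=(0.58, 0.49, 0.36),
)

#: Frozen published model 2 (after removal of one response outlier).
MODEL2_PUBLISHED = MLRModel(
    descriptor_names=("EEig05x", "Mor10u", "nArOH"),
    intercept=-4.07,
    coefficients=(1.85, 1.60, 0.56),
    std_coefficients=(0.59, 0.52, 0.39),
)

PUBLISHED_MODELS = {"published1": MODEL1_PUBLISHED, "published2": MODEL2_PUBLISHED}


@dataclass(frozen=True)
class SplitResult:
    """Disjoint partition of the tested compounds."""

    training_ids: tuple[int, ...] = ()
    test_ids: tuple[int, ...] = ()
    excluded_inactive_ids: tuple[int, ...] = ()
    outlier_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        groups = [
            set(self.training_ids),
            set(self.test_ids),
            set(self.excluded_inactive_ids),
            set(self.outlier_ids),
        ]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be disjoint")

    @property
    def all_ids(self) -> set[int]:
        return (
            set(self.training_ids)
            | set(self.test_ids)
            | set(self.excluded_inactive_ids)
            | set(self.outlier_ids)
        )


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset search.

    Defaults follow common GA-MLR practice: tournament selection of size
    2, single elite, uniform crossover, per-bit mutation.
    """

    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    subset_size_max: int = 3
    fitness: str = "Q2LOO"  # or "R2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("population and generations must be >= 1")
        if self.subset_size_max < 1:
            raise ValueError("subset_size_max must be >= 1")
        if self.fitness not in ("Q2LOO", "R2"):
            raise ValueError("fitness must be 'Q2LOO' or 'R2'")


@dataclass
class GAResult:
    """Best model found by :func:`ga_select` plus the retained search log."""

    model: "MLRModel"
    best_fitness: float
    fitness_history: list[float] = field(default_factory=list)
    selected_columns: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Descriptor pruning


def prune_descriptors(
    matrix: pd.DataFrame,
    const_fraction: float = 0.85,
    max_abs_corr: float = 0.95,
) -> pd.DataFrame:
    """Drop (semi-)constant and highly intercorrelated descriptor columns.

    A column is (semi-)constant when its modal value covers more than
    ``const_fraction`` of the rows.  Of each remaining pair with
    |Pearson r| > ``max_abs_corr`` the later column (by column order) is
    dropped, deterministically.
    """
    if matrix.isna().any().any():
        raise ValueError("descriptor matrix has missing cells")
    keep = []
    for col in matrix.columns:
        frac = matrix[col].value_counts(normalize=True).iloc[0]
        if frac <= const_fraction:
            keep.append(col)
    pruned = matrix[keep]
    if pruned.shape[1] == 0:
        raise ValueError("all descriptor columns are (semi-)constant")
    corr = pruned.corr().abs().to_numpy()
    cols = list(pruned.columns)
    dropped: set[int] = set()
    for i in range(len(cols)):
        if i in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if j not in dropped and corr[i, j] > max_abs_corr:
                dropped.add(j)
    survivors = [c for k, c in enumerate(cols) if k not in dropped]
    if not survivors:
        raise ValueError("all descriptor columns dropped by pruning")
    return pruned[survivors]


# ---------------------------------------------------------------------------
# Dataset bookkeeping


def exclude_inactives(
    records: Sequence[CompoundRecord],
    n_exclude: int = 8,
    seed: int = 0,
) -> SplitResult:
    """Randomly exclude ``n_exclude`` of the NA (inactive) tested compounds.

    Returns a partial SplitResult: the excluded ids, with every other
    tested compound placed in ``training_ids`` pending the actual split.
    """
    tested = [r for r in records if r.is_tested]
    na_ids = [r.compound_id for r in tested if r.inhibition_pct is None]
    if n_exclude > len(na_ids):
        raise ValueError(
            f"cannot exclude {n_exclude} inactives; only {len(na_ids)} NA "
            "compounds available"
        )
    rng = np.random.default_rng(seed)
    excluded = tuple(
        sorted(int(i) for i in rng.choice(na_ids, size=n_exclude, replace=False))
    )
    retained = tuple(
        r.compound_id for r in tested if r.compound_id not in excluded
    )
    return SplitResult(training_ids=retained, excluded_inactive_ids=excluded)


def activity_ranked_split(
    ids: Sequence[int],
    responses: Sequence[float],
    n_groups: int = 5,
    seed: int = 0,
    descending: bool = True,
) -> SplitResult:
    """Activity-sampling train/test split.

    Ranks compounds by response (most to least active by default, ties
    broken by compound id), partitions the ranking into ``n_groups``
    contiguous blocks whose sizes differ by at most one, and draws one
    compound per block for the test set.
    """
    ids = list(ids)
    responses = list(responses)
    if len(ids) != len(responses):
        raise ValueError("ids and responses must pair up")
    if len(ids) < n_groups:
        raise ValueError(f"need at least {n_groups} records to split")
    order = sorted(
        range(len(ids)),
        key=lambda k: (-responses[k] if descending else responses[k], ids[k]),
    )
    ranked = [ids[k] for k in order]
    blocks = np.array_split(np.array(ranked), n_groups)
    rng = np.random.default_rng(seed)
    test = tuple(sorted(int(rng.choice(block)) for block in blocks))
    train = tuple(i for i in sorted(ids) if i not in test)
    return SplitResult(training_ids=train, test_ids=test)


# ---------------------------------------------------------------------------
# OLS fitting and prediction


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j + 1}" for j in range(arr.shape[1])]


def fit_ols(X, y, training_ids: Sequence[int] | None = None) -> MLRModel:
    """Ordinary least squares with intercept over named descriptor columns.

    Standardized coefficients use population standard deviations, so a
    perfect single-predictor fit has beta exactly 1.
    """
    arr, names = _as_design(X)
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(arr, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _suspect_columns(arr, names)
        raise SingularityError(
            f"design matrix is rank deficient (suspect columns: {bad})"
        )
    res = sm.OLS(y, design).fit()
    coefs = res.params[1:]
    sd_y = y.std()
    if sd_y == 0:
        betas = tuple(0.0 for _ in coefs)
    else:
        betas = tuple(float(b * arr[:, j].std() / sd_y) for j, b in enumerate(coefs))
    return MLRModel(
        descriptor_names=tuple(names),
        intercept=float(res.params[0]),
        coefficients=tuple(float(b) for b in coefs),
        std_coefficients=betas,
        training_ids=None if training_ids is None else tuple(training_ids),
    )


def _suspect_columns(arr: np.ndarray, names: list[str]) -> list[str]:
    bad = [names[j] for j in range(arr.shape[1]) if arr[:, j].std() == 0]
    if not bad and arr.shape[1] >= 2:
        corr = np.corrcoef(arr, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 1 - 1e-12:
                    bad.extend([names[i], names[j]])
    return sorted(set(bad))


def predict(model: MLRModel, x) -> np.ndarray | float:
    """Model prediction intercept + sum_j b_j x_j.

    Accepts a mapping of descriptor name -> value, a DataFrame (columns
    aligned by name), or a plain array in the model's descriptor order.
    Returns a scalar for a single vector, else an array.
    """
    coefs = np.asarray(model.coefficients)
    if isinstance(x, Mapping):
        missing = [n for n in model.descriptor_names if n not in x]
        if missing:
            raise KeyError(f"descriptor(s) missing from input: {missing}")
        vec = np.array([float(x[n]) for n in model.descriptor_names])
        return float(model.intercept + vec @ coefs)
    if isinstance(x, pd.DataFrame):
        missing = [n for n in model.descriptor_names if n not in x.columns]
        if missing:
            raise KeyError(f"descriptor column(s) missing: {missing}")
        arr = x[list(model.descriptor_names)].to_numpy(dtype=float)
        return model.intercept + arr @ coefs
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != len(coefs):
            raise ValueError("descriptor vector length mismatch")
        return float(model.intercept + arr @ coefs)
    return model.intercept + arr @ coefs


# ---------------------------------------------------------------------------
# GA subset search


def _ols_r2_q2(arr: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """R2 and hat-matrix LOO Q2 for the design [1, arr]; -inf if singular."""
    n = arr.shape[0]
    design = np.column_stack([np.ones(n), arr])
    q, r = np.linalg.qr(design)
    if np.abs(np.diag(r)).min() < 1e-10 * max(1.0, np.abs(np.diag(r)).max()):
        return -np.inf, -np.inf
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - design @ coef
    h = (q**2).sum(axis=1)
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return -np.inf, -np.inf
    r2 = 1 - (resid**2).sum() / tss
    one_minus_h = 1 - h
    if (one_minus_h <= 1e-12).any():
        return float(r2), -np.inf
    press = ((resid / one_minus_h) ** 2).sum()
    return float(r2), float(1 - press / tss)


def loo_q2_fast(X, y) -> float:
    """Leave-one-out Q2 via the hat-matrix shortcut e_i / (1 - h_ii)."""
    arr, _ = _as_design(X)
    return _ols_r2_q2(arr, np.asarray(y, dtype=float))[1]


def _fitness_of(cols: tuple[int, ...], arr, y, kind: str, cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    if not cols:
        val = -np.inf
    else:
        r2, q2 = _ols_r2_q2(arr[:, cols], y)
        val = q2 if kind == "Q2LOO" else r2
    cache[cols] = val
    return val


def _better(cand: tuple[float, tuple[int, ...]], best) -> bool:
    """Strictly-better comparison; exact fitness ties go to the
    lexicographically smaller column tuple (lower indices win)."""
    if best is None:
        return True
    if cand[0] != best[0]:
        return cand[0] > best[0]
    return cand[1] < best[1]


def ga_select(matrix: pd.DataFrame, y, cfg: GAConfig) -> GAResult:
    """Genetic-algorithm search for the best descriptor subset (size <= max).

    Binary chromosomes over the columns of ``matrix``; fitness is the OLS
    leave-one-out Q2 (or R2) of the encoded subset.  Tournament selection
    (size 2), uniform crossover, per-bit mutation with repair to the size
    budget, single-elite survival.  Fully reproducible from ``cfg.seed``;
    the per-generation best fitness is retained as the search log.
    """
    arr, names = _as_design(matrix)
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple[int, ...], float] = {}

    def repair(cols: set[int]) -> tuple[int, ...]:
        cols = set(cols)
        while len(cols) > cfg.subset_size_max:
            cols.remove(int(rng.choice(sorted(cols))))
        if not cols:
            cols = {int(rng.integers(p))}
        return tuple(sorted(cols))

    # initial population: random subsets of size 1..max
    population: list[tuple[int, ...]] = []
    for _ in range(cfg.population_size):
        size = int(rng.integers(1, cfg.subset_size_max + 1))
        population.append(
            tuple(sorted(int(c) for c in rng.choice(p, size=min(size, p), replace=False)))
        )

    best: tuple[float, tuple[int, ...]] | None = None
    history: list[float] = []
    for _gen in range(cfg.generations):
        fits = [
            _fitness_of(ind, arr, y, cfg.fitness, cache) for ind in population
        ]
        for ind, fit in zip(population, fits):
            if _better((fit, ind), best):
                best = (fit, ind)
        history.append(best[0])

        def tournament() -> tuple[int, ...]:
            i, j = rng.integers(len(population)), rng.integers(len(population))
            ci, cj = (fits[i], population[i]), (fits[j], population[j])
            return ci[1] if _better(ci, cj) or ci == cj else cj[1]

        children: list[tuple[int, ...]] = [best[1]]  # elitism
        while len(children) < cfg.population_size:
            pa, pb = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                union = set(pa) | set(pb)
                inter = set(pa) & set(pb)
                child = set(inter)
                for c in union - inter:  # uniform: each disputed bit 50/50
                    if rng.random() < 0.5:
                        child.add(c)
            else:
                child = set(pa)
            mutated = set(child)
            for c in sorted(child):
                if rng.random() < cfg.mutation_rate:
                    mutated.discard(c)
                    mutated.add(int(rng.integers(p)))
            if rng.random() < cfg.mutation_rate:
                mutated.add(int(rng.integers(p)))
            children.append(repair(mutated))
        population = children

    assert best is not None
    cols = best[1]
    sub = pd.DataFrame(arr[:, cols], columns=[names[c] for c in cols])
    model = fit_ols(sub, y)
    return GAResult(
        model=model,
        best_fitness=best[0],
        fitness_history=history,
        selected_columns=cols,
    )
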