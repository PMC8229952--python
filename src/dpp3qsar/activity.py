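"""Enzyme-assay arithmetic: % inhibition, response transform, IC50.

The assay measures residual hDPP III activity with and without inhibitor
at a fixed 10 uM concentration; percent inhibition is
(control - inhibited)/control * 100.  The QSAR response is log10 of that
percentage.  IC50 for the potent compounds is estimated by an ordinary
least-squares line of % inhibition against concentration, solved for 50%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DoseResponseSeries",
    "percent_inhibition",
    "log_response",
    "ic50_linear",
    "ActivityError",
]


class ActivityError(ValueError):
    """Raised for out-of-domain assay arithmetic."""


@dataclass(frozen=True)
class DoseResponseSeries:
    """Paired inhibitor concentrations (uM) and % inhibition values."""

    concentrations: tuple[float, ...]
    inhibitions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.inhibitions):
            raise ActivityError("concentrations and inhibitions must pair up")
        if len(self.concentrations) < 2:
            raise ActivityError("a dose-response series needs >= 2 points")
        if any(c <= 0 for c in self.concentrations):
            raise ActivityError("concentrations must be strictly positive")

    @classmethod
    def from_arrays(cls, concentrations, inhibitions) -> "DoseResponseSeries":
        return cls(
            tuple(float(c) for c in concentrations),
            tuple(float(i) for i in inhibitions),
        )


def percent_inhibition(
    control_activity: float, inhibited_activity: float
) -> float:
    """% inh. = (control - inhibited) / control * 100.

    May be negative (apparent activation); such values are flagged with a
    warning rather than clipped.
    """
    if control_activity <= 0:
        raise ActivityError("control activity must be positive")
    value = (control_activity - inhibited_activity) / control_activity * 100.0
    if value < 0:
        warnings.warn(
            f"negative % inhibition ({value:.2f}): apparent activation"
        )
    return value


def log_response(
    inhibition_pct: float | None, na_value: float = 0.0
) -> float:
    """log10 of the % inhibition; the NA sentinel maps to ``na_value``.

    Inactive compounds kept in the modeling pool carry response 0.00,
    the dataset's tabulated convention for NA rows.
    """
    if inhibition_pct is None or (
        isinstance(inhibition_pct, float) and math.isnan(inhibition_pct)
    ):
        return na_value
    if inhibition_pct < 0:
        raise ActivityError("negative % inhibition has no log response")
    if inhibition_pct == 0:
        raise ActivityError(
            "zero % inhibition has no log response; pass None for NA"
        )
    return math.log10(inhibition_pct)


def ic50_linear(series: DoseResponseSeries) -> float:
    """IC50 (uM) from the OLS line of % inhibition vs concentration.

    Fits inh = a + b*c and returns (50 - a)/b.  Warns when the estimate
    falls outside the tested concentration range; raises on a degenerate
    (zero-slope) fit or a non-positive estimate.
    """
    conc = np.asarray(series.concentrations, dtype=float)
    inh = np.asarray(series.inhibitions, dtype=float)
    if np.unique(conc).size < 2:
        raise ActivityError("need >= 2 distinct concentrations")
    fit = stats.linregress(conc, inh)
    if not np.isfinite(fit.slope) or fit.slope == 0:
        raise ActivityError("degenerate dose-response fit: zero slope")
    ic50 = (50.0 - fit.intercept) / fit.slope
    if ic50 <= 0:
        raise ActivityError(f"non-physical IC50 estimate {ic50:.3g} uM")
    if not (conc.min() <= ic50 <= conc.max()):
        warnings.warn(
            f"IC50 estimate {ic50:.3g} uM lies outside the tested range "
            f"[{conc.min():g}, {conc.max():g}] uM"
        )
    return float(ic50)
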