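"""Growth and pigmentation phenotype arithmetic.

Percent change in viable-cell number, population doubling time from
exponential growth, coefficient of variation, the ratio of trypan-blue cell
loss to supernatant dead cells (death versus cycle-arrest attribution), and
ordinary-least-squares calibration curves for melanin quantification.

Paper-facing percentages and ratios are conventionally reported rounded to
the nearest integer; each function returns the full-precision value, and
:func:`rounded` gives the reporting form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def rounded(x: float) -> int:
    """Reporting convention: nearest integer (half away from zero)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def percent_reduction(n_control: float, n_treated: float) -> float:
    """100 * (n_control - n_treated) / n_control."""
    if n_control <= 0:
        raise ValueError("control count must be positive")
    return 100.0 * (n_control - n_treated) / n_control


def doubling_time(n1: float, n2: float, delta_t_h: float) -> float:
    """Population doubling time: delta_t * ln 2 / ln(n2 / n1), in hours."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be positive")
    if delta_t_h <= 0:
        raise ValueError("time interval must be positive")
    if n2 <= n1:
        raise ValueError("no doubling: n2 must exceed n1")
    return delta_t_h * np.log(2.0) / np.log(n2 / n1)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV as a percentage: 100 * sd / mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return 100.0 * sd / mean


def death_vs_loss_ratio(
    n_control: float, n_treated: float, supernatant_dead: float
) -> float:
    """How many times the cell-number deficit exceeds the dead cells recovered
    in the supernatant: (n_control - n_treated) / supernatant_dead.

    A large ratio indicates the deficit is not explained by death alone.
    """
    if supernatant_dead <= 0:
        raise ValueError("supernatant dead count must be positive")
    if n_control <= n_treated:
        raise ValueError("control count must exceed treated count")
    return (n_control - n_treated) / supernatant_dead


@dataclass
class CalibrationCurve:
    """OLS line signal = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float

    def invert(self, y: float) -> float:
        """Concentration giving signal ``y``."""
        if self.slope == 0:
            raise ZeroDivisionError("zero slope; curve cannot be inverted")
        return (y - self.intercept) / self.slope

    def detection_limit(self) -> float:
        """Conventional 3.3 * sigma / slope limit of detection."""
        if self.slope == 0:
            raise ZeroDivisionError("zero slope")
        return 3.3 * self.residual_sd / abs(self.slope)


def fit_calibration(x_concentrations, y_signals) -> CalibrationCurve:
    """Fit an OLS calibration line through standards of known concentration."""
    x = np.asarray(x_concentrations, dtype=float)
    y = np.asarray(y_signals, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(len(x) - 2, 1)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
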