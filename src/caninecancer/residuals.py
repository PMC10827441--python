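"""Per-breed residual diagnostics around the fitted mortality curve.

Excess cancer mortality is the percent deviation of a breed's observed
lifetime cancer mortality from the multi-stage expectation at its
weight. New-observation prediction bands around the fitted curve flag
breeds with notable deviations, and an iterative Grubbs test identifies
statistically significant outliers among the raw residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_datasets import DatasetTable
from .lifespan import LifespanModel, expected_lifespan
from .multistage import MultistageFit, design_matrix

__all__ = [
    "ResidualRecord",
    "PredictionBands",
    "GrubbsOutlier",
    "excess_table",
    "prediction_bands",
    "grubbs_statistic",
    "grubbs_critical_value",
    "grubbs_pvalue",
    "grubbs_iterative",
    "flag_bands",
]

BAND_FLAGS = ("above95_2t", "above95_1t", "above90_2t", "below95_2t")


@dataclass
class ResidualRecord:
    breed_name: str
    weight_kg: float
    observed: float
    predicted: float
    band_flags: set[str] = field(default_factory=set)
    grubbs: tuple[float, float, int] | None = None  # (G, p bound, removal order)

    @property
    def raw_residual(self) -> float:
        return self.observed - self.predicted

    @property
    def excess_cancer_pct(self) -> float:
        return 100.0 * self.raw_residual / self.predicted


@dataclass
class PredictionBands:
    """New-observation bands around the fitted mortality curve."""

    weights: np.ndarray
    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    tails: str  # "one" or "two"


@dataclass(frozen=True)
class GrubbsOutlier:
    index: int
    value: float
    G: float
    p_bound: float
    order_removed: int


def excess_table(
    table: DatasetTable, fit: MultistageFit, lifespan_model: LifespanModel
) -> list[ResidualRecord]:
    """One residual record per breed; band flags left unset."""
    records = []
    for rec in table:
        t = expected_lifespan(lifespan_model, rec.weight_kg)
        pred = float(
            sum(
                fit.coefficients[m].estimate * rec.weight_kg * t**m
                for m in fit.powers
            )
        )
        if pred <= 0:
            raise ValueError(
                f"{rec.breed_name!r}: nonpositive predicted mortality {pred}"
            )
        records.append(
            ResidualRecord(
                breed_name=rec.breed_name,
                weight_kg=rec.weight_kg,
                observed=rec.cancer_mortality,
                predicted=pred,
            )
        )
    return records


def prediction_bands(
    fit: MultistageFit,
    lifespan_model: LifespanModel,
    weight_grid: Sequence[float],
    level: float = 0.95,
    tails: str = "two",
) -> PredictionBands:
    """Prediction bands for a new breed-level observation.

    Half-width t_{q, n-k} * s * sqrt(1 + x'(X'X)^-1 x) with q =
    1-(1-level)/2 for two-tailed bands and q = level for one-tailed; x is
    the design row at the grid weight.
    """
    if tails not in {"one", "two"}:
        raise ValueError("tails must be 'one' or 'two'")
    if fit.xtx_inv is None or not np.isfinite(fit.sigma2):
        raise ValueError("fit carries no design information for bands")
    w = np.asarray(weight_grid, dtype=float)
    t = expected_lifespan(lifespan_model, w)
    t = np.atleast_1d(np.asarray(t, float))
    w1 = np.atleast_1d(w)
    X = design_matrix(w1, t, fit.powers)
    center = X @ fit.coefficient_vector()
    q = level if tails == "one" else 1.0 - (1.0 - level) / 2.0
    df = fit.n - len(fit.powers)
    tcrit = stats.t.ppf(q, df)
    leverage = np.einsum("ij,jk,ik->i", X, fit.xtx_inv, X)
    half = tcrit * np.sqrt(fit.sigma2) * np.sqrt(1.0 + leverage)
    return PredictionBands(
        weights=w1,
        center=center,
        lower=center - half,
        upper=center + half,
        level=level,
        tails=tails,
    )


# ---------------------------------------------------------------------------
# Grubbs outlier test


def grubbs_statistic(values: np.ndarray) -> tuple[int, float]:
    """(index, G) of the most extreme standardized deviation."""
    mean = values.mean()
    sd = values.std(ddof=1)
    dev = np.abs(values - mean)
    idx = int(np.argmax(dev))
    return idx, float(dev[idx] / sd)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value at level alpha for sample size n."""
    t2 = stats.t.isf(alpha / (2.0 * n), n - 2) ** 2
    return ((n - 1) / np.sqrt(n)) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_pvalue(G: float, n: int) -> float:
    """Approximate two-sided p-value for an observed Grubbs statistic.

    Inverts the critical-value relation back to a t quantile and applies
    the Bonferroni bound over the n candidate points; capped at 1.
    """
    denom = (n - 1) ** 2 - n * G**2
    if denom <= 0:
        return 0.0
    t2 = (n - 2) * n * G**2 / denom
    return float(min(1.0, 2.0 * n * stats.t.sf(np.sqrt(t2), n - 2)))


def grubbs_iterative(
    residuals: Sequence[float], alpha: float = 0.05
) -> list[GrubbsOutlier]:
    """Repeatedly apply the Grubbs test, deleting each detected outlier.

    Detection order is by decreasing absolute deviation: only the most
    extreme remaining value is ever tested. Returns the outliers in the
    order removed, each with its G statistic and two-sided p bound.
    """
    values = np.asarray(residuals, dtype=float)
    if values.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    remaining = list(range(values.size))
    out: list[GrubbsOutlier] = []
    order = 0
    while len(remaining) >= 3:
        sub = values[remaining]
        if sub.std(ddof=1) == 0:
            warnings.warn("zero variance: no outliers detectable", RuntimeWarning)
            break
        local_idx, G = grubbs_statistic(sub)
        n = len(remaining)
        if G <= grubbs_critical_value(n, alpha):
            break
        order += 1
        global_idx = remaining.pop(local_idx)
        out.append(
            GrubbsOutlier(
                index=global_idx,
                value=float(values[global_idx]),
                G=G,
                p_bound=grubbs_pvalue(G, n),
                order_removed=order,
            )
        )
    return out


def flag_bands(
    records: Sequence[ResidualRecord],
    fit: MultistageFit,
    lifespan_model: LifespanModel,
) -> list[ResidualRecord]:
    """Set band-exceedance flags on each record (strict inequalities).

    Flags: above/below the two-tailed 95% band, above the one-tailed 95%
    band, and above the two-tailed 90% band, each evaluated at the
    breed's own weight.
    """
    weights = [r.weight_kg for r in records]
    b95_2 = prediction_bands(fit, lifespan_model, weights, level=0.95, tails="two")
    b95_1 = prediction_bands(fit, lifespan_model, weights, level=0.95, tails="one")
    b90_2 = prediction_bands(fit, lifespan_model, weights, level=0.90, tails="two")
    for i, rec in enumerate(records):
        flags = set()
        if rec.observed > b95_2.upper[i]:
            flags.add("above95_2t")
        if rec.observed > b95_1.upper[i]:
            flags.add("above95_1t")
        if rec.observed > b90_2.upper[i]:
            flags.add("above90_2t")
        if rec.observed < b95_2.lower[i]:
            flags.add("below95_2t")
        rec.band_flags = flags
    return list(records)
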