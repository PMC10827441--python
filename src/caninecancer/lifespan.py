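"""Weight-lifespan allometry across dog breeds.

Large breeds die younger: median lifespan declines close to linearly
with adult weight, T = a - b*W. The regression-predicted lifespan (never
the registry value) feeds the carcinogenesis fit, so that a breed's own
cancer mortality cannot leak into the lifespan used to predict it.
Registry ("observed") lifespans are only compared with the prediction to
form excess-longevity residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_datasets import hierarchical_mean

__all__ = [
    "LifespanModel",
    "LongevityResidual",
    "DEFAULT_LIFESPAN",
    "fit_weight_lifespan",
    "pool_regressions",
    "expected_lifespan",
    "observed_lifespan_from_ranges",
    "excess_longevity",
]


@dataclass(frozen=True)
class LifespanModel:
    """The linear lifespan law T = a - b*W (b stored positive)."""

    intercept_a: float
    slope_b: float
    n_breeds: int
    fit_r2: float | None = None

    def __post_init__(self) -> None:
        if self.intercept_a <= 0:
            raise ValueError(f"intercept must be positive, got {self.intercept_a}")
        if self.slope_b < 0:
            raise ValueError(f"slope must be nonnegative, got {self.slope_b}")

    @property
    def max_weight(self) -> float:
        """Largest weight with a positive predicted lifespan."""
        if self.slope_b == 0:
            return np.inf
        return self.intercept_a / self.slope_b

    def predict(self, weight_kg):
        return expected_lifespan(self, weight_kg)


#: Pooled default law used throughout the breed analyses.
DEFAULT_LIFESPAN = LifespanModel(intercept_a=13.3, slope_b=0.08, n_breeds=158)


@dataclass(frozen=True)
class LongevityResidual:
    """Percent deviation of a breed's registry lifespan from the size law."""

    breed_name: str
    expected_T: float
    observed_T: float

    @property
    def excess_longevity_pct(self) -> float:
        return excess_longevity(self.observed_T, self.expected_T)


def fit_weight_lifespan(
    weights: Sequence[float],
    lifespans: Sequence[float],
    group_sizes: Sequence[int] | None = None,
) -> LifespanModel:
    """OLS fit of the declining lifespan law T = a - b*W.

    ``group_sizes`` records how many breeds each point represents (points
    may be breed-group means); their sum becomes the pooling weight
    ``n_breeds``. The regression itself is unweighted.
    """
    w = np.asarray(weights, dtype=float)
    t = np.asarray(lifespans, dtype=float)
    if w.size != t.size:
        raise ValueError("weights and lifespans differ in length")
    if w.size < 3:
        raise ValueError(f"need at least 3 points, got {w.size}")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.ptp(w) == 0:
        raise np.linalg.LinAlgError("constant weights: slope is unidentifiable")
    slope, intercept = np.polyfit(w, t, 1)
    if 0 < slope < 1e-10:  # numerically flat line
        slope = 0.0
    resid = t - (intercept + slope * w)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    n = int(sum(group_sizes)) if group_sizes is not None else int(w.size)
    return LifespanModel(
        intercept_a=float(intercept),
        slope_b=float(-slope),
        n_breeds=n,
        fit_r2=r2,
    )


def pool_regressions(models: Sequence[LifespanModel]) -> LifespanModel:
    """Pool published regressions by breed-number-weighted coefficient means.

    Coefficients are averaged (weighted by each model's ``n_breeds``)
    rather than refitting stacked data, because the inputs are published
    fitted lines, not raw points.
    """
    if len(models) < 2:
        raise ValueError("pooling needs at least two models")
    n = np.array([m.n_breeds for m in models], dtype=float)
    if n.sum() <= 0:
        raise ValueError("total breed weight is zero")
    a = float(np.average([m.intercept_a for m in models], weights=n))
    b = float(np.average([m.slope_b for m in models], weights=n))
    return LifespanModel(intercept_a=a, slope_b=b, n_breeds=int(n.sum()))


def expected_lifespan(model: LifespanModel, weight_kg):
    """Predicted lifespan a - b*W; errors where the line goes nonpositive."""
    w = np.asarray(weight_kg, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight must be positive")
    t = model.intercept_a - model.slope_b * w
    if np.any(t <= 0):
        raise ValueError(
            f"weight beyond the supported domain (max {model.max_weight:.1f} kg): "
            "predicted lifespan is nonpositive"
        )
    return float(t) if np.isscalar(weight_kg) else t


def observed_lifespan_from_ranges(
    ranges: Mapping[str, tuple[float | None, float | None]],
) -> float:
    """Registry lifespan from per-sex (low, high) ranges.

    Hierarchical mean: within sex, then between sexes; no outlier
    screening (there is a single registry source).
    """
    return hierarchical_mean(ranges)


def excess_longevity(observed_T: float, expected_T: float) -> float:
    """Percent deviation of observed from size-predicted lifespan."""
    if expected_T <= 0:
        raise ValueError("expected lifespan must be positive")
    return 100.0 * (observed_T - expected_T) / expected_T
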