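"""Multi-stage carcinogenesis model fitting and selection.

The multi-stage model predicts that the lifetime probability of a cancer
requiring M driver mutations scales as (cell number) x (divisions per
cell)^M. Taking breed cell number proportional to weight W and divisions
proportional to lifespan T, breed-level lifetime cancer mortality is
modelled as a positive combination of terms W*T^m over candidate driver
counts m in {2..6}:

    p_k = A2*W_k*T_k^2 + A3*W_k*T_k^3 + ... + A6*W_k*T_k^6

with T_k predicted from weight by the lifespan law and no intercept (a
weightless breed has no cells at risk). The model is linear in the A_m,
so constrained stepwise selection reduces to comparing exact linear
least-squares fits by AIC, keeping only terms with significantly
positive coefficients.

The same model compared across species at their evolutionary cancer-risk
equilibrium yields the product u*k (driver mutation probability per
division x divisions per year), calibrating the somatic parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .io_datasets import DatasetTable
from .lifespan import LifespanModel, expected_lifespan

__all__ = [
    "CANDIDATE_POWERS",
    "CoefficientStats",
    "MultistageFit",
    "CandidateRow",
    "ModelSelectionReport",
    "CrossSpeciesParams",
    "design_matrix",
    "fit_fixed_powers",
    "aic",
    "stepwise_select",
    "predict",
    "solve_cross_species",
    "division_rate",
]

#: Driver-mutation counts considered biologically plausible.
CANDIDATE_POWERS = (2, 3, 4, 5, 6)


class CoefficientStats(NamedTuple):
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class MultistageFit:
    """A fitted positive-power model for one set of candidate powers."""

    powers: tuple[int, ...]
    coefficients: dict[int, CoefficientStats]
    n: int
    rss: float
    aic: float
    alpha: float = 0.05
    sigma2: float = field(default=np.nan, repr=False)
    xtx_inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def all_positive(self) -> bool:
        return all(c.estimate > 0 for c in self.coefficients.values())

    @property
    def all_significant(self) -> bool:
        return all(c.p < self.alpha for c in self.coefficients.values())

    @property
    def admissible(self) -> bool:
        """Every coefficient positive and significant, as the model requires."""
        return self.all_positive and self.all_significant

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[m].estimate for m in self.powers])


@dataclass
class CandidateRow:
    powers: tuple[int, ...]
    fit: MultistageFit
    delta_aic: float
    stepwise: bool = False


@dataclass
class ModelSelectionReport:
    """Machine twin of the stepwise candidate table."""

    candidates: list[CandidateRow]
    best: MultistageFit
    equivalent_set: list[CandidateRow]
    reference_powers: tuple[int, ...]

    def row(self, powers: Sequence[int]) -> CandidateRow | None:
        key = tuple(sorted(powers))
        for c in self.candidates:
            if c.powers == key:
                return c
        return None

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.candidates:
            label = " & ".join(f"W.T^{m}" for m in c.powers)
            rows.append(
                {
                    "model": label,
                    "powers": ",".join(map(str, c.powers)),
                    "delta_aic": c.delta_aic,
                    "aic": c.fit.aic,
                    "rss": c.fit.rss,
                    "all_positive": c.fit.all_positive,
                    "all_significant": c.fit.all_significant,
                    "equivalent_to_best": c in self.equivalent_set,
                    "stepwise_path": c.stepwise,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design and fitting


def design_matrix(
    weights: Sequence[float], lifespans: Sequence[float], powers: Sequence[int]
) -> np.ndarray:
    """Columns W*T^m for each candidate power m; never an intercept."""
    powers = tuple(powers)
    if not powers:
        raise ValueError("at least one power is required")
    w = np.asarray(weights, dtype=float)
    t = np.asarray(lifespans, dtype=float)
    if w.shape != t.shape:
        raise ValueError("weights and lifespans differ in length")
    if np.any(t <= 0):
        raise ValueError("lifespans must be positive")
    return np.column_stack([w * t**m for m in powers])


def aic(rss: float, n: int, k_params: int) -> float:
    """Gaussian least-squares AIC, error variance counted as a parameter.

    AIC = n*ln(rss/n) + 2*(k+1). Only differences between candidate fits
    on the same data are meaningful.
    """
    if n <= k_params:
        raise ValueError("n must exceed the number of parameters")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0:
        warnings.warn("perfect fit: AIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (k_params + 1)


def _aicc(rss: float, n: int, k_params: int) -> float:
    k = k_params + 1  # incl. error variance
    base = aic(rss, n, k_params)
    if n - k - 1 <= 0:
        raise ValueError("n too small for AICc")
    return base + 2.0 * k * (k + 1) / (n - k - 1)


def fit_fixed_powers(
    table: DatasetTable,
    lifespan_model: LifespanModel,
    powers: Sequence[int],
    alpha: float = 0.05,
    aic_variant: str = "aic",
    lifespans: Sequence[float] | None = None,
) -> MultistageFit:
    """Zero-intercept least squares of cancer mortality on W*T^m terms.

    The model is linear in the A_m, so the direct linear solution is the
    global optimum any iterative least-squares minimiser must reach.
    Per-coefficient standard errors, t = A/se and two-sided p-values use
    the usual OLS covariance on n - |powers| residual degrees of freedom.
    ``lifespans`` overrides the lifespan-law prediction (used for
    diagnostics; the pipeline always predicts T from weight).
    """
    powers = tuple(sorted(set(int(m) for m in powers)))
    w = table.weights()
    y = table.mortalities()
    n = w.size
    if n < len(powers) + 2:
        raise ValueError(
            f"need at least {len(powers) + 2} breeds for powers {powers}, got {n}"
        )
    t = np.asarray(lifespans, float) if lifespans is not None else expected_lifespan(lifespan_model, w)
    X = design_matrix(w, t, powers)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient design for powers {powers}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    k = len(powers)
    crit = _aicc(rss, n, k) if aic_variant == "aicc" else aic(rss, n, k)
    coefficients = {
        m: CoefficientStats(
            estimate=float(res.params[j]),
            se=float(res.bse[j]),
            t=float(res.tvalues[j]),
            p=float(res.pvalues[j]),
        )
        for j, m in enumerate(powers)
    }
    return MultistageFit(
        powers=powers,
        coefficients=coefficients,
        n=n,
        rss=rss,
        aic=crit,
        alpha=alpha,
        sigma2=rss / (n - k),
        xtx_inv=np.linalg.inv(X.T @ X),
    )


def _prune(fit: MultistageFit) -> tuple[int, ...]:
    """Powers surviving the positivity/significance screen."""
    return tuple(
        m
        for m in fit.powers
        if fit.coefficients[m].estimate > 0 and fit.coefficients[m].p < fit.alpha
    )


def stepwise_select(
    table: DatasetTable,
    lifespan_model: LifespanModel,
    alpha: float = 0.05,
    aic_variant: str = "aic",
    reference_powers: Sequence[int] = (4,),
    equivalence_delta: float = 2.0,
) -> ModelSelectionReport:
    """Constrained stepwise selection over the candidate powers.

    Starting from the lowest power {2}, the next higher power is added at
    each step; after each fit, terms with negative or non-significant
    coefficients are discarded before the next addition. The walk stops
    once the newly added higher power fails the screen while the retained
    set is fully positive-significant. Every single-power model and every
    contiguous pair is also fitted so the report covers the full
    candidate table. Candidates within ``equivalence_delta`` AIC units of
    the best admissible fit, and themselves admissible, form the
    equivalent set.
    """

    fits: dict[tuple[int, ...], MultistageFit] = {}
    stepwise_path: set[tuple[int, ...]] = set()

    def _fit(powers: Sequence[int]) -> MultistageFit:
        key = tuple(sorted(set(powers)))
        if key not in fits:
            fits[key] = fit_fixed_powers(
                table, lifespan_model, key, alpha=alpha, aic_variant=aic_variant
            )
        return fits[key]

    # Stepwise walk.
    current: tuple[int, ...] = ()
    for m in CANDIDATE_POWERS:
        trial = tuple(sorted(set(current) | {m}))
        fit = _fit(trial)
        stepwise_path.add(trial)
        retained = _prune(fit)
        if not retained:
            # Everything failed the screen; continue from the new power alone
            # so the walk can keep climbing.
            current = (m,)
            continue
        if retained != trial:
            fit_retained = _fit(retained)
            stepwise_path.add(retained)
            if m not in retained and _prune(fit_retained) == retained:
                current = retained
                break
            current = retained
        else:
            current = trial

    # Exhaustive single powers and contiguous pairs (the printed table rows).
    for m in CANDIDATE_POWERS:
        _fit((m,))
    for m in CANDIDATE_POWERS[:-1]:
        _fit((m, m + 1))

    reference = _fit(reference_powers)
    candidates = [
        CandidateRow(
            powers=key,
            fit=f,
            delta_aic=f.aic - reference.aic,
            stepwise=key in stepwise_path,
        )
        for key, f in sorted(fits.items(), key=lambda kv: (min(kv[0]), len(kv[0]), kv[0]))
    ]
    admissible = [c for c in candidates if c.fit.admissible]
    if not admissible:
        raise RuntimeError("no candidate model has all-positive significant terms")
    best = min(admissible, key=lambda c: c.fit.aic).fit
    equivalent = [
        c
        for c in admissible
        if abs(c.fit.aic - best.aic) < equivalence_delta
    ]
    return ModelSelectionReport(
        candidates=candidates,
        best=best,
        equivalent_set=equivalent,
        reference_powers=tuple(sorted(reference_powers)),
    )


def predict(fit: MultistageFit, lifespan_model: LifespanModel, weight_kg):
    """Model-expected cancer mortality at a weight; clipped to [0, 1]."""
    w = np.asarray(weight_kg, dtype=float)
    t = expected_lifespan(lifespan_model, w)
    t = np.asarray(t, dtype=float)
    p = np.zeros_like(w, dtype=float)
    for m in fit.powers:
        p = p + fit.coefficients[m].estimate * w * t**m
    if np.any(p < 0) or np.any(p > 1):
        warnings.warn(
            "predicted mortality outside [0, 1]; clipping for reporting",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(weight_kg) else p


# ---------------------------------------------------------------------------
# Cross-species calibration


@dataclass(frozen=True)
class CrossSpeciesParams:
    """Two species at the same equilibrium lifetime cancer risk.

    ``cell_ratio`` is C_high/C_low (e.g. human/wolf cell number),
    ``lifespan_ratio`` T_high/T_low, ``t_low`` the reproductive life of
    the smaller species in years, and ``m_high``/``m_low`` their driver
    mutation counts.
    """

    cell_ratio: float
    lifespan_ratio: float
    t_low: float
    m_high: int
    m_low: int

    def __post_init__(self) -> None:
        for name in ("cell_ratio", "lifespan_ratio", "t_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_high == self.m_low:
            raise ValueError("m_high = m_low leaves u*k unidentified")


def solve_cross_species(params: CrossSpeciesParams) -> float:
    """Solve C_h*(uk*T_h)^Mh = C_l*(uk*T_l)^Ml for the product u*k.

    Closed form: uk = [cell_ratio * lifespan_ratio^Mh *
    t_low^(Mh-Ml)]^(-1/(Mh-Ml)), in per-year units.
    """
    dm = params.m_high - params.m_low
    return float(
        (params.cell_ratio * params.lifespan_ratio**params.m_high * params.t_low**dm)
        ** (-1.0 / dm)
    )


def division_rate(uk: float, u: float) -> tuple[float, int]:
    """Split u*k into a division rate given a per-division mutation rate.

    Returns (k divisions/year, days per division rounded to the nearest
    day).
    """
    if u <= 0:
        raise ValueError("u must be positive")
    k = uk / u
    return k, int(round(365.0 / k))
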