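"""Associations of residual cancer risk and longevity with inbreeding and clades.

Pearson correlations of per-breed excess cancer mortality and excess
longevity with published inbreeding proxies (SNP- and WGS-based
inbreeding coefficients, runs of homozygosity, genome-wide lack of
heterozygosity, MHC diversity); one-way ANOVA of excess cancer mortality
across breed clades with Fisher's LSD a-posteriori comparisons; and
exact two-sided sign tests for clades deviating consistently above or
below expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_datasets import INBREEDING_MEASURES, DatasetTable
from .residuals import ResidualRecord

__all__ = [
    "AssociationResult",
    "CladeSummary",
    "AnovaResult",
    "pearson",
    "correlation_matrix",
    "clade_summaries",
    "clade_anova",
    "sign_test",
]


@dataclass(frozen=True)
class AssociationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CladeSummary:
    clade: str
    n_breeds: int
    mean_excess_pct: float
    mean_weight: float
    mean_mortality: float
    n_above: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    msw: float
    lsd: pd.DataFrame  # pairwise clade comparisons


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> AssociationResult:
    """Pearson r with a two-sided t-based p-value; listwise deletion."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y differ in length")
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    if xa.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {xa.size}")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(xa, ya)
    return AssociationResult(
        x_name=x_name, y_name=y_name, r=float(res.statistic), p=float(res.pvalue), n=int(xa.size)
    )


def correlation_matrix(
    frames: Mapping[str, pd.DataFrame],
    y_columns: Sequence[str] = ("excess_cancer_pct", "excess_longevity_pct"),
    measures: Sequence[str] = INBREEDING_MEASURES,
    min_pairs: int = 3,
) -> list[AssociationResult]:
    """Correlation cells for each (inbreeding measure, dataset, outcome).

    ``frames`` maps a dataset label to a per-breed frame carrying a
    ``breed`` column, the outcome columns, and whatever inbreeding
    measure columns exist. Each cell uses its own complete pairs
    (listwise deletion), so n varies across cells; cells with fewer than
    ``min_pairs`` pairs, or with no measure column at all, are simply
    absent from the output.
    """
    out: list[AssociationResult] = []
    for label, df in frames.items():
        if df["breed"].str.strip().str.casefold().duplicated().any():
            raise ValueError(f"duplicate breed rows in dataset {label!r}")
        for y_col in y_columns:
            if y_col not in df.columns:
                continue
            for m in measures:
                if m not in df.columns:
                    continue
                pair = df[[m, y_col]].dropna()
                if len(pair) < min_pairs:
                    continue
                try:
                    res = pearson(
                        pair[m], pair[y_col], x_name=m, y_name=f"{y_col}[{label}]"
                    )
                except ValueError:
                    continue
                out.append(res)
    return out


def clade_summaries(
    table: DatasetTable,
    residuals: Sequence[ResidualRecord] | None = None,
    clade_map: Mapping[str, str] | None = None,
    min_breeds: int = 3,
) -> list[CladeSummary]:
    """Unweighted per-clade means; clades below ``min_breeds`` dropped.

    Clade labels come from the records unless ``clade_map`` (breed ->
    clade) overrides them. Excess percentages require matching residual
    records.
    """
    excess = {}
    if residuals is not None:
        excess = {r.breed_name: r.excess_cancer_pct for r in residuals}
    groups: dict[str, list] = {}
    for rec in table:
        clade = (clade_map or {}).get(rec.breed_name, rec.clade)
        if clade is None:
            continue
        groups.setdefault(clade, []).append(rec)
    out = []
    for clade, recs in sorted(groups.items()):
        if len(recs) < min_breeds:
            continue
        ex = [excess[r.breed_name] for r in recs if r.breed_name in excess]
        out.append(
            CladeSummary(
                clade=clade,
                n_breeds=len(recs),
                mean_excess_pct=float(np.mean(ex)) if ex else float("nan"),
                mean_weight=float(np.mean([r.weight_kg for r in recs])),
                mean_mortality=float(np.mean([r.cancer_mortality for r in recs])),
                n_above=sum(1 for e in ex if e > 0),
            )
        )
    return out


def clade_anova(
    excess_by_clade: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Fisher's LSD pairwise comparisons.

    Clades with fewer than two breeds carry no within-clade variance and
    are excluded with a warning. LSD uses the pooled within-clade mean
    square and its residual degrees of freedom; no family-wise
    correction is applied.
    """
    import warnings

    groups: dict[str, np.ndarray] = {}
    for clade, vals in excess_by_clade.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.warn(
                f"clade {clade!r} has fewer than 2 breeds; excluded", RuntimeWarning
            )
            continue
        groups[clade] = arr
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two clades with >= 2 breeds")
    names = sorted(groups)
    all_vals = np.concatenate([groups[c] for c in names])
    grand = all_vals.mean()
    n_total = all_vals.size
    g = len(names)
    ssb = sum(groups[c].size * (groups[c].mean() - grand) ** 2 for c in names)
    ssw = sum(float(np.sum((groups[c] - groups[c].mean()) ** 2)) for c in names)
    df_b, df_w = g - 1, n_total - g
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        F = np.inf
        p = 0.0
    else:
        F = msb / msw
        p = float(stats.f.sf(F, df_b, df_w))
    rows = []
    for i, ci in enumerate(names):
        for cj in names[i + 1 :]:
            diff = groups[ci].mean() - groups[cj].mean()
            se = np.sqrt(msw * (1.0 / groups[ci].size + 1.0 / groups[cj].size))
            t = diff / se if se > 0 else np.inf
            p_ij = float(2.0 * stats.t.sf(abs(t), df_w))
            rows.append(
                {
                    "clade_i": ci,
                    "clade_j": cj,
                    "mean_diff": diff,
                    "t": t,
                    "p": p_ij,
                    "significant": p_ij < alpha,
                }
            )
    return AnovaResult(
        F=float(F),
        p=p,
        df_between=df_b,
        df_within=df_w,
        msw=float(msw),
        lsd=pd.DataFrame(rows),
    )


def sign_test(n_positive: int, n: int) -> float:
    """Exact two-sided sign test at p0 = 1/2.

    p = 2 * min(P(X <= k), P(X >= k)) under Binomial(n, 1/2), capped at 1.
    """
    if not (0 <= n_positive <= n):
        raise ValueError("n_positive must lie in [0, n]")
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(
        stats.binomtest(n_positive, n, 0.5, alternative="two-sided").pvalue
    )
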