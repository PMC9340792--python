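"""Lifespan baselines, per-year rates, group slope contrasts and per-decade
scaling-exponent fits on harmonized tables.

Rates for the primary variables are fit on the (back-transformed,
harmonized) measurement scale so they read in natural units (mm/year,
mm^2/year); the folding variables K, S, I and GI are fit as-is.  Group
slope differences are tested through the age x group interaction (Wald t),
with optional Bonferroni or Tukey (studentized-range) family-wise
adjustment; the sign convention is second group minus first group in the
order supplied (so ``groups=("CTL", "AD")`` reports AD - CTL).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import as_frame
from .folding_geometry import ScalingFit, fit_alpha
from .uncertainty_budget import UncertaintyBudget

logger = logging.getLogger(__name__)

ADJUSTMENTS = ("none", "bonferroni", "tukey")


@dataclass(frozen=True)
class TrajectoryFit:
    """Least-squares line of one variable on age within a (group, ROI) cell."""

    variable: str
    group: str
    roi: str
    slope: float
    intercept: float
    slope_se: float
    ci95: tuple
    percent_per_year: float
    reference_age: float
    n: int


@dataclass(frozen=True)
class SlopeContrast:
    variable: str
    roi: str
    group_a: str
    group_b: str
    estimate: float  # slope(group_b) - slope(group_a)
    se: float
    p_value: float
    p_adjusted: float
    adjustment: str


@dataclass
class AlphaByDecade:
    """Per-decade scaling-exponent fits for one group.

    ``bins`` lists (low, high, n, fit-or-None); bins with n below ``min_n``
    are fit-less and echoed in ``omitted``.
    """

    group: str
    min_n: int
    bins: list = field(default_factory=list)
    omitted: list = field(default_factory=list)


def _cell_line(ages: np.ndarray, values: np.ndarray):
    res = stats.linregress(ages, values)
    n = ages.size
    se = float(res.stderr) if res.stderr is not None else math.nan
    if n >= 3 and se > 0:
        t = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - t * se, res.slope + t * se)
    else:
        ci = (res.slope, res.slope)
    return float(res.slope), float(res.intercept), se, (float(ci[0]), float(ci[1]))


def fit_trajectories(
    data,
    variables,
    groups=None,
    rois=None,
    reference_age: float | None = None,
) -> list:
    """Per-(variable, group, ROI) lines of value on age.

    ``percent_per_year`` divides the slope by the fitted value at
    ``reference_age`` (default: the healthy-control grand mean age of the
    input, echoed on every fit).  Cells with fewer than 3 distinct ages are
    skipped with a warning.
    """
    df = as_frame(data)
    if groups is None:
        groups = tuple(sorted(df["group"].unique()))
    if rois is None:
        rois = tuple(sorted(df["roi"].unique()))
    if reference_age is None:
        ctl = df[df["group"] == "CTL"]
        base = ctl if len(ctl) else df
        reference_age = float(base["age_years"].mean())
    fits = []
    for variable in variables:
        for group in groups:
            for roi in rois:
                cell = df[(df["group"] == group) & (df["roi"] == roi)]
                ages = cell["age_years"].to_numpy(float)
                if cell.empty or np.unique(ages).size < 3:
                    logger.warning(
                        "skipping degenerate cell variable=%s group=%s roi=%s",
                        variable, group, roi,
                    )
                    continue
                vals = cell[variable].to_numpy(float)
                slope, intercept, se, ci = _cell_line(ages, vals)
                at_ref = intercept + slope * reference_age
                pct = 100.0 * slope / at_ref if at_ref != 0 else math.nan
                fits.append(
                    TrajectoryFit(
                        variable=variable,
                        group=group,
                        roi=roi,
                        slope=slope,
                        intercept=intercept,
                        slope_se=se,
                        ci95=ci,
                        percent_per_year=pct,
                        reference_age=reference_age,
                        n=int(ages.size),
                    )
                )
    return fits


def _group_slopes(cell: pd.DataFrame, variable: str, groups):
    """Joint OLS value ~ age x group; returns per-group slopes, the
    covariance of the slope estimates and the residual dof."""
    frames = [cell[cell["group"] == g] for g in groups]
    if any(f.empty for f in frames):
        raise ValueError("every contrasted group needs data in the cell")
    X_parts, y_parts = [], []
    k = len(groups)
    for gi, f in enumerate(frames):
        ages = f["age_years"].to_numpy(float)
        n = ages.size
        block = np.zeros((n, 2 * k))
        block[:, 2 * gi] = 1.0
        block[:, 2 * gi + 1] = ages
        X_parts.append(block)
        y_parts.append(f[variable].to_numpy(float))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(y.size - 2 * k, 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    slopes = beta[1::2]
    cov = s2 * xtx_inv[1::2, 1::2]
    return slopes, cov, dof


def compare_slopes(
    data,
    variable: str,
    groups,
    rois=None,
    adjustment: str = "tukey",
) -> list:
    """Pairwise group differences in the age slope, per ROI.

    Each ROI cell is fit as separate lines per group (equivalently the full
    age x group interaction model); the contrast slope(g_b) - slope(g_a) is
    tested with a Wald t against the residual dof.  Adjustment: ``none``,
    ``bonferroni`` (across every contrast produced by the call) or ``tukey``
    (studentized range across the groups of a cell).
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; choose from {ADJUSTMENTS}")
    df = as_frame(data)
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups to contrast")
    if rois is None:
        rois = tuple(sorted(df["roi"].unique()))
    k = len(groups)
    raw = []
    for roi in rois:
        cell = df[df["roi"] == roi]
        slopes, cov, dof = _group_slopes(cell, variable, groups)
        for ia, ib in itertools.combinations(range(k), 2):
            est = float(slopes[ib] - slopes[ia])
            var = float(cov[ia, ia] + cov[ib, ib] - 2 * cov[ia, ib])
            se = math.sqrt(max(var, 0.0))
            if se == 0:
                t = 0.0 if est == 0 else math.inf
            else:
                t = est / se
            p = float(2 * stats.t.sf(abs(t), dof)) if math.isfinite(t) else 0.0
            if adjustment == "tukey":
                q = abs(t) * math.sqrt(2.0)
                p_adj = float(stats.studentized_range.sf(q, k, dof)) if math.isfinite(t) else 0.0
            else:
                p_adj = p
            raw.append([variable, roi, groups[ia], groups[ib], est, se, p, p_adj])
    m = len(raw)
    out = []
    for row in raw:
        variable_, roi, ga, gb, est, se, p, p_adj = row
        if adjustment == "bonferroni":
            p_adj = min(1.0, p * m)
        p_adj = max(p_adj, p) if adjustment != "none" else p
        out.append(
            SlopeContrast(
                variable=variable_,
                roi=roi,
                group_a=ga,
                group_b=gb,
                estimate=est,
                se=se,
                p_value=p,
                p_adjusted=p_adj,
                adjustment=adjustment,
            )
        )
    return out


DECADES = tuple((lo, lo + 10) for lo in range(0, 100, 10))


def alpha_by_decade(data, min_n: int = 10, groups=None) -> dict:
    """Scaling-exponent fits per 10-year age bin and group.

    Bins partition [0, 100) (the last bin includes age 100); bins with
    fewer than ``min_n`` rows are omitted and listed with their counts.
    """
    df = as_frame(data)
    if df.empty:
        raise ValueError("empty input")
    if groups is None:
        groups = tuple(sorted(df["group"].unique()))
    out = {}
    for group in groups:
        sub = df[df["group"] == group]
        res = AlphaByDecade(group=group, min_n=min_n)
        for lo, hi in DECADES:
            upper_closed = hi >= 100
            sel = (sub["age_years"] >= lo) & (
                (sub["age_years"] <= hi) if upper_closed else (sub["age_years"] < hi)
            )
            cell = sub[sel]
            n = int(len(cell))
            if n < max(min_n, 2):
                res.bins.append((lo, hi, n, None))
                if n > 0:
                    res.omitted.append((lo, hi, n))
                continue
            try:
                fit = fit_alpha(cell)
            except ValueError:
                res.bins.append((lo, hi, n, None))
                res.omitted.append((lo, hi, n))
                continue
            res.bins.append((lo, hi, n, fit))
        out[group] = res
    return out


@dataclass(frozen=True)
class BaselineEntry:
    """A normative band: value(age) = intercept + slope * age +/- sigma_total."""

    variable: str
    group: str
    roi: str
    intercept: float
    slope: float
    reference_age: float
    sigma_total: float | None

    def band(self, age: float):
        mid = self.intercept + self.slope * age
        if self.sigma_total is None:
            return (math.nan, mid, math.nan)
        return (mid - self.sigma_total, mid, mid + self.sigma_total)

    @property
    def no_band(self) -> bool:
        return self.sigma_total is None


def baseline_table(fits, budgets) -> list:
    """Join trajectory fits with uncertainty budgets into baseline bands.

    ``budgets`` maps variable name to :class:`UncertaintyBudget` (or is a
    budget list).  A fit whose variable is missing from a *non-empty*
    budget set raises; with an empty budget set entries are emitted without
    bands and flagged.
    """
    if not isinstance(budgets, dict):
        budgets = {b.variable: b for b in budgets}
    entries = []
    for fit in fits:
        if budgets:
            budget = budgets.get(fit.variable)
            if budget is None:
                raise ValueError(f"no uncertainty budget for variable {fit.variable!r}")
            sigma = budget.sigma_total
        else:
            sigma = None
        entries.append(
            BaselineEntry(
                variable=fit.variable,
                group=fit.group,
                roi=fit.roi,
                intercept=fit.intercept,
                slope=fit.slope,
                reference_age=fit.reference_age,
                sigma_total=sigma,
            )
        )
    return entries
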