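"""Uncertainty budgets: sigma_Natural, sigma_Random, sigma_Sample and their
quadrature total per variable.

Three uncorrelated error tiers are distinguished:

* ``sigma_Natural`` — inter-individual biological spread, estimated as the
  residual standard deviation of the joint mixed-model trend fit;
* ``sigma_Random`` — acquisition + processing noise, estimated from
  repeated acquisitions of the same subjects as the unweighted mean of the
  per-subject sample standard deviations (no bias correction: with 3
  repeats this estimator is biased low by the factor c4(3) ~ 0.8862, which
  is documented rather than corrected);
* ``sigma_Sample`` — the between-site systematic shift, estimated as the
  random-intercept standard deviation of the same mixed model.

They combine with no correlation terms:

    sigma_X^2 = sigma_Natural^2 + sigma_Random^2 + sigma_Sample^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import RepeatedMeasureSet
from .folding_geometry import DEFAULT_S_VARIANT, add_folding_columns
from .harmonization import HarmonizationFit

logger = logging.getLogger(__name__)


def c4(n: int) -> float:
    """Expected value of the sample SD of n normal draws, in units of the
    true sigma (the 'c4' unbiasing constant of control-chart practice)."""
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2.0) / math.gamma((n - 1) / 2.0)


@dataclass
class UncertaintyBudget:
    variable: str
    sigma_natural: float
    sigma_random: float
    sigma_sample: float
    sigma_total: float
    percent_of_intercept: float | None = None
    boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "sigma_natural": self.sigma_natural,
            "sigma_random": self.sigma_random,
            "sigma_sample": self.sigma_sample,
            "sigma_total": self.sigma_total,
            "percent_of_intercept": self.percent_of_intercept,
            "boundary": self.boundary,
        }


def total_sigma(sigma_natural: float, sigma_random: float, sigma_sample: float) -> float:
    """Quadrature combination of the three uncorrelated tiers."""
    comps = (sigma_natural, sigma_random, sigma_sample)
    if any(c < 0 for c in comps):
        raise ValueError("uncertainty components must be non-negative")
    # hypot is overflow/underflow-safe, unlike sqrt(sum of squares)
    return math.hypot(*comps)


def repeated_measures_sd(sets) -> float:
    """Mean per-subject sample SD (n-1 denominator) across repeat sets.

    Sets with fewer than two values are excluded with a warning; if all are
    excluded a ValueError is raised.  No c4 bias correction is applied.
    """
    sds = []
    for s in sets:
        if s.n < 2:
            logger.warning("excluding repeat set %s with %d value(s)", s.subject_id, s.n)
            continue
        sds.append(np.std(s.values, ddof=1))
    if not sds:
        raise ValueError("no repeat set with >= 2 values")
    return float(np.mean(sds))


def build_budget(
    fit: HarmonizationFit,
    sigma_random: float,
    reference_intercept: float | None = None,
) -> UncertaintyBudget:
    """Assemble the budget from a trend fit plus a repeated-measure SD.

    ``sigma_Natural`` is the fit's residual SD, ``sigma_Sample`` its
    random-intercept SD; ``percent_of_intercept`` is computed against
    ``reference_intercept`` (by convention the healthy-control fixed
    intercept at age 0) when supplied.  A boundary-flagged fit propagates
    its flag into the budget.
    """
    total = total_sigma(fit.sigma_residual, sigma_random, fit.sigma_sample)
    percent = None
    if reference_intercept is not None and reference_intercept != 0:
        percent = 100.0 * total / abs(reference_intercept)
    return UncertaintyBudget(
        variable=fit.variable,
        sigma_natural=fit.sigma_residual,
        sigma_random=sigma_random,
        sigma_sample=fit.sigma_sample,
        sigma_total=total,
        percent_of_intercept=percent,
        boundary=fit.boundary,
    )


def propagate_repeats_to_ksi(
    repeats: pd.DataFrame, s_variant: str = DEFAULT_S_VARIANT
) -> pd.DataFrame:
    """Map each repeated acquisition through the folding change of basis.

    The repeats table carries the primary variables per (subject, repeat);
    the returned copy adds K, S, I and GI columns so the repeated-measure SD
    of the folding variables can be taken on their own scale (propagation
    through the change of basis, the default route for their
    ``sigma_Random``).
    """
    work = repeats.copy()
    x_at = np.log10(work["total_area_mm2"].to_numpy(float))
    x_ae = np.log10(work["exposed_area_mm2"].to_numpy(float))
    x_t2 = 2.0 * np.log10(work["avg_thickness_mm"].to_numpy(float))
    from .folding_geometry import basis_matrix

    ksi = np.column_stack([x_at, x_ae, x_t2]) @ basis_matrix(s_variant).T
    work["K"], work["S"], work["I"] = ksi[:, 0], ksi[:, 1], ksi[:, 2]
    work["GI"] = work["total_area_mm2"] / work["exposed_area_mm2"]
    return work


def repeats_sd_for_variable(
    repeats: pd.DataFrame, variable: str, log10: bool = False
) -> float:
    """Repeated-measure SD for any column of a repeats table."""
    sets = []
    for sid, sub in repeats.groupby("subject_id", sort=True):
        vals = sub[variable].to_numpy(float)
        if log10:
            vals = np.log10(vals)
        sets.append(RepeatedMeasureSet(str(sid), variable, tuple(vals)))
    return repeated_measures_sd(sets)
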