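"""Multisite harmonization: joint log-linear age trend with per-(sample, ROI)
random intercepts, removal of the predicted sample shifts, and de-aging.

The model for a primary variable Y is the linear mixed model

    log10 Y = a * age (+ ROI and age x ROI fixed terms) + u_{sample:ROI} + eps,
    u ~ N(0, sigma_sample^2),  eps ~ N(0, sigma_residual^2)

fit by REML (unbiased variance components).  The predicted random
intercepts are BLUPs — shrinkage estimates of each site's systematic shift
— and harmonization subtracts them on the log10 scale.  By default only
healthy-control records inform the fit; patient records from the same
sample are shifted with the control-derived prediction.

K, S and I are linear combinations of the log variables, so harmonizing
T, A_T and A_E and deriving K/S/I afterwards is exactly equivalent to
shifting K/S/I by the corresponding linear combination of the sample
offsets; the pipeline therefore harmonizes the primary variables and
derives the folding variables from the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .data_model import PRIMARY_VARIABLES, as_frame

logger = logging.getLogger(__name__)

_CELL_SEP = "||"
CTL_GROUP = "CTL"


@dataclass
class HarmonizationFit:
    """A fitted joint trend for one variable.

    ``slope`` is the age coefficient for the reference ROI;
    ``fixed_params`` carries all fixed-effect coefficients;
    ``random_intercepts`` maps (sample, roi) to the predicted shift in the
    fitting scale (log10 units for primary variables).
    """

    variable: str
    transform: str  # "log10" | "identity"
    slope: float
    slope_se: float
    fixed_params: dict
    random_intercepts: dict
    sigma_residual: float
    sigma_sample: float
    n_obs: int
    converged: bool = True
    boundary: bool = False
    single_sample: bool = False
    use_roi_interaction: bool = False
    ctl_only: bool = True
    rois: tuple = ()
    reference_roi: str = ""
    warnings: list = field(default_factory=list)

    def slope_for_roi(self, roi: str) -> float:
        s = self.fixed_params.get("age", 0.0)
        key = f"age:C(roi)[T.{roi}]"
        return s + self.fixed_params.get(key, 0.0)

    def intercept_for_roi(self, roi: str) -> float:
        b = self.fixed_params.get("Intercept", 0.0)
        key = f"C(roi)[T.{roi}]"
        return b + self.fixed_params.get(key, 0.0)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "transform": self.transform,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "fixed_params": dict(self.fixed_params),
            "random_intercepts": {
                f"{s}{_CELL_SEP}{r}": v for (s, r), v in self.random_intercepts.items()
            },
            "sigma_residual": self.sigma_residual,
            "sigma_sample": self.sigma_sample,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
            "single_sample": self.single_sample,
            "use_roi_interaction": self.use_roi_interaction,
            "ctl_only": self.ctl_only,
            "rois": list(self.rois),
            "reference_roi": self.reference_roi,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonizationFit":
        d = dict(d)
        d["random_intercepts"] = {
            tuple(k.split(_CELL_SEP, 1)): v for k, v in d["random_intercepts"].items()
        }
        d["rois"] = tuple(d.get("rois", ()))
        return cls(**d)


def _prepare(df: pd.DataFrame, variable: str, transform: str, ctl_only: bool) -> pd.DataFrame:
    work = df.copy()
    if ctl_only and "group" in work.columns:
        work = work[work["group"] == CTL_GROUP]
        if work.empty:
            raise ValueError("no healthy-control rows available for the fit")
    y = work[variable].to_numpy(float)
    if transform == "log10":
        if np.any(y <= 0):
            raise ValueError(f"non-positive values in {variable}; cannot take log10")
        work["_y"] = np.log10(y)
    elif transform == "identity":
        work["_y"] = y
    else:
        raise ValueError(f"unknown transform {transform!r}")
    work["_cell"] = work["sample"].astype(str) + _CELL_SEP + work["roi"].astype(str)
    return work


def fit_joint_trend(
    data,
    variable: str,
    use_roi_interaction: bool | None = None,
    ctl_only: bool = True,
    transform: str = "log10",
) -> HarmonizationFit:
    """REML fit of the joint age trend with (sample x ROI) random intercepts.

    ``use_roi_interaction=None`` enables ROI main effects and the age x ROI
    interaction automatically when more than one ROI is present.  With a
    single sample the random part is degenerate: the fit falls back to OLS
    with all shifts identically zero and is flagged ``single_sample``.
    A random-intercept variance estimated at the boundary (0) is returned
    with ``boundary=True``, not raised, since the uncertainty budget
    consumes it.
    """
    df = as_frame(data)
    work = _prepare(df, variable, transform, ctl_only)
    rois = tuple(sorted(work["roi"].unique()))
    if use_roi_interaction is None:
        use_roi_interaction = len(rois) > 1
    if work["age_years"].nunique() < 3:
        raise ValueError("need at least 3 distinct ages")
    work = work.rename(columns={"age_years": "age"})
    formula = "_y ~ age * C(roi)" if use_roi_interaction else "_y ~ age"

    samples = work["sample"].unique()
    fit_warnings: list[str] = []
    if len(samples) < 2:
        ols = smf.ols(formula, data=work).fit()
        resid_sd = float(np.sqrt(max(ols.ssr, 0.0) / max(ols.df_resid, 1)))
        random_intercepts = {
            (s, r): 0.0 for s in samples for r in work["roi"].unique()
        }
        return HarmonizationFit(
            variable=variable,
            transform=transform,
            slope=float(ols.params.get("age", np.nan)),
            slope_se=float(ols.bse.get("age", np.nan)),
            fixed_params={k: float(v) for k, v in ols.params.items()},
            random_intercepts=random_intercepts,
            sigma_residual=resid_sd,
            sigma_sample=0.0,
            n_obs=int(ols.nobs),
            single_sample=True,
            boundary=True,
            use_roi_interaction=bool(use_roi_interaction),
            ctl_only=ctl_only,
            rois=rois,
            reference_roi=rois[0],
            warnings=["single sample: random part degenerate, shifts fixed at 0"],
        )

    model = smf.mixedlm(formula, data=work, groups=work["_cell"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=True, maxiter=500)
        if not getattr(result, "converged", True):
            result = model.fit(reml=True, method="powell", maxiter=1000)
    for w in caught:
        fit_warnings.append(str(w.message))

    sigma_sample = float(np.sqrt(max(result.cov_re.iloc[0, 0], 0.0)))
    sigma_residual = float(np.sqrt(max(result.scale, 0.0)))
    boundary = sigma_sample < 1e-8 * max(sigma_residual, 1e-300)
    if boundary:
        fit_warnings.append("random-intercept variance at boundary (~0)")
    random_intercepts = {}
    if boundary:
        # zero random-effect variance shrinks every prediction to zero
        random_intercepts = {
            (s, r): 0.0
            for s, r in {tuple(c.split(_CELL_SEP, 1)) for c in work["_cell"].unique()}
        }
    else:
        for cell, eff in result.random_effects.items():
            s, r = str(cell).split(_CELL_SEP, 1)
            random_intercepts[(s, r)] = float(np.asarray(eff).ravel()[0])
    return HarmonizationFit(
        variable=variable,
        transform=transform,
        slope=float(result.fe_params.get("age", np.nan)),
        slope_se=float(result.bse_fe.get("age", np.nan)),
        fixed_params={k: float(v) for k, v in result.fe_params.items()},
        random_intercepts=random_intercepts,
        sigma_residual=sigma_residual,
        sigma_sample=sigma_sample,
        n_obs=int(result.nobs),
        converged=bool(getattr(result, "converged", True)),
        boundary=boundary,
        use_roi_interaction=bool(use_roi_interaction),
        ctl_only=ctl_only,
        rois=rois,
        reference_roi=rois[0],
        warnings=fit_warnings,
    )


def _shifts_for(df: pd.DataFrame, fit: HarmonizationFit, strict: bool) -> np.ndarray:
    b = np.zeros(len(df))
    keys = list(zip(df["sample"].astype(str), df["roi"].astype(str)))
    for i, key in enumerate(keys):
        if key in fit.random_intercepts:
            b[i] = fit.random_intercepts[key]
        elif strict:
            raise KeyError(
                f"no harmonization shift for sample {key[0]!r} / ROI {key[1]!r}"
            )
    return b


def harmonize(data, fit: HarmonizationFit, strict: bool = True) -> pd.DataFrame:
    """Subtract the predicted per-(sample, ROI) shift on the fitting scale.

    For a log10-fit variable the natural-scale column is divided by
    ``10^b``; all other columns are untouched.  Unseen (sample, ROI) cells
    raise in strict mode and pass through unchanged otherwise.
    """
    df = as_frame(data).copy()
    b = _shifts_for(df, fit, strict)
    if fit.transform == "log10":
        df[fit.variable] = df[fit.variable].to_numpy(float) * 10.0 ** (-b)
    else:
        df[fit.variable] = df[fit.variable].to_numpy(float) - b
    return df


def deage(data, fit: HarmonizationFit, reference_age_years: float) -> pd.DataFrame:
    """Express each value at a common reference age by removing the fitted
    trend: on the fitting scale, value' = value - a_roi * (age - ref)."""
    df = as_frame(data).copy()
    ages = df["age_years"].to_numpy(float)
    slopes = np.array([fit.slope_for_roi(r) for r in df["roi"].astype(str)])
    delta = slopes * (ages - float(reference_age_years))
    if fit.transform == "log10":
        df[fit.variable] = df[fit.variable].to_numpy(float) * 10.0 ** (-delta)
    else:
        df[fit.variable] = df[fit.variable].to_numpy(float) - delta
    return df


def fit_primary_trends(
    data,
    use_roi_interaction: bool | None = None,
    ctl_only: bool = True,
) -> dict:
    """Joint-trend fits for T, A_T and A_E (log10 scale)."""
    return {
        var: fit_joint_trend(data, var, use_roi_interaction=use_roi_interaction, ctl_only=ctl_only)
        for var in PRIMARY_VARIABLES
    }


def harmonize_primary(data, fits: dict, strict: bool = True) -> pd.DataFrame:
    """Apply :func:`harmonize` for the three primary variables in sequence."""
    df = as_frame(data)
    for var in PRIMARY_VARIABLES:
        df = harmonize(df, fits[var], strict=strict)
    return df
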