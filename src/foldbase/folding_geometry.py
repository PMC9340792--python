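"""The change of basis between log-morphometrics and the folding variables.

A self-similar model of cortical folding predicts the power law
``T^(1/2) A_T = k A_E^alpha`` with the universal exponent ``alpha = 5/4``.
Working with the base-10 logs ``x_AT = log10 A_T``, ``x_AE = log10 A_E`` and
``x_T2 = log10 T^2``, the model suggests a rotated coordinate system:

* ``K = x_AT - (5/4) x_AE + (1/4) x_T2``  (= log10 k, the near-invariant);
* ``I = x_AT + x_AE + x_T2``              (isometric volume, overall size);
* ``S``, the shape axis.  Two conventions are implemented: the commonly
  printed form ``(3/2) x_AT - (3/4) x_AE - (9/4) x_T2`` and the
  ``orthogonal`` form ``(3/2) x_AT + (3/4) x_AE - (9/4) x_T2``, which is the
  unique direction (up to scale) perpendicular to both the K and I axes.
  The printed form is *not* perpendicular to I (dot product -3/2); the
  orthogonal form is the default and every output is tagged with the
  variant used.

All three maps are linear in log space, hence invertible; the gyrification
index ``GI = A_T / A_E`` and the ordinary-least-squares estimate of the
self-similarity exponent ``alpha`` live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MorphRecord, as_frame

K_VECTOR = np.array([1.0, -1.25, 0.25])
I_VECTOR = np.array([1.0, 1.0, 1.0])
S_VECTOR_PRINTED = np.array([1.5, -0.75, -2.25])
S_VECTOR_ORTHOGONAL = np.array([1.5, 0.75, -2.25])

S_VARIANTS = ("orthogonal", "printed")
DEFAULT_S_VARIANT = "orthogonal"


def s_vector(s_variant: str = DEFAULT_S_VARIANT) -> np.ndarray:
    if s_variant == "orthogonal":
        return S_VECTOR_ORTHOGONAL
    if s_variant == "printed":
        return S_VECTOR_PRINTED
    raise ValueError(f"unknown s_variant {s_variant!r}")


def basis_matrix(s_variant: str = DEFAULT_S_VARIANT) -> np.ndarray:
    """Rows map (x_AT, x_AE, x_T2) onto (K, S, I)."""
    return np.vstack([K_VECTOR, s_vector(s_variant), I_VECTOR])


_INVERSE = {v: np.linalg.inv(basis_matrix(v)) for v in S_VARIANTS}


@dataclass(frozen=True)
class LogCoordinates:
    """Base-10 logs of (A_T, A_E, T^2); dimensionless log-mm^2 values."""

    x_at: float
    x_ae: float
    x_t2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x_at, self.x_ae, self.x_t2])


@dataclass(frozen=True)
class FoldingCoordinates:
    K: float
    S: float
    I: float
    s_variant: str = DEFAULT_S_VARIANT

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.S, self.I])


def to_log_coords(thickness_mm, total_area_mm2=None, exposed_area_mm2=None) -> LogCoordinates:
    """Exact base-10 log coordinates of a record or of (T, A_T, A_E)."""
    if isinstance(thickness_mm, MorphRecord):
        rec = thickness_mm
        thickness_mm = rec.avg_thickness_mm
        total_area_mm2 = rec.total_area_mm2
        exposed_area_mm2 = rec.exposed_area_mm2
    t, at, ae = float(thickness_mm), float(total_area_mm2), float(exposed_area_mm2)
    if not (t > 0 and at > 0 and ae > 0):
        raise ValueError(f"non-positive morphometrics: T={t}, A_T={at}, A_E={ae}")
    return LogCoordinates(math.log10(at), math.log10(ae), 2.0 * math.log10(t))


def compute_ksi(coords: LogCoordinates, s_variant: str = DEFAULT_S_VARIANT) -> FoldingCoordinates:
    x = coords.as_array()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite log coordinates")
    k, s, i = basis_matrix(s_variant) @ x
    return FoldingCoordinates(float(k), float(s), float(i), s_variant)


def invert_ksi(fc: FoldingCoordinates) -> LogCoordinates:
    """Inverse change of basis; ``compute_ksi(invert_ksi(fc)) == fc`` to 1e-10."""
    x = _INVERSE[fc.s_variant] @ fc.as_array()
    return LogCoordinates(*map(float, x))


def compute_gi(record_or_total, exposed_area_mm2=None) -> float:
    """Gyrification index GI = A_T / A_E."""
    if isinstance(record_or_total, MorphRecord):
        at = record_or_total.total_area_mm2
        ae = record_or_total.exposed_area_mm2
    else:
        at, ae = float(record_or_total), float(exposed_area_mm2)
    if ae == 0:
        raise ValueError("exposed area is zero")
    return at / ae


def add_folding_columns(df_or_records, s_variant: str = DEFAULT_S_VARIANT) -> pd.DataFrame:
    """Return a copy of the table augmented with K, S, I, GI columns
    (vectorised change of basis) and an explicit ``s_variant`` tag column."""
    df = as_frame(df_or_records).copy()
    x_at = np.log10(df["total_area_mm2"].to_numpy(float))
    x_ae = np.log10(df["exposed_area_mm2"].to_numpy(float))
    x_t2 = 2.0 * np.log10(df["avg_thickness_mm"].to_numpy(float))
    coords = np.column_stack([x_at, x_ae, x_t2])
    ksi = coords @ basis_matrix(s_variant).T
    df["K"] = ksi[:, 0]
    df["S"] = ksi[:, 1]
    df["I"] = ksi[:, 2]
    df["GI"] = df["total_area_mm2"].to_numpy(float) / df["exposed_area_mm2"].to_numpy(float)
    df["s_variant"] = s_variant
    return df


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of ``log10(A_T sqrt(T))`` on ``log10(A_E)``.

    ``alpha`` is the slope (self-similarity exponent), ``log10_k`` the
    intercept.  The 95% CI is Student-t based and only defined for n >= 3.
    """

    alpha: float
    log10_k: float
    ci95_alpha: tuple
    n: int
    r2: float
    alpha_se: float


def fit_alpha_xy(x: np.ndarray, y: np.ndarray) -> ScalingFit:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need at least two points to fit alpha")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all log10(A_E) values identical")
    res = stats.linregress(x, y)
    n = int(x.size)
    if n >= 3 and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    elif n >= 3:
        ci = (res.slope, res.slope)
    else:
        ci = (math.nan, math.nan)
    return ScalingFit(
        alpha=float(res.slope),
        log10_k=float(res.intercept),
        ci95_alpha=(float(ci[0]), float(ci[1])),
        n=n,
        r2=float(res.rvalue**2),
        alpha_se=float(res.stderr) if res.stderr is not None else math.nan,
    )


def fit_alpha(data) -> ScalingFit:
    """Fit the scaling exponent on a record collection or morph table.

    Each row (hemisphere observation) contributes one point; the response is
    ``y = log10(A_T) + (1/2) log10(T)`` and the regressor ``x = log10(A_E)``.
    """
    df = as_frame(data)
    x = np.log10(df["exposed_area_mm2"].to_numpy(float))
    y = np.log10(df["total_area_mm2"].to_numpy(float)) + 0.5 * np.log10(
        df["avg_thickness_mm"].to_numpy(float)
    )
    return fit_alpha_xy(x, y)
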