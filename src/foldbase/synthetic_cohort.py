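"""Synthetic multisite cohorts with known ground truth.

Every downstream stage (harmonization, uncertainty budgeting, model
selection, trajectory fitting) is exercised on cohorts generated here, so
the generator emulates the structure of heterogeneous multisite
morphometrics:

* per-sample age windows (wide lifespan cohorts next to narrow young or
  elderly cohorts);
* additive per-(sample, ROI) offsets on the log10 scale — the systematic
  acquisition/processing shift each site contributes, drawn
  ``N(0, sigma_sample)`` unless pinned explicitly;
* a shared log-linear age trend per variable (optionally per-group, e.g. a
  flat K trend for the AD group);
* two noise tiers: natural inter-individual spread (``sigma_natural``) baked
  into every observation, and repeated-measure noise (``sigma_random``)
  realised only by :func:`generate_repeats`;
* geometry consistent with the folding scaling law when generated in
  ``ksi_latent`` mode (latent K, S, I drawn and inverted through the change
  of basis, so constant K yields alpha = 5/4 exactly in the noise-free
  limit).

Default numeric choices (sample layout, noise tiers, slopes) are generator
defaults that mimic published cohort tables at order-of-magnitude level;
they are not claims about any real dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import PRIMARY_VARIABLES, RepeatedMeasureSet
from .folding_geometry import DEFAULT_S_VARIANT, _INVERSE, basis_matrix

KSI_NAMES = ("K", "S", "I")


@dataclass(frozen=True)
class LinearTrend:
    """A linear age trend: value = intercept + slope * age (+ noise).

    ``sigma`` is a Gaussian sd and ``spread`` a uniform half-width, both
    applied on the trend's own scale (log10 units for primary variables,
    natural units for latent K/S/I).
    """

    intercept: float
    slope: float = 0.0
    sigma: float = 0.0
    spread: float = 0.0


@dataclass
class GroupSpec:
    """Per-diagnostic-group trends, one per variable.

    ``log10_trends`` drives ``log_linear`` generation (keys are the primary
    variable names); ``ksi_trends`` drives ``ksi_latent`` generation (keys
    "K", "S", "I").  In ``ksi_latent`` mode the Gaussian ``sigma`` of the K
    trend is realised as measurement noise on log10 A_T — i.e. response
    noise on log10(A_T sqrt(T)) with log10 A_E left noise-free — while the
    S and I sigmas perturb the latent coordinates before inversion.
    """

    name: str
    log10_trends: dict | None = None
    ksi_trends: dict | None = None


@dataclass
class SampleSpec:
    """One acquisition site / cohort."""

    name: str
    n_subjects: dict  # group name -> subject count
    age_low: float
    age_high: float
    age_dist: str = "uniform"  # "uniform" | "truncnorm"
    age_mean: float | None = None
    age_sd: float | None = None
    group_ages: dict | None = None  # optional per-group (low, high) override
    sigma_natural: float | None = None  # per-sample override (log_linear mode)
    slope_delta: float = 0.0  # added to every variable's slope (log10/yr)
    offsets: dict | None = None  # roi -> variable -> shift; None => drawn


@dataclass
class CohortSpec:
    samples: list
    groups: dict  # group name -> GroupSpec
    rois: tuple = ("hemisphere",)
    hemispheres: tuple = ("left", "right")
    roi_shifts: dict | None = None  # roi -> trend-name -> intercept shift
    sigma_natural: float = 0.1
    sigma_random: float = 0.019
    sigma_sample: float = 0.085
    generation_mode: str = "log_linear"  # or "ksi_latent"
    s_variant: str = DEFAULT_S_VARIANT
    seed: int = 0

    def validate(self) -> None:
        if self.generation_mode not in ("log_linear", "ksi_latent"):
            raise ValueError(f"unknown generation_mode {self.generation_mode!r}")
        for s in (self.sigma_natural, self.sigma_random, self.sigma_sample):
            if s < 0:
                raise ValueError("noise tiers must be non-negative")
        rois = set(self.rois)
        for samp in self.samples:
            if any(n < 1 for n in samp.n_subjects.values()):
                raise ValueError(f"sample {samp.name}: n_subjects must be >= 1")
            for g in samp.n_subjects:
                if g not in self.groups:
                    raise ValueError(f"sample {samp.name} references unknown group {g!r}")
            if samp.offsets is not None and not set(samp.offsets) <= rois:
                raise ValueError(
                    f"sample {samp.name}: offset ROIs {sorted(set(samp.offsets) - rois)} "
                    "not in the cohort ROI set"
                )
        if self.roi_shifts is not None and not set(self.roi_shifts) <= rois:
            raise ValueError("roi_shifts reference ROIs outside the cohort ROI set")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        def _trends(td):
            if td is None:
                return None
            return {k: LinearTrend(**v) if isinstance(v, dict) else v for k, v in td.items()}

        groups = {
            name: GroupSpec(
                name=g.get("name", name),
                log10_trends=_trends(g.get("log10_trends")),
                ksi_trends=_trends(g.get("ksi_trends")),
            )
            for name, g in d["groups"].items()
        }
        samples = [SampleSpec(**s) for s in d["samples"]]
        rest = {
            k: v
            for k, v in d.items()
            if k not in ("samples", "groups")
        }
        if "rois" in rest:
            rest["rois"] = tuple(rest["rois"])
        if "hemispheres" in rest:
            rest["hemispheres"] = tuple(rest["hemispheres"])
        return cls(samples=samples, groups=groups, **rest)

    @classmethod
    def from_yaml(cls, path_or_text) -> "CohortSpec":
        p = Path(path_or_text)
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class GroundTruth:
    """The realised generative quantities, reproducible from (spec, seed)."""

    seed: int
    offsets: dict  # (sample, roi, variable) -> log10 shift
    slopes: dict  # (group, name) -> slope per year
    sigma_natural: float
    sigma_random: float
    sigma_sample: float
    sample_sigma_natural: dict
    latent: pd.DataFrame | None = None
    stream_seeds: dict = field(default_factory=dict)


def _draw_ages(rng, samp: SampleSpec, group: str, n: int) -> np.ndarray:
    low, high = samp.age_low, samp.age_high
    if samp.group_ages and group in samp.group_ages:
        low, high = samp.group_ages[group]
    if samp.age_dist == "uniform":
        return rng.uniform(low, high, size=n)
    if samp.age_dist == "truncnorm":
        mean = samp.age_mean if samp.age_mean is not None else 0.5 * (low + high)
        sd = samp.age_sd if samp.age_sd is not None else (high - low) / 4.0
        out = np.empty(n)
        filled = 0
        while filled < n:  # simple rejection sampling; windows are wide
            draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
            draw = draw[(draw >= low) & (draw <= high)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out
    raise ValueError(f"unknown age_dist {samp.age_dist!r}")


def _realise_offsets(spec: CohortSpec, rng) -> dict:
    """Per-(sample, ROI, variable) additive log10 shifts, centred on zero."""
    offsets = {}
    for samp in spec.samples:
        for roi in spec.rois:
            for var in PRIMARY_VARIABLES:
                if samp.offsets is not None:
                    val = float(samp.offsets.get(roi, {}).get(var, 0.0))
                elif spec.sigma_sample > 0:
                    val = float(rng.normal(0.0, spec.sigma_sample))
                else:
                    val = 0.0
                offsets[(samp.name, roi, var)] = val
    return offsets


def generate_cohort(spec: CohortSpec, seed: int | None = None):
    """Generate a cohort table plus its :class:`GroundTruth`.

    Returns ``(df, truth)`` where ``df`` is a canonical morph table (one row
    per subject x hemisphere x ROI) and the same ``(spec, seed)`` pair always
    reproduces it bit-identically.
    """
    spec.validate()
    root_seed = int(spec.seed if seed is None else seed)
    ss = np.random.SeedSequence(root_seed)
    off_ss, age_ss, noise_ss = ss.spawn(3)
    rng_off = np.random.default_rng(off_ss)
    rng_age = np.random.default_rng(age_ss)
    rng_noise = np.random.default_rng(noise_ss)

    offsets = _realise_offsets(spec, rng_off)
    roi_shifts = spec.roi_shifts or {}
    inv = _INVERSE[spec.s_variant]

    frames = []
    latent_frames = []
    slopes = {}
    sample_sigma = {}
    for samp in spec.samples:
        sigma_nat = spec.sigma_natural if samp.sigma_natural is None else samp.sigma_natural
        sample_sigma[samp.name] = sigma_nat
        for group, n in samp.n_subjects.items():
            gspec = spec.groups[group]
            ages = _draw_ages(rng_age, samp, group, int(n))
            sids = np.array([f"{samp.name}-{group}-{i:05d}" for i in range(int(n))])
            for roi in spec.rois:
                shift = roi_shifts.get(roi, {})
                if spec.generation_mode == "log_linear":
                    trends = gspec.log10_trends
                    if trends is None:
                        raise ValueError(f"group {group}: log10_trends required")
                    # subject-level latent log10 values (noise-free)
                    latent_log = {}
                    for var in PRIMARY_VARIABLES:
                        tr = trends[var]
                        slopes[(group, var)] = tr.slope
                        latent_log[var] = (
                            tr.intercept
                            + float(shift.get(var, 0.0))
                            + (tr.slope + samp.slope_delta) * ages
                        )
                    for hemi in spec.hemispheres:
                        row = {
                            "subject_id": sids,
                            "sample": samp.name,
                            "group": group,
                            "sex": "unknown",
                            "age_years": ages,
                            "hemisphere": hemi,
                            "roi": roi,
                        }
                        for var in PRIMARY_VARIABLES:
                            eps = (
                                rng_noise.normal(0.0, sigma_nat, size=ages.size)
                                if sigma_nat > 0
                                else 0.0
                            )
                            row[var] = 10.0 ** (
                                latent_log[var] + offsets[(samp.name, roi, var)] + eps
                            )
                        frames.append(pd.DataFrame(row))
                    lat = pd.DataFrame(
                        {"subject_id": sids, "sample": samp.name, "group": group,
                         "roi": roi, "age_years": ages}
                    )
                    for var in PRIMARY_VARIABLES:
                        lat[var] = 10.0 ** latent_log[var]
                    latent_frames.append(lat)
                else:  # ksi_latent
                    trends = gspec.ksi_trends
                    if trends is None:
                        raise ValueError(f"group {group}: ksi_trends required")
                    latent = {}
                    for name in KSI_NAMES:
                        tr = trends[name]
                        slopes[(group, name)] = tr.slope
                        val = tr.intercept + float(shift.get(name, 0.0)) + (
                            tr.slope + samp.slope_delta
                        ) * ages
                        if tr.spread > 0:
                            val = val + rng_noise.uniform(-tr.spread, tr.spread, ages.size)
                        if name != "K" and tr.sigma > 0:
                            val = val + rng_noise.normal(0.0, tr.sigma, ages.size)
                        latent[name] = val
                    ksi = np.column_stack([latent[n] for n in KSI_NAMES])
                    logs = ksi @ inv.T  # columns x_at, x_ae, x_t2
                    k_sigma = trends["K"].sigma
                    for hemi in spec.hemispheres:
                        x_at = logs[:, 0].copy()
                        if k_sigma > 0:
                            # K-direction measurement noise: perturb A_T only,
                            # so log10(A_T sqrt(T)) is noisy while A_E is not.
                            x_at = x_at + rng_noise.normal(0.0, k_sigma, ages.size)
                        row = {
                            "subject_id": sids,
                            "sample": samp.name,
                            "group": group,
                            "sex": "unknown",
                            "age_years": ages,
                            "hemisphere": hemi,
                            "roi": roi,
                            "avg_thickness_mm": 10.0 ** (
                                0.5 * logs[:, 2]
                                + offsets[(samp.name, roi, "avg_thickness_mm")]
                            ),
                            "total_area_mm2": 10.0 ** (
                                x_at + offsets[(samp.name, roi, "total_area_mm2")]
                            ),
                            "exposed_area_mm2": 10.0 ** (
                                logs[:, 1] + offsets[(samp.name, roi, "exposed_area_mm2")]
                            ),
                        }
                        frames.append(pd.DataFrame(row))
                    lat = pd.DataFrame(
                        {"subject_id": sids, "sample": samp.name, "group": group,
                         "roi": roi, "age_years": ages}
                    )
                    for j, name in enumerate(KSI_NAMES):
                        lat[name] = ksi[:, j]
                    latent_frames.append(lat)

    df = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        seed=root_seed,
        offsets=offsets,
        slopes=slopes,
        sigma_natural=spec.sigma_natural,
        sigma_random=spec.sigma_random,
        sigma_sample=spec.sigma_sample,
        sample_sigma_natural=sample_sigma,
        latent=pd.concat(latent_frames, ignore_index=True),
        stream_seeds={
            "offsets": off_ss.entropy,
            "ages": age_ss.entropy,
            "noise": noise_ss.entropy,
        },
    )
    return df, truth


def generate_repeats(
    spec: CohortSpec,
    n_repeats: int = 3,
    n_subjects: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeated acquisitions of the same subjects under identical conditions.

    Each subject's latent (noise-free) values are drawn from the first
    sample's CTL-equivalent trend; every repeat then adds independent
    Gaussian noise with sd ``spec.sigma_random`` on the log10 scale of each
    primary variable.  Returns a long table with columns ``subject_id, age,
    repeat`` plus the three primary variables (natural scale); the default
    design is 50 subjects x 3 repeats.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    spec.validate()
    root = int(spec.seed if seed is None else seed)
    rng = np.random.default_rng(np.random.SeedSequence((root, 0x5EED)))
    samp = spec.samples[0]
    group = next(iter(samp.n_subjects))
    gspec = spec.groups[group]
    ages = _draw_ages(rng, samp, group, n_subjects)
    roi = spec.rois[0]
    shift = (spec.roi_shifts or {}).get(roi, {})
    if spec.generation_mode == "log_linear":
        latent_log = {
            var: gspec.log10_trends[var].intercept
            + float(shift.get(var, 0.0))
            + gspec.log10_trends[var].slope * ages
            for var in PRIMARY_VARIABLES
        }
    else:
        inv = _INVERSE[spec.s_variant]
        ksi = np.column_stack(
            [
                gspec.ksi_trends[nm].intercept + gspec.ksi_trends[nm].slope * ages
                for nm in KSI_NAMES
            ]
        )
        logs = ksi @ inv.T
        latent_log = {
            "avg_thickness_mm": 0.5 * logs[:, 2],
            "total_area_mm2": logs[:, 0],
            "exposed_area_mm2": logs[:, 1],
        }
    rows = []
    for r in range(n_repeats):
        row = {
            "subject_id": np.array([f"repeat-{i:04d}" for i in range(n_subjects)]),
            "age": ages,
            "repeat": r,
        }
        for var in PRIMARY_VARIABLES:
            eps = (
                rng.normal(0.0, spec.sigma_random, size=n_subjects)
                if spec.sigma_random > 0
                else 0.0
            )
            row[var] = 10.0 ** (latent_log[var] + eps)
        rows.append(pd.DataFrame(row))
    return pd.concat(rows, ignore_index=True)


def repeats_to_sets(repeats: pd.DataFrame, variable: str, log10: bool = True):
    """Group a repeats table into :class:`RepeatedMeasureSet` objects.

    With ``log10=True`` (the scale on which repeated-measure noise is
    declared for the primary variables) the values are base-10 logs and the
    set is named ``log10_<variable>``.
    """
    name = f"log10_{variable}" if log10 else variable
    sets = []
    for sid, sub in repeats.groupby("subject_id", sort=True):
        vals = sub[variable].to_numpy(float)
        if log10:
            vals = np.log10(vals)
        sets.append(RepeatedMeasureSet(subject_id=str(sid), variable=name, values=tuple(vals)))
    return sets


# ---------------------------------------------------------------------------
# Scenario builders (generator defaults; see docs/methods.md)
# ---------------------------------------------------------------------------

#: Default log10 trends per primary variable for a healthy-control group:
#: thickness ~ 2.8 mm at age 0 shrinking ~1%/decade, areas in the 10^5 /
#: 10^5 mm^2 range with slow decline.
_CTL_LOG10_TRENDS = {
    "avg_thickness_mm": LinearTrend(intercept=0.45, slope=-0.0044),
    "total_area_mm2": LinearTrend(intercept=5.33, slope=-0.00104),
    "exposed_area_mm2": LinearTrend(intercept=4.93, slope=-0.00048),
}
_AD_LOG10_TRENDS = {
    "avg_thickness_mm": LinearTrend(intercept=0.43, slope=-0.00025),
    "total_area_mm2": LinearTrend(intercept=5.30, slope=-0.00040),
    "exposed_area_mm2": LinearTrend(intercept=4.92, slope=-0.00045),
}

#: 9 samples loosely mimicking published multisite cohort tables: a large
#: elderly cohort with a patient arm, several narrow young cohorts, a few
#: wide lifespan cohorts.
_DEFAULT_SAMPLES = (
    ("ELDERLY-A", {"CTL": 300, "AD": 180}, 56, 96),
    ("LIFESPAN-A", {"CTL": 100}, 24, 76),
    ("YOUNG-A", {"CTL": 104}, 18, 26),
    ("YOUNG-B", {"CTL": 112}, 18, 26),
    ("YOUNG-C", {"CTL": 300}, 22, 36),
    ("CLINIC-A", {"CTL": 77, "AD": 13}, 43, 86),
    ("LIFESPAN-B", {"CTL": 190}, 20, 86),
    ("LIFESPAN-C", {"CTL": 84}, 4, 85),
    ("LIFESPAN-D", {"CTL": 156}, 18, 94),
)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The shipped default scenario: 9 samples, CTL + AD, hemisphere ROI."""
    samples = [
        SampleSpec(name=n, n_subjects=dict(g), age_low=lo, age_high=hi)
        for n, g, lo, hi in _DEFAULT_SAMPLES
    ]
    for samp in samples:
        if "AD" in samp.n_subjects:
            samp.group_ages = {"AD": (max(samp.age_low, 56.0), min(samp.age_high, 92.0))}
    groups = {
        "CTL": GroupSpec("CTL", log10_trends=dict(_CTL_LOG10_TRENDS)),
        "AD": GroupSpec("AD", log10_trends=dict(_AD_LOG10_TRENDS)),
    }
    return CohortSpec(samples=samples, groups=groups, seed=seed)


def recovery_cohort_spec(n_per_sample: int = 150, seed: int = 0) -> CohortSpec:
    """9-sample CTL-only scenario used for harmonization / uncertainty
    recovery checks: shared slope -0.0044 log10/yr for thickness, noise
    tiers (0.1, 0.019, 0.085) in log10 units, ~2 x n_per_sample rows per
    sample (both hemispheres)."""
    windows = [(56, 96), (24, 76), (18, 26), (18, 26), (22, 36), (43, 80), (20, 86), (4, 85), (18, 94)]
    samples = [
        SampleSpec(name=f"S{i+1}", n_subjects={"CTL": n_per_sample}, age_low=lo, age_high=hi)
        for i, (lo, hi) in enumerate(windows)
    ]
    groups = {"CTL": GroupSpec("CTL", log10_trends=dict(_CTL_LOG10_TRENDS))}
    return CohortSpec(
        samples=samples,
        groups=groups,
        sigma_natural=0.1,
        sigma_random=0.019,
        sigma_sample=0.085,
        seed=seed,
    )


def constant_k_spec(
    n: int = 500,
    noise_sd: float = 0.02,
    decade_span: float = 1.0,
    seed: int = 0,
) -> CohortSpec:
    """Scaling-law-conformant geometry: constant K, exposed areas spanning
    ``decade_span`` decades, Gaussian noise ``noise_sd`` on
    log10(A_T sqrt(T)).  ``fit_alpha`` on such a cohort recovers 5/4."""
    inv = _INVERSE[DEFAULT_S_VARIANT]
    x_ae_per_i = abs(inv[1, 2])  # d x_AE / d I at fixed K, S
    spread_i = 0.5 * decade_span / x_ae_per_i
    groups = {
        "CTL": GroupSpec(
            "CTL",
            ksi_trends={
                "K": LinearTrend(intercept=-0.66, slope=0.0, sigma=noise_sd),
                "S": LinearTrend(intercept=9.84, slope=0.0),
                "I": LinearTrend(intercept=11.0, slope=0.0, spread=spread_i),
            },
        )
    }
    samples = [SampleSpec(name="SIM", n_subjects={"CTL": n}, age_low=20, age_high=80)]
    return CohortSpec(
        samples=samples,
        groups=groups,
        hemispheres=("left",),
        sigma_sample=0.0,
        generation_mode="ksi_latent",
        seed=seed,
    )


def ksi_trend_spec(
    n_ctl: int = 800,
    n_ad: int = 800,
    k_sigma: float = 0.016,
    seed: int = 0,
) -> CohortSpec:
    """CTL-declining / AD-flat K scenario for trajectory and contrast tests.

    CTL K falls at -8.6e-4 per year while the AD K trend is flat, matched to
    the CTL value around age 75; S rises and I falls for CTL.
    """
    groups = {
        "CTL": GroupSpec(
            "CTL",
            ksi_trends={
                "K": LinearTrend(intercept=-0.59, slope=-8.6e-4, sigma=k_sigma),
                "S": LinearTrend(intercept=9.77, slope=1.6e-3, sigma=0.12),
                "I": LinearTrend(intercept=11.14, slope=-3.1e-3, sigma=0.082),
            },
        ),
        "AD": GroupSpec(
            "AD",
            ksi_trends={
                "K": LinearTrend(intercept=-0.6545, slope=0.0, sigma=k_sigma),
                "S": LinearTrend(intercept=9.80, slope=3.0e-4, sigma=0.12),
                "I": LinearTrend(intercept=11.10, slope=-1.4e-3, sigma=0.082),
            },
        ),
    }
    samples = [
        SampleSpec(
            name="SIM",
            n_subjects={"CTL": n_ctl, "AD": n_ad},
            age_low=20,
            age_high=90,
            group_ages={"AD": (56, 92)},
        )
    ]
    return CohortSpec(
        samples=samples,
        groups=groups,
        hemispheres=("left",),
        sigma_sample=0.0,
        generation_mode="ksi_latent",
        seed=seed,
    )


def evidence_scenario_spec(
    kind: str = "common_slope",
    n_per_sample: int = 40,
    seed: int = 0,
) -> CohortSpec:
    """Trend-model-selection scenarios.

    ``common_slope``: one shared slope, per-sample dispersions following a
    fixed heteroscedastic ramp (the dispersion scheme of the per-sample-sigma
    model).  ``per_sample_slope``: additionally a fixed standardized pattern
    of per-sample slope offsets with sd = 3x the nominal slope standard
    error, the regime in which per-sample-slope models should be preferred.
    """
    if kind not in ("common_slope", "per_sample_slope"):
        raise ValueError(f"unknown evidence scenario {kind!r}")
    sigma_ramp = 0.1 * np.array([0.45, 0.6, 0.75, 0.9, 1.0, 1.15, 1.3, 1.6, 2.0])
    if kind == "per_sample_slope":
        sd_age = (80.0 - 20.0) / np.sqrt(12.0)
        se_nominal = 0.1 / (np.sqrt(n_per_sample) * sd_age)
        pattern = np.linspace(-1.0, 1.0, 9)
        pattern = pattern / pattern.std()
        slope_deltas = 3.0 * se_nominal * pattern
    else:
        slope_deltas = np.zeros(9)
    samples = [
        SampleSpec(
            name=f"S{i+1}",
            n_subjects={"CTL": n_per_sample},
            age_low=20,
            age_high=80,
            sigma_natural=float(sigma_ramp[i]),
            slope_delta=float(slope_deltas[i]),
        )
        for i in range(9)
    ]
    groups = {"CTL": GroupSpec("CTL", log10_trends=dict(_CTL_LOG10_TRENDS))}
    return CohortSpec(
        samples=samples,
        groups=groups,
        hemispheres=("left",),
        sigma_sample=0.085,
        seed=seed,
    )
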