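import numpy as np
import pandas as pd
import pytest


def make_valid_frame(n: int = 3, seed: int = 0, with_gi: bool = False) -> pd.DataFrame:
    """A small, always-valid morph table for I/O and validation tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        at = float(rng.uniform(1.5e5, 2.5e5))
        rows.append(
            {
                "subject_id": f"sub-{i:03d}",
                "sample": "SITE-A" if i % 2 == 0 else "SITE-B",
                "group": "CTL",
                "sex": "F" if i % 2 == 0 else "M",
                "age_years": float(rng.uniform(20, 80)),
                "hemisphere": "left" if i % 2 == 0 else "right",
                "roi": "hemisphere",
                "avg_thickness_mm": float(rng.uniform(2.0, 3.0)),
                "total_area_mm2": at,
                "exposed_area_mm2": at / float(rng.uniform(2.2, 2.8)),
            }
        )
        if with_gi:
            rows[-1]["local_gi"] = rows[-1]["total_area_mm2"] / rows[-1]["exposed_area_mm2"]
    return pd.DataFrame(rows)


def linear_cohort(
    slope: float = -0.002,
    intercept: float = 0.5,
    n: int = 40,
    samples=("SITE-A",),
    offsets=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noise-controlled single-ROI cohort with log10(T) exactly linear in age.

    ``offsets`` maps sample name to an additive log10 shift (the systematic
    site effect).  A_T and A_E are fixed so only thickness carries signal.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for s in samples:
        ages = np.linspace(10, 90, n)
        logt = intercept + slope * ages
        if offsets:
            logt = logt + offsets.get(s, 0.0)
        if noise_sd > 0:
            logt = logt + rng.normal(0, noise_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{s}-{i:03d}" for i in range(n)],
                    "sample": s,
                    "group": "CTL",
                    "sex": "unknown",
                    "age_years": ages,
                    "hemisphere": "left",
                    "roi": "hemisphere",
                    "avg_thickness_mm": 10.0**logt,
                    "total_area_mm2": 2.0e5,
                    "exposed_area_mm2": 8.0e4,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The 9-sample recovery scenario shared by harmonization and budget
    recovery checks: shared slope -0.0044 log10/yr, tiers (0.1, 0.019, 0.085)."""
    from foldbase.synthetic_cohort import generate_cohort, recovery_cohort_spec

    spec = recovery_cohort_spec(seed=20260925)
    df, truth = generate_cohort(spec)
    return spec, df, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    from foldbase.harmonization import fit_joint_trend

    _, df, _ = recovery_cohort
    return fit_joint_trend(df, "avg_thickness_mm")
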