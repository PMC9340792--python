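import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldbase.folding_geometry import add_folding_columns
from foldbase.synthetic_cohort import generate_cohort, ksi_trend_spec
from foldbase.trajectories import (
    alpha_by_decade,
    baseline_table,
    compare_slopes,
    fit_trajectories,
)
from foldbase.uncertainty_budget import UncertaintyBudget


def _ksi_frame(groups=("CTL",), slopes=None, intercepts=None, noise=0.0,
               n=50, ages=(20, 90), seed=0, roi="hemisphere"):
    """Minimal table with a K column exactly linear in age per group."""
    rng = np.random.default_rng(seed)
    slopes = slopes or {}
    intercepts = intercepts or {}
    frames = []
    for g in groups:
        a = np.linspace(*ages, n)
        k = intercepts.get(g, -0.55) + slopes.get(g, -8.6e-4) * a
        if noise:
            k = k + rng.normal(0, noise, n)
        frames.append(pd.DataFrame({
            "subject_id": [f"{g}-{i}" for i in range(n)],
            "sample": "SIM", "group": g, "roi": roi,
            "age_years": a, "K": k,
        }))
    return pd.concat(frames, ignore_index=True)


class TestFitTrajectories:
    def test_noise_free_slope_exact(self):
        df = _ksi_frame(slopes={"CTL": -8.6e-4})
        (fit,) = fit_trajectories(df, ["K"])
        assert fit.slope == pytest.approx(-8.6e-4, abs=1e-12)
        assert fit.ci95[0] <= fit.slope <= fit.ci95[1]

    def test_simulated_group_slopes_within_ci(self):
        df, _ = generate_cohort(ksi_trend_spec(seed=41))
        k = add_folding_columns(df)
        fits = {f.group: f for f in fit_trajectories(k, ["K"], groups=("CTL", "AD"))}
        assert fits["CTL"].ci95[0] <= -8.6e-4 <= fits["CTL"].ci95[1]
        assert fits["AD"].ci95[0] <= 0.0 <= fits["AD"].ci95[1]

    def test_percent_per_year_uses_reference_age(self):
        df = _ksi_frame()
        (fit,) = fit_trajectories(df, ["K"], reference_age=50.0)
        at_ref = fit.intercept + fit.slope * 50.0
        assert fit.percent_per_year == pytest.approx(100 * fit.slope / at_ref)
        assert fit.reference_age == 50.0

    def test_single_age_cell_skipped_with_warning(self, caplog):
        df = _ksi_frame()
        df["age_years"] = 40.0
        with caplog.at_level("WARNING"):
            fits = fit_trajectories(df, ["K"])
        assert fits == []
        assert "degenerate" in caplog.text


class TestCompareSlopes:
    def test_identical_groups_give_null_contrast(self):
        base = _ksi_frame(noise=0.01, seed=3)
        dup = base.copy()
        dup["group"] = "AD"
        df = pd.concat([base, dup], ignore_index=True)
        (c,) = compare_slopes(df, "K", ("CTL", "AD"), adjustment="none")
        assert c.estimate == pytest.approx(0.0, abs=1e-15)
        assert c.p_value > 0.99

    def test_noise_free_difference_exact(self):
        df = pd.concat([
            _ksi_frame(groups=("CTL",), slopes={"CTL": -8.6e-4}),
            _ksi_frame(groups=("AD",), slopes={"AD": 0.4e-4}),
        ], ignore_index=True)
        (c,) = compare_slopes(df, "K", ("CTL", "AD"), adjustment="tukey")
        assert c.estimate == pytest.approx(9.0e-4, abs=1e-12)
        assert c.p_adjusted >= c.p_value

    def test_matches_classical_interaction_t_test(self):
        """With adjustment='none' the contrast equals the textbook two-line
        interaction t-test computed from scratch."""
        rng = np.random.default_rng(9)
        n = 12
        rows = []
        for g, slope in (("CTL", -8e-4), ("AD", -1e-4)):
            a = rng.uniform(20, 90, n)
            k = -0.55 + slope * a + rng.normal(0, 0.02, n)
            rows.append(pd.DataFrame({
                "subject_id": [f"{g}{i}" for i in range(n)], "sample": "SIM",
                "group": g, "roi": "hemisphere", "age_years": a, "K": k,
            }))
        df = pd.concat(rows, ignore_index=True)
        (c,) = compare_slopes(df, "K", ("CTL", "AD"), adjustment="none")
        # oracle: separate OLS per group, pooled residual variance, Wald t
        def cell(g):
            sub = df[df["group"] == g]
            x, y = sub["age_years"].to_numpy(), sub["K"].to_numpy()
            sxx = np.sum((x - x.mean()) ** 2)
            b1 = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            b0 = y.mean() - b1 * x.mean()
            rss = np.sum((y - b0 - b1 * x) ** 2)
            return b1, sxx, rss
        b1a, sxxa, rssa = cell("CTL")
        b1b, sxxb, rssb = cell("AD")
        dof = 2 * n - 4
        s2 = (rssa + rssb) / dof
        se = math.sqrt(s2 * (1 / sxxa + 1 / sxxb))
        t = (b1b - b1a) / se
        p = 2 * stats.t.sf(abs(t), dof)
        assert c.estimate == pytest.approx(b1b - b1a, abs=1e-10)
        assert c.se == pytest.approx(se, rel=1e-8)
        assert c.p_value == pytest.approx(p, rel=1e-6)

    def test_unknown_adjustment_rejected(self):
        df = _ksi_frame(groups=("CTL", "AD"))
        with pytest.raises(ValueError, match="adjustment"):
            compare_slopes(df, "K", ("CTL", "AD"), adjustment="fdr")

    def test_bonferroni_scales_with_family_size(self):
        frames = []
        for roi in ("frontal", "temporal"):
            frames.append(_ksi_frame(groups=("CTL", "AD"), noise=0.02, seed=5, roi=roi))
        df = pd.concat(frames, ignore_index=True)
        raw = compare_slopes(df, "K", ("CTL", "AD"), adjustment="none")
        bon = compare_slopes(df, "K", ("CTL", "AD"), adjustment="bonferroni")
        for r, b in zip(raw, bon):
            assert b.p_adjusted == pytest.approx(min(1.0, r.p_value * len(raw)))


@pytest.fixture(scope="module")
def ksi_cohort():
    from foldbase.synthetic_cohort import constant_k_spec

    spec = constant_k_spec(n=600, noise_sd=0.02)
    spec.samples[0].age_low, spec.samples[0].age_high = 20, 60
    df, _ = generate_cohort(spec, seed=13)
    return df


class TestAlphaByDecade:
    def test_constant_k_bins_cover_theoretical_exponent(self, ksi_cohort):
        res = alpha_by_decade(ksi_cohort, min_n=10)["CTL"]
        fitted = [(lo, f) for lo, hi, n, f in res.bins if f is not None]
        assert {lo for lo, _ in fitted} == {20, 30, 40, 50}
        for lo, f in fitted:
            assert f.ci95_alpha[0] <= 1.25 <= f.ci95_alpha[1]

    def test_small_bins_omitted_and_listed(self, ksi_cohort):
        res = alpha_by_decade(ksi_cohort, min_n=10_000)["CTL"]
        assert all(f is None for _, _, _, f in res.bins)
        assert {(lo, hi) for lo, hi, n in res.omitted} == {(20, 30), (30, 40), (40, 50), (50, 60)}

    def test_groups_sharing_data_get_identical_bins(self, ksi_cohort):
        doubled = pd.concat(
            [ksi_cohort, ksi_cohort.assign(group="AD")], ignore_index=True
        )
        res = alpha_by_decade(doubled, min_n=10)
        for (la, ha, na, fa), (lb, hb, nb, fb) in zip(res["CTL"].bins, res["AD"].bins):
            assert (la, ha, na) == (lb, hb, nb)
            if fa is not None:
                assert fa.alpha == pytest.approx(fb.alpha, abs=1e-12)

    def test_monotone_subsetting(self, ksi_cohort):
        full = alpha_by_decade(ksi_cohort, min_n=10)["CTL"]
        pruned_df = ksi_cohort[ksi_cohort["age_years"] >= 30]
        pruned = alpha_by_decade(pruned_df, min_n=10)["CTL"]
        for (lo, hi, n, f), (lo2, hi2, n2, f2) in zip(full.bins, pruned.bins):
            if lo >= 30 and f is not None:
                assert f2 is not None and f2.alpha == pytest.approx(f.alpha, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_by_decade(_ksi_frame().iloc[0:0])


class TestBaselines:
    def _budget(self, sigma):
        return UncertaintyBudget("K", sigma, 0.0, 0.0, sigma)

    def test_band_is_line_plus_minus_sigma(self):
        df = _ksi_frame(slopes={"CTL": -8.6e-4}, intercepts={"CTL": -0.5})
        fits = fit_trajectories(df, ["K"])
        (entry,) = baseline_table(fits, {"K": self._budget(0.026)})
        lo, mid, hi = entry.band(40.0)
        assert mid == pytest.approx(-0.5 - 8.6e-4 * 40, abs=1e-9)
        assert hi - lo == pytest.approx(2 * 0.026)

    def test_missing_budget_variable_rejected(self):
        df = _ksi_frame()
        fits = fit_trajectories(df, ["K"])
        with pytest.raises(ValueError, match="budget"):
            baseline_table(fits, {"S": self._budget(0.1)})

    def test_empty_budget_flagged_without_bands(self):
        df = _ksi_frame()
        fits = fit_trajectories(df, ["K"])
        (entry,) = baseline_table(fits, {})
        assert entry.no_band
        assert math.isnan(entry.band(40.0)[0])

    def test_one_sigma_band_covers_about_two_thirds(self):
        df = _ksi_frame(noise=0.016, n=2000, seed=21)
        fits = fit_trajectories(df, ["K"])
        (entry,) = baseline_table(fits, {"K": self._budget(0.016)})
        lo = entry.intercept + entry.slope * df["age_years"] - entry.sigma_total
        hi = lo + 2 * entry.sigma_total
        coverage = np.mean((df["K"] >= lo) & (df["K"] <= hi))
        assert coverage >= 0.60


def test_slopes_invariant_to_per_sample_shifts():
    """Adding per-sample constants leaves within-group slopes and the
    interaction contrast unchanged on balanced designs."""
    base = pd.concat([
        _ksi_frame(groups=("CTL",), noise=0.02, seed=2),
        _ksi_frame(groups=("AD",), slopes={"AD": 0.0}, noise=0.02, seed=4),
    ], ignore_index=True)
    shifted = base.copy()
    shifted["K"] = shifted["K"] + 0.25  # same shift for every row of the sample
    f0 = {f.group: f.slope for f in fit_trajectories(base, ["K"])}
    f1 = {f.group: f.slope for f in fit_trajectories(shifted, ["K"])}
    for g in f0:
        assert f0[g] == pytest.approx(f1[g], abs=1e-8)
    (c0,) = compare_slopes(base, "K", ("CTL", "AD"), adjustment="none")
    (c1,) = compare_slopes(shifted, "K", ("CTL", "AD"), adjustment="none")
    assert c0.estimate == pytest.approx(c1.estimate, abs=1e-8)
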