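import math

import numpy as np
import pytest

from foldbase.evidence import (
    MODEL_IDS,
    ModelEvidence,
    ParamPrior,
    TrendModel,
    compare_models,
    data_fingerprint,
    extract_sample_data,
    log_marginal_likelihood,
    make_trend_model,
    parameter_posterior,
)
from foldbase.harmonization import fit_joint_trend
from foldbase.synthetic_cohort import evidence_scenario_spec, generate_cohort


def _conjugate_oracle(y, sigma, W):
    """Closed-form evidence for mu = b, known sigma, b ~ U(-W, W)."""
    n = y.size
    ybar = float(y.mean())
    ss = float(np.sum((y - ybar) ** 2))
    logc = -n / 2 * math.log(2 * math.pi * sigma**2) - ss / (2 * sigma**2)
    z = math.sqrt(n) / (sigma * math.sqrt(2))
    mass = 0.5 * (math.erf((W - ybar) * z) - math.erf((-W - ybar) * z))
    return logc + math.log(sigma * math.sqrt(2 * math.pi / n) * mass) - math.log(2 * W)


def _intercept_model(W, sigma, samples=("S1",)):
    return TrendModel(
        model_id="base",
        shared={},
        per_sample={s: {"b": ParamPrior("uniform", -W, W)} for s in samples},
        quadratic=False,
        fixed_sigma=sigma,
    )


class TestEvidenceEngine:
    def test_matches_closed_form_gaussian_integral(self):
        rng = np.random.default_rng(42)
        sigma, n, W = 0.1, 20, 0.5
        y = rng.normal(0.02, sigma, n)
        data = {"S1": (np.zeros(n), y)}
        ev = log_marginal_likelihood(_intercept_model(W, sigma), data,
                                     n_nodes=200, error_estimate=True)
        exact = _conjugate_oracle(y, sigma, W)
        assert abs(ev.log_marginal_likelihood - exact) < 1e-6
        assert ev.error_estimate < 1e-6

    def test_occam_penalty_for_widened_prior(self):
        """Widening an irrelevant prior range x10 costs ~log 10 of evidence
        once the likelihood is fully contained."""
        rng = np.random.default_rng(7)
        sigma, n, W = 0.5, 10, 1.0
        y = rng.normal(0.0, sigma, n)
        data = {"S1": (np.zeros(n), y)}
        z1 = log_marginal_likelihood(_intercept_model(W, sigma), data,
                                     n_nodes=600, error_estimate=False)
        z10 = log_marginal_likelihood(_intercept_model(10 * W, sigma), data,
                                      n_nodes=600, error_estimate=False)
        drop = z1.log_marginal_likelihood - z10.log_marginal_likelihood
        assert drop == pytest.approx(math.log(10), abs=1e-3)

    def test_sample_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(20, 80, 30)
        data = {"A": (x, -0.004 * x + 0.5 + rng.normal(0, 0.1, 30)),
                "B": (x, -0.004 * x + 0.4 + rng.normal(0, 0.1, 30))}
        swapped = {"A": data["B"], "B": data["A"]}
        za = log_marginal_likelihood(make_trend_model("base", data), data,
                                     n_nodes=48, error_estimate=False)
        zb = log_marginal_likelihood(make_trend_model("base", swapped), swapped,
                                     n_nodes=48, error_estimate=False)
        assert za.log_marginal_likelihood == pytest.approx(
            zb.log_marginal_likelihood, abs=1e-9
        )

    def test_duplicated_data_preserves_nested_ranking(self):
        rng = np.random.default_rng(11)
        x = np.linspace(20, 80, 25)
        y = -0.002 * x + 0.5 + rng.normal(0, 1e-6, x.size)
        data = {"S1": (x, y)}
        doubled = {"S1": (np.concatenate([x, x]), np.concatenate([y, y]))}
        for d in (data, doubled):
            evs = [
                log_marginal_likelihood(make_trend_model(m, d), d,
                                        n_nodes=48, error_estimate=False)
                for m in ("base", "iv")
            ]
            table = compare_models(evs)
            assert table.iloc[0]["model"] == "base"  # extra c param only costs

    def test_prior_range_edge_mass_warning(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.5, 0.05, 30)  # bulk of likelihood far outside [0, 0.1]
        data = {"S1": (np.zeros(30), y)}
        model = TrendModel("base", shared={},
                           per_sample={"S1": {"b": ParamPrior("uniform", 0.0, 0.1)}},
                           quadratic=False, fixed_sigma=0.05)
        ev = log_marginal_likelihood(model, data, n_nodes=64, error_estimate=False)
        assert any("edge" in w for w in ev.warnings)

    def test_parameter_counts_per_model(self):
        rng = np.random.default_rng(1)
        data = {
            s: (rng.uniform(20, 80, 10), rng.normal(0.4, 0.1, 10))
            for s in ("A", "B", "C")
        }
        J = 3
        expected = {"base": 1 + J + J, "i": 1 + J + 1, "ii": 3 * J,
                    "iii": 2 * J + 1, "iv": 2 + J + J}
        for mid in MODEL_IDS:
            assert make_trend_model(mid, data).n_parameters == expected[mid]


class TestCompareModels:
    def _ev(self, mid, logz, fp="f"):
        return ModelEvidence(mid, logz, None, 1, 10, "test", fp)

    def test_odds_and_probabilities(self):
        table = compare_models([self._ev("m1", -100.0), self._ev("m2", -103.0)])
        assert table.iloc[0]["model"] == "m1"
        assert table.iloc[1]["odds_vs_best"] == pytest.approx(math.exp(-3))
        assert table.iloc[0]["posterior_probability"] == pytest.approx(0.9526, abs=1e-3)
        assert table["posterior_probability"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_evidence_splits_evenly(self):
        table = compare_models([self._ev("m1", -50.0), self._ev("m2", -50.0)])
        assert np.allclose(table["posterior_probability"], 0.5)
        assert np.allclose(table["odds_vs_best"], 1.0)

    def test_single_model_gets_probability_one(self):
        table = compare_models([self._ev("only", -10.0)])
        assert table.iloc[0]["posterior_probability"] == 1.0

    def test_different_data_fingerprints_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            compare_models([self._ev("m1", -1.0, "fp-a"), self._ev("m2", -2.0, "fp-b")])


class TestParameterPosterior:
    def test_noise_free_slope_mode(self):
        x = np.linspace(20, 80, 25)
        data = {"S1": (x, -0.002 * x + 0.5)}
        model = make_trend_model("base", data)
        post = parameter_posterior(model, data, "a", n_grid=201, n_nodes=24)
        assert post.mode == pytest.approx(-0.002, abs=1e-6)

    def test_conjugate_interval_matches_analytic(self):
        rng = np.random.default_rng(7)
        sigma, n, W = 0.1, 40, 1.0
        y = rng.normal(0.3, sigma, n)
        data = {"S1": (np.zeros(n), y)}
        post = parameter_posterior(_intercept_model(W, sigma), data, ("S1", "b"),
                                   n_grid=2001, n_nodes=64)
        se = sigma / math.sqrt(n)
        assert post.mode == pytest.approx(y.mean(), abs=1e-4)
        assert post.ci95[0] == pytest.approx(y.mean() - 1.959964 * se, abs=1e-3)
        assert post.ci95[1] == pytest.approx(y.mean() + 1.959964 * se, abs=1e-3)

    def test_slope_posterior_consistent_with_reml(self):
        df, _ = generate_cohort(evidence_scenario_spec("common_slope", n_per_sample=30),
                                seed=77)
        data = extract_sample_data(df, "avg_thickness_mm", roi="hemisphere")
        model = make_trend_model("base", data)
        post = parameter_posterior(model, data, "a", n_grid=101, n_nodes=24)
        fit = fit_joint_trend(df, "avg_thickness_mm")
        post_se = (post.ci95[1] - post.ci95[0]) / (2 * 1.959964)
        combined = math.hypot(post_se, fit.slope_se)
        assert abs(post.mode - fit.slope) < combined

    def test_unknown_target_rejected(self):
        data = {"S1": (np.linspace(0, 1, 5), np.zeros(5))}
        model = make_trend_model("base", data)
        with pytest.raises(ValueError):
            parameter_posterior(model, data, "c")


def test_fingerprint_sensitive_to_values_not_order():
    x = np.arange(5.0)
    y = np.ones(5)
    a = {"A": (x, y), "B": (x, 2 * y)}
    b = {"B": (x, 2 * y), "A": (x, y)}
    assert data_fingerprint(a) == data_fingerprint(b)
    c = {"A": (x, y), "B": (x, 2.0001 * y)}
    assert data_fingerprint(a) != data_fingerprint(c)
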