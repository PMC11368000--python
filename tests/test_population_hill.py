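"""Hill model, closed-form PODs vs root-finder oracle, posterior PODs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from cardiopop.population_hill import (
    HillParams,
    PopulationPosterior,
    SamplerSettings,
    fit_population,
    hill_response,
    pod_from_hill,
    pods_from_posterior,
    sample_random_individual_pods,
)
from cardiopop.synthetic_study import TrueHill, simulate_response_table


def bisection_pod(params: HillParams, b: float) -> float:
    """Independent oracle: root of |r(c) - 1| = b by bracketing bisection."""
    if params.emax <= b:
        return np.inf

    def f(log_c):
        return abs(hill_response(np.exp(log_c), params) - 1.0) - b

    return float(np.exp(brentq(f, -30, 30, xtol=1e-12, rtol=1e-15)))


class TestHillResponse:
    def test_half_max_identity(self):
        p = HillParams(10, 0.5, 2, "decrease")
        assert abs(hill_response(10.0, p) - 1.0) == pytest.approx(0.25)

    def test_asymptote(self):
        p = HillParams(10, 0.5, 1, "increase")
        assert hill_response(1e12, p) == pytest.approx(1.5, rel=1e-6)

    def test_baseline_anchored_at_one(self):
        p = HillParams(3, 0.8, 2, "decrease")
        assert hill_response(0.0, p) == 1.0

    def test_direct_evaluation_decreasing(self):
        p = HillParams(10, 0.5, 1, "decrease")
        assert hill_response(10.0, p) == pytest.approx(0.75)

    def test_monotone_in_concentration(self):
        p = HillParams(5, 0.6, 1.7, "decrease")
        c = np.logspace(-3, 4, 200)
        r = hill_response(c, p)
        assert np.all(np.diff(r) < 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-1.0, HillParams(10, 0.5, 1))


class TestPodFromHill:
    def test_closed_form_example(self):
        pod = pod_from_hill(HillParams(10, 0.5, 1, "decrease"), 0.05)
        assert pod == pytest.approx(10 * 0.05 / 0.45, rel=1e-12)
        assert pod == pytest.approx(1.1111, abs=1e-4)

    def test_asystole_ec95_closed_form(self):
        pod = pod_from_hill(HillParams(50, 1.0, 2, "decrease"), 0.95)
        assert pod == pytest.approx(50 * np.sqrt(19), rel=1e-12)
        assert pod == pytest.approx(217.94, abs=0.01)

    def test_unreachable_benchmark_censored(self):
        assert pod_from_hill(HillParams(10, 0.04, 1), 0.05) == np.inf

    def test_closed_form_matches_bisection_on_random_sweep(self, rng):
        for _ in range(1000):
            p = HillParams(
                ec50_uM=float(10 ** rng.uniform(-2, 3)),
                emax=float(rng.uniform(0.01, 1.0)),
                hill_n=float(rng.uniform(0.3, 5.0)),
                direction="decrease",
            )
            b = float(rng.uniform(0.01, 0.95))
            closed = pod_from_hill(p, b)
            oracle = bisection_pod(p, b)
            if np.isinf(closed):
                assert np.isinf(oracle)
            else:
                assert closed == pytest.approx(oracle, rel=1e-6)

    def test_invalid_benchmark_rejected(self):
        with pytest.raises(ValueError):
            pod_from_hill(HillParams(10, 0.5, 1), 1.5)


def _degenerate_posterior(
    ec50=10.0, emax=0.5, hill_n=1.0, sigma_e=0.0, sigma_m=0.0,
    n_draws=200, n_donors=4, direction="decrease",
):
    """Posterior object with point-mass draws for analytic checks."""
    S = n_draws
    draws = {
        "mu_log_ec50": np.full(S, np.log(ec50)),
        "mu_log_emax": np.full(S, np.log(emax)),
        "log_n": np.full(S, np.log(hill_n)),
        "sigma_log_ec50": np.full(S, sigma_e),
        "sigma_log_emax": np.full(S, sigma_m),
        "sigma_resid": np.full(S, 0.05),
        "z": np.zeros((S, n_donors, 2)),
    }
    return PopulationPosterior(
        draws=draws, donor_ids=[f"D{i}" for i in range(n_donors)],
        direction=direction, rhat={"mu_log_ec50": 1.0}, converged=True,
        n_chains=4, n_iter=2000, seed=0,
    )


class TestPodsFromPosterior:
    def test_zero_population_variance_p05_equals_median_exactly(self):
        ps = pods_from_posterior(_degenerate_posterior(), "EC05")
        np.testing.assert_array_equal(ps.pod_p05_draws, ps.pod_median_draws)

    def test_zero_z_scores_make_donor_pods_equal_median(self):
        ps = pods_from_posterior(_degenerate_posterior(sigma_e=0.4), "EC05")
        for d in range(4):
            np.testing.assert_allclose(
                ps.donor_pod_draws[:, d], ps.pod_median_draws
            )

    def test_lognormal_ec50_spread_matches_closed_form(self):
        # random effect only on log EC50 with SD 0.7 and n=1:
        # POD_50 / POD_05 = exp(1.645 * 0.7) ~ 3.16
        ps = pods_from_posterior(
            _degenerate_posterior(sigma_e=0.7), "EC05",
            m_individuals=4000, seed=3,
        )
        ratio = np.median(ps.pod_median_draws / ps.pod_p05_draws)
        assert ratio == pytest.approx(np.exp(1.6449 * 0.7), rel=0.05)

    def test_drawwise_ordering_p05_below_median(self):
        ps = pods_from_posterior(
            _degenerate_posterior(sigma_e=0.4, sigma_m=0.2), "EC05", seed=5
        )
        ok = np.isfinite(ps.pod_p05_draws) & np.isfinite(ps.pod_median_draws)
        assert np.all(ps.pod_p05_draws[ok] <= ps.pod_median_draws[ok])

    def test_random_individual_sampler_spread(self):
        post = _degenerate_posterior(sigma_e=0.7)
        pods = sample_random_individual_pods(post, "EC05", n=20000, seed=2)
        # 5th pct of random individuals matches the sensitive-individual POD
        expected = pod_from_hill(HillParams(10, 0.5, 1, "decrease"), 0.05)
        assert np.median(pods) == pytest.approx(expected, rel=0.05)
        assert np.percentile(pods, 5) == pytest.approx(
            expected / np.exp(1.6449 * 0.7), rel=0.07
        )


class TestFitPopulation:
    def test_recovers_population_ec50_within_twofold(self):
        true = TrueHill(10.0, 0.5, 1.0, "decrease")
        resp, _ = simulate_response_table(
            true, n_donors=16, donor_sigma={"ec50": 0.3, "emax": 0.0},
            noise_cv=0.05, seed=42,
        )
        post = fit_population(resp, "decrease", SamplerSettings.desk(), seed=42)
        est = float(np.median(np.exp(post.draws["mu_log_ec50"])))
        assert post.converged
        assert 5.0 <= est <= 20.0
        assert post.n_draws == 1000

    def test_inert_chemical_pods_mostly_censored(self):
        rng = np.random.default_rng(0)
        rows = [
            {"donor_id": f"D{d}", "conc_uM": c,
             "response": 1.0 + rng.normal(0, 0.05)}
            for d in range(8)
            for c in (0.1, 1.0, 10.0, 100.0)
        ]
        post = fit_population(
            pd.DataFrame(rows), "decrease",
            SamplerSettings(n_iter=1500, max_iter=1500), seed=1,
        )
        ps = pods_from_posterior(post, "EC05")
        assert np.mean(~np.isfinite(ps.pod_median_draws)) >= 0.5

    def test_identical_chains_rhat_near_one(self):
        from cardiopop.population_hill import _rank_normalized_split_rhat

        draws = np.random.default_rng(0).standard_normal(4000)
        chains = np.stack([draws[:2000], draws[:2000]])
        assert _rank_normalized_split_rhat(chains) == pytest.approx(1.0, abs=0.02)

    def test_too_few_donors_rejected(self):
        df = pd.DataFrame(
            {"donor_id": ["D1"] * 4, "conc_uM": [0.1, 1, 10, 100],
             "response": [1, 1, 0.9, 0.6]}
        )
        with pytest.raises(ValueError, match="2 donors"):
            fit_population(df, "decrease")
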