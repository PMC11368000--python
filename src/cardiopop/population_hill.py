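"""Hierarchical Bayesian random-effects Hill concentration-response model.

For one chemical x phenotype, the vehicle-normalized response of donor ``d``
at concentration ``c`` is modelled as

    y ~ Normal( r_d(c), sigma_resid ),
    r_d(c) = 1 +/- emax_d * c^n / (ec50_d^n + c^n),

with the sign set by the phenotype's adverse direction, the baseline anchored
at 1.0 (vehicle), and donor-level lognormal random effects on ec50 and emax
(non-centered donor Z-scores; the Hill coefficient ``n`` is shared across
donors, since four test concentrations cannot identify donor-specific
slopes). All parameters are fitted on the natural-log scale so they are
strictly positive; emax is truncated at 1 so that decreasing responses stay
non-negative.

Posterior sampling uses an affine-invariant ensemble MCMC sampler (emcee)
run as several independent ensembles ("chains"); the first half of each
chain is discarded as warmup, convergence is judged by the rank-normalized
split potential scale reduction factor (R-hat <= 1.2), the iteration count
is doubled up to a ceiling when convergence fails, and a converged fit is
subsampled to 1,000 retained draws (250 per chain).

Points of departure (PODs) follow in closed form from the Hill parameters:
the concentration producing a fixed benchmark change b (5%, 10% or 95%) is

    POD = ec50 * ( b / (emax - b) )^(1/n),

censored at +infinity when emax never reaches the benchmark. From the
posterior we derive the median-individual POD, the population 5th-percentile
("sensitive individual") POD via Monte-Carlo virtual individuals, and
donor-specific PODs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .phenotypes import BENCHMARK_CHANGES, PHENOTYPES

__all__ = [
    "HillParams",
    "HillPriors",
    "SamplerSettings",
    "PopulationPosterior",
    "PODSet",
    "hill_response",
    "pod_from_hill",
    "fit_population",
    "pods_from_posterior",
    "sample_random_individual_pods",
]


@dataclass(frozen=True)
class HillParams:
    """Hill parameters on the natural scale (all strictly positive)."""

    ec50_uM: float
    emax: float
    hill_n: float
    direction: str = "decrease"

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0 or self.emax <= 0 or self.hill_n <= 0:
            raise ValueError("Hill parameters must be strictly positive")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")


def hill_response(conc_uM, params: HillParams):
    """Expected vehicle-normalized response ratio at ``conc_uM``.

    r(0) = 1; |r - 1| -> emax as c -> inf; |r(ec50) - 1| = emax / 2.
    """
    c = np.asarray(conc_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    frac = np.where(
        c > 0,
        1.0 / (1.0 + (params.ec50_uM / np.where(c > 0, c, 1.0)) ** params.hill_n),
        0.0,
    )
    sign = 1.0 if params.direction == "increase" else -1.0
    out = 1.0 + sign * params.emax * frac
    return out if out.ndim else float(out)


def _pod_closed_form(ec50, emax, hill_n, b):
    """Vectorized POD; +inf where the benchmark change is unreachable."""
    ec50 = np.asarray(ec50, dtype=float)
    emax = np.asarray(emax, dtype=float)
    hill_n = np.asarray(hill_n, dtype=float)
    reach = emax > b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(reach, b / np.where(reach, emax - b, 1.0), np.inf)
        pod = ec50 * ratio ** (1.0 / hill_n)
    return np.where(reach, pod, np.inf)


def pod_from_hill(params: HillParams, benchmark_change: float) -> float:
    """Concentration producing the benchmark change; ``inf`` when censored."""
    if not 0.0 < benchmark_change < 1.0:
        raise ValueError("benchmark_change must be in (0, 1)")
    return float(
        _pod_closed_form(params.ec50_uM, params.emax, params.hill_n, benchmark_change)
    )


# ---------------------------------------------------------------------------
# Priors and sampler settings
# ---------------------------------------------------------------------------


@dataclass
class HillPriors:
    """Weakly-informative priors on the log-scale parameters.

    Defaults: log ec50 centered at the geometric mid-point of the tested
    concentration range with SD 2; log emax centered at log 0.2 with SD 1
    and upper-truncated so emax <= 1; log n centered at 0 with SD 0.5;
    half-normal(1) on the population SDs and half-normal(0.2) on the
    residual SD of the response ratio.
    """

    log_ec50_loc: float = math.log(math.sqrt(0.1 * 100.0))
    log_ec50_scale: float = 2.0
    log_emax_loc: float = math.log(0.2)
    log_emax_scale: float = 1.0
    log_n_loc: float = 0.0
    log_n_scale: float = 0.5
    sigma_ec50_scale: float = 1.0
    sigma_emax_scale: float = 1.0
    sigma_resid_scale: float = 0.2
    emax_cap: float = 1.0

    @classmethod
    def from_concentrations(cls, conc_uM: Sequence[float], **overrides) -> "HillPriors":
        c = np.asarray(conc_uM, dtype=float)
        loc = float(np.log(np.sqrt(c.min() * c.max())))
        return cls(log_ec50_loc=loc, **overrides)


@dataclass
class SamplerSettings:
    """Ensemble-MCMC schedule.

    ``full`` mode follows the 8,000-32,000 iteration schedule with doubling
    on failed convergence; ``desk`` mode is the reduced schedule used for
    routine testing.
    """

    n_chains: int = 4
    n_iter: int = 2000
    max_iter: int = 8000
    n_walkers: int | None = None
    rhat_threshold: float = 1.2
    n_keep: int = 1000

    @classmethod
    def desk(cls, **kw) -> "SamplerSettings":
        return cls(n_iter=2000, max_iter=8000, **kw)

    @classmethod
    def full(cls, **kw) -> "SamplerSettings":
        return cls(n_iter=8000, max_iter=32000, **kw)


@dataclass
class PopulationPosterior:
    """Retained posterior draws plus convergence metadata.

    ``draws`` holds, per retained draw: population-median log-parameters
    (mu_log_ec50, mu_log_emax, log_n), population SDs (sigma_log_ec50,
    sigma_log_emax), donor Z-scores ``z`` with shape (S, n_donors, 2)
    ordered (ec50, emax), and the residual SD ``sigma_resid``.
    """

    draws: dict[str, np.ndarray]
    donor_ids: list
    direction: str
    rhat: dict[str, float]
    converged: bool
    n_chains: int
    n_iter: int
    seed: int
    emax_cap: float = 1.0

    @property
    def n_draws(self) -> int:
        return self.draws["mu_log_ec50"].size

    @property
    def rhat_max(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return float(max(vals)) if vals else float("nan")

    def population_median_params(self) -> dict[str, np.ndarray]:
        """Natural-scale parameters of the median individual, per draw."""
        d = self.draws
        return {
            "ec50": np.exp(d["mu_log_ec50"]),
            "emax": np.minimum(np.exp(d["mu_log_emax"]), self.emax_cap),
            "hill_n": np.exp(d["log_n"]),
        }

    def donor_params(self) -> dict[str, np.ndarray]:
        """Natural-scale donor-level parameters, shape (S, n_donors)."""
        d = self.draws
        log_ec50 = d["mu_log_ec50"][:, None] + d["sigma_log_ec50"][:, None] * d["z"][:, :, 0]
        log_emax = d["mu_log_emax"][:, None] + d["sigma_log_emax"][:, None] * d["z"][:, :, 1]
        return {
            "ec50": np.exp(log_ec50),
            "emax": np.minimum(np.exp(log_emax), self.emax_cap),
            "hill_n": np.exp(d["log_n"])[:, None],
        }

    def residual_cv_percent(self) -> float:
        """Posterior-median residual SD as % of the control level (1.0)."""
        return float(np.median(self.draws["sigma_resid"]) * 100.0)


# ---------------------------------------------------------------------------
# Log-posterior
# ---------------------------------------------------------------------------


def _param_names(n_donors: int) -> list[str]:
    # centered parameterization: donor-level log-parameters are free
    # coordinates; Z-scores are derived when draws are extracted
    names = [
        "mu_log_ec50",
        "mu_log_emax",
        "log_n",
        "log_sigma_log_ec50",
        "log_sigma_log_emax",
        "log_sigma_resid",
    ]
    names += [f"log_ec50[{d}]" for d in range(n_donors)]
    names += [f"log_emax[{d}]" for d in range(n_donors)]
    return names


def _make_log_prob(conc, donor_idx, y, n_donors, direction, priors: HillPriors):
    logc = np.log(conc)
    sign = 1.0 if direction == "increase" else -1.0
    N = y.size
    log_emax_cap = math.log(priors.emax_cap)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu_le, mu_lm, ln_n = theta[:, 0], theta[:, 1], theta[:, 2]
        ls_e, ls_m, ls_r = theta[:, 3], theta[:, 4], theta[:, 5]
        log_ec50_d = theta[:, 6 : 6 + n_donors]                     # (W, D)
        log_emax_d = theta[:, 6 + n_donors : 6 + 2 * n_donors]
        sig_e, sig_m, sig_r = np.exp(ls_e), np.exp(ls_m), np.exp(ls_r)

        lp = (
            -0.5 * ((mu_le - priors.log_ec50_loc) / priors.log_ec50_scale) ** 2
            - 0.5 * ((mu_lm - priors.log_emax_loc) / priors.log_emax_scale) ** 2
            - 0.5 * ((ln_n - priors.log_n_loc) / priors.log_n_scale) ** 2
            - 0.5 * (sig_e / priors.sigma_ec50_scale) ** 2 + ls_e
            - 0.5 * (sig_m / priors.sigma_emax_scale) ** 2 + ls_m
            - 0.5 * (sig_r / priors.sigma_resid_scale) ** 2 + ls_r
        )
        # donor-level lognormal random effects (centered)
        with np.errstate(over="ignore", invalid="ignore"):
            lp += (
                -0.5 * (((log_ec50_d - mu_le[:, None]) / sig_e[:, None]) ** 2).sum(axis=1)
                - n_donors * ls_e
                - 0.5 * (((log_emax_d - mu_lm[:, None]) / sig_m[:, None]) ** 2).sum(axis=1)
                - n_donors * ls_m
            )

        # truncation: population-median and donor-level emax <= cap
        bad = (mu_lm > log_emax_cap) | (log_emax_d > log_emax_cap).any(axis=1)
        # numerical guard against overflowing exponents
        bad |= ~np.isfinite(lp)

        with np.errstate(over="ignore", invalid="ignore"):
            n_hill = np.exp(np.clip(ln_n, -20, 20))[:, None]         # (W, 1)
            frac = expit(n_hill * (logc[None, :] - log_ec50_d[:, donor_idx]))
            pred = 1.0 + sign * np.exp(np.clip(log_emax_d[:, donor_idx], -700, 700)) * frac
            resid = y[None, :] - pred
            loglik = -0.5 * (resid**2).sum(axis=1) / sig_r**2 - N * ls_r
        out = lp + loglik
        bad |= ~np.isfinite(out)
        out[bad] = -np.inf
        return out

    return log_prob


def _initial_walkers(rng, n_walkers, n_donors, priors: HillPriors, log_prob):
    """Draw walkers from a mildly narrowed version of the prior, resampling
    any that land in a zero-density region."""
    def draw(n):
        # overdispersed but coherent: each walker's donor-level spread
        # matches its own population-SD coordinate, and the ensemble spans
        # a wide range of SDs so the donor directions are explorable
        th = np.empty((n, 6 + 2 * n_donors))
        th[:, 0] = priors.log_ec50_loc + rng.standard_normal(n) * min(priors.log_ec50_scale, 1.0)
        th[:, 1] = priors.log_emax_loc + rng.standard_normal(n) * 0.5
        th[:, 1] = np.minimum(th[:, 1], math.log(priors.emax_cap) - 0.02)
        th[:, 2] = priors.log_n_loc + rng.standard_normal(n) * 0.25
        th[:, 3] = rng.uniform(math.log(0.2), math.log(1.5), n)
        th[:, 4] = rng.uniform(math.log(0.05), math.log(0.8), n)
        th[:, 5] = np.log(np.abs(rng.standard_normal(n)) * priors.sigma_resid_scale * 0.5 + 1e-2)
        sig_e = np.exp(th[:, 3])[:, None]
        sig_m = np.exp(th[:, 4])[:, None]
        th[:, 6 : 6 + n_donors] = (
            th[:, [0]] + rng.standard_normal((n, n_donors)) * sig_e
        )
        th[:, 6 + n_donors :] = np.minimum(
            th[:, [1]] + rng.standard_normal((n, n_donors)) * sig_m,
            math.log(priors.emax_cap) - 0.01,
        )
        return th

    walkers = draw(n_walkers)
    for _ in range(100):
        lp = log_prob(walkers)
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        walkers[bad] = draw(int(bad.sum()))
    return walkers


def _rank_normalized_split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split-R-hat for one parameter, chains (C, K)."""
    import arviz as az

    return float(az.rhat(np.asarray(chains), method="rank"))


def fit_population(
    responses: pd.DataFrame,
    direction: str,
    settings: SamplerSettings | None = None,
    priors: HillPriors | None = None,
    seed: int = 0,
) -> PopulationPosterior:
    """Fit the population Hill model for one chemical x phenotype.

    ``responses`` needs columns donor_id, conc_uM, response (the
    vehicle-normalized ratio). Rows with missing responses are dropped.
    """
    import emcee

    settings = settings or SamplerSettings.desk()
    df = responses.dropna(subset=["response"]).copy()
    if df.empty:
        raise ValueError("no usable responses")
    donors = sorted(df["donor_id"].unique().tolist())
    if len(donors) < 2:
        raise ValueError("need responses from at least 2 donors")
    donor_idx = df["donor_id"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    conc = df["conc_uM"].to_numpy(dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    y = df["response"].to_numpy(dtype=float)

    if priors is None:
        priors = HillPriors.from_concentrations(conc)
    D = len(donors)
    ndim = 6 + 2 * D
    n_walkers = settings.n_walkers or max(2 * ndim + 2, 24)
    if n_walkers % 2:
        n_walkers += 1
    log_prob = _make_log_prob(conc, donor_idx, y, D, direction, priors)
    names = _param_names(D)

    n_iter = settings.n_iter
    converged = False
    while True:
        chains = []
        for c in range(settings.n_chains):
            ss = np.random.SeedSequence((seed, n_iter, c))
            rng = np.random.default_rng(ss)
            p0 = _initial_walkers(rng, n_walkers, D, priors, log_prob)
            sampler = emcee.EnsembleSampler(
                n_walkers, ndim, log_prob, vectorize=True,
            )
            sampler.random_state = np.random.RandomState(
                int(ss.generate_state(1)[0]) % (2**31 - 1)
            ).get_state()
            sampler.run_mcmc(p0, n_iter, progress=False, skip_initial_state_check=True)
            chain = sampler.get_chain()            # (steps, walkers, ndim)
            keep = chain[n_iter // 2 :]            # discard first half
            chains.append(keep.reshape(-1, ndim))  # step-major flatten
        stacked = np.stack(chains)                 # (C, K, ndim)

        # thin (order-preserving) for the diagnostic only
        K = stacked.shape[1]
        stride = max(1, K // 4000)
        diag = stacked[:, ::stride, :]
        rhat = {}
        for j, name in enumerate(names):
            rhat[name] = _rank_normalized_split_rhat(diag[:, :, j])
        converged = max(rhat.values()) <= settings.rhat_threshold
        if converged or n_iter >= settings.max_iter:
            break
        n_iter = min(2 * n_iter, settings.max_iter)

    # subsample to n_keep draws: n_keep / n_chains random draws per chain
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    per_chain = settings.n_keep // settings.n_chains
    picks = [rng.choice(stacked.shape[1], size=per_chain, replace=False)
             for _ in range(settings.n_chains)]
    sub = np.concatenate([stacked[c][idx] for c, idx in enumerate(picks)], axis=0)

    sig_e = np.exp(sub[:, 3])
    sig_m = np.exp(sub[:, 4])
    # derive donor Z-scores from the centered donor log-parameters
    z_e = (sub[:, 6 : 6 + D] - sub[:, [0]]) / np.maximum(sig_e, 1e-12)[:, None]
    z_m = (sub[:, 6 + D : 6 + 2 * D] - sub[:, [1]]) / np.maximum(sig_m, 1e-12)[:, None]
    draws = {
        "mu_log_ec50": sub[:, 0],
        "mu_log_emax": sub[:, 1],
        "log_n": sub[:, 2],
        "sigma_log_ec50": sig_e,
        "sigma_log_emax": sig_m,
        "sigma_resid": np.exp(sub[:, 5]),
        "z": np.stack([z_e, z_m], axis=2),
    }
    return PopulationPosterior(
        draws=draws,
        donor_ids=donors,
        direction=direction,
        rhat=rhat,
        converged=bool(converged),
        n_chains=settings.n_chains,
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PODs
# ---------------------------------------------------------------------------


@dataclass
class PODSet:
    """Draw-wise and summarized PODs for one chemical x phenotype."""

    chemical_id: str
    phenotype: str
    benchmark: str
    pod_median_draws: np.ndarray          # (S,)
    pod_p05_draws: np.ndarray             # (S,)
    donor_pod_draws: np.ndarray           # (S, D)
    donor_ids: list
    rhat_max: float = np.nan
    converged: bool = True

    @staticmethod
    def _summary(draws: np.ndarray) -> tuple[float, float, float, float]:
        # order-statistic quantiles: draws may contain +inf (censored), and
        # interpolating between infinities would produce NaN
        med = float(np.quantile(draws, 0.5, method="lower"))
        lo = float(np.quantile(draws, 0.05, method="lower"))
        hi = float(np.quantile(draws, 0.95, method="lower"))
        frac_cens = float(np.mean(~np.isfinite(draws)))
        return med, lo, hi, frac_cens

    @property
    def pod_median(self) -> float:
        return self._summary(self.pod_median_draws)[0]

    @property
    def pod_median_ci90(self) -> tuple[float, float]:
        s = self._summary(self.pod_median_draws)
        return s[1], s[2]

    @property
    def pod_p05(self) -> float:
        return self._summary(self.pod_p05_draws)[0]

    @property
    def pod_p05_ci90(self) -> tuple[float, float]:
        s = self._summary(self.pod_p05_draws)
        return s[1], s[2]

    @property
    def censored_fraction(self) -> float:
        return self._summary(self.pod_median_draws)[3]

    @property
    def censored(self) -> bool:
        """A POD summary is censored when >50% of draws are censored."""
        return self.censored_fraction > 0.5

    def donor_pods(self) -> pd.Series:
        """Posterior-median POD per donor."""
        return pd.Series(
            np.median(self.donor_pod_draws, axis=0), index=self.donor_ids
        )


def pods_from_posterior(
    posterior: PopulationPosterior,
    benchmark: str | float,
    chemical_id: str = "",
    phenotype: str = "",
    m_individuals: int = 1000,
    seed: int = 0,
) -> PODSet:
    """Derive the POD set from a fitted posterior.

    Per retained draw: the median-individual POD comes from the
    population-median parameters; the sensitive-individual POD is the 5th
    percentile of the POD over ``m_individuals`` virtual individuals sampled
    from the random-effect distribution; donor PODs use the donor-level
    parameters. Summaries are posterior medians with 90% CIs.
    """
    if isinstance(benchmark, str):
        b = BENCHMARK_CHANGES[benchmark]
        bname = benchmark
    else:
        b = float(benchmark)
        bname = f"EC{round(b * 100):02d}"
    d = posterior.draws
    med = posterior.population_median_params()
    pod_median = _pod_closed_form(med["ec50"], med["emax"], med["hill_n"], b)

    S = posterior.n_draws
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    z1 = rng.standard_normal((S, m_individuals))
    z2 = rng.standard_normal((S, m_individuals))
    ec50_i = np.exp(d["mu_log_ec50"][:, None] + d["sigma_log_ec50"][:, None] * z1)
    emax_i = np.minimum(
        np.exp(d["mu_log_emax"][:, None] + d["sigma_log_emax"][:, None] * z2),
        posterior.emax_cap,
    )
    pods_i = _pod_closed_form(ec50_i, emax_i, np.exp(d["log_n"])[:, None], b)
    pod_p05 = np.quantile(pods_i, 0.05, axis=1, method="lower")

    dp = posterior.donor_params()
    donor_pods = _pod_closed_form(dp["ec50"], dp["emax"], dp["hill_n"], b)

    return PODSet(
        chemical_id=chemical_id,
        phenotype=phenotype,
        benchmark=bname,
        pod_median_draws=pod_median,
        pod_p05_draws=pod_p05,
        donor_pod_draws=donor_pods,
        donor_ids=list(posterior.donor_ids),
        rhat_max=posterior.rhat_max,
        converged=posterior.converged,
    )


def sample_random_individual_pods(
    posterior: PopulationPosterior,
    benchmark: str | float,
    n: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo PODs of random individuals: per sample, draw a posterior
    draw (medians + variances) and fresh Z-scores for each parameter."""
    b = BENCHMARK_CHANGES[benchmark] if isinstance(benchmark, str) else float(benchmark)
    d = posterior.draws
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    s_idx = rng.integers(0, posterior.n_draws, size=n)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    ec50 = np.exp(d["mu_log_ec50"][s_idx] + d["sigma_log_ec50"][s_idx] * z1)
    emax = np.minimum(
        np.exp(d["mu_log_emax"][s_idx] + d["sigma_log_emax"][s_idx] * z2),
        posterior.emax_cap,
    )
    return _pod_closed_form(ec50, emax, np.exp(d["log_n"][s_idx]), b)


def benchmark_for_phenotype(phenotype: str) -> str:
    return PHENOTYPES[phenotype].benchmark
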