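"""Probabilistic in vitro-to-in vivo extrapolation and margins of exposure.

External oral exposure estimates (mg/kg BW/day), given as a median and a
95th-percentile upper bound of the predicted population-median exposure, are
fit to an equivalent lognormal distribution and sampled by Monte Carlo. Each
dose sample is converted to a steady-state plasma concentration via a
per-unit-dose factor Css(1 mg/kg/day) computed from a well-stirred
three-compartment steady-state clearance model:

    Css [uM]  =  D / CL,   D = 1000 / MW   [umol/kg/day per 1 mg/kg/day],
    CL [L/day/kg] = 24 * ( fup * GFR  +  Q_l * fup * Clint / (Q_l + fup * Clint) ),

with glomerular filtration rate GFR and liver blood flow Q_l per kg body
weight. A second, more conservative conversion assumes no hepatic clearance
(Clint = 0), leaving only renal filtration of the unbound fraction.
Biomonitoring blood ranges, when available, are used directly as internal
concentrations.

The margin of exposure (MOE) compares bioactivity with internal exposure:
the population-median MOE divides the 5th-percentile bound of the
median-individual POD distribution by the 95th-percentile internal
concentration; the random-individual MOE uses the 5th percentile of the
random-individual POD distribution instead. Bands: < 1 likely of concern,
1-100 of potential concern, >= 100 protective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

Z95 = float(norm.ppf(0.95))        # 1.6449

# Physiological defaults (per kg body weight)
DEFAULT_GFR_PERKG = 1.53 * 60.0 / 1000.0    # 1.53 mL/min/kg -> 0.0918 L/h/kg
DEFAULT_QLIVER_PERKG = 1.24                 # L/h/kg

CSS_METHODS = ("steady_state_3c", "no_hepatic_clearance")
MOE_BANDS = ("<1", "1-100", ">=100")


@dataclass(frozen=True)
class TKParams:
    """Toxicokinetic parameters for the steady-state conversion."""

    mw: float                                   # g/mol
    fup: float                                  # fraction unbound in plasma
    clint: float = 0.0                          # intrinsic hepatic clearance, L/h/kg
    gfr_perkg: float = DEFAULT_GFR_PERKG        # L/h/kg
    q_liver_perkg: float = DEFAULT_QLIVER_PERKG # L/h/kg

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if not 0.0 <= self.fup <= 1.0:
            raise ValueError("fup must be in [0, 1]")
        if self.clint < 0 or self.gfr_perkg <= 0 or self.q_liver_perkg <= 0:
            raise ValueError("clearance parameters must be non-negative")


@dataclass(frozen=True)
class ExposureEstimate:
    """Predicted oral exposure and optional biomonitoring blood range."""

    chemical_id: str
    oral_median: float                  # mg/kg BW/day
    oral_upper95: float                 # mg/kg BW/day
    biomonitoring_lo: float | None = None   # uM, 5th percentile
    biomonitoring_hi: float | None = None   # uM, 95th percentile

    def __post_init__(self) -> None:
        if self.oral_median <= 0:
            raise ValueError("oral_median must be positive")
        if self.oral_upper95 < self.oral_median:
            raise ValueError("oral_upper95 must be >= oral_median")


def fit_exposure_lognormal(median: float, upper95: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) of log-exposure matching the 50th and 95th
    percentiles exactly: mu = ln median, sigma = (ln u95 - ln median)/z95."""
    if median <= 0 or upper95 < median:
        raise ValueError("need 0 < median <= upper95")
    mu = float(np.log(median))
    sigma = float((np.log(upper95) - np.log(median)) / Z95)
    return mu, sigma


def css_per_unit_dose(tk: TKParams, method: str = "steady_state_3c") -> float:
    """Steady-state plasma concentration (uM) per 1 mg/kg BW/day oral dose.

    ``no_hepatic_clearance`` forces Clint = 0, leaving renal filtration of
    the unbound fraction as the only elimination route.
    """
    if method not in CSS_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if tk.fup == 0:
        raise ZeroDivisionError(
            f"fup = 0 gives infinite Css; exclude this chemical"
        )
    clint = 0.0 if method == "no_hepatic_clearance" else tk.clint
    dose_umol = 1000.0 / tk.mw                        # umol/kg/day
    hepatic = (
        tk.q_liver_perkg * tk.fup * clint / (tk.q_liver_perkg + tk.fup * clint)
        if clint > 0
        else 0.0
    )
    cl = 24.0 * (tk.fup * tk.gfr_perkg + hepatic)     # L/day/kg
    return dose_umol / cl


def moe_band(moe: float) -> str:
    """<1 likely of concern; 1-100 potential concern; >=100 protective."""
    if moe < 1.0:
        return "<1"
    if moe < 100.0:
        return "1-100"
    return ">=100"


@dataclass
class MOEResult:
    """Margins of exposure for one chemical across phenotypes x methods."""

    chemical_id: str
    table: pd.DataFrame          # phenotype, method, conc_q95, moe_median, moe_random
    min_moe: float
    band: str | None
    excluded: bool = False
    reason: str = ""


def _internal_conc_q95(
    exposure: ExposureEstimate,
    tk: TKParams | None,
    methods: Iterable[str],
    n_mc: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """95th-percentile internal concentration per exposure method (uM)."""
    out: dict[str, float] = {}
    mu, sigma = fit_exposure_lognormal(exposure.oral_median, exposure.oral_upper95)
    if tk is not None:
        doses = (
            np.full(n_mc, np.exp(mu))
            if sigma == 0
            else np.exp(rng.normal(mu, sigma, size=n_mc))
        )
        for method in methods:
            factor = css_per_unit_dose(tk, method)
            conc = doses * factor
            out[method] = float(np.exp(mu) * factor) if sigma == 0 else float(
                np.percentile(conc, 95)
            )
    if exposure.biomonitoring_hi is not None:
        # the reported range is already an internal concentration
        out["biomonitoring"] = float(exposure.biomonitoring_hi)
    return out


def compute_moe(
    pod_draws: Mapping[str, Mapping[str, np.ndarray]],
    exposure: ExposureEstimate,
    tk: TKParams | None,
    n_mc: int = 10000,
    seed: int = 0,
    methods: Iterable[str] = CSS_METHODS,
) -> MOEResult:
    """Monte-Carlo margins of exposure for one chemical.

    ``pod_draws`` maps active phenotype -> {"median": draws of the
    median-individual POD, "random": draws of random-individual PODs}
    (uM; +inf marks censored draws). The population-median MOE divides the
    5th percentile of the median-POD distribution by the 95th percentile of
    the internal concentration; the random-individual MOE uses the 5th
    percentile of the random-individual distribution. The summary MOE is
    the minimum across phenotypes and exposure methods.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    rows = []
    conc_q95 = _internal_conc_q95(exposure, tk, methods, n_mc, rng)
    if not conc_q95:
        return MOEResult(exposure.chemical_id, pd.DataFrame(), np.nan, None,
                         excluded=True, reason="no internal-concentration route")
    any_finite = False
    for phenotype, draws in pod_draws.items():
        med = np.asarray(draws["median"], dtype=float)
        if np.mean(~np.isfinite(med)) >= 0.95:
            continue  # all-censored phenotype: no POD distribution
        pod_q05_median = float(np.percentile(med, 5))
        rnd = draws.get("random")
        pod_q05_random = (
            float(np.percentile(np.asarray(rnd, dtype=float), 5))
            if rnd is not None
            else np.nan
        )
        for method, q95 in conc_q95.items():
            moe_med = pod_q05_median / q95
            moe_rnd = pod_q05_random / q95 if np.isfinite(pod_q05_random) else np.nan
            if np.isfinite(moe_med):
                any_finite = True
            rows.append(
                {
                    "phenotype": phenotype,
                    "method": method,
                    "conc_q95_uM": q95,
                    "moe_population_median": moe_med,
                    "moe_random_individual": moe_rnd,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty or not any_finite:
        return MOEResult(exposure.chemical_id, table, np.nan, None,
                         excluded=True, reason="all PODs censored")
    candidates = pd.concat(
        [table["moe_population_median"], table["moe_random_individual"]]
    ).dropna()
    min_moe = float(candidates.min())
    return MOEResult(exposure.chemical_id, table, min_moe, moe_band(min_moe))


def moe_table(results: Iterable[MOEResult]) -> pd.DataFrame:
    """Flat summary across chemicals (the ``moe.csv`` contract)."""
    rows = []
    for r in results:
        rows.append(
            {
                "chemical_id": r.chemical_id,
                "min_moe": r.min_moe,
                "band": r.band,
                "excluded": r.excluded,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
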