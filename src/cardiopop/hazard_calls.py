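"""Activity calls, population-variability criteria and TDVF05.

A chemical x phenotype combination is called **active** when all four
activity criteria hold:

  (i)   adequate MCMC convergence, R-hat <= 1.2;
  (ii)  model-fit coefficient of variability < 20%;
  (iii) population-median POD below 3x the maximum tested concentration
        (300 uM at the default 100 uM top concentration);
  (iv)  the 5th percentile of the posterior maximum response (Emax)
        exceeds a 10% change.

It additionally qualifies for **population-variability** analysis when

  (5)  the 90% CI of the population-median POD spans < 100-fold;
  (6)  the 90% CI of the sensitive (population 5th-percentile) POD spans
       < 100-fold;
  (7)  at least half the donors have non-zero data at >= 3 concentrations.

For qualifying combinations the toxicodynamic variability factor
TDVF05 = POD(median individual) / POD(sensitive 5th-percentile individual)
is computed draw-wise and summarized by its posterior median, then placed
in a band relative to the conventional default factor 10^(1/2) ~ 3.16 and
the total default of 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population_hill import PODSet, PopulationPosterior

TDVF_DEFAULT = math.sqrt(10.0)       # 3.16, conventional toxicodynamic factor
TDVF_BANDS = ("<10^1/2", "10^1/2-10", ">10")


@dataclass(frozen=True)
class ActivityThresholds:
    """Criterion cut-offs; defaults are the published values."""

    rhat_max: float = 1.2
    fit_cv_pct: float = 20.0
    pod_max_factor: float = 3.0          # x max tested concentration
    emax_q05_min: float = 0.10
    ci_fold_max: float = 100.0
    coverage_min: float = 0.5
    min_concs: int = 3
    fit_cv_basis: str = "residual"       # or "pod"


@dataclass
class ActivityCall:
    chemical_id: str
    phenotype: str
    c1_convergence: bool
    c2_cv_fit: bool
    c3_pod_range: bool
    c4_emax: bool
    v5_median_ci_span: bool
    v6_sensitive_ci_span: bool
    v7_data_coverage: bool
    fit_cv_pct: float
    reason: str = ""

    @property
    def active(self) -> bool:
        return self.c1_convergence and self.c2_cv_fit and self.c3_pod_range and self.c4_emax

    @property
    def active_popvar(self) -> bool:
        return self.active and self.v5_median_ci_span and self.v6_sensitive_ci_span and self.v7_data_coverage

    @property
    def status(self) -> str:
        if self.active_popvar:
            return "active_popvar"
        return "active" if self.active else "inactive"


def fit_cv_percent(
    posterior: PopulationPosterior,
    podset: PODSet | None = None,
    basis: str = "residual",
) -> float:
    """Model-fit coefficient of variability (%).

    ``residual`` (default): posterior-median residual SD as a percentage of
    the control-normalized response level (1.0). ``pod``: CV of the finite
    median-POD posterior draws. The published criterion names a "CV for
    model fit" without defining it; both readings are available.
    """
    if basis == "residual":
        return posterior.residual_cv_percent()
    if basis == "pod":
        if podset is None:
            raise ValueError("pod basis needs a PODSet")
        d = podset.pod_median_draws
        d = d[np.isfinite(d)]
        if d.size < 2 or d.mean() == 0:
            return float("inf")
        return float(d.std(ddof=1) / d.mean() * 100.0)
    raise ValueError(f"unknown basis {basis!r}")


def data_coverage(
    responses: pd.DataFrame,
    min_concs: int = 3,
) -> float:
    """Fraction of donors with non-missing data at >= ``min_concs``
    concentrations (wells present and not QC-failed)."""
    ok = responses.dropna(subset=["response"])
    per_donor = ok.groupby("donor_id")["conc_uM"].nunique()
    donors = responses["donor_id"].nunique()
    if donors == 0:
        return 0.0
    return float((per_donor >= min_concs).sum() / donors)


def call_activity(
    podset: PODSet | None,
    posterior: PopulationPosterior | None,
    coverage: float,
    max_conc_uM: float = 100.0,
    thresholds: ActivityThresholds = ActivityThresholds(),
) -> ActivityCall:
    """Apply activity criteria (i)-(iv) and variability criteria (5)-(7)."""
    chem = podset.chemical_id if podset else ""
    phen = podset.phenotype if podset else ""
    if podset is None or posterior is None:
        return ActivityCall(
            chem, phen, False, False, False, False, False, False, False,
            fit_cv_pct=float("nan"), reason="missing posterior",
        )
    cv = fit_cv_percent(posterior, podset, basis=thresholds.fit_cv_basis)
    c1 = bool(podset.rhat_max <= thresholds.rhat_max)
    c2 = bool(cv < thresholds.fit_cv_pct)
    c3 = bool(podset.pod_median < thresholds.pod_max_factor * max_conc_uM)
    emax_draws = posterior.population_median_params()["emax"]
    c4 = bool(np.percentile(emax_draws, 5) > thresholds.emax_q05_min)

    lo, hi = podset.pod_median_ci90
    v5 = bool(np.isfinite(lo) and np.isfinite(hi) and lo > 0 and hi / lo < thresholds.ci_fold_max)
    lo5, hi5 = podset.pod_p05_ci90
    v6 = bool(np.isfinite(lo5) and np.isfinite(hi5) and lo5 > 0 and hi5 / lo5 < thresholds.ci_fold_max)
    v7 = bool(coverage >= thresholds.coverage_min)
    return ActivityCall(chem, phen, c1, c2, c3, c4, v5, v6, v7, fit_cv_pct=cv)


def tdvf_band(tdvf: float) -> str:
    """Band relative to the 10^(1/2) and 10 default factors."""
    if tdvf < TDVF_DEFAULT:
        return "<10^1/2"
    if tdvf <= 10.0:
        return "10^1/2-10"
    return ">10"


@dataclass
class TDVFResult:
    chemical_id: str
    phenotype: str
    tdvf05: float                   # posterior median of the draw-wise ratio
    ci90: tuple[float, float]
    band: str
    excluded_fraction: float        # draws dropped for censored sensitive POD
    draws: np.ndarray = field(repr=False, default=None)


def tdvf05(podset: PODSet) -> TDVFResult:
    """Toxicodynamic variability factor TDVF05 for one chemical x phenotype.

    The ratio POD(median individual)/POD(sensitive individual) is taken
    draw-wise (preserving the draw-wise ordering POD_05 <= POD_50), and the
    posterior median of the ratio is reported, not the ratio of summaries.
    Draws with a censored sensitive POD are excluded with their fraction
    recorded.
    """
    med = podset.pod_median_draws
    p05 = podset.pod_p05_draws
    valid = np.isfinite(p05) & np.isfinite(med)
    excluded = float(1.0 - valid.mean())
    if valid.sum() == 0:
        return TDVFResult(
            podset.chemical_id, podset.phenotype, float("nan"),
            (float("nan"), float("nan")), "", excluded, np.array([]),
        )
    ratio = med[valid] / p05[valid]
    tdvf = float(np.median(ratio))
    lo, hi = np.percentile(ratio, [5, 95])
    return TDVFResult(
        podset.chemical_id, podset.phenotype, tdvf, (float(lo), float(hi)),
        tdvf_band(tdvf), excluded, ratio,
    )


def activity_table(calls: list[ActivityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": c.chemical_id,
                "phenotype": c.phenotype,
                "c1_convergence": c.c1_convergence,
                "c2_cv_fit": c.c2_cv_fit,
                "c3_pod_range": c.c3_pod_range,
                "c4_emax": c.c4_emax,
                "v5_median_ci_span": c.v5_median_ci_span,
                "v6_sensitive_ci_span": c.v6_sensitive_ci_span,
                "v7_data_coverage": c.v7_data_coverage,
                "fit_cv_pct": c.fit_cv_pct,
                "status": c.status,
            }
            for c in calls
        ]
    )


def tdvf_table(results: list[TDVFResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "phenotype": r.phenotype,
                "tdvf05": r.tdvf05,
                "ci90_lo": r.ci90[0],
                "ci90_hi": r.ci90[1],
                "band": r.band,
                "excluded_fraction": r.excluded_fraction,
            }
            for r in results
        ]
    )
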