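"""Vehicle normalization, control gating and reproducibility analysis.

Raw per-well phenotype values are expressed relative to the mean of the
vehicle-control wells (0.5% DMSO) on the same plate, so 1.0 means
"indistinguishable from control". Reproducibility is quantified by Pearson
correlation of replicate wells, and the observed variability in control
wells is decomposed into donor (biological), plate (technical),
vehicle-vs-media and residual components with a nested random-effects model
fitted by REML (method-of-moments fallback with negative components
truncated at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calcium_features import CYTOTOX_NUCLEI_FRAC

# Channels derived per well before vehicle normalization: within-well
# treated/baseline ratios for the functional readouts, raw counts for nuclei.
RATIO_CHANNELS = ("beat_rate_ratio", "decay_to_rise_ratio", "nuclei_ratio")


class MissingVehicleError(ValueError):
    """A plate has no vehicle wells to normalize against."""


def well_channels(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Within-well measurement channels from the phenotype table.

    beat_rate_ratio and decay_to_rise_ratio compare the treated phase with
    the same well's baseline (chronotropy and QT-proxy change);
    nuclei_ratio carries the raw count until vehicle normalization.
    """
    out = phenotypes[["plate_id", "well"]].copy()
    out["beat_rate_ratio"] = (
        phenotypes["beat_rate_bpm_treated"] / phenotypes["beat_rate_bpm_baseline"]
    )
    out["decay_to_rise_ratio"] = (
        phenotypes["decay_to_rise_treated"] / phenotypes["decay_to_rise_baseline"]
    )
    out["nuclei_ratio"] = phenotypes["nuclei_count"].astype(float)
    if "quality_ok" in phenotypes:
        bad = ~phenotypes["quality_ok"].astype(bool)
        out.loc[bad.to_numpy(), ["beat_rate_ratio", "decay_to_rise_ratio"]] = np.nan
    return out


def normalize_to_vehicle(
    phenotypes: pd.DataFrame,
    wells: pd.DataFrame,
    channels: tuple[str, ...] = RATIO_CHANNELS,
) -> pd.DataFrame:
    """Divide each well's channel values by its plate's vehicle mean.

    Returns one row per well with normalized channels plus the well
    identity columns; vehicle wells average to 1.0 per plate x channel by
    construction. Raises :class:`MissingVehicleError` naming any plate
    without vehicle wells.
    """
    chan = well_channels(phenotypes) if "beat_rate_ratio" not in phenotypes else phenotypes
    df = wells.merge(chan, on=["plate_id", "well"], how="inner")
    veh = df[df["treatment_type"] == "vehicle"]
    missing = set(df["plate_id"]) - set(veh["plate_id"])
    if missing:
        raise MissingVehicleError(
            f"plates without vehicle wells: {sorted(missing)}"
        )
    veh_means = veh.groupby("plate_id")[list(channels)].mean()
    out = df.copy()
    for ch in channels:
        out[ch] = df[ch] / df["plate_id"].map(veh_means[ch])
    return out


def replicate_correlation(values_a, values_b) -> dict:
    """Pearson r and two-sided p for paired replicate measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        return {"pearson_r": np.nan, "p_value": np.nan, "degenerate": True}
    r, p = stats.pearsonr(a, b)
    return {"pearson_r": float(r), "p_value": float(p), "degenerate": False}


@dataclass
class VarianceDecomposition:
    """Fractions of control-well variance by source, plus CVs (%)."""

    phenotype: str
    fractions: dict[str, float]     # donor, plate, vehicle_vs_media, residual
    cv_total: float
    cv_donor: float
    zero_variance: bool = False
    estimator: str = "reml"

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not self.zero_variance and abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {total}, not 1")


def _mom_decomposition(df: pd.DataFrame) -> tuple[dict[str, float], float]:
    """Method-of-moments nested components, truncated at zero."""
    grand = df["value"].mean()
    # between-donor
    donor_means = df.groupby("donor_id")["value"].mean()
    var_donor = max(donor_means.var(ddof=1) if len(donor_means) > 1 else 0.0, 0.0)
    # plate within donor
    plate_means = df.groupby(["donor_id", "plate_id"])["value"].mean()
    per_donor_var = plate_means.groupby("donor_id").var(ddof=1).dropna()
    var_plate = max(float(per_donor_var.mean()) if len(per_donor_var) else 0.0, 0.0)
    var_donor = max(var_donor - var_plate / max(
        df.groupby("donor_id")["plate_id"].nunique().mean(), 1.0), 0.0)
    # vehicle vs media (fixed contrast) as explained variance
    grp = df.groupby("treatment_type")["value"].mean()
    fitted = df["treatment_type"].map(grp)
    var_fixed = max(float(np.var(fitted, ddof=0)), 0.0)
    resid = df["value"] - fitted - (
        df["donor_id"].map(donor_means) - grand
    )
    var_resid = max(float(np.var(resid, ddof=0)) - var_plate, 0.0)
    return (
        {
            "donor": var_donor,
            "plate": var_plate,
            "vehicle_vs_media": var_fixed,
            "residual": var_resid,
        },
        grand,
    )


def decompose_variance(
    control_values: pd.DataFrame,
    phenotype: str = "",
) -> VarianceDecomposition:
    """Decompose control-well variability into donor / plate / control-type
    / residual components.

    ``control_values`` needs columns donor_id, plate_id, treatment_type
    (vehicle or media) and value (raw phenotype units). Donor and
    plate-within-donor enter as nested random effects estimated by REML;
    the vehicle-vs-media contrast is a fixed effect whose contribution is
    measured as explained variance. Single-level factors get a zero
    component with a warning.
    """
    df = control_values.dropna(subset=["value"]).copy()
    if df["donor_id"].nunique() < 2:
        raise ValueError("need control wells from at least 2 donors")
    grand = df["value"].mean()
    if np.allclose(df["value"].var(ddof=0), 0.0):
        return VarianceDecomposition(
            phenotype,
            {"donor": 0.0, "plate": 0.0, "vehicle_vs_media": 0.0, "residual": 0.0},
            cv_total=0.0,
            cv_donor=0.0,
            zero_variance=True,
        )

    multi_plate = (df.groupby("donor_id")["plate_id"].nunique() > 1).any()
    if not multi_plate:
        warnings.warn("single plate per donor: plate component set to 0")

    components: dict[str, float] | None = None
    estimator = "reml"
    try:
        import statsmodels.formula.api as smf

        vc = {"plate": "0 + C(plate_id)"} if multi_plate else {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ C(treatment_type)",
                df,
                groups="donor_id",
                re_formula="1",
                vc_formula=vc or None,
            )
            fit = model.fit(reml=True)
        var_donor = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
        var_plate = (
            max(float(np.asarray(fit.vcomp)[0]), 0.0) if multi_plate else 0.0
        )
        var_resid = max(float(fit.scale), 0.0)
        fitted_fixed = np.asarray(fit.model.exog @ fit.fe_params)
        var_fixed = max(float(np.var(fitted_fixed, ddof=0)), 0.0)
        components = {
            "donor": var_donor,
            "plate": var_plate,
            "vehicle_vs_media": var_fixed,
            "residual": var_resid,
        }
    except Exception:
        components = None
    if components is None:
        components, grand = _mom_decomposition(df)
        estimator = "method_of_moments"

    total = sum(components.values())
    fractions = {k: v / total for k, v in components.items()}
    return VarianceDecomposition(
        phenotype,
        fractions,
        cv_total=float(np.sqrt(total) / grand * 100.0),
        cv_donor=float(np.sqrt(components["donor"]) / grand * 100.0),
        estimator=estimator,
    )


@dataclass
class ControlGateResult:
    plate_id: str
    passed: bool
    isoproterenol_ok: bool
    propranolol_ok: bool
    sotalol_ok: bool
    vehicle_beating: bool


def control_gate(
    normalized: pd.DataFrame,
    phenotypes: pd.DataFrame,
    plate_id: str,
) -> ControlGateResult:
    """Directional positive/negative-control check for one plate.

    Passes iff isoproterenol wells raise the beat-rate ratio above 1,
    propranolol lowers it below 1, sotalol raises the decay-to-rise ratio
    above 1, and the vehicle wells beat spontaneously. Thresholds are
    directional only: control effect sizes are donor-specific.
    """
    plate = normalized[normalized["plate_id"] == plate_id]
    ph = phenotypes[phenotypes["plate_id"] == plate_id]

    def mean_ratio(chem: str, channel: str) -> float:
        sub = plate[
            (plate["treatment_type"] == "positive_control")
            & (plate["chemical_id"] == chem)
        ]
        return float(sub[channel].mean()) if len(sub) else np.nan

    iso = mean_ratio("isoproterenol", "beat_rate_ratio")
    prop = mean_ratio("propranolol", "beat_rate_ratio")
    sot = mean_ratio("sotalol", "decay_to_rise_ratio")
    veh_wells = plate[plate["treatment_type"] == "vehicle"]["well"]
    veh_ph = ph[ph["well"].isin(veh_wells)]
    vehicle_beating = bool(
        len(veh_ph) > 0 and (veh_ph["beat_rate_bpm_treated"] > 0).all()
    )
    iso_ok = bool(iso > 1.0)
    prop_ok = bool(prop < 1.0)
    sot_ok = bool(sot > 1.0)
    return ControlGateResult(
        plate_id=plate_id,
        passed=iso_ok and prop_ok and sot_ok and vehicle_beating,
        isoproterenol_ok=iso_ok,
        propranolol_ok=prop_ok,
        sotalol_ok=sot_ok,
        vehicle_beating=vehicle_beating,
    )


def qc_report(normalized: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-plate gate results plus intra-plate replicate correlations."""
    rows = []
    for pid in sorted(normalized["plate_id"].unique()):
        gate = control_gate(normalized, phenotypes, pid)
        plate = normalized[normalized["plate_id"] == pid]
        test = plate[plate["treatment_type"] == "test"]
        rep_r, rep_p = np.nan, np.nan
        dup = test.groupby(["chemical_id", "conc_uM"]).filter(lambda g: len(g) == 2)
        if len(dup) >= 6:
            first = dup.groupby(["chemical_id", "conc_uM"])["beat_rate_ratio"].first()
            second = dup.groupby(["chemical_id", "conc_uM"])["beat_rate_ratio"].last()
            ok = first.notna() & second.notna()
            if ok.sum() >= 3:
                res = replicate_correlation(first[ok], second[ok])
                rep_r, rep_p = res["pearson_r"], res["p_value"]
        rows.append(
            {
                "plate_id": pid,
                "gate_passed": gate.passed,
                "isoproterenol_ok": gate.isoproterenol_ok,
                "propranolol_ok": gate.propranolol_ok,
                "sotalol_ok": gate.sotalol_ok,
                "vehicle_beating": gate.vehicle_beating,
                "replicate_pearson_r": rep_r,
                "replicate_p_value": rep_p,
            }
        )
    return pd.DataFrame(rows)
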