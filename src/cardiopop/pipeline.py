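"""End-to-end orchestration with stable file contracts.

Stages run in dependency order:

    simulate -> features -> qc -> fit -> calls -> toxpi -> moe -> sar

Every stage reads and writes CSV tables under one run directory, validating
schemas on both sides, so stages can be re-run independently and a rerun
with the same configuration and seed reproduces all stochastic outputs.
Posterior draws are persisted per chemical x phenotype so downstream stages
(calls, moe, sar) can recompute POD draws deterministically.

Tables are UTF-8 CSV with "." decimals; censored PODs are serialized as the
literal token "Inf" together with a censored flag column. A JSON manifest
records versions, seeds, thresholds and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calcium_features import phenotype_table
from .hazard_calls import (
    ActivityThresholds,
    activity_table,
    call_activity,
    data_coverage,
    tdvf05,
    tdvf_table,
)
from .ivive_moe import ExposureEstimate, TKParams, compute_moe, moe_table
from .phenotypes import PHENOTYPE_NAMES, PHENOTYPES
from .plate_qc import decompose_variance, normalize_to_vehicle, qc_report
from .population_hill import (
    PODSet,
    PopulationPosterior,
    SamplerSettings,
    fit_population,
    pods_from_posterior,
    sample_random_individual_pods,
)
from .structure_activity import (
    bioactivity_matrix,
    permutation_significance,
    spearman_screen,
    variation_filter,
)
from .synthetic_study import StudyConfig, generate_study
from .toxpi_rank import pod_input_matrix, toxpi_scores

log = logging.getLogger("cardiopop")

STAGES = ("simulate", "features", "qc", "fit", "calls", "toxpi", "moe", "sar")

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "wells": ("plate_id", "well", "row", "col", "donor_id", "treatment_type",
              "chemical_id", "conc_uM", "batch"),
    "traces": ("plate_id", "well", "phase", "frame", "value"),
    "nuclei": ("plate_id", "well", "nuclei_count"),
    "registry": ("chemical_id", "name", "subclass"),
    "exposures": ("chemical_id", "oral_median", "oral_upper95"),
    "tk_params": ("chemical_id", "mw", "fup", "clint"),
    "phenotypes": ("plate_id", "well", "beat_rate_bpm_baseline",
                   "beat_rate_bpm_treated", "decay_to_rise_baseline",
                   "decay_to_rise_treated", "peak_count_treated", "asystole",
                   "nuclei_count"),
    "normalized": ("plate_id", "well", "donor_id", "treatment_type",
                   "chemical_id", "conc_uM", "beat_rate_ratio",
                   "decay_to_rise_ratio", "nuclei_ratio"),
    "qc_report": ("plate_id", "gate_passed"),
    "variance_decomposition": ("phenotype", "frac_donor", "frac_plate",
                               "frac_vehicle_vs_media", "frac_residual",
                               "cv_total", "cv_donor"),
    "pods": ("chemical_id", "phenotype", "benchmark", "pod_median",
             "pod_median_ci90_lo", "pod_median_ci90_hi", "pod_p05",
             "pod_p05_ci90_lo", "pod_p05_ci90_hi", "rhat_max", "converged",
             "censored_fraction", "censored"),
    "activity_calls": ("chemical_id", "phenotype", "status"),
    "tdvf": ("chemical_id", "phenotype", "tdvf05", "band"),
    "toxpi": ("chemical_id", "overall_score", "rank"),
    "moe": ("chemical_id", "min_moe", "band"),
    "sar_correlations": ("descriptor", "variable", "spearman_rho", "p", "q"),
    "sar_predictions": ("variable", "cv_prediction_r", "empirical_p", "p_adj", "q"),
}


class SchemaError(ValueError):
    """A table violates its file contract."""


def validate_table(df: pd.DataFrame, name: str, path: str | Path = "") -> None:
    required = TABLE_SCHEMAS[name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        where = f" in {path}" if path else ""
        raise SchemaError(
            f"table '{name}'{where}: missing required column(s) {missing}"
        )


def write_table(df: pd.DataFrame, name: str, outdir: Path) -> Path:
    validate_table(df, name)
    path = outdir / f"{name}.csv"
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            vals = out[col]
            if np.isinf(vals).any():
                out[col] = vals.replace({np.inf: "Inf", -np.inf: "-Inf"})
    out.to_csv(path, index=False)
    return path


def read_table(name: str, outdir: Path) -> pd.DataFrame:
    path = outdir / f"{name}.csv"
    if not path.exists():
        raise FileNotFoundError(f"required table {path} not found; run earlier stages")
    df = pd.read_csv(path)
    for col in df.columns:
        if df[col].dtype == object and df[col].isin(["Inf", "-Inf"]).any():
            df[col] = df[col].replace({"Inf": np.inf, "-Inf": -np.inf}).astype(float)
    validate_table(df, name, path)
    return df


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the published criteria."""

    outdir: str | Path = "run"
    seed: int = 0
    mode: str = "desk"                    # desk | full
    study: StudyConfig = field(default_factory=StudyConfig)
    phenotypes: tuple[str, ...] = PHENOTYPE_NAMES
    thresholds: ActivityThresholds = field(default_factory=ActivityThresholds)
    n_mc: int = 10000
    n_perm: int | None = None             # None -> 999 desk / 10000 full
    m_individuals: int = 1000
    sar_min_only: bool = False            # screen only across-donor minima

    def sampler_settings(self) -> SamplerSettings:
        return SamplerSettings.full() if self.mode == "full" else SamplerSettings.desk()

    @property
    def n_permutations(self) -> int:
        if self.n_perm is not None:
            return self.n_perm
        return 10000 if self.mode == "full" else 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        study = StudyConfig(**raw.pop("study", {}))
        thresholds = ActivityThresholds(**raw.pop("thresholds", {}))
        return cls(study=study, thresholds=thresholds, **raw)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    study = dataclasses.replace(config.study, seed=config.seed)
    bundle = generate_study(study)
    counts = {}
    for name, df in (
        ("wells", bundle.wells),
        ("traces", bundle.traces),
        ("nuclei", bundle.nuclei),
        ("registry", bundle.registry),
        ("exposures", bundle.exposures),
        ("tk_params", bundle.tk_params),
    ):
        write_table(df, name, outdir)
        counts[name] = len(df)
    bundle.descriptors.to_csv(outdir / "descriptors.csv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for key, df in bundle.truth.items():
        df.to_csv(truth_dir / f"{key}.csv", index=False)
    return counts


def stage_features(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    wells = read_table("wells", outdir)
    traces = read_table("traces", outdir)
    nuclei = read_table("nuclei", outdir)
    phen = phenotype_table(wells, traces, nuclei, rate_hz=config.study.rate_hz)
    write_table(phen, "phenotypes", outdir)
    return {"phenotypes": len(phen)}


def stage_qc(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    wells = read_table("wells", outdir)
    phen = read_table("phenotypes", outdir)
    normalized = normalize_to_vehicle(phen, wells)
    write_table(normalized, "normalized", outdir)
    report = qc_report(normalized, phen)
    write_table(report, "qc_report", outdir)

    controls = normalized[normalized["treatment_type"].isin(["vehicle", "media"])]
    raw = wells.merge(phen, on=["plate_id", "well"])
    raw = raw[raw["treatment_type"].isin(["vehicle", "media"])]
    vd_rows = []
    for phenotype, col in (
        ("beat_rate", "beat_rate_bpm_treated"),
        ("decay_to_rise", "decay_to_rise_treated"),
        ("nuclei", "nuclei_count"),
    ):
        sub = raw.rename(columns={col: "value"})[
            ["donor_id", "plate_id", "treatment_type", "value"]
        ]
        try:
            vd = decompose_variance(sub, phenotype)
        except ValueError:
            continue
        vd_rows.append(
            {
                "phenotype": phenotype,
                "frac_donor": vd.fractions["donor"],
                "frac_plate": vd.fractions["plate"],
                "frac_vehicle_vs_media": vd.fractions["vehicle_vs_media"],
                "frac_residual": vd.fractions["residual"],
                "cv_total": vd.cv_total,
                "cv_donor": vd.cv_donor,
                "estimator": vd.estimator,
            }
        )
    write_table(pd.DataFrame(vd_rows), "variance_decomposition", outdir)
    _ = controls  # kept for symmetry with the normalized-unit view
    return {"normalized": len(normalized), "qc_report": len(report)}


def assemble_responses(
    normalized: pd.DataFrame, chemical_id: str, phenotype: str
) -> pd.DataFrame:
    """Donor/concentration/response rows for one chemical x phenotype."""
    channel = {
        "beat_rate_ratio": "beat_rate_ratio",
        "decay_to_rise_ratio": "decay_to_rise_ratio",
        "nuclei_ratio": "nuclei_ratio",
    }[PHENOTYPES[phenotype].channel]
    sub = normalized[
        (normalized["treatment_type"] == "test")
        & (normalized["chemical_id"] == chemical_id)
    ]
    return pd.DataFrame(
        {
            "donor_id": sub["donor_id"],
            "conc_uM": sub["conc_uM"].astype(float),
            "response": sub[channel].astype(float),
        }
    )


def _posterior_path(outdir: Path, chemical_id: str, phenotype: str) -> Path:
    safe = chemical_id.replace("/", "_").replace(" ", "_").replace(":", "-")
    return outdir / "posteriors" / f"{safe}__{phenotype}.npz"


def save_posterior(post: PopulationPosterior, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "donor_ids": post.donor_ids,
        "direction": post.direction,
        "rhat": post.rhat,
        "converged": post.converged,
        "n_chains": post.n_chains,
        "n_iter": post.n_iter,
        "seed": post.seed,
        "emax_cap": post.emax_cap,
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **post.draws)


def load_posterior(path: Path) -> PopulationPosterior:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        draws = {k: data[k] for k in data.files if k != "meta"}
    return PopulationPosterior(
        draws=draws,
        donor_ids=meta["donor_ids"],
        direction=meta["direction"],
        rhat=meta["rhat"],
        converged=meta["converged"],
        n_chains=meta["n_chains"],
        n_iter=meta["n_iter"],
        seed=meta["seed"],
        emax_cap=meta["emax_cap"],
    )


def _fit_seed(root_seed: int, chemical_id: str, phenotype: str) -> int:
    """Deterministic per-combination child seed below 2**31."""
    h = 0
    for ch in f"{chemical_id}|{phenotype}":
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return (root_seed * 1000003 + h) % (2**31 - 1)


def stage_fit(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    normalized = read_table("normalized", outdir)
    settings = config.sampler_settings()
    chems = sorted(
        normalized.loc[normalized["treatment_type"] == "test", "chemical_id"]
        .dropna()
        .unique()
    )
    rows = []
    for chem in chems:
        for phen in config.phenotypes:
            pdef = PHENOTYPES[phen]
            responses = assemble_responses(normalized, chem, phen)
            if responses["response"].notna().sum() < 8:
                continue
            t0 = time.perf_counter()
            seed = _fit_seed(config.seed, chem, phen)
            post = fit_population(
                responses, direction=pdef.direction, settings=settings, seed=seed
            )
            podset = pods_from_posterior(
                post, pdef.benchmark, chemical_id=chem, phenotype=phen,
                m_individuals=config.m_individuals, seed=seed,
            )
            save_posterior(post, _posterior_path(outdir, chem, phen))
            lo, hi = podset.pod_median_ci90
            lo5, hi5 = podset.pod_p05_ci90
            row = {
                "chemical_id": chem,
                "phenotype": phen,
                "benchmark": podset.benchmark,
                "pod_median": podset.pod_median,
                "pod_median_ci90_lo": lo,
                "pod_median_ci90_hi": hi,
                "pod_p05": podset.pod_p05,
                "pod_p05_ci90_lo": lo5,
                "pod_p05_ci90_hi": hi5,
                "rhat_max": podset.rhat_max,
                "converged": podset.converged,
                "censored_fraction": podset.censored_fraction,
                "censored": podset.censored,
            }
            for donor, pod in podset.donor_pods().items():
                row[f"pod_donor_{donor}"] = pod
            rows.append(row)
            log.info(
                "fit chemical=%s phenotype=%s converged=%s wall=%.1fs",
                chem, phen, post.converged, time.perf_counter() - t0,
            )
    pods = pd.DataFrame(rows)
    write_table(pods, "pods", outdir)
    return {"pods": len(pods)}


def _load_podsets(
    config: PipelineConfig, outdir: Path
) -> dict[tuple[str, str], tuple[PODSet, PopulationPosterior]]:
    pods = read_table("pods", outdir)
    out = {}
    for rec in pods.itertuples(index=False):
        path = _posterior_path(outdir, rec.chemical_id, rec.phenotype)
        if not path.exists():
            continue
        post = load_posterior(path)
        seed = _fit_seed(config.seed, rec.chemical_id, rec.phenotype)
        podset = pods_from_posterior(
            post, PHENOTYPES[rec.phenotype].benchmark,
            chemical_id=rec.chemical_id, phenotype=rec.phenotype,
            m_individuals=config.m_individuals, seed=seed,
        )
        out[(rec.chemical_id, rec.phenotype)] = (podset, post)
    return out


def stage_calls(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    normalized = read_table("normalized", outdir)
    podsets = _load_podsets(config, outdir)
    max_conc = float(max(config.study.concentrations_uM))
    calls, tdvfs = [], []
    for (chem, phen), (podset, post) in sorted(podsets.items()):
        responses = assemble_responses(normalized, chem, phen)
        cov = data_coverage(responses, config.thresholds.min_concs)
        call = call_activity(
            podset, post, cov, max_conc_uM=max_conc, thresholds=config.thresholds
        )
        calls.append(call)
        if call.active_popvar:
            tdvfs.append(tdvf05(podset))
    write_table(activity_table(calls), "activity_calls", outdir)
    write_table(tdvf_table(tdvfs), "tdvf", outdir)
    return {"activity_calls": len(calls), "tdvf": len(tdvfs)}


def stage_toxpi(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    podsets = _load_podsets(config, outdir)
    calls = read_table("activity_calls", outdir)
    inactive = {
        (r.chemical_id, r.phenotype)
        for r in calls.itertuples(index=False)
        if r.status == "inactive"
    }
    usable = []
    for key, (podset, _post) in podsets.items():
        if key in inactive:
            # inactive combinations contribute no potency signal
            podset.donor_pod_draws = np.full_like(podset.donor_pod_draws, np.inf)
            podset.pod_median_draws = np.full_like(podset.pod_median_draws, np.inf)
        usable.append(podset)
    matrix = pod_input_matrix(usable)
    scores = toxpi_scores(matrix).reset_index()
    write_table(scores, "toxpi", outdir)
    return {"toxpi": len(scores)}


def stage_moe(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    podsets = _load_podsets(config, outdir)
    calls = read_table("activity_calls", outdir)
    exposures = read_table("exposures", outdir).set_index("chemical_id")
    tks = read_table("tk_params", outdir).set_index("chemical_id")
    active = calls[calls["status"] != "inactive"]
    results = []
    for chem in sorted(active["chemical_id"].unique()):
        if chem not in exposures.index:
            continue
        exp_row = exposures.loc[chem]
        exposure = ExposureEstimate(
            chemical_id=chem,
            oral_median=float(exp_row["oral_median"]),
            oral_upper95=float(exp_row["oral_upper95"]),
            biomonitoring_lo=(
                float(exp_row["biomonitoring_lo"])
                if "biomonitoring_lo" in exp_row and pd.notna(exp_row["biomonitoring_lo"])
                else None
            ),
            biomonitoring_hi=(
                float(exp_row["biomonitoring_hi"])
                if "biomonitoring_hi" in exp_row and pd.notna(exp_row["biomonitoring_hi"])
                else None
            ),
        )
        tk = None
        if chem in tks.index:
            t = tks.loc[chem]
            tk = TKParams(
                mw=float(t["mw"]), fup=float(t["fup"]), clint=float(t["clint"]),
                gfr_perkg=float(t.get("gfr_perkg", TKParams(500, 0.1).gfr_perkg)),
                q_liver_perkg=float(t.get("q_liver_perkg", TKParams(500, 0.1).q_liver_perkg)),
            )
        draws = {}
        for phen in active[active["chemical_id"] == chem]["phenotype"]:
            podset, post = podsets[(chem, phen)]
            seed = _fit_seed(config.seed, chem, phen)
            draws[phen] = {
                "median": podset.pod_median_draws,
                "random": sample_random_individual_pods(
                    post, podset.benchmark, n=config.n_mc, seed=seed
                ),
            }
        if not draws:
            continue
        results.append(
            compute_moe(draws, exposure, tk, n_mc=config.n_mc, seed=config.seed)
        )
    table = moe_table(results)
    write_table(table, "moe", outdir)
    for r in results:
        if not r.table.empty:
            r.table.assign(chemical_id=r.chemical_id).to_csv(
                outdir / "moe_detail.csv",
                mode="a",
                header=not (outdir / "moe_detail.csv").exists(),
                index=False,
            )
    return {"moe": len(table)}


def stage_sar(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    podsets = _load_podsets(config, outdir)
    descriptors = pd.read_csv(outdir / "descriptors.csv", index_col="chemical_id")
    bio = bioactivity_matrix([ps for ps, _ in podsets.values()])
    if config.sar_min_only:
        bio = bio[[c for c in bio.columns if c.endswith("|min")]]
    filtered = variation_filter(descriptors)
    corr = spearman_screen(filtered, bio)
    write_table(corr, "sar_correlations", outdir)
    preds = permutation_significance(
        filtered, bio, n_perm=config.n_permutations, seed=config.seed
    )
    write_table(preds, "sar_predictions", outdir)
    return {"sar_correlations": len(corr), "sar_predictions": len(preds)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "features": stage_features,
    "qc": stage_qc,
    "fit": stage_fit,
    "calls": stage_calls,
    "toxpi": stage_toxpi,
    "moe": stage_moe,
    "sar": stage_sar,
}


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages in dependency order; write a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "cardiopop",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        counts = _STAGE_FUNCS[stage](config, outdir)
        wall = time.perf_counter() - t0
        log.info("stage=%s wall=%.1fs rows=%s", stage, wall, counts)
        manifest["stages"][stage] = {"rows": counts, "wall_s": round(wall, 2)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
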