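"""Synthetic population cardiotoxicity studies.

Generates complete in-silico screens with the statistical structure the
downstream analysis assumes: iPSC-derived cardiomyocytes from multiple
donors (default 16, one 384-well plate per donor with a 308-well interior),
a chemical library (default: the 56-chemical registry spanning 8 structural
subclasses) tested at 4 concentrations (0.1/1/10/100 uM), vehicle (n=15),
media (n=5) and positive-control wells (isoproterenol, propranolol, sotalol
in concentration-response) on every plate, and 6 chemicals duplicated as
intra-plate replicates.

The generative model mirrors the fitted one: each active chemical x
phenotype has population Hill parameters; donors get lognormal
(multiplicative) random effects on ec50 and emax; plates contribute a
single multiplicative lognormal technical factor per measurement channel;
wells add multiplicative lognormal noise with a configurable CV. Calcium
traces are synthesized beat-by-beat as fast-exponential-rise /
slower-exponential-decay transients so that re-measuring them recovers the
generating beat rate and decay-to-rise ratio.

Everything derives deterministically from one root seed via named child
streams, so identical configurations reproduce byte-identical bundles and
each component can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium_features import CalciumTrace
from .ivive_moe import TKParams
from .phenotypes import PHENOTYPE_NAMES, PHENOTYPES

__all__ = [
    "TrueHill",
    "ChemicalSpec",
    "StudyConfig",
    "StudyBundle",
    "PlateCapacityError",
    "generate_study",
    "synthesize_trace",
    "default_chemicals",
    "simulate_response_table",
    "REGISTRY",
    "SUBCLASSES",
    "REPLICATE_CHEMICALS",
]

# ---------------------------------------------------------------------------
# Chemical registry: 56 chemicals over the 8 structural subclasses
# ---------------------------------------------------------------------------

SUBCLASSES = (
    "PFCA", "ALCOHOL", "PFAN", "PFECA", "PFSA", "n:2 FTOH", "n:2 FTS", "Other",
)

REGISTRY: tuple[tuple[str, str], ...] = (
    # ALCOHOL (9)
    ("PFUd2OH", "ALCOHOL"), ("PFPOH", "ALCOHOL"), ("PFBOH", "ALCOHOL"),
    ("AmFPrOH", "ALCOHOL"), ("PFHp2OH", "ALCOHOL"), ("7H 6:1 FTOH", "ALCOHOL"),
    ("C7F3ETOH", "ALCOHOL"), ("HpFBOH", "ALCOHOL"), ("CFHx2OH", "ALCOHOL"),
    # n:2 FTOH (4)
    ("4:2 FTOH", "n:2 FTOH"), ("6:1 FTOH", "n:2 FTOH"),
    ("6:2 FTOH", "n:2 FTOH"), ("8:2 FTOH", "n:2 FTOH"),
    # n:2 FTS (2)
    ("6:2 FTS", "n:2 FTS"), ("8:2 FTS", "n:2 FTS"),
    # PFAN (8)
    ("PFHpAM", "PFAN"), ("PFNAM", "PFAN"), ("PFOAM", "PFAN"),
    ("PFO2AM", "PFAN"), ("PFPAM", "PFAN"), ("PFHxSA", "PFAN"),
    ("MeFOSE", "PFAN"), ("PFOAMD", "PFAN"),
    # PFCA (17)
    ("4H-PFBA", "PFCA"), ("5:3 FTCA", "PFCA"), ("PFIpOA", "PFCA"),
    ("TFPrOA", "PFCA"), ("7:3 FTCA", "PFCA"), ("Cl-PFNA", "PFCA"),
    ("NH4PFOA", "PFCA"), ("PFHx2OA", "PFCA"), ("PFBA", "PFCA"),
    ("PFDA", "PFCA"), ("PFHpA", "PFCA"), ("PFHxA", "PFCA"),
    ("PFNA", "PFCA"), ("PFOA", "PFCA"), ("PFPeA", "PFCA"),
    ("PFPrA", "PFCA"), ("PFUnDA", "PFCA"),
    # PFECA (7)
    ("MePF2ETOA", "PFECA"), ("PFMBA", "PFECA"), ("PFPE-6", "PFECA"),
    ("NFDHA", "PFECA"), ("PFHx2Et2OA", "PFECA"), ("PFMPA", "PFECA"),
    ("PFPE-1", "PFECA"),
    # PFSA (6)
    ("ET-PFBS", "PFSA"), ("4:2 FTS", "PFSA"), ("PFBS", "PFSA"),
    ("PFHxS", "PFSA"), ("PFOS", "PFSA"), ("PFBS-K", "PFSA"),
    # Other (3)
    ("3:3 FTCA", "Other"), ("8:2 FTPA", "Other"), ("PFHx2ON", "Other"),
)

# Chemicals duplicated on every plate as intra-plate replicates.
REPLICATE_CHEMICALS = (
    "PFOA", "TFPrOA", "PFPE-6", "PFPOH", "7H 6:1 FTOH", "PFHxSA",
)

N_BATCHES = 6


class PlateCapacityError(ValueError):
    """Requested chemicals do not fit on one plate alongside the controls."""


@dataclass(frozen=True)
class TrueHill:
    """Generating population Hill parameters for one phenotype."""

    ec50_uM: float
    emax: float
    hill_n: float
    direction: str

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0 or self.emax <= 0 or self.hill_n <= 0:
            raise ValueError("TrueHill parameters must be strictly positive")
        if self.direction == "decrease" and self.emax > 1:
            raise ValueError("emax must be <= 1 for decreasing phenotypes")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def frac(self, conc):
        c = np.asarray(conc, dtype=float)
        return 1.0 / (1.0 + (self.ec50_uM / np.maximum(c, 1e-300)) ** self.hill_n) * (c > 0)

    def ratio(self, conc):
        s = 1.0 if self.direction == "increase" else -1.0
        return 1.0 + s * self.emax * self.frac(conc)


@dataclass
class ChemicalSpec:
    """One library chemical: identity, subclass, true effects, annotations.

    ``effects`` maps phenotype name -> TrueHill; phenotypes absent from the
    mapping are inert. Exposure / TK / descriptor values are optional; when
    missing they are sampled from the documented default ranges.
    """

    chemical_id: str
    subclass: str
    effects: dict[str, TrueHill] = field(default_factory=dict)
    exposure_median: float | None = None       # mg/kg BW/day
    exposure_upper95: float | None = None
    biomonitoring_lo: float | None = None      # uM
    biomonitoring_hi: float | None = None
    tk: TKParams | None = None
    descriptors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise ValueError(
                f"subclass {self.subclass!r} not one of {SUBCLASSES}"
            )
        for name in self.effects:
            if name not in PHENOTYPE_NAMES:
                raise ValueError(f"unknown phenotype {name!r}")
        if (
            self.exposure_median is not None
            and self.exposure_upper95 is not None
            and self.exposure_upper95 < self.exposure_median
        ):
            raise ValueError("exposure_upper95 must be >= exposure_median")


# Positive controls encoded with their textbook directions of action:
# isoproterenol raises beat rate, propranolol lowers it, sotalol prolongs
# repolarization (higher decay-to-rise ratio).
POSITIVE_CONTROLS: dict[str, TrueHill] = {
    "isoproterenol": TrueHill(0.05, 0.8, 1.0, "increase"),
    "propranolol": TrueHill(1.0, 0.6, 1.0, "decrease"),
    "sotalol": TrueHill(5.0, 0.5, 1.0, "increase"),
}
_CONTROL_PHENOTYPE = {
    "isoproterenol": "positive_chronotrope",
    "propranolol": "negative_chronotrope",
    "sotalol": "qt_prolongation",
}

# Measurement channels carried by raw well values.
CHANNELS = ("beat_rate", "decay_to_rise", "nuclei")


@dataclass
class StudyConfig:
    """Design and generative parameters of a synthetic study.

    Defaults reproduce the reference screen design: 16 donors, the
    56-chemical registry at 0.1/1/10/100 uM on 384-well plates with a
    308-well interior, 15 vehicle + 5 media + 12 positive-control wells and
    6 intra-plate replicate chemicals per plate. Donor random-effect SDs
    default to 0.7 (log ec50) and 0.2 (log emax): 0.7 puts the median
    toxicodynamic variability factor at the conventional default of
    10^(1/2) ~ 3.16, a realistic centre for donor-to-donor potency spread.
    """

    n_donors: int = 16
    chemicals: list[ChemicalSpec] | None = None     # None -> default_chemicals
    concentrations_uM: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    plate_rows: int = 16
    plate_cols: int = 24
    n_vehicle: int = 15
    n_media: int = 5
    intra_plate_replicate_chemicals: tuple[str, ...] = REPLICATE_CHEMICALS
    chemicals_per_plate: int | None = None          # None -> as many as fit
    phenotype_noise_cv: float | Mapping[str, float] = 0.05
    donor_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"ec50": 0.7, "emax": 0.2}
    )
    plate_sigma: float = 0.05
    baseline_bpm: float = 30.0
    baseline_decay_to_rise: float = 3.0
    baseline_nuclei: float = 2000.0
    donor_baseline_sigma: float = 0.1     # log-SD of donor baselines
    rate_hz: float = 8.0
    duration_s: float = 100.0
    trace_noise_sd: float = 0.02          # a.u., unit pulse amplitude
    generate_traces: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        if c.size < 2 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if self.interior_wells <= self.n_control_wells:
            raise ValueError("control wells do not fit on one plate")

    @property
    def interior_wells(self) -> int:
        return (self.plate_rows - 2) * (self.plate_cols - 2)

    @property
    def edge_wells(self) -> int:
        return self.plate_rows * self.plate_cols - self.interior_wells

    @property
    def n_control_wells(self) -> int:
        return (
            self.n_vehicle
            + self.n_media
            + len(POSITIVE_CONTROLS) * len(self.concentrations_uM)
        )

    @property
    def test_well_capacity(self) -> int:
        return self.interior_wells - self.n_control_wells

    def noise_cv(self, channel: str) -> float:
        if isinstance(self.phenotype_noise_cv, Mapping):
            return float(self.phenotype_noise_cv.get(channel, 0.0))
        return float(self.phenotype_noise_cv)


@dataclass
class StudyBundle:
    """All tables of one synthetic study, plus the generating truth."""

    wells: pd.DataFrame
    traces: pd.DataFrame
    nuclei: pd.DataFrame
    registry: pd.DataFrame
    exposures: pd.DataFrame
    tk_params: pd.DataFrame
    descriptors: pd.DataFrame
    truth: dict[str, pd.DataFrame]
    config: StudyConfig


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------


def synthesize_trace(
    bpm: float,
    decay_to_rise: float,
    duration_s: float = 100.0,
    rate_hz: float = 8.0,
    noise_sd: float = 0.0,
    rise_s: float = 0.25,
    phase: str = "baseline",
    rng: np.random.Generator | None = None,
) -> CalciumTrace:
    """Synthesize a calcium-flux recording with known beat structure.

    Each beat is a fast exponential rise / slower exponential decay
    transient; the time constants are set so the 10%-of-amplitude crossings
    sit ``rise_s`` before and ``rise_s * decay_to_rise`` after the peak,
    matching how the feature extractor measures beat timing. Beats are
    evenly spaced with the first at half a period, so the pulse count is
    exactly round(bpm * duration / 60). ``bpm = 0`` yields a flat baseline.
    """
    if bpm < 0:
        raise ValueError("bpm must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_samples = rate_hz * duration_s
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError("rate_hz * duration_s must be integral")
    n_samples = int(round(n_samples))
    t = np.arange(n_samples) / rate_hz
    x = np.zeros(n_samples)
    n_pulses = int(round(bpm * duration_s / 60.0))
    if n_pulses > 0:
        if decay_to_rise <= 0:
            raise ValueError("decay_to_rise must be positive")
        period = duration_s / n_pulses
        decay_s = rise_s * decay_to_rise
        total = rise_s + decay_s
        if total > 0.9 * period:       # keep transients inside one period
            scale = 0.9 * period / total
            rise_s, decay_s = rise_s * scale, decay_s * scale
        tau_r = rise_s / math.log(10.0)
        tau_d = decay_s / math.log(10.0)
        peaks = (np.arange(n_pulses) + 0.5) * period
        dt = t[:, None] - peaks[None, :]
        pulse = np.where(
            dt <= 0,
            np.exp(np.minimum(dt, 0.0) / tau_r),
            np.exp(-np.maximum(dt, 0.0) / tau_d),
        )
        x = pulse.sum(axis=1)
    x += 1.0                          # baseline fluorescence offset
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        x = x + rng.normal(0.0, noise_sd, size=n_samples)
    return CalciumTrace(x, rate_hz=rate_hz, phase=phase)


# ---------------------------------------------------------------------------
# Default chemical library
# ---------------------------------------------------------------------------


def default_chemicals(
    rng: np.random.Generator | None = None,
    active_fraction: float = 0.5,
) -> list[ChemicalSpec]:
    """The 56-chemical registry with sampled true effects.

    Roughly half the library is inert in every phenotype; active chemicals
    affect 1-3 randomly chosen phenotypes with log-uniform potencies across
    the tested range, moderate efficacies for graded phenotypes and full
    efficacy (emax = 1) with a steep slope for asystole.
    """
    rng = rng or np.random.default_rng(0)
    chems = []
    for chem_id, subclass in REGISTRY:
        effects: dict[str, TrueHill] = {}
        if rng.uniform() < active_fraction:
            k = int(rng.integers(1, 4))
            phens = list(rng.choice(PHENOTYPE_NAMES, size=k, replace=False))
            for p in phens:
                pdef = PHENOTYPES[p]
                ec50 = float(10 ** rng.uniform(math.log10(0.3), math.log10(80.0)))
                n = float(rng.uniform(1.0, 3.0))
                if p == "asystole":
                    emax = 1.0
                    n = float(rng.uniform(2.0, 4.0))
                else:
                    emax = float(rng.uniform(0.15, 0.6))
                effects[p] = TrueHill(ec50, emax, n, pdef.direction)
        chems.append(ChemicalSpec(chem_id, subclass, effects))
    return chems


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------


def _well_name(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def _plate_chunks(config: StudyConfig) -> list[list[ChemicalSpec]]:
    """Split the library into per-plate chunks; replicate chemicals occupy
    two concentration-series slots on their plate."""
    chems = config.chemicals
    n_conc = len(config.concentrations_uM)
    max_slots = config.test_well_capacity // n_conc
    reps = set(config.intra_plate_replicate_chemicals)

    def slots(chem: ChemicalSpec) -> int:
        return 2 if chem.chemical_id in reps else 1

    if config.chemicals_per_plate is not None:
        worst = max(
            (sum(slots(c) for c in chems[i : i + config.chemicals_per_plate])
             for i in range(0, len(chems), config.chemicals_per_plate)),
            default=0,
        )
        if worst > max_slots:
            raise PlateCapacityError(
                f"{config.chemicals_per_plate} chemicals/plate need up to "
                f"{worst} series slots but only {max_slots} fit alongside controls"
            )
        size = config.chemicals_per_plate
        return [chems[i : i + size] for i in range(0, len(chems), size)]

    chunks: list[list[ChemicalSpec]] = [[]]
    used = 0
    for chem in chems:
        s = slots(chem)
        if s > max_slots:
            raise PlateCapacityError(
                f"chemical {chem.chemical_id} needs {s} series slots; plate fits {max_slots}"
            )
        if used + s > max_slots:
            chunks.append([])
            used = 0
        chunks[-1].append(chem)
        used += s
    return chunks


def _layout_plate(
    config: StudyConfig,
    plate_id: str,
    donor_id: str,
    batch: int,
    chunk: list[ChemicalSpec],
) -> list[dict]:
    """Assign treatments to interior wells, row-major."""
    names = [
        _well_name(r, c)
        for r in range(1, config.plate_rows - 1)
        for c in range(1, config.plate_cols - 1)
    ]
    rows_cols = {
        _well_name(r, c): (r, c)
        for r in range(config.plate_rows)
        for c in range(config.plate_cols)
    }
    reps = set(config.intra_plate_replicate_chemicals)
    assignments: list[tuple[str, str | None, float | None]] = []
    assignments += [("vehicle", None, None)] * config.n_vehicle
    assignments += [("media", None, None)] * config.n_media
    for ctrl in POSITIVE_CONTROLS:
        for conc in config.concentrations_uM:
            assignments.append(("positive_control", ctrl, conc))
    for chem in chunk:
        n_series = 2 if chem.chemical_id in reps else 1
        for _ in range(n_series):
            for conc in config.concentrations_uM:
                assignments.append(("test", chem.chemical_id, conc))
    if len(assignments) > len(names):
        raise PlateCapacityError(
            f"plate {plate_id}: {len(assignments)} wells needed, "
            f"{len(names)} interior wells available"
        )
    recs = []
    for name, (ttype, chem_id, conc) in zip(names, assignments):
        r, c = rows_cols[name]
        recs.append(
            {
                "plate_id": plate_id,
                "well": name,
                "row": r,
                "col": c,
                "donor_id": donor_id,
                "treatment_type": ttype,
                "chemical_id": chem_id,
                "conc_uM": conc,
                "batch": batch,
            }
        )
    return recs


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

_STREAMS = (
    "library", "donor_baseline", "donor_effects", "plate_factors",
    "well_noise", "traces", "exposure", "tk", "descriptors",
)


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named child streams derived from the root seed.

    Derivation: ``SeedSequence((seed, k))`` where ``k`` is the stream's
    position in the fixed ``_STREAMS`` order, so any stream can be
    regenerated without producing the others.
    """
    return {
        name: np.random.default_rng(np.random.SeedSequence((seed, k)))
        for k, name in enumerate(_STREAMS)
    }


def _effect_ratio(
    effects: Mapping[str, TrueHill],
    donor_effects: Mapping[tuple[str, str], tuple[float, float]],
    chem_id: str,
    phenotype: str,
    conc: float,
) -> float:
    th = effects.get(phenotype)
    if th is None:
        return 1.0
    ec50_d, emax_d = donor_effects[(chem_id, phenotype)]
    adj = TrueHill(ec50_d, emax_d, th.hill_n, th.direction)
    return float(adj.ratio(conc))


def generate_study(config: StudyConfig | None = None) -> StudyBundle:
    """Generate a complete synthetic study bundle from one root seed."""
    config = config or StudyConfig()
    rngs = _child_rngs(config.seed)
    if config.chemicals is None:
        config = replace(config, chemicals=default_chemicals(rngs["library"]))
    chems = config.chemicals
    chem_by_id = {c.chemical_id: c for c in chems}
    n_conc = len(config.concentrations_uM)

    donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    batches = {d: (i % N_BATCHES) + 1 for i, d in enumerate(donors)}

    # donor baselines (spontaneous beat rate, decay-to-rise, nuclei)
    rb = rngs["donor_baseline"]
    donor_base = pd.DataFrame(
        {
            "donor_id": donors,
            "bpm": config.baseline_bpm
            * np.exp(rb.normal(0, config.donor_baseline_sigma, config.n_donors)),
            "decay_to_rise": config.baseline_decay_to_rise
            * np.exp(rb.normal(0, config.donor_baseline_sigma / 2, config.n_donors)),
            "nuclei": config.baseline_nuclei
            * np.exp(rb.normal(0, config.donor_baseline_sigma / 2, config.n_donors)),
        }
    )

    # donor-level random effects on every chemical x phenotype (controls too)
    re_rng = rngs["donor_effects"]
    sig_e = float(config.donor_sigma.get("ec50", 0.0))
    sig_m = float(config.donor_sigma.get("emax", 0.0))
    donor_eff_rows = []
    donor_eff: dict[str, dict[tuple[str, str], tuple[float, float]]] = {d: {} for d in donors}
    all_effects: list[tuple[str, str, TrueHill]] = []
    for chem in chems:
        for p, th in chem.effects.items():
            all_effects.append((chem.chemical_id, p, th))
    for ctrl, th in POSITIVE_CONTROLS.items():
        all_effects.append((ctrl, _CONTROL_PHENOTYPE[ctrl], th))
    for chem_id, p, th in all_effects:
        z_e = re_rng.standard_normal(config.n_donors)
        z_m = re_rng.standard_normal(config.n_donors)
        for i, d in enumerate(donors):
            ec50_d = th.ec50_uM * math.exp(sig_e * z_e[i])
            emax_d = th.emax * math.exp(sig_m * z_m[i])
            if th.direction == "decrease":
                emax_d = min(emax_d, 1.0)
            donor_eff[d][(chem_id, p)] = (ec50_d, emax_d)
            donor_eff_rows.append(
                {
                    "chemical_id": chem_id,
                    "phenotype": p,
                    "donor_id": d,
                    "ec50_uM": ec50_d,
                    "emax": emax_d,
                    "hill_n": th.hill_n,
                    "direction": th.direction,
                }
            )

    # plates: chunk library, one plate set per donor
    chunks = _plate_chunks(config)
    well_rows: list[dict] = []
    plate_ids = []
    for d in donors:
        for j, chunk in enumerate(chunks):
            plate_id = f"{d}_P{j + 1}"
            plate_ids.append(plate_id)
            well_rows += _layout_plate(config, plate_id, d, batches[d], chunk)
    wells = pd.DataFrame(well_rows)

    pf_rng = rngs["plate_factors"]
    plate_factors = pd.DataFrame(
        [
            {"plate_id": pid, "channel": ch,
             "factor": math.exp(pf_rng.normal(0, config.plate_sigma))}
            for pid in plate_ids
            for ch in CHANNELS
        ]
    )
    pf = plate_factors.set_index(["plate_id", "channel"])["factor"]

    # expected + noisy raw channel values per well
    noise_rng = rngs["well_noise"]
    base_by_donor = donor_base.set_index("donor_id")
    ctrl_effects = {
        ctrl: {_CONTROL_PHENOTYPE[ctrl]: th} for ctrl, th in POSITIVE_CONTROLS.items()
    }
    truth_well_rows = []
    raw = {"bpm_baseline": [], "bpm_treated": [], "d2r_baseline": [],
           "d2r_treated": [], "nuclei": []}
    for rec in wells.itertuples(index=False):
        b = base_by_donor.loc[rec.donor_id]
        if rec.treatment_type in ("vehicle", "media"):
            ratios = {"beat_rate": 1.0, "decay_to_rise": 1.0, "nuclei": 1.0}
        else:
            if rec.treatment_type == "positive_control":
                effects = ctrl_effects[rec.chemical_id]
            else:
                effects = chem_by_id[rec.chemical_id].effects
            de = donor_eff[rec.donor_id]
            chrono = 1.0
            for p in ("positive_chronotrope", "negative_chronotrope"):
                chrono *= _effect_ratio(effects, de, rec.chemical_id, p, rec.conc_uM)
            chrono *= _effect_ratio(effects, de, rec.chemical_id, "asystole", rec.conc_uM)
            ratios = {
                "beat_rate": max(chrono, 0.0),
                "decay_to_rise": _effect_ratio(
                    effects, de, rec.chemical_id, "qt_prolongation", rec.conc_uM
                ),
                "nuclei": max(
                    _effect_ratio(effects, de, rec.chemical_id, "cytotoxicity", rec.conc_uM),
                    0.0,
                ),
            }
        truth_well_rows.append(
            {"plate_id": rec.plate_id, "well": rec.well, **{
                f"{ch}_ratio": ratios[ch] for ch in CHANNELS}}
        )

        def noisy(value: float, channel: str) -> float:
            cv = config.noise_cv(channel)
            plate_f = pf[(rec.plate_id, channel)]
            n = math.exp(noise_rng.normal(0, cv)) if cv > 0 else 1.0
            return value * plate_f * n

        raw["bpm_baseline"].append(noisy(b["bpm"], "beat_rate"))
        raw["bpm_treated"].append(noisy(b["bpm"] * ratios["beat_rate"], "beat_rate"))
        raw["d2r_baseline"].append(noisy(b["decay_to_rise"], "decay_to_rise"))
        raw["d2r_treated"].append(
            noisy(b["decay_to_rise"] * ratios["decay_to_rise"], "decay_to_rise")
        )
        raw["nuclei"].append(noisy(b["nuclei"] * ratios["nuclei"], "nuclei"))

    nuclei = pd.DataFrame(
        {
            "plate_id": wells["plate_id"],
            "well": wells["well"],
            "nuclei_count": np.maximum(np.round(raw["nuclei"]).astype(int), 0),
        }
    )

    # traces
    trace_frames: list[pd.DataFrame] = []
    if config.generate_traces:
        tr_rng = rngs["traces"]
        n_frames = int(round(config.rate_hz * config.duration_s))
        frame_idx = np.arange(n_frames)
        for i, rec in enumerate(wells.itertuples(index=False)):
            for phase, bpm_key, d2r_key in (
                ("baseline", "bpm_baseline", "d2r_baseline"),
                ("treated", "bpm_treated", "d2r_treated"),
            ):
                trace = synthesize_trace(
                    bpm=max(raw[bpm_key][i], 0.0),
                    decay_to_rise=max(raw[d2r_key][i], 1e-6),
                    duration_s=config.duration_s,
                    rate_hz=config.rate_hz,
                    noise_sd=config.trace_noise_sd,
                    phase=phase,
                    rng=tr_rng,
                )
                trace_frames.append(
                    pd.DataFrame(
                        {
                            "plate_id": rec.plate_id,
                            "well": rec.well,
                            "phase": phase,
                            "frame": frame_idx,
                            "value": trace.samples,
                        }
                    )
                )
    traces = (
        pd.concat(trace_frames, ignore_index=True)
        if trace_frames
        else pd.DataFrame(columns=["plate_id", "well", "phase", "frame", "value"])
    )

    registry = pd.DataFrame(
        {
            "chemical_id": [c.chemical_id for c in chems],
            "name": [c.chemical_id for c in chems],
            "subclass": [c.subclass for c in chems],
        }
    )

    # exposures and TK parameters (sampled defaults when unspecified)
    ex_rng = rngs["exposure"]
    ex_rows = []
    for c in chems:
        med = c.exposure_median
        up = c.exposure_upper95
        if med is None:
            med = float(10 ** ex_rng.uniform(-8, -4))        # mg/kg BW/day
            up = med * 10 ** ex_rng.uniform(0.5, 2.0)
        elif up is None:
            up = med
        ex_rows.append(
            {
                "chemical_id": c.chemical_id,
                "oral_median": med,
                "oral_upper95": up,
                "biomonitoring_lo": c.biomonitoring_lo,
                "biomonitoring_hi": c.biomonitoring_hi,
                "source": "specified" if c.exposure_median is not None else "sampled",
            }
        )
    exposures = pd.DataFrame(ex_rows)

    tk_rng = rngs["tk"]
    tk_rows = []
    for c in chems:
        tk = c.tk
        if tk is None:
            tk = TKParams(
                mw=float(tk_rng.uniform(200, 600)),
                fup=float(10 ** tk_rng.uniform(-2, -0.3)),
                clint=float(tk_rng.uniform(0, 5)),
            )
        tk_rows.append(
            {
                "chemical_id": c.chemical_id,
                "mw": tk.mw,
                "fup": tk.fup,
                "clint": tk.clint,
                "gfr_perkg": tk.gfr_perkg,
                "q_liver_perkg": tk.q_liver_perkg,
            }
        )
    tk_params = pd.DataFrame(tk_rows)

    descriptors = _generate_descriptors(chems, rngs["descriptors"], tk_params)

    pop_rows = []
    for chem in chems:
        for p in PHENOTYPE_NAMES:
            th = chem.effects.get(p)
            pop_rows.append(
                {
                    "chemical_id": chem.chemical_id,
                    "phenotype": p,
                    "active": th is not None,
                    "ec50_uM": th.ec50_uM if th else np.nan,
                    "emax": th.emax if th else np.nan,
                    "hill_n": th.hill_n if th else np.nan,
                    "direction": th.direction if th else PHENOTYPES[p].direction,
                }
            )

    truth = {
        "population": pd.DataFrame(pop_rows),
        "donor": pd.DataFrame(donor_eff_rows),
        "donor_baseline": donor_base,
        "plate_factors": plate_factors,
        "wells": pd.DataFrame(truth_well_rows),
        "raw_channels": pd.DataFrame(
            {
                "plate_id": wells["plate_id"],
                "well": wells["well"],
                **{k: v for k, v in raw.items()},
            }
        ),
    }

    return StudyBundle(
        wells=wells,
        traces=traces,
        nuclei=nuclei,
        registry=registry,
        exposures=exposures,
        tk_params=tk_params,
        descriptors=descriptors,
        truth=truth,
        config=config,
    )


def _generate_descriptors(
    chems: Sequence[ChemicalSpec],
    rng: np.random.Generator,
    tk_params: pd.DataFrame,
    n_substructure: int = 120,
    plant_signal: bool = True,
) -> pd.DataFrame:
    """Chemicals x descriptors matrix: sparse substructure counts plus a
    small block of physicochemical properties.

    When ``plant_signal`` is on (default), a handful of substructure counts
    and the chain-length / molecular-weight properties co-vary with each
    chemical's true potency (its lowest log EC50 across phenotypes), so
    structure-activity screens have signal to find; chemicals carrying
    explicit ``descriptors`` overrides keep their specified values.
    """
    n = len(chems)
    potency = np.zeros(n)
    for i, c in enumerate(chems):
        if c.effects:
            potency[i] = -math.log10(min(th.ec50_uM for th in c.effects.values()))
        else:
            potency[i] = -math.log10(300.0)      # inert: beyond tested range
    pscale = (potency - potency.mean()) / (potency.std() + 1e-12)

    cols: dict[str, np.ndarray] = {}
    for j in range(n_substructure):
        base = rng.poisson(rng.uniform(0.2, 2.0), size=n).astype(float)
        if plant_signal and j < 10:
            # shift counts with potency, keeping them non-negative integers
            base = np.round(np.maximum(base + pscale * rng.uniform(0.5, 1.5), 0))
        cols[f"sub_{j:03d}"] = base
    mw = tk_params["mw"].to_numpy()
    cols["mw"] = mw
    chain = np.clip(np.round(4 + 2 * pscale + rng.normal(0, 1, n)), 2, 14)
    cols["carbon_chain_length"] = chain if plant_signal else rng.integers(2, 14, n)
    cols["log_kow"] = 0.4 * chain + rng.normal(0, 0.5, n)
    cols["henrys_law"] = rng.normal(-3, 1.5, n)
    cols["melting_point"] = rng.normal(100, 40, n)
    cols["boiling_point"] = rng.normal(180, 50, n)
    cols["vapor_pressure"] = rng.normal(-2, 1.2, n)
    cols["water_solubility"] = -0.5 * chain + rng.normal(0, 1, n)

    df = pd.DataFrame(cols, index=[c.chemical_id for c in chems])
    df.index.name = "chemical_id"
    for i, c in enumerate(chems):
        if c.descriptors:
            for k, v in c.descriptors.items():
                df.loc[c.chemical_id, k] = v
    return df


# ---------------------------------------------------------------------------
# Direct response simulation (no plates/traces) for model-recovery studies
# ---------------------------------------------------------------------------


def simulate_response_table(
    true: TrueHill,
    n_donors: int = 16,
    concentrations_uM: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    donor_sigma: Mapping[str, float] | None = None,
    noise_cv: float = 0.05,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vehicle-normalized responses straight from the generative model.

    Skips plates and traces; used for parameter-recovery and calibration
    studies of the population fit. Returns (responses, donor_truth).
    Noise is additive normal on the response-ratio scale with SD
    ``noise_cv`` (matching the fitted residual model).
    """
    donor_sigma = donor_sigma or {"ec50": 0.0, "emax": 0.0}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 21)))
    sig_e = float(donor_sigma.get("ec50", 0.0))
    sig_m = float(donor_sigma.get("emax", 0.0))
    donors = [f"D{i + 1:02d}" for i in range(n_donors)]
    rows, truth_rows = [], []
    for d in donors:
        ec50_d = true.ec50_uM * math.exp(sig_e * rng.standard_normal())
        emax_d = true.emax * math.exp(sig_m * rng.standard_normal())
        if true.direction == "decrease":
            emax_d = min(emax_d, 1.0)
        th = TrueHill(ec50_d, emax_d, true.hill_n, true.direction)
        truth_rows.append(
            {"donor_id": d, "ec50_uM": ec50_d, "emax": emax_d, "hill_n": true.hill_n}
        )
        for conc in concentrations_uM:
            mu = float(th.ratio(conc))
            for _ in range(n_replicates):
                y = mu + (rng.normal(0, noise_cv) if noise_cv > 0 else 0.0)
                rows.append({"donor_id": d, "conc_uM": conc, "response": y})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
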