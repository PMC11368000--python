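"""Feature extraction from paired baseline/treated calcium-flux traces.

A well is recorded twice (before and 90 min after dosing) as a fluorescence
time series, by default 8 frames/s for 100 s (800 frames). Spontaneously
beating cardiomyocytes produce one calcium transient per beat; from the two
recordings and the nuclei count we derive the per-well phenotypes:

* beat rate (beats/min) in each phase and their ratio (chronotropy);
* decay-to-rise ratio: per-beat time from peak back down to baseline divided
  by time from baseline up to peak, averaged over measurable beats — an
  in vitro proxy for QT-interval prolongation;
* asystole: zero treated peaks without concurrent cytotoxicity;
* nuclei count, consumed as-is.

Peak detection and beat timing are deterministic and invariant to positive
rescaling of the trace; all thresholds are relative to per-trace or per-beat
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

DEFAULT_RATE_HZ = 8.0
DEFAULT_MIN_PROMINENCE_FRAC = 0.2
DEFAULT_MIN_PERIOD_S = 0.25   # 240 bpm ceiling
# Baseline level for beat timing: 10% of the beat's prominence above the
# local inter-beat minimum on each side of the peak.
BASELINE_FRAC = 0.1


@dataclass
class CalciumTrace:
    """One phase of a well's calcium-flux recording."""

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    phase: str = "baseline"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite values")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass
class PhenotypeVector:
    """Per-well derived phenotypes (treated phase unless suffixed)."""

    beat_rate_bpm: float
    decay_to_rise: float          # NaN when no measurable beats
    peak_count: int
    asystole: bool
    nuclei_count: int
    beat_rate_bpm_baseline: float = np.nan
    decay_to_rise_baseline: float = np.nan
    chronotropy_ratio: float = np.nan   # treated / baseline beat rate
    quality_ok: bool = True             # False when baseline is non-beating


def detect_peaks(
    trace: CalciumTrace,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
    reference_range: float | None = None,
) -> np.ndarray:
    """Indices of calcium-transient peaks.

    Peaks are local maxima separated by at least ``min_period_s`` whose
    prominence is at least ``min_prominence_frac`` of the trace range.
    ``reference_range`` substitutes an external amplitude scale for the
    trace's own range — the paired-phase scorer passes the larger of the
    two phases' ranges, so a quiescent (asystolic) post-treatment trace
    containing only measurement noise is judged against the well's real
    beating amplitude and yields no peaks. Detection is deterministic and
    invariant to positive rescaling; a constant trace has no peaks.
    """
    x = trace.samples
    rng = float(np.ptp(x)) if reference_range is None else float(reference_range)
    if rng == 0.0:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_period_s * trace.rate_hz)))
    peaks, _ = find_peaks(x, prominence=min_prominence_frac * rng, distance=distance)
    return peaks


def _crossing_time(x: np.ndarray, i_from: int, i_to: int, level: float,
                   rate_hz: float, rising: bool) -> float:
    """Linearly interpolated time of the last (rising) / first (falling)
    crossing of ``level`` between ``i_from`` and ``i_to``; NaN if the
    segment never reaches the level (beat truncated by the window)."""
    seg = x[i_from : i_to + 1]
    below = seg <= level
    if not below.any():
        return np.nan
    idx = np.nonzero(below)[0]
    if rising:
        j = idx[-1]               # last sample at/below level before peak
        if j == seg.size - 1:
            return (i_from + j) / rate_hz
        t0, v0, v1 = i_from + j, seg[j], seg[j + 1]
    else:
        j = idx[0]                # first sample at/below level after peak
        if j == 0:
            return i_from / rate_hz
        t0, v0, v1 = i_from + j - 1, seg[j - 1], seg[j]
    if v1 == v0:
        return t0 / rate_hz
    frac = (level - v0) / (v1 - v0)
    return (t0 + frac) / rate_hz


def beat_timings(
    trace: CalciumTrace,
    peaks: Sequence[int] | None = None,
    **peak_kwargs,
) -> pd.DataFrame:
    """Rise and decay durations per measurable beat.

    For each peak, the left/right boundaries are the neighbouring peaks (or
    the trace ends); the baseline level on each side sits ``BASELINE_FRAC``
    of that side's prominence above the local inter-beat minimum. Rise time
    runs from the upward baseline crossing to the peak, decay time from the
    peak to the downward crossing. Beats whose transient is truncated by the
    recording window are dropped.
    """
    x = trace.samples
    if peaks is None:
        peaks = detect_peaks(trace, **peak_kwargs)
    peaks = np.asarray(peaks, dtype=int)
    rows = []
    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < peaks.size else x.size - 1
        if p <= lo or p >= hi:
            continue
        left_min = float(x[lo:p].min())
        right_min = float(x[p : hi + 1].min())
        level_l = left_min + BASELINE_FRAC * (x[p] - left_min)
        level_r = right_min + BASELINE_FRAC * (x[p] - right_min)
        t_peak = p / trace.rate_hz
        t_up = _crossing_time(x, lo, p, level_l, trace.rate_hz, rising=True)
        t_dn = _crossing_time(x, p, hi, level_r, trace.rate_hz, rising=False)
        rise = t_peak - t_up
        decay = t_dn - t_peak
        if np.isnan(rise) or np.isnan(decay) or rise <= 0 or decay <= 0:
            continue
        rows.append({"peak_index": p, "rise_s": rise, "decay_s": decay})
    return pd.DataFrame(rows, columns=["peak_index", "rise_s", "decay_s"])


def beat_rate_bpm(trace: CalciumTrace, peaks: Sequence[int] | None = None,
                  **peak_kwargs) -> float:
    if peaks is None:
        peaks = detect_peaks(trace, **peak_kwargs)
    return 60.0 * len(peaks) / trace.duration_s


def decay_to_rise_ratio(trace: CalciumTrace, peaks: Sequence[int] | None = None,
                        **peak_kwargs) -> float:
    """Mean per-beat decay/rise time ratio; NaN without measurable beats."""
    t = beat_timings(trace, peaks=peaks, **peak_kwargs)
    if t.empty:
        return np.nan
    return float((t["decay_s"] / t["rise_s"]).mean())


def phenotypes_from_traces(
    baseline: CalciumTrace,
    treated: CalciumTrace,
    nuclei_count: int,
    cytotox_flag: bool = False,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
) -> PhenotypeVector:
    """Score one well from its paired recordings.

    A baseline phase without any detected beat marks the well unusable
    (``quality_ok=False``): the cells never beat, so chronotropy relative to
    baseline is undefined. Asystole is a treated peak count of zero without
    concurrent cytotoxicity (quiescence, not death).
    """
    kw = dict(min_prominence_frac=min_prominence_frac, min_period_s=min_period_s)
    # one amplitude reference for both phases: the same well, dye and
    # optics produce both recordings, so the larger range is the well's
    # true beating amplitude even if one phase is quiescent
    ref = max(float(np.ptp(baseline.samples)), float(np.ptp(treated.samples)))
    peaks_b = detect_peaks(baseline, reference_range=ref, **kw)
    peaks_t = detect_peaks(treated, reference_range=ref, **kw)
    br_b = beat_rate_bpm(baseline, peaks=peaks_b)
    br_t = beat_rate_bpm(treated, peaks=peaks_t)
    quality_ok = peaks_b.size > 0
    chrono = br_t / br_b if quality_ok else np.nan
    return PhenotypeVector(
        beat_rate_bpm=br_t,
        decay_to_rise=decay_to_rise_ratio(treated, peaks=peaks_t),
        peak_count=int(peaks_t.size),
        asystole=bool(peaks_t.size == 0 and not cytotox_flag),
        nuclei_count=int(nuclei_count),
        beat_rate_bpm_baseline=br_b,
        decay_to_rise_baseline=decay_to_rise_ratio(baseline, peaks=peaks_b),
        chronotropy_ratio=chrono,
        quality_ok=quality_ok,
    )


# Cytotoxicity benchmark direction: a well is flagged cytotoxic when its
# nuclei count falls below this fraction of the plate vehicle mean.
CYTOTOX_NUCLEI_FRAC = 0.9


def phenotype_table(
    wells: pd.DataFrame,
    traces: pd.DataFrame,
    nuclei: pd.DataFrame,
    rate_hz: float = DEFAULT_RATE_HZ,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
) -> pd.DataFrame:
    """Score every well of a study (the ``phenotypes.csv`` contract).

    ``wells`` lists experimental wells; ``traces`` is long-format
    (plate_id, well, phase, frame, value); ``nuclei`` maps wells to counts.
    The cytotoxicity flag feeding the asystole call compares each well's
    nuclei count with its plate's vehicle mean.
    """
    nuc = nuclei.set_index(["plate_id", "well"])["nuclei_count"]
    veh_wells = wells[wells["treatment_type"] == "vehicle"]
    veh_mean = (
        veh_wells.merge(nuclei, on=["plate_id", "well"])
        .groupby("plate_id")["nuclei_count"]
        .mean()
    )
    series = {
        key: grp.sort_values("frame")["value"].to_numpy()
        for key, grp in traces.groupby(["plate_id", "well", "phase"], sort=False)
    }
    rows = []
    for rec in wells.itertuples(index=False):
        key_b = (rec.plate_id, rec.well, "baseline")
        key_t = (rec.plate_id, rec.well, "treated")
        if key_b not in series or key_t not in series:
            continue
        n = int(nuc.get((rec.plate_id, rec.well), 0))
        cytotox = (
            rec.plate_id in veh_mean.index
            and n < CYTOTOX_NUCLEI_FRAC * veh_mean[rec.plate_id]
        )
        pv = phenotypes_from_traces(
            CalciumTrace(series[key_b], rate_hz, "baseline"),
            CalciumTrace(series[key_t], rate_hz, "treated"),
            nuclei_count=n,
            cytotox_flag=bool(cytotox),
            min_prominence_frac=min_prominence_frac,
            min_period_s=min_period_s,
        )
        rows.append(
            {
                "plate_id": rec.plate_id,
                "well": rec.well,
                "beat_rate_bpm_baseline": pv.beat_rate_bpm_baseline,
                "beat_rate_bpm_treated": pv.beat_rate_bpm,
                "decay_to_rise_baseline": pv.decay_to_rise_baseline,
                "decay_to_rise_treated": pv.decay_to_rise,
                "peak_count_treated": pv.peak_count,
                "asystole": pv.asystole,
                "nuclei_count": pv.nuclei_count,
                "chronotropy_ratio": pv.chronotropy_ratio,
                "quality_ok": pv.quality_ok,
            }
        )
    return pd.DataFrame(rows)
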