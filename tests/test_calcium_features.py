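"""Waveform synthesis round-trips and feature-extraction invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopop.calcium_features import (
    CalciumTrace,
    beat_rate_bpm,
    decay_to_rise_ratio,
    detect_peaks,
    phenotypes_from_traces,
)
from cardiopop.synthetic_study import synthesize_trace


class TestSynthesizeTrace:
    def test_pulse_count_and_length_by_construction(self):
        tr = synthesize_trace(30, 3.0, duration_s=100, rate_hz=8, noise_sd=0)
        assert tr.samples.size == 800
        assert len(detect_peaks(tr)) == 50

    def test_zero_bpm_gives_flat_baseline(self):
        tr = synthesize_trace(0, 3.0, duration_s=100, rate_hz=8, noise_sd=0)
        assert np.ptp(tr.samples) == 0.0
        assert len(detect_peaks(tr)) == 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthesize_trace(30, 3.0, noise_sd=-0.1)

    def test_negative_bpm_rejected(self):
        with pytest.raises(ValueError):
            synthesize_trace(-5, 3.0)

    def test_non_integral_frame_count_rejected(self):
        with pytest.raises(ValueError):
            synthesize_trace(30, 3.0, duration_s=100.07, rate_hz=8)


class TestRoundTrip:
    @pytest.mark.parametrize("bpm", [6.0, 12.0, 30.0, 60.0, 120.0])
    def test_noise_free_bpm_recovered_exactly(self, bpm):
        tr = synthesize_trace(bpm, 3.0, duration_s=100, rate_hz=8, noise_sd=0)
        assert beat_rate_bpm(tr) == pytest.approx(bpm, abs=1e-12)

    @pytest.mark.parametrize("d2r", [1.5, 2.0, 3.0, 4.0])
    def test_decay_to_rise_recovered_within_quantization(self, d2r):
        # measured rise and decay are each good to the 2/rate_hz
        # quantization bound; at 12 bpm the beat peaks fall on the frame
        # grid so the ratio itself is recovered tightly
        from cardiopop.calcium_features import beat_timings

        tr = synthesize_trace(12, d2r, duration_s=100, rate_hz=8, noise_sd=0)
        t = beat_timings(tr)
        rise, decay = 0.25, 0.25 * d2r
        assert abs(t["rise_s"].mean() - rise) <= 2 / 8
        assert abs(t["decay_s"].mean() - decay) <= 2 / 8
        assert decay_to_rise_ratio(tr) == pytest.approx(d2r, abs=0.35)

    def test_decay_to_rise_quantization_bound_off_grid(self):
        # worst-case sampling phase (peaks between frames) still keeps the
        # per-beat timings within the 2/rate_hz quantization bound
        from cardiopop.calcium_features import beat_timings

        tr = synthesize_trace(20, 3.0, duration_s=100, rate_hz=8, noise_sd=0)
        t = beat_timings(tr)
        assert abs(t["rise_s"].mean() - 0.25) <= 2 / 8
        assert abs(t["decay_s"].mean() - 0.75) <= 2 / 8

    def test_rise_decay_quarter_three_quarter_gives_three(self):
        tr = synthesize_trace(30, 3.0, duration_s=100, rate_hz=8, noise_sd=0,
                              rise_s=0.25)
        assert decay_to_rise_ratio(tr) == pytest.approx(3.0, abs=0.25)

    def test_noisy_pulse_recovery_across_seeds(self):
        # 50-pulse trace with 5% amplitude noise recovers all 50 peaks
        for seed in range(100):
            tr = synthesize_trace(
                30, 3.0, duration_s=100, rate_hz=8, noise_sd=0.05,
                rng=np.random.default_rng(seed),
            )
            assert len(detect_peaks(tr)) == 50


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        tr = CalciumTrace(np.full(800, 3.3))
        assert detect_peaks(tr).size == 0

    def test_deterministic(self):
        tr = synthesize_trace(30, 3.0, noise_sd=0.05,
                              rng=np.random.default_rng(5))
        a = detect_peaks(tr)
        b = detect_peaks(tr)
        np.testing.assert_array_equal(a, b)


class TestInvariants:
    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4),
           offset=st.floats(min_value=-10, max_value=10))
    def test_scale_and_offset_invariance(self, scale, offset):
        base = synthesize_trace(24, 2.5, noise_sd=0.02,
                                rng=np.random.default_rng(3))
        treat = synthesize_trace(12, 2.5, noise_sd=0.02, phase="treated",
                                 rng=np.random.default_rng(4))
        ref = phenotypes_from_traces(base, treat, 1000)
        base2 = CalciumTrace(base.samples * scale + offset)
        treat2 = CalciumTrace(treat.samples * scale + offset, phase="treated")
        got = phenotypes_from_traces(base2, treat2, 1000)
        assert got.beat_rate_bpm == ref.beat_rate_bpm
        assert got.beat_rate_bpm_baseline == ref.beat_rate_bpm_baseline
        assert got.peak_count == ref.peak_count
        assert got.decay_to_rise == pytest.approx(ref.decay_to_rise, rel=1e-9)

    def test_time_reversal_inverts_decay_to_rise(self):
        tr = synthesize_trace(20, 3.0, duration_s=100, rate_hz=8, noise_sd=0)
        rev = CalciumTrace(tr.samples[::-1].copy())
        fwd = decay_to_rise_ratio(tr)
        bwd = decay_to_rise_ratio(rev)
        assert bwd == pytest.approx(1.0 / fwd, rel=0.05)


class TestPhenotypesFromTraces:
    def test_chronotropy_ratio_is_treated_over_baseline(self):
        base = synthesize_trace(30, 3.0, noise_sd=0)
        treat = synthesize_trace(15, 3.0, noise_sd=0, phase="treated")
        pv = phenotypes_from_traces(base, treat, 1500)
        assert pv.chronotropy_ratio == pytest.approx(0.5)
        assert pv.quality_ok

    def test_flat_treated_without_cytotoxicity_is_asystole(self):
        base = synthesize_trace(30, 3.0, noise_sd=0)
        treat = synthesize_trace(0, 3.0, noise_sd=0, phase="treated")
        pv = phenotypes_from_traces(base, treat, 1500, cytotox_flag=False)
        assert pv.asystole and pv.peak_count == 0

    def test_flat_treated_with_cytotoxicity_is_not_asystole(self):
        base = synthesize_trace(30, 3.0, noise_sd=0)
        treat = synthesize_trace(0, 3.0, noise_sd=0, phase="treated")
        pv = phenotypes_from_traces(base, treat, 100, cytotox_flag=True)
        assert not pv.asystole

    def test_quiescent_noisy_treated_trace_scores_zero_peaks(self):
        # measurement noise in an asystolic well must not read as beating
        base = synthesize_trace(30, 3.0, noise_sd=0.02,
                                rng=np.random.default_rng(8))
        treat = synthesize_trace(0, 3.0, noise_sd=0.02, phase="treated",
                                 rng=np.random.default_rng(9))
        pv = phenotypes_from_traces(base, treat, 1500)
        assert pv.peak_count == 0 and pv.asystole

    def test_non_beating_baseline_flags_well_unusable(self):
        base = synthesize_trace(0, 3.0, noise_sd=0)
        treat = synthesize_trace(30, 3.0, noise_sd=0, phase="treated")
        pv = phenotypes_from_traces(base, treat, 1500)
        assert not pv.quality_ok
        assert np.isnan(pv.chronotropy_ratio)
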