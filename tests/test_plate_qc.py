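"""Vehicle normalization, replicate correlation, variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from cardiopop.plate_qc import (
    MissingVehicleError,
    control_gate,
    decompose_variance,
    normalize_to_vehicle,
    replicate_correlation,
)


def _toy_tables():
    """Two plates with vehicle means 100 and 50 on a single channel."""
    rows = []
    for plate, veh in (("P1", 100.0), ("P2", 50.0)):
        for i in range(3):
            rows.append((plate, f"V{i}", "vehicle", None, None, veh))
        rows.append((plate, "T0", "test", "X", 10.0, 60.0))
    wells = pd.DataFrame(
        rows, columns=["plate_id", "well", "treatment_type", "chemical_id",
                       "conc_uM", "value"],
    )
    wells["donor_id"] = "D01"
    wells["row"] = 1
    wells["col"] = 1
    wells["batch"] = 1
    chan = wells[["plate_id", "well"]].copy()
    chan["beat_rate_ratio"] = wells["value"]
    chan["decay_to_rise_ratio"] = wells["value"]
    chan["nuclei_ratio"] = wells["value"]
    return wells.drop(columns="value"), chan


class TestNormalization:
    def test_per_plate_vehicle_division(self):
        wells, chan = _toy_tables()
        out = normalize_to_vehicle(chan, wells)
        test = out[out.treatment_type == "test"].set_index("plate_id")
        # identical raw value 60 against vehicle means 100 and 50
        assert test.loc["P1", "beat_rate_ratio"] == pytest.approx(0.6)
        assert test.loc["P2", "beat_rate_ratio"] == pytest.approx(1.2)

    def test_vehicle_wells_average_to_one(self, small_normalized):
        veh = small_normalized[small_normalized.treatment_type == "vehicle"]
        means = veh.groupby("plate_id")[
            ["beat_rate_ratio", "decay_to_rise_ratio", "nuclei_ratio"]
        ].mean()
        assert np.allclose(means.to_numpy(), 1.0)

    def test_idempotent(self):
        wells, chan = _toy_tables()
        once = normalize_to_vehicle(chan, wells)
        twice = normalize_to_vehicle(
            once[["plate_id", "well", "beat_rate_ratio",
                  "decay_to_rise_ratio", "nuclei_ratio"]],
            wells,
        )
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_missing_vehicle_plate_named(self):
        wells, chan = _toy_tables()
        wells.loc[wells.plate_id == "P2", "treatment_type"] = "media"
        with pytest.raises(MissingVehicleError, match="P2"):
            normalize_to_vehicle(chan, wells)


class TestReplicateCorrelation:
    def test_identical_vectors(self):
        assert replicate_correlation([1, 2, 3], [1, 2, 3])["pearson_r"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert replicate_correlation([1, 2, 3], [3, 2, 1])["pearson_r"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # cov = 1.0, sd_x = sd_y = sqrt(5/3) -> r = 0.6
        res = replicate_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert res["pearson_r"] == pytest.approx(0.6)

    def test_zero_variance_flagged(self):
        res = replicate_correlation([1, 1, 1], [1, 2, 3])
        assert res["degenerate"] and np.isnan(res["pearson_r"])


def _control_wells(seed, sd_donor=2.0, sd_resid=1.0, sd_plate=0.0,
                   delta_media=0.0, n_donors=16, n_plates=2, n_wells=10):
    rng = np.random.default_rng(seed)
    rows, donor_effects = [], {}
    for d in range(n_donors):
        ed = rng.normal(0, sd_donor)
        donor_effects[d] = ed
        for p in range(n_plates):
            ep = rng.normal(0, sd_plate)
            for w in range(n_wells):
                ttype = "vehicle" if w < (3 * n_wells) // 4 else "media"
                rows.append(
                    {
                        "donor_id": f"D{d:02d}",
                        "plate_id": f"D{d:02d}P{p}",
                        "treatment_type": ttype,
                        "value": 30.0 + ed + ep
                        + (delta_media if ttype == "media" else 0.0)
                        + rng.normal(0, sd_resid),
                    }
                )
    df = pd.DataFrame(rows)
    realized_donor_var = np.var(list(donor_effects.values()), ddof=1)
    return df, realized_donor_var


class TestVarianceDecomposition:
    def test_fractions_sum_to_one(self):
        df, _ = _control_wells(0)
        vd = decompose_variance(df, "beat_rate")
        assert sum(vd.fractions.values()) == pytest.approx(1.0)
        assert vd.cv_total >= vd.cv_donor >= 0

    def test_recovers_realized_planted_fraction_across_seeds(self):
        # estimator accuracy against the realized donor variance per seed
        hits = 0
        for seed in range(10):
            df, donor_var = _control_wells(seed, sd_donor=2.0, sd_resid=1.0)
            vd = decompose_variance(df, "beat_rate")
            truth_frac = donor_var / (donor_var + 1.0)
            if abs(vd.fractions["donor"] - truth_frac) <= 0.05:
                hits += 1
        assert hits >= 9

    def test_equal_mean_vehicle_media_contributes_nothing(self):
        df, _ = _control_wells(1, delta_media=0.0)
        vd = decompose_variance(df, "x")
        assert vd.fractions["vehicle_vs_media"] < 0.02

    def test_media_shift_detected(self):
        df, _ = _control_wells(1, delta_media=3.0)
        vd = decompose_variance(df, "x")
        assert vd.fractions["vehicle_vs_media"] > 0.05

    def test_all_identical_reported_as_zero_variance(self):
        df, _ = _control_wells(0, sd_donor=0, sd_resid=0)
        df["value"] = 7.0
        vd = decompose_variance(df, "x")
        assert vd.zero_variance
        assert all(v == 0 for v in vd.fractions.values())

    def test_single_plate_per_donor_warns(self):
        df, _ = _control_wells(0, n_plates=1)
        with pytest.warns(UserWarning, match="single plate"):
            vd = decompose_variance(df, "x")
        assert vd.fractions["plate"] == 0.0


class TestControlGate:
    def test_generator_encoded_controls_pass(self, small_normalized, small_phenotypes):
        res = control_gate(small_normalized, small_phenotypes, "D01_P1")
        assert res.passed

    def test_inverted_isoproterenol_fails(self, small_normalized, small_phenotypes):
        flipped = small_normalized.copy()
        mask = (flipped.plate_id == "D01_P1") & (
            flipped.chemical_id == "isoproterenol"
        )
        flipped.loc[mask, "beat_rate_ratio"] = 0.5
        res = control_gate(flipped, small_phenotypes, "D01_P1")
        assert not res.passed and not res.isoproterenol_ok

    def test_non_beating_vehicle_fails(self, small_normalized, small_phenotypes):
        dead = small_phenotypes.copy()
        veh = small_normalized[
            (small_normalized.plate_id == "D01_P1")
            & (small_normalized.treatment_type == "vehicle")
        ]["well"]
        mask = (dead.plate_id == "D01_P1") & dead.well.isin(veh)
        dead.loc[mask, "beat_rate_bpm_treated"] = 0.0
        res = control_gate(small_normalized, dead, "D01_P1")
        assert not res.passed and not res.vehicle_beating
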