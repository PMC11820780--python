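"""Synthetic peak-table generator: grids, designs, noise and carryover."""

import numpy as np
import pandas as pd
import pytest

from srmquant.synthetic import (
    ResponseModel,
    SyntheticTruth,
    VALIDATION_LEVELS_UGL,
    build_calibration_series,
    build_spiking_design,
    make_truth,
    plan_validation_sequence,
    simulate_peak_table,
)


class TestCalibrationSeries:
    def test_validation_grid_is_the_14_level_series(self):
        for cset in ("HILIC", "RP_Aqu", "RP_Hep"):
            levels = build_calibration_series(cset)
            assert len(levels) == 14
            assert levels[0] == 0.0
            assert min(l for l in levels if l > 0) == 0.1
            assert max(levels) == 50_000.0

    def test_working_grids_span_the_stated_ranges(self):
        hilic = build_calibration_series("HILIC", grid="working")
        assert min(l for l in hilic if l > 0) == pytest.approx(0.03)
        assert max(hilic) == pytest.approx(25_000.0)
        for cset in ("RP_Aqu", "RP_Hep"):
            rp = build_calibration_series(cset, grid="working")
            assert min(l for l in rp if l > 0) == pytest.approx(0.1)
            assert max(rp) == pytest.approx(50_000.0)

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            build_calibration_series("LC")


class TestSpikingDesign:
    def test_native_mode_multipliers(self):
        d = build_spiking_design("x", native_conc=100.0)
        assert d.levels == (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
        assert d.n == 18

    def test_lloq_mode_multipliers(self):
        d = build_spiking_design("x", lloq=2.0)
        assert d.levels == (25.0, 50.0, 75.0, 100.0, 125.0, 150.0)

    def test_single_level_keeps_highest(self):
        d = build_spiking_design("x", lloq=2.0, single_level=True)
        assert d.levels == (150.0,)
        assert d.mode == "single_level"

    def test_zero_native_directs_to_lloq_mode(self):
        with pytest.raises(ValueError, match="lloq"):
            build_spiking_design("x", native_conc=0.0)
        with pytest.raises(ValueError):
            build_spiking_design("x", native_conc=1.0, lloq=1.0)
        with pytest.raises(ValueError):
            build_spiking_design("x")


def _noiseless_truth(carryover=0.0, mf5=1.0, mf100=1.0, drift_end=1.0):
    model = ResponseModel(
        analyte_id="x",
        slope=1000.0,
        measurement_rsd=0.0,
        baseline_noise_sd=0.0,
        carryover_fraction=carryover,
        matrix_factor={5: mf5, 100: mf100},
    )
    return SyntheticTruth(
        models={"x": model},
        native_conc={"x": 500.0},
        drift_start=1.0,
        drift_end=drift_end,
        seed=0,
    )


def _plan(rows):
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "role", "dilution_factor", "nominal_ugL", "spike_level", "replicate"],
    )
    df.insert(0, "injection_index", np.arange(len(df)))
    return df


class TestSimulate:
    def test_zero_noise_area_equals_response(self):
        truth = _noiseless_truth()
        plan = _plan([("std", "standard", np.nan, 1.0, -1, 0)])
        table = simulate_peak_table(truth, plan)
        quant = table[table["transition"] == "quantifier"]
        assert quant["area"].iloc[0] == pytest.approx(1000.0)

    def test_carryover_chain_decays_geometrically(self):
        truth = _noiseless_truth(carryover=0.02)
        plan = _plan(
            [
                ("std", "standard", np.nan, 10.0, -1, 0),
                ("b1", "blank", np.nan, np.nan, -1, 0),
                ("b2", "blank", np.nan, np.nan, -1, 0),
            ]
        )
        table = simulate_peak_table(truth, plan)
        quant = table[table["transition"] == "quantifier"]["area"].to_numpy()
        assert quant[0] == pytest.approx(10_000.0)
        assert quant[1] == pytest.approx(0.02 * 10_000.0)
        assert quant[2] == pytest.approx(0.02**2 * 10_000.0)

    def test_round_trip_through_response_model_at_zero_noise(self):
        truth = _noiseless_truth(mf5=0.8, mf100=0.95)
        plan = _plan(
            [
                ("s", "sample", 5, np.nan, -1, 0),
                ("s", "sample", 100, np.nan, -1, 0),
            ]
        )
        table = simulate_peak_table(truth, plan)
        quant = table[table["transition"] == "quantifier"]
        for _, row in quant.iterrows():
            d = int(row["dilution_factor"])
            mf = truth.models["x"].matrix_factor[d]
            expected = mf * 1000.0 * 500.0 / d
            assert row["area"] == pytest.approx(expected)
            # exact inversion: area / (mf * slope) * d recovers the native conc
            assert row["area"] / (mf * 1000.0) * d == pytest.approx(500.0)

    def test_seed_reproducibility(self):
        truth = make_truth(["a", "b"], seed=3)
        plan = plan_validation_sequence(["a", "b"], sample_ids=["s"], seed=3)
        t1 = simulate_peak_table(truth, plan, seed=9)
        t2 = simulate_peak_table(truth, plan, seed=9)
        t3 = simulate_peak_table(truth, plan, seed=10)
        pd.testing.assert_frame_equal(t1, t2)
        assert not np.allclose(t1["area"], t3["area"])

    def test_expected_area_linear_in_matrix_factor_and_drift(self):
        # Monte-Carlo mean within 3 standard errors of the analytic expectation
        rng_areas = []
        for mf, drift in [(0.5, 1.0), (1.0, 1.0), (1.0, 0.8)]:
            model = ResponseModel(
                analyte_id="x", slope=1000.0, measurement_rsd=0.05,
                matrix_factor={5: mf, 100: mf},
            )
            truth = SyntheticTruth(
                models={"x": model}, native_conc={"x": 100.0},
                drift_start=drift, drift_end=drift, seed=1,
            )
            plan = _plan([("s", "sample", 5, np.nan, -1, 0)] * 1000)
            table = simulate_peak_table(truth, plan, seed=1)
            areas = table[table["transition"] == "quantifier"]["area"].to_numpy()
            expected = drift * mf * 1000.0 * 100.0 / 5
            se = areas.std(ddof=1) / np.sqrt(len(areas))
            assert abs(areas.mean() - expected) < 3 * se
            rng_areas.append(areas.mean())

    def test_negative_concentration_rejected(self):
        truth = _noiseless_truth()
        truth.native_conc["x"] = -5.0
        plan = _plan([("s", "sample", 5, np.nan, -1, 0)])
        with pytest.raises(ValueError):
            simulate_peak_table(truth, plan)


class TestSequencePlan:
    def test_blank_follows_the_1mgL_standard(self):
        plan = plan_validation_sequence(["a"], seed=0)
        idx_1mg = plan[
            (plan["role"] == "standard") & (plan["nominal_ugL"] == 1000.0)
        ]["injection_index"].to_numpy()
        for i in idx_1mg:
            assert plan.iloc[i + 1]["role"] == "blank"

    def test_samples_measured_in_duplicate(self):
        plan = plan_validation_sequence(
            ["a"], sample_ids=["s1", "s2", "s3"], seed=4
        )
        samples = plan[plan["role"] == "sample"]
        counts = samples.groupby("sample_id")["replicate"].nunique()
        assert (counts == 2).all()

    def test_randomization_is_seeded(self):
        p1 = plan_validation_sequence(["a"], sample_ids=list("abcdef"), seed=5)
        p2 = plan_validation_sequence(["a"], sample_ids=list("abcdef"), seed=5)
        p3 = plan_validation_sequence(["a"], sample_ids=list("abcdef"), seed=6)
        pd.testing.assert_frame_equal(p1, p2)
        assert not p1.equals(p3)
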