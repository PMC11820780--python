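"""Drift correction, dilution selection, recovery correction, deconvolution,
trueness."""

import numpy as np
import pandas as pd
import pytest

from srmquant.calibration import CalibrationCurve
from srmquant.datasets import nist_srm1950_table
from srmquant.quantify import (
    QuantResult,
    check_ion_ratio,
    combine_duplicates,
    deconvolute_isomers,
    drift_correct,
    quantify_sample,
    trueness_report,
)
from srmquant.validation import RecoveryResult


def _curve(lloq=1.0, uloq=1000.0, slope=2.0, ion_ratio_ref=None):
    return CalibrationCurve(
        "x", "linear", (0.0, slope), 1.0, lod=lloq, lloq=lloq, uloq=uloq,
        ion_ratio_ref=ion_ratio_ref,
    )


def _recovery(ra, dilution=5):
    return RecoveryResult("x", dilution, "slope_ratio", ra_mean=ra)


class TestDriftCorrect:
    def _table(self, areas):
        return pd.DataFrame(
            {
                "injection_index": np.arange(len(areas)),
                "analyte_id": "x",
                "area": areas,
            }
        )

    def test_equal_anchors_leave_areas_unchanged(self):
        table = self._table([100.0, 90.0, 80.0])
        anchors = pd.DataFrame(
            {"injection_index": [0, 2], "analyte_id": "x", "area": [50.0, 50.0]}
        )
        out = drift_correct(table, anchors)
        assert np.allclose(out["area"], table["area"])

    def test_linear_decline_fully_corrected(self):
        # QC areas fall 100 -> 80 linearly: corrected QC areas equalize
        idx = np.arange(0, 11)
        qc_areas = 100.0 - 2.0 * idx
        table = self._table(qc_areas)
        anchors = pd.DataFrame(
            {"injection_index": idx, "analyte_id": "x", "area": qc_areas}
        )
        out = drift_correct(table, anchors)
        assert np.allclose(out["area"], 100.0)
        assert out["area"].std() == pytest.approx(0.0, abs=1e-9)

    def test_needs_two_anchors(self):
        table = self._table([1.0])
        anchors = pd.DataFrame(
            {"injection_index": [0], "analyte_id": "x", "area": [50.0]}
        )
        with pytest.raises(ValueError):
            drift_correct(table, anchors)

    def test_correction_reduces_qc_spread_under_noisy_drift(self):
        rng = np.random.default_rng(3)
        idx = np.arange(40)
        drift = np.linspace(1.0, 0.75, 40)
        areas = 1000.0 * drift * rng.lognormal(0, 0.02, 40)
        table = self._table(areas)
        anchor_idx = idx[::8]
        anchors = pd.DataFrame(
            {"injection_index": anchor_idx, "analyte_id": "x", "area": areas[anchor_idx]}
        )
        out = drift_correct(table, anchors)
        assert out["area"].std() < table["area"].std()


class TestIonRatio:
    def test_within_tolerance_passes(self):
        assert check_ion_ratio(0.50, 0.50) == "pass"

    def test_outside_tolerance_fails(self):
        assert check_ion_ratio(0.70, 0.50, tolerance_rel=0.30) == "fail"  # 0.20 > 0.15

    def test_missing_qualifier_not_evaluable(self):
        assert check_ion_ratio(None, 0.5) == "not evaluable"


class TestQuantifySample:
    def test_in_range_measurement_scales_by_dilution(self):
        res = quantify_sample({5: 100.0}, _curve())  # area 100 -> 50 µg/L
        assert res.concentration == pytest.approx(250.0)
        assert res.dilution_used == 5
        assert res.censoring == "quantified"

    def test_recovery_correction_doubles_at_ra_50(self):
        res = quantify_sample({5: 100.0}, _curve(), recovery={5: _recovery(50.0)})
        assert res.concentration == pytest.approx(500.0)
        assert res.recovery_corrected

    def test_ra_100_changes_nothing(self):
        base = quantify_sample({5: 100.0}, _curve())
        same = quantify_sample({5: 100.0}, _curve(), recovery={5: _recovery(100.0)})
        assert same.concentration == base.concentration
        assert not same.recovery_corrected

    def test_most_dilute_in_range_wins(self):
        res = quantify_sample({5: 1000.0, 100: 50.0}, _curve())
        assert res.dilution_used == 100
        assert res.concentration == pytest.approx(25.0 * 100)

    def test_low_abundance_prefers_least_dilute(self):
        res = quantify_sample(
            {5: 1000.0, 100: 50.0}, _curve(), prefer_least_dilute=True
        )
        assert res.dilution_used == 5

    def test_above_uloq_at_both_dilutions_censored_with_advisory(self):
        res = quantify_sample({5: 1e7, 100: 1e6}, _curve())
        assert res.censoring == ">ULOQ"
        assert res.concentration is None
        assert "higher dilution" in res.advisory

    def test_below_lloq_at_both_dilutions(self):
        res = quantify_sample({5: 0.5, 100: 0.1}, _curve())
        assert res.censoring == "<LLOQ"

    def test_dilution_consistency_at_unit_matrix_factor(self):
        # zero noise, matrix factor 1: both routes give the same plasma conc
        plasma = 2000.0
        curve = _curve(uloq=100000.0)
        areas = {d: curve.slope * plasma / d for d in (5, 100)}
        r5 = quantify_sample({5: areas[5]}, curve)
        r100 = quantify_sample({100: areas[100]}, curve)
        assert r5.concentration == pytest.approx(r100.concentration)

    def test_ion_ratio_verdict_attached(self):
        curve = _curve(ion_ratio_ref=0.5)
        res = quantify_sample(
            {5: 100.0}, curve, qualifier_areas={5: 50.0}
        )
        assert res.ion_ratio_observed == pytest.approx(0.5)
        assert res.ion_ratio_pass == "pass"

    def test_single_transition_not_evaluable_but_quantified(self):
        res = quantify_sample({5: 100.0}, _curve(ion_ratio_ref=None))
        assert res.censoring == "quantified"
        assert res.ion_ratio_pass == "not evaluable"


class TestDeconvolution:
    @pytest.mark.parametrize(
        "total,unique,expected,flag",
        [
            (10.0, 4.0, 6.0, "ok"),
            (4.0, 4.0, 0.0, "ok"),
            (3.0, 4.0, 0.0, "negative_difference"),
        ],
    )
    def test_subtraction_and_censoring(self, total, unique, expected, flag):
        conc, got_flag = deconvolute_isomers(total, unique)
        assert conc == pytest.approx(expected)
        assert got_flag == flag

    def test_censored_input_not_evaluable(self):
        censored = QuantResult("s", "x", None, None, censoring="<LLOQ")
        conc, flag = deconvolute_isomers(censored, 4.0)
        assert conc is None and flag == "not evaluable"

    def test_sum_is_conserved_before_censoring(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            total = float(rng.uniform(1, 100))
            unique = float(rng.uniform(0, total))
            leu, _ = deconvolute_isomers(total, unique)
            assert leu + unique == pytest.approx(total)


class TestDuplicates:
    def _q(self, conc, censoring="quantified"):
        return QuantResult("s", "x", conc, 5, censoring=censoring)

    def test_both_quantified_averaged(self):
        merged = combine_duplicates(self._q(100.0), self._q(120.0))
        assert merged.concentration == pytest.approx(110.0)

    def test_disagreement_quantified_wins_with_flag(self):
        merged = combine_duplicates(self._q(None, "<LLOQ"), self._q(100.0))
        assert merged.concentration == pytest.approx(100.0)
        assert "disagreement" in merged.advisory


class TestTrueness:
    def test_identity_is_100(self):
        rep = trueness_report([50.0], [50.0])
        assert rep.table["trueness_pct"].iloc[0] == 100

    def test_printed_reference_rows(self):
        rep = trueness_report([2146.0, 645655.0], [3325.0, 1514000.0])
        assert list(rep.table["trueness_pct"]) == [65, 43]

    def test_nist_table_counts(self):
        t = nist_srm1950_table()
        rep = trueness_report(t["measured_ugL"], t["certified_ugL"], analytes=t["analyte"])
        expected = [65, 69, 78, 80, 84, 84, 92, 94, 94, 99, 116, 168, 113, 96, 43]
        assert list(rep.table["trueness_pct"].dropna().astype(int)) == expected
        assert rep.n_evaluable == 15
        assert rep.n_within == 11

    def test_certified_must_be_positive(self):
        with pytest.raises(ValueError):
            trueness_report([1.0], [0.0])
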