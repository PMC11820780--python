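"""Weighted calibration fits, quantification limits and curve inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srmquant.calibration import (
    CalibrationCurve,
    CalibrationModel,
    OutOfRangeError,
    back_calculate,
    determine_lod_lloq,
    determine_uloq,
    fit_calibration,
    ion_ratio,
)


def _wls_oracle(conc, area, order):
    """Closed-form weighted normal equations and weighted r^2."""
    x = np.asarray(conc, float)
    y = np.asarray(area, float)
    w = 1.0 / x
    X = np.column_stack([x**k for k in range(order + 1)])
    beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
    resid = y - X @ beta
    ybar = np.sum(w * y) / np.sum(w)
    r2 = 1.0 - np.sum(w * resid**2) / np.sum(w * (y - ybar) ** 2)
    return beta, r2


class TestFit:
    def test_exact_line(self):
        curve = fit_calibration([(c, 2 * c + 1) for c in (1, 10, 100)])
        assert curve.model == "linear"
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("order,model", [(1, "linear"), (2, "quadratic")])
    def test_matches_normal_equations_oracle(self, order, model):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(order + 2, 12))
            conc = np.sort(rng.uniform(0.5, 1000, n))
            true = 500 * conc - 0.05 * conc**2
            area = true * rng.lognormal(0, 0.05, n)
            curve = fit_calibration(list(zip(conc, area)), model=model)
            beta, r2 = _wls_oracle(conc, area, order)
            assert np.allclose(curve.coefficients, beta, rtol=1e-8)
            assert curve.r2 == pytest.approx(r2, rel=1e-8)

    def test_zero_level_excluded_from_fit(self):
        with_zero = fit_calibration([(0, 5), (1, 3), (10, 21), (100, 201)])
        without = fit_calibration([(1, 3), (10, 21), (100, 201)])
        assert with_zero.coefficients == without.coefficients

    def test_saturating_series_selects_quadratic(self):
        # curvature strong enough that the linear weighted r2 < 0.995
        conc = [1, 3, 10, 30, 100, 300, 1000]
        pts = [(c, 100 * c - 0.05 * c**2) for c in conc]
        lin = fit_calibration(pts, model="linear")
        assert lin.r2 < 0.995
        auto = fit_calibration(pts)
        assert auto.model == "quadratic"
        assert auto.curvature == pytest.approx(-0.05, rel=1e-6)

    def test_insufficient_or_degenerate_points(self):
        with pytest.raises(ValueError):
            fit_calibration([(1, 2), (2, 4)])
        with pytest.raises(ValueError):
            fit_calibration([(5, 2), (5, 3), (5, 4)])

    def test_model_results_summary(self):
        res = CalibrationModel([1, 10, 100], [3, 21, 201], analyte_id="val").fit()
        text = res.summary()
        assert "val" in text and "slope" in text and "1/x" in text


class TestLodLloq:
    def _series(self, levels, areas, noise_sd=1.0):
        areas = np.asarray(areas, float)
        return pd.DataFrame(
            {
                "level": levels,
                "area": areas,
                "height": areas / 10.0,
                "noise_sd": noise_sd / 10.0,
            }
        )

    def test_sn_thresholds(self):
        # areas = 1000*c and noise such that S/N = 400*c: detection (S/N >= 3)
        # first reached at 0.01, quantification (S/N >= 10) at 0.03
        levels = [0.001, 0.003, 0.01, 0.03, 0.1]
        areas = [c * 1000 for c in levels]
        series = self._series(levels, areas, noise_sd=2.5)
        lod, lloq = determine_lod_lloq(series)
        assert lod == pytest.approx(0.01)
        assert lloq == pytest.approx(0.03)

    def test_all_levels_quantifiable(self):
        levels = [1, 3, 10]
        series = self._series(levels, [1000, 3000, 10000], noise_sd=10.0)
        lod, lloq = determine_lod_lloq(series)
        assert lod == 1 and lloq == 1

    def test_carryover_plateau_fallback(self):
        # flat areas at the three lowest levels (carryover peaks), then a jump
        levels = [0.1, 0.3, 1.0, 3.0, 10.0]
        areas = [50, 52, 51, 3000, 10000]
        series = self._series(levels, areas, noise_sd=10.0)
        lod, lloq = determine_lod_lloq(series)
        assert lod is None
        assert lloq == pytest.approx(3.0)

    def test_unordered_levels_rejected(self):
        series = self._series([1, 0.5, 2], [10, 5, 20])
        with pytest.raises(ValueError):
            determine_lod_lloq(series)

    def test_lloq_monotone_in_noise(self):
        levels = [0.1, 0.3, 1, 3, 10, 30]
        areas = [c * 1000 for c in levels]
        results = []
        for scale in (1.0, 3.0, 10.0, 100.0):
            series = self._series(levels, areas, noise_sd=20.0 * scale)
            results.append(determine_lod_lloq(series))
        lods = [r[0] for r in results]
        lloqs = [r[1] for r in results]
        for a, b in zip(lods, lods[1:]):
            assert b is None or (a is not None and b >= a)
        for a, b in zip(lloqs, lloqs[1:]):
            assert b is None or (a is not None and b >= a)


class TestUloq:
    def test_perfect_line_keeps_top_level(self):
        pts = [(c, 2 * c) for c in [1, 3, 10, 30, 100, 300, 1000]]
        assert determine_uloq(pts, lloq=1) == 1000

    def test_saturation_truncates(self):
        # strong saturation: back-calculation at the top level falls below 95%
        conc = [1, 3, 10, 30, 100, 300, 1000, 3000, 10000]
        pts = [(c, 1000 * (c - 4.5e-5 * c**2)) for c in conc]
        uloq = determine_uloq(pts, lloq=1, model="linear")
        assert uloq is not None
        assert uloq < 10000

    def test_undetermined_when_nothing_fits(self):
        rng = np.random.default_rng(0)
        pts = [(c, float(rng.uniform(0, 1))) for c in [1, 3, 10, 30]]
        assert determine_uloq(pts, lloq=1, model="linear") is None


class TestIonRatio:
    def test_mean_of_three_levels(self):
        assert ion_ratio([(50, 100), (49, 98), (51, 102)]) == pytest.approx(0.5)
        assert ion_ratio([(10, 10), (20, 20), (30, 30)]) == pytest.approx(1.0)

    def test_random_triple_matches_hand_mean(self):
        rng = np.random.default_rng(5)
        quals = rng.uniform(10, 100, 3)
        quants = rng.uniform(100, 1000, 3)
        expected = np.mean(quals / quants)
        assert ion_ratio(list(zip(quals, quants))) == pytest.approx(expected)

    def test_requires_three_levels(self):
        with pytest.raises(ValueError):
            ion_ratio([(1, 2), (2, 4)])


class TestBackCalculate:
    def test_linear(self):
        curve = CalibrationCurve(None, "linear", (0.0, 2.0), 1.0)
        assert back_calculate(curve, 200) == pytest.approx(100.0)

    def test_quadratic_monotone_branch(self):
        curve = CalibrationCurve(None, "quadratic", (0.0, 1.0, -0.001), 1.0, uloq=200)
        assert back_calculate(curve, 90) == pytest.approx(100.0)

    def test_out_of_range_flagged(self):
        curve = CalibrationCurve(None, "quadratic", (0.0, 1.0, -0.001), 1.0, uloq=200)
        with pytest.raises(OutOfRangeError):
            back_calculate(curve, 260)  # beyond the apex (250 at vertex 500)... area 260 > max on branch

    def test_nonpositive_slope_rejected(self):
        curve = CalibrationCurve(None, "linear", (0.0, -2.0), 1.0)
        with pytest.raises(ValueError):
            back_calculate(curve, 10)

    @given(
        slope=st.floats(10, 1000),
        intercept=st.floats(-50, 50),
        curvature=st.floats(-0.01, 0.0),
        conc=st.floats(1.0, 900.0),
    )
    def test_roundtrip_identity(self, slope, intercept, curvature, conc):
        """back_calculate(predict(c)) == c on the monotone branch."""
        curve = CalibrationCurve(
            None,
            "quadratic" if curvature else "linear",
            (intercept, slope, curvature),
            1.0,
            uloq=1000.0,
        )
        if curvature < 0 and conc > -slope / (2 * curvature):
            return  # beyond the vertex: not invertible by construction
        area = float(curve.predict(conc))
        tol = 1e-6 if curvature else 1e-9
        assert back_calculate(curve, area) == pytest.approx(conc, rel=tol)
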