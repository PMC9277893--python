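"""Survival-curve assembly, AUC statistic, loess averaging, exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clscreen.survival import (
    LoessAverager,
    SurvivalCurve,
    area_under_curve,
    average_curve,
    exclude_strains,
    normalize_curve,
)


def _points(days, fracs, qc=None):
    df = pd.DataFrame({"day": days, "fraction_viable": fracs})
    if qc is not None:
        df["qc_pass"] = qc
    return df


def _curve(days, survival, strain="s", rep="r1"):
    return SurvivalCurve(strain, rep, np.asarray(days, float), np.asarray(survival, float))


class TestNormalization:
    def test_ratio_arithmetic(self):
        c = normalize_curve(_points([0, 2, 4], [0.95, 0.76, 0.475]))
        np.testing.assert_allclose(c.survival, [100.0, 80.0, 50.0])

    def test_zero_day0_viability_is_no_growth(self):
        with pytest.raises(ValueError, match="no growth"):
            normalize_curve(_points([0, 2], [0.0, 0.1]))

    def test_missing_day0_rejected(self):
        with pytest.raises(ValueError, match="day-0"):
            normalize_curve(_points([2, 4], [0.9, 0.5]))

    def test_survival_above_100_kept_and_flagged(self):
        c = normalize_curve(_points([0, 2], [0.8, 0.9]))
        assert c.survival[1] == pytest.approx(112.5)
        assert c.over_100

    def test_qc_failures_dropped_before_normalizing(self):
        c = normalize_curve(
            _points([0, 2, 4], [1.0, 0.5, 0.25], qc=[True, False, True])
        )
        assert list(c.days) == [0.0, 4.0]


class TestAreaStatistic:
    def test_constant_curve_rectangle(self):
        a = area_under_curve(_curve([0, 2, 4, 6, 8], [100] * 5))
        assert a.area == pytest.approx(800.0)
        assert a.span == (0.0, 8.0)

    def test_immediate_death_single_trapezoid(self):
        a = area_under_curve(_curve([0, 2, 4, 6, 8], [100, 0, 0, 0, 0]))
        assert a.area == pytest.approx(100.0)

    def test_matches_dense_integration_oracle(self):
        # trapezoid over observed days vs fine-grid integration of the
        # piecewise-linear interpolant (knots included so it is exact)
        rng = np.random.default_rng(42)
        for _ in range(1_000):
            days = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
            surv = np.concatenate([[100.0], rng.uniform(0, 110, 4)])
            a = area_under_curve(_curve(days, surv)).area
            grid = np.union1d(np.linspace(0, 8, 10_001), days)
            y = np.interp(grid, days, surv)
            dense = float(np.sum((y[:-1] + y[1:]) / 2 * np.diff(grid)))
            assert abs(a - dense) < 1e-9

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            area_under_curve(_curve([0.0], [100.0]))

    @given(c=st.floats(0.01, 1.0), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_scaling_linearity_and_terminal_zero_bound(self, c, seed):
        rng = np.random.default_rng(seed)
        days = np.array([0.0, 2.0, 4.0, 6.0])
        surv = np.concatenate([[100.0], rng.uniform(0, 100, 3)])
        base = area_under_curve(_curve(days, surv)).area
        # linearity holds for the sub-curve past day 0 (day-0 anchor is fixed)
        scaled = np.trapezoid(surv * c, days)
        assert scaled == pytest.approx(base * c, rel=1e-12)
        # appending a terminal 0 adds at most half the final trapezoid
        ext = area_under_curve(
            _curve(np.append(days, 8.0), np.append(surv, 0.0))
        ).area
        assert base <= ext <= base + 0.5 * 2.0 * surv[-1] + 1e-9

    def test_area_span_equals_observed_span(self):
        a = area_under_curve(_curve([0, 2, 6], [100, 50, 10]))
        assert a.span == (0.0, 6.0)


class TestLoessAverage:
    def test_identical_constant_replicates_zero_band(self):
        curves = [_curve([0, 2, 4, 6, 8], [100] * 5, rep=f"r{i}") for i in range(3)]
        out = average_curve(curves)
        np.testing.assert_allclose(out["fitted"], 100.0, atol=1e-8)
        np.testing.assert_allclose(out["upper"] - out["lower"], 0.0, atol=1e-8)

    def test_noiseless_linear_matches_ols(self):
        x = np.tile([0.0, 2.0, 4.0, 6.0, 8.0], 3)
        y = 100.0 - 10.0 * x
        model = LoessAverager(span=1.0, degree=1).fit(x, y)
        grid = np.linspace(0, 8, 21)
        # closed-form OLS line as oracle
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            model.predict(grid), beta[0] + beta[1] * grid, atol=1e-8
        )

    def test_band_ordering_and_replicate_requirements(self):
        curves = [
            _curve([0, 2, 4], [100, 80, 60], rep="r1"),
            _curve([0, 2, 4], [100, 70, 40], rep="r2"),
        ]
        out = average_curve(curves)
        assert (out["lower"] <= out["fitted"] + 1e-12).all()
        assert (out["fitted"] <= out["upper"] + 1e-12).all()
        with pytest.raises(ValueError, match="2 replicate"):
            average_curve(curves[:1])
        with pytest.raises(ValueError, match="mix strains"):
            average_curve([curves[0], _curve([0, 2, 4], [100, 70, 40], strain="t")])

    def test_band_covers_true_trajectory(self):
        # 30 noisy replicates of a known decay: the 95% band should contain
        # the truth at >= 90% of grid points on average over seeds
        days = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        true = 100.0 * np.exp(-((days / 4.0) ** 2))
        grid = days
        coverages = []
        for seed in range(12):
            rng = np.random.default_rng(1000 + seed)
            x = np.tile(days, 30)
            y = np.concatenate([true + rng.normal(0, 4.0, 5) for _ in range(30)])
            model = LoessAverager(span=0.75, degree=2).fit(x, y)
            band = model.predict_band(grid)
            inside = (band["lower"] <= true) & (true <= band["upper"])
            coverages.append(inside.mean())
        assert np.mean(coverages) >= 0.9


class TestExclusion:
    def _viability(self, strain, day0_frac=1.0, qc_late=True):
        return [
            {"strain": strain, "day": 0.0, "fraction_viable": day0_frac, "qc_pass": True},
            {"strain": strain, "day": 2.0, "fraction_viable": 0.5, "qc_pass": qc_late},
            {"strain": strain, "day": 4.0, "fraction_viable": 0.2, "qc_pass": qc_late},
        ]

    def test_no_growth_and_flagged_strains_excluded(self):
        rows = (
            self._viability("ok")
            + self._viability("dead0", day0_frac=0.0)
            + self._viability("noqc", qc_late=False)
            + self._viability("flagged")
            + self._viability("ok2")
        )
        retained, log = exclude_strains(
            pd.DataFrame(rows), growth_flags={"flagged": False}
        )
        assert retained == {"ok", "ok2"}
        reasons = dict(zip(log["strain"], log["reason"]))
        assert reasons["dead0"] == "no growth"
        assert reasons["flagged"] == "no growth or regrowth"
        assert "QC" in reasons["noqc"]

    def test_clean_strain_retained(self):
        retained, log = exclude_strains(pd.DataFrame(self._viability("s")))
        assert retained == {"s"} and log.empty


class TestCurveInvariants:
    def test_day_zero_anchor_enforced(self):
        with pytest.raises(ValueError):
            _curve([0, 2], [99.0, 50.0])
        with pytest.raises(ValueError):
            _curve([1, 2], [100.0, 50.0])
        with pytest.raises(ValueError):
            _curve([0, 2, 2], [100.0, 50.0, 40.0])
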