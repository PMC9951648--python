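"""Regression coefficients, forecast tables, combination and accuracy."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import herdcast as hc
from herdcast.biometrics import DescriptiveStats, correlation_from_arrays
from herdcast.forecasting import (
    ForecastTable,
    GridSpec,
    RegressionCoefficient,
    build_forecast_table,
    forecast_accuracy,
)
from herdcast.herd_data import (
    BIRTH_LIVE_WEIGHT,
    BIRTH_WITHERS_HEIGHT,
    DAM_WEIGHT,
    LIVE_WEIGHT,
    round_half_up,
)


def _stats(trait, age, mean, sd, n=50):
    import math

    return DescriptiveStats(trait=trait, age_months=age, n=n, mean=mean, sem=sd / math.sqrt(n), sd=sd)


def _corr(pair_x, pair_y, r, n=50):
    import math

    m_r = (1 - r * r) / math.sqrt(n - 2)
    return hc.CorrelationEstimate(pair_x, pair_y, n, r, m_r, r / m_r if m_r else float("inf"), True)


class TestRegressionCoefficient:
    def test_zero_r_gives_zero_slope(self):
        b = hc.regression_coefficient(
            _stats(LIVE_WEIGHT, 0, 26, 2.8),
            _stats("pre_slaughter_mass_kg", None, 425.7, 39.0),
            _corr(BIRTH_LIVE_WEIGHT, ("pre_slaughter_mass_kg", None), 0.0),
        )
        assert b.b == 0.0

    def test_identity_scaling(self):
        b = hc.regression_coefficient(
            _stats("a", 0, 10, 3.0),
            _stats("b", None, 20, 3.0),
            _corr(("a", 0), ("b", None), 1.0),
        )
        assert b.b == pytest.approx(1.0)

    def test_published_coefficient_reproduced(self):
        """r = 0.9, sigma_y = 62.8, sigma_x = 5.0 gives the printed b = 11.3."""
        b = hc.regression_coefficient(
            _stats(LIVE_WEIGHT, 0, 26, 5.0),
            _stats("pre_slaughter_mass_kg", None, 425.7, 62.8),
            _corr(BIRTH_LIVE_WEIGHT, ("pre_slaughter_mass_kg", None), 0.9),
        )
        assert round_half_up(b.b, 2) == 11.3

    def test_degenerate_marker_rejected(self):
        with pytest.raises(ZeroDivisionError):
            hc.regression_coefficient(
                _stats("a", 0, 10, 0.0),
                _stats("b", None, 20, 3.0),
                _corr(("a", 0), ("b", None), 0.5),
            )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-0.99, 0.99), st.floats(0.1, 50), st.floats(0.1, 50))
    def test_product_of_reciprocal_slopes_is_r_squared(self, r, sx, sy):
        fwd = hc.regression_coefficient(
            _stats("x", 0, 0, sx), _stats("y", None, 0, sy), _corr(("x", 0), ("y", None), r)
        )
        rev = hc.regression_coefficient(
            _stats("y", None, 0, sy), _stats("x", 0, 0, sx), _corr(("y", None), ("x", 0), r)
        )
        assert fwd.b * rev.b == pytest.approx(r * r, abs=1e-10)

    def test_matches_least_squares_slope(self, big_herd):
        """b = r * sigma_y / sigma_x equals the least-squares fit on herd data."""
        m_stats = hc.describe(big_herd, LIVE_WEIGHT, 0)
        t_stats = hc.describe(big_herd, "pre_slaughter_mass_kg")
        corr = hc.correlate(big_herd, BIRTH_LIVE_WEIGHT, ("pre_slaughter_mass_kg", None))
        b = hc.regression_coefficient(m_stats, t_stats, corr)
        x = big_herd.trait_values(BIRTH_LIVE_WEIGHT)
        y = big_herd.trait_values(("pre_slaughter_mass_kg", None)).loc[x.index]
        lsq = np.polyfit(x.to_numpy(), y.to_numpy(), 1)[0]
        assert b.b == pytest.approx(lsq, rel=1e-8)


def _printed_table(marker, mean, rows):
    """Forecast table from printed slopes and anchors."""
    stats = _stats(marker[0], marker[1], mean, 1.0)
    targets = [
        (_stats(t, None, anchor, 1.0), RegressionCoefficient.from_slope(marker, t, b))
        for t, b, anchor in rows
    ]
    return build_forecast_table(stats, targets)


@pytest.fixture()
def withers_table():
    return _printed_table(
        BIRTH_WITHERS_HEIGHT,
        70.0,
        [("pre_slaughter_mass_kg", 5.1, 425.7), ("slaughter_mass_kg", 2.8, 237.3), ("pulp_mass_kg", 1.9, 175.2)],
    )


@pytest.fixture()
def birthweight_table():
    return _printed_table(
        BIRTH_LIVE_WEIGHT,
        26.0,
        [("pre_slaughter_mass_kg", 11.3, 425.7), ("slaughter_mass_kg", 6.0, 237.3), ("pulp_mass_kg", 4.7, 175.2)],
    )


class TestForecastTable:
    def test_anchor_at_marker_mean(self, withers_table):
        assert withers_table.predict("pre_slaughter_mass_kg", 70.0) == pytest.approx(425.7)

    def test_printed_cells_reproduced(self, withers_table, birthweight_table):
        assert round_half_up(withers_table.predict("pre_slaughter_mass_kg", 76.0), 1) == 456.3
        assert round_half_up(birthweight_table.predict("slaughter_mass_kg", 20.0), 1) == 201.3
        assert round_half_up(birthweight_table.predict("pulp_mass_kg", 32.0), 1) == 203.4

    def test_adjacent_cells_differ_by_b_times_step(self, withers_table):
        for row in withers_table.rows:
            cells = [withers_table.predict(row.target, float(x)) for x in withers_table.grid]
            diffs = np.diff(cells)
            assert np.allclose(diffs, row.b * 1.0)

    def test_grid_centered_on_rounded_mean(self):
        tab = _printed_table(DAM_WEIGHT, 512.4, [("pre_slaughter_mass_kg", 1.3, 425.7)])
        assert tab.grid.min() == 506.0 and tab.grid.max() == 518.0
        assert 512.0 in tab.grid

    def test_rendered_frame_has_one_decimal_cells(self, withers_table):
        frame = withers_table.to_frame()
        assert frame.loc[frame["index"] == "pre_slaughter_mass_kg", "76"].iloc[0] == 456.3

    def test_mismatched_marker_rejected(self, withers_table):
        stats = _stats(LIVE_WEIGHT, 0, 26, 2.8)
        coef = RegressionCoefficient.from_slope(BIRTH_WITHERS_HEIGHT, "pulp_mass_kg", 1.9)
        with pytest.raises(ValueError):
            build_forecast_table(stats, [(_stats("pulp_mass_kg", None, 175.2, 1.0), coef)])


class TestForecastAnimal:
    def _tables(self):
        dam = _printed_table(
            DAM_WEIGHT,
            512.0,
            [("pre_slaughter_mass_kg", 4 / 3, 425.7), ("pulp_mass_kg", 0.5, 175.2)],
        )
        bw = _printed_table(
            BIRTH_LIVE_WEIGHT,
            26.0,
            [("pre_slaughter_mass_kg", 11.3, 425.7), ("pulp_mass_kg", 4.7, 175.2)],
        )
        wh = _printed_table(
            BIRTH_WITHERS_HEIGHT,
            70.0,
            [("pre_slaughter_mass_kg", 5.1, 425.7), ("pulp_mass_kg", 1.9, 175.2)],
        )
        return {t.marker: t for t in (dam, bw, wh)}

    def test_combined_is_arithmetic_mean(self):
        tables = self._tables()
        fc = hc.forecast_animal(tables, {DAM_WEIGHT: 521, BIRTH_LIVE_WEIGHT: 27, BIRTH_WITHERS_HEIGHT: 70})
        per = [fc.per_marker[m]["pre_slaughter_mass_kg"] for m in tables]
        assert fc.combined["pre_slaughter_mass_kg"] == pytest.approx(np.mean(per))
        assert min(per) <= fc.combined["pre_slaughter_mass_kg"] <= max(per)

    def test_markers_at_means_give_anchors(self):
        fc = hc.forecast_animal(
            self._tables(), {DAM_WEIGHT: 512, BIRTH_LIVE_WEIGHT: 26, BIRTH_WITHERS_HEIGHT: 70}
        )
        assert fc.combined["pre_slaughter_mass_kg"] == pytest.approx(425.7)
        assert fc.combined["pulp_mass_kg"] == pytest.approx(175.2)

    def test_permutation_invariance(self):
        tables = self._tables()
        values = {DAM_WEIGHT: 520, BIRTH_LIVE_WEIGHT: 28, BIRTH_WITHERS_HEIGHT: 72}
        a = hc.forecast_animal(tables, values)
        b = hc.forecast_animal(tables, dict(reversed(list(values.items()))))
        assert a.combined == b.combined

    def test_linear_mode_independent_of_grid(self):
        stats = _stats(BIRTH_LIVE_WEIGHT[0], 0, 26.0, 2.8)
        coef = RegressionCoefficient.from_slope(BIRTH_LIVE_WEIGHT, "pulp_mass_kg", 4.7)
        entry = (_stats("pulp_mass_kg", None, 175.2, 1.0), coef)
        fine = build_forecast_table(stats, [entry], GridSpec(6, 0.5))
        coarse = build_forecast_table(stats, [entry], GridSpec(6, 3.0))
        assert fine.predict("pulp_mass_kg", 27.3) == pytest.approx(coarse.predict("pulp_mass_kg", 27.3))

    def test_nearest_mode_snaps_to_grid(self):
        tables = self._tables()
        fc = hc.forecast_animal(tables, {BIRTH_LIVE_WEIGHT: 27.4}, interpolation="nearest")
        expected = tables[BIRTH_LIVE_WEIGHT].predict("pulp_mass_kg", 27.0)
        assert fc.per_marker[BIRTH_LIVE_WEIGHT]["pulp_mass_kg"] == pytest.approx(expected)

    def test_out_of_grid_nearest_warns_and_uses_line(self):
        tables = self._tables()
        with pytest.warns(UserWarning, match="outside grid"):
            fc = hc.forecast_animal(tables, {DAM_WEIGHT: 521.0}, interpolation="nearest")
        assert fc.per_marker[DAM_WEIGHT]["pre_slaughter_mass_kg"] == pytest.approx(425.7 + (4 / 3) * 9)


class TestAccuracy:
    @pytest.mark.parametrize(
        "forecast, actual, unrounded, rounded",
        [
            (428.6, 420.3, 98.06, 98),
            (234.1, 210.3, 89.83, 90),
            (423.2, 398.8, 94.23, 94),
        ],
    )
    def test_farm_level_cells(self, forecast, actual, unrounded, rounded):
        acc = forecast_accuracy(forecast, actual)
        assert acc == pytest.approx(unrounded, abs=0.005)
        assert round_half_up(acc, 0) == rounded

    def test_exact_forecast_is_100(self):
        assert forecast_accuracy(237.3, 237.3) == 100.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            forecast_accuracy(0.0, 10.0)
        with pytest.raises(ValueError):
            forecast_accuracy(10.0, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    def test_bounded_above_by_100(self, f, a):
        assert forecast_accuracy(f, a) <= 100.0


class TestApprobation:
    def test_self_approbation_on_noise_free_herd_is_100(self):
        """With zero residual noise the tables predict the train herd exactly at farm level."""
        cfg = hc.default_config(n_animals=400, seed=31)
        for link in cfg.slaughter_link.values():
            link.resid_sd = 0.0
        ds = hc.generate_herd(cfg)
        reports = hc.approbate(ds, ds, targets=["pre_slaughter_mass_kg", "slaughter_mass_kg"])
        for rep in reports:
            assert rep.accuracy_pct == pytest.approx(100.0, abs=0.2)

    def test_farm_level_accuracy_is_accuracy_of_means(self, big_herd):
        reports = hc.approbate(big_herd, big_herd, targets=["pre_slaughter_mass_kg"])
        rep = reports[0]
        assert rep.accuracy_pct == pytest.approx(
            forecast_accuracy(rep.forecast_mean, rep.actual_mean), abs=1e-12
        )

    def test_own_tables_beat_foreign_tables_on_shifted_farm(self):
        """Farm-specific tables improve accuracy on a mean-shifted herd."""
        cfg_a = hc.default_config(n_animals=1500, seed=61)
        farm_a = hc.generate_herd(cfg_a)
        cfg_b = hc.default_config(n_animals=1500, seed=62)
        for key in cfg_b.means:
            if key[0] == LIVE_WEIGHT or key == DAM_WEIGHT:
                cfg_b.means[key] *= 0.93
        for link in cfg_b.slaughter_link.values():
            link.mean *= 0.90
        farm_b = hc.generate_herd(cfg_b)
        farm_b.provenance["farm"] = "B"

        foreign = hc.approbate(farm_a, farm_b, targets=["pre_slaughter_mass_kg"])[0]
        own = hc.approbate(farm_b, farm_b, targets=["pre_slaughter_mass_kg"])[0]
        assert own.accuracy_pct >= foreign.accuracy_pct
        assert foreign.accuracy_pct < 99.0  # the shift is visible, not a no-op

    def test_empty_test_set_rejected(self, big_herd, tiny_herd):
        with pytest.raises(ValueError, match="slaughter"):
            hc.approbate(big_herd, tiny_herd)

    def test_report_is_serializable(self, big_herd):
        rep = hc.approbate(big_herd, big_herd, targets=["pulp_mass_kg"])[0]
        d = dataclasses.asdict(rep)
        assert d["target"] == "pulp_mass_kg"
        assert rep.accuracy_rounded == round_half_up(rep.accuracy_pct, 0)
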