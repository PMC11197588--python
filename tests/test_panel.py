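"""Panel data model: factor derivation, weekly aggregation, NDVI, LPGP, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maizeyield.panel import (
    MissingDataError,
    PanelSchemaError,
    SeasonWindow,
    aggregate_ndvi_weekly,
    aggregate_weekly,
    compute_daily_factors,
    compute_lpgp,
    read_panel,
    validate_panel,
    week_of_year,
    write_panel,
)


class TestDailyFactors:
    @pytest.mark.parametrize(
        "tmax,tmin,kwargs,expected",
        [
            (25, 15, {}, (10.0, 0.0)),                       # plain capped-average GDD
            (32, 22, {}, (16.0, 3.0)),                       # tmax capped at 30; KDD above 29
            (25, 15, {"kdd_threshold": 29}, (10.0, 0.0)),    # below KDD threshold
            (8, 2, {}, (0.0, 0.0)),                          # cold day clamps GDD at 0
        ],
    )
    def test_degree_day_formulas(self, tmax, tmin, kwargs, expected):
        gdd, kdd, _ = compute_daily_factors(tmin, tmax, 5.0, 15.0, **kwargs)
        assert gdd == pytest.approx(expected[0])
        assert kdd == pytest.approx(expected[1])

    def test_vpd_is_mean_of_extremes(self):
        _, _, vpd = compute_daily_factors(15, 25, 4.0, 16.0)
        assert vpd == pytest.approx(10.0)

    def test_missing_temperature_raises(self):
        with pytest.raises(MissingDataError):
            compute_daily_factors(np.nan, 25, 4, 16)

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ValueError):
            compute_daily_factors(15, 25, 4, 16, gdd_base=30, gdd_cap=10)

    @given(
        tmin=st.floats(-20, 25), dt=st.floats(0, 20),
        bump=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_gdd_monotone_in_temperature(self, tmin, dt, bump):
        """GDD never decreases when either temperature rises; KDD follows tmax."""
        tmax = tmin + dt
        g0, k0, _ = compute_daily_factors(tmin, tmax, 1, 2)
        g1, k1, _ = compute_daily_factors(tmin, tmax + bump, 1, 2)
        g2, _, _ = compute_daily_factors(min(tmin + bump, tmax), tmax, 1, 2)
        assert g1 >= g0 - 1e-12 and g2 >= g0 - 1e-12
        assert k1 >= k0 - 1e-12


def _daily_factor_frame(values, n_weeks=21, start_week=18):
    """Daily frame covering the window with constant factor values."""
    days = np.arange((start_week - 1) * 7 + 1, (start_week - 1 + n_weeks) * 7 + 1)
    return pd.DataFrame({
        "day_of_year": days,
        "gdd": np.full(len(days), values.get("gdd", 0.0)),
        "kdd": np.full(len(days), values.get("kdd", 0.0)),
        "prcp": np.full(len(days), values.get("prcp", 0.0)),
        "vpd": np.full(len(days), values.get("vpd", 0.0)),
    })


class TestWeeklyAggregation:
    def test_sums_and_shape(self):
        daily = _daily_factor_frame({"gdd": 10.0, "prcp": 0.0})
        weekly = aggregate_weekly(daily)
        assert len(weekly) == 21                      # weeks 18-38
        np.testing.assert_allclose(weekly["gdd"], 70.0)
        assert (weekly["prcp"] == 0.0).all()

    def test_two_missing_days_rescaled(self, caplog):
        daily = _daily_factor_frame({"gdd": 10.0})
        daily = daily[~daily["day_of_year"].isin([120, 121])]  # two days of week 18
        weekly = aggregate_weekly(daily)
        assert weekly.loc[weekly["week"] == 1, "gdd"].iloc[0] == pytest.approx(70.0)

    def test_three_missing_days_rejected(self):
        daily = _daily_factor_frame({"gdd": 10.0})
        daily = daily[~daily["day_of_year"].isin([120, 121, 122])]
        with pytest.raises(MissingDataError):
            aggregate_weekly(daily)

    def test_aggregation_is_linear(self):
        rng = np.random.default_rng(3)
        a = _daily_factor_frame({})
        b = _daily_factor_frame({})
        for col in ("gdd", "kdd", "prcp", "vpd"):
            a[col] = rng.uniform(0, 5, len(a))
            b[col] = rng.uniform(0, 5, len(b))
        both = a.copy()
        for col in ("gdd", "kdd", "prcp", "vpd"):
            both[col] = a[col] + b[col]
        wa, wb, wboth = aggregate_weekly(a), aggregate_weekly(b), aggregate_weekly(both)
        for col in ("gdd", "kdd", "prcp", "vpd"):
            np.testing.assert_allclose(wa[col] + wb[col], wboth[col], atol=1e-9)


class TestNdviAggregation:
    def test_weekly_median(self):
        window = SeasonWindow()
        days18 = [120, 122, 124]  # all in week 18
        obs = pd.DataFrame({"day_of_year": days18 + [245], "ndvi": [0.2, 0.8, 0.5, 0.6]})
        values = aggregate_ndvi_weekly(obs, window)
        assert values[0] == pytest.approx(0.5)

    def test_gap_interpolation(self):
        # observations in window weeks 1 and 3 only -> week 2 interpolated
        obs = pd.DataFrame({"day_of_year": [120, 134], "ndvi": [0.2, 0.6]})
        values = aggregate_ndvi_weekly(obs, SeasonWindow())
        assert values[1] == pytest.approx(0.4)
        # constant extension past the last observed week
        assert values[-1] == pytest.approx(0.6)

    def test_single_week_insufficient(self):
        obs = pd.DataFrame({"day_of_year": [120, 121], "ndvi": [0.3, 0.4]})
        with pytest.raises(MissingDataError):
            aggregate_ndvi_weekly(obs, SeasonWindow())

    def test_clipped_to_valid_range(self):
        obs = pd.DataFrame({"day_of_year": [120, 240], "ndvi": [1.7, -1.5]})
        values = aggregate_ndvi_weekly(obs, SeasonWindow())
        assert values.max() <= 1.0 and values.min() >= -1.0


class TestLpgp:
    def test_linear_ramp_crossing(self):
        # trailing 7-day mean first exceeds 13 C at day 110; first frost at 290
        doy = np.arange(1, 366)
        tmean = 13.0 + 0.2 * (doy - 113)  # mean of days d-6..d crosses 13 at d=116
        # find expected crossing by direct scan of the construction
        trailing = pd.Series(tmean).rolling(7).mean().to_numpy()
        expected_plant = int(doy[np.argmax((doy >= 60) & (trailing > 13.0))])
        tmin = np.where(doy >= 290, -2.0, 5.0)
        daily = pd.DataFrame({"day_of_year": doy, "tmean": tmean, "tmin": tmin})
        assert compute_lpgp(daily) == 290 - expected_plant

    def test_no_frost_falls_back_to_day_365(self):
        doy = np.arange(1, 366)
        daily = pd.DataFrame({"day_of_year": doy, "tmean": 20.0, "tmin": 10.0})
        lpgp = compute_lpgp(daily)
        assert lpgp == 365 - 60  # always warm: planting at the day-60 earliest bound

    def test_never_warm_enough_raises(self):
        doy = np.arange(1, 366)
        daily = pd.DataFrame({"day_of_year": doy, "tmean": 5.0, "tmin": 0.0})
        with pytest.raises(MissingDataError):
            compute_lpgp(daily)


class TestPanelIO:
    def test_round_trip_identity(self, small_panel, tmp_path):
        write_panel(small_panel, tmp_path)
        back = read_panel(tmp_path)
        for attr in ("panel", "soil", "yields"):
            left = getattr(small_panel, attr).reset_index(drop=True)
            right = getattr(back, attr).reset_index(drop=True)
            pd.testing.assert_frame_equal(left, right, check_exact=False, atol=1e-9, check_dtype=False)

    def test_duplicate_county_year_rejected(self, small_panel, tmp_path):
        write_panel(small_panel, tmp_path)
        dup = pd.concat([small_panel.yields, small_panel.yields.iloc[[0]]])
        dup.to_csv(tmp_path / "yields.csv", index=False)
        with pytest.raises(PanelSchemaError):
            read_panel(tmp_path)

    def test_short_week_block_rejected(self, small_panel, tmp_path):
        write_panel(small_panel, tmp_path)
        trimmed = small_panel.panel.iloc[1:]  # drop one week row
        trimmed.to_csv(tmp_path / "weekly_panel.csv", index=False)
        with pytest.raises(PanelSchemaError):
            read_panel(tmp_path)

    def test_predictor_counts(self, small_arrays):
        """5 temporal variables x 21 weeks, plus 5 soil = the 110-wide design."""
        n, t, v = small_arrays["Xt"].shape
        assert (t, v) == (21, 5)
        assert t * v == 105
        assert t * v + small_arrays["Xs"].shape[1] == 110


def test_week_of_year_blocks():
    assert week_of_year(1) == 1 and week_of_year(7) == 1 and week_of_year(8) == 2
    window = SeasonWindow()
    assert window.n_steps == 21 and window.weeks[0] == 18 and window.weeks[-1] == 38
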