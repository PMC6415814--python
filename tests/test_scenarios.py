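"""Synthetic forcing generators: seeded, bounded, correctly shaped."""

import numpy as np
import pandas as pd
import pytest

from pelagics.scenarios import (
    ForcingSeries,
    ScenarioSpec,
    SecondPeak,
    accident_series,
    build_forcings,
    build_grid,
    default_site_peaks,
    draw_spawn_dates,
    preaccident_series,
    substream,
    temperature_series,
)


def test_preaccident_draws_within_range(daily_axis):
    water = preaccident_series(daily_axis, (1e-3, 3e-3), substream(0, "w"))
    assert water.min() >= 1e-3 and water.max() <= 3e-3
    # roughly uniform: mean near the midpoint
    assert water.mean() == pytest.approx(2e-3, rel=0.05)


def test_preaccident_deterministic_under_seed(daily_axis):
    a = preaccident_series(daily_axis, (1e-3, 3e-3), substream(7, "w"))
    b = preaccident_series(daily_axis, (1e-3, 3e-3), substream(7, "w"))
    c = preaccident_series(daily_axis, (1e-3, 3e-3), substream(8, "w"))
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_substreams_are_independent():
    a = substream(0, "alpha").uniform(size=100)
    b = substream(0, "beta").uniform(size=100)
    assert not np.array_equal(a, b)


def test_accident_series_shape(daily_axis):
    spec = ScenarioSpec(peak_Bq_l=10.0, seed=3)
    water = accident_series(daily_axis, spec)
    acc = daily_axis.get_loc(pd.Timestamp(spec.accident_date))
    floor = 2e-3
    # pre-accident part keeps the baseline draws
    assert water[:acc].max() <= 3e-3
    # linear rise reaches the peak exactly rise_d days after the accident
    assert water[acc + spec.rise_d] == pytest.approx(10.0)
    assert np.argmax(water) == acc + spec.rise_d
    # quasi-exponential decline: halving time of the excess over the floor
    t0 = acc + spec.rise_d
    excess = water[t0:] - floor
    assert excess[25] == pytest.approx(excess[0] / 2, rel=1e-9)
    # eventually back near the floor
    assert water[-1] == pytest.approx(floor, rel=1e-2)


def test_accident_series_second_peak(daily_axis):
    base = ScenarioSpec(peak_Bq_l=10.0, seed=3)
    bumped = ScenarioSpec(peak_Bq_l=10.0, seed=3, second_peak=SecondPeak(0.5, 40, 10))
    w0 = accident_series(daily_axis, base)
    w1 = accident_series(daily_axis, bumped)
    acc = daily_axis.get_loc(pd.Timestamp(base.accident_date))
    assert np.all(w1 >= w0 - 1e-15)
    lag_window = slice(acc + 40, acc + 80)
    assert w1[lag_window].max() > w0[lag_window].max()


def test_accident_peak_below_floor_rejected(daily_axis):
    with pytest.raises(ValueError, match="floor"):
        accident_series(daily_axis, ScenarioSpec(peak_Bq_l=1e-4))


def test_accident_date_outside_axis_rejected():
    dates = pd.date_range("2002-01-01", "2005-01-01", freq="D")
    with pytest.raises(ValueError, match="accident_date"):
        accident_series(dates, ScenarioSpec())


def test_temperature_seasonal_cycle(daily_axis):
    temp = temperature_series(daily_axis, ScenarioSpec())
    assert temp.min() == pytest.approx(10.0, abs=0.05)
    assert temp.max() == pytest.approx(25.0, abs=0.05)
    # annual periodicity
    assert temp[0] == pytest.approx(temp[365], abs=0.3)


def test_draw_spawn_dates_seeded_and_centred():
    years = range(2002, 2013)
    a = draw_spawn_dates(135, 15.0, years, substream(1, "s"))
    b = draw_spawn_dates(135, 15.0, years, substream(1, "s"))
    assert a == b
    exact = draw_spawn_dates(135, 0.0, [2004], substream(1, "s"))
    assert exact[0] == pd.Timestamp("2004-01-01") + pd.Timedelta(days=134)
    offsets = [(d - pd.Timestamp(year=d.year, month=1, day=1)).days - 134 for d in a]
    assert max(abs(o) for o in offsets) < 75  # draws stay near the peak


def test_build_grid_default():
    grid = build_grid()
    assert len(grid) == 30
    assert grid.site_ids[0] == "S01" and grid.site_ids[-1] == "S30"
    assert grid.latitudes[0] == pytest.approx(38.5)
    assert grid.latitudes[-1] == pytest.approx(36.0)
    assert len(set(grid.site_ids)) == 30


def test_default_site_peaks_profile():
    grid = build_grid()
    peaks = default_site_peaks(grid)
    assert peaks.min() >= 0.5 and peaks.max() <= 50.0
    # maximum at the site closest to the release latitude
    i = np.argmax(peaks)
    assert abs(grid.latitudes[i] - 37.42) == np.min(np.abs(grid.latitudes - 37.42))


def test_build_forcings_per_site(daily_axis):
    grid = build_grid(4, (38.5, 36.0))
    base = ScenarioSpec(seed=5)
    forcings = build_forcings(grid, base)
    assert [f.site_id for f in forcings] == grid.site_ids
    # baselines are independent per site
    acc = daily_axis.get_loc(pd.Timestamp(base.accident_date))
    assert not np.array_equal(forcings[0].water_Bq_l[:acc], forcings[1].water_Bq_l[:acc])
    # northern site (38.5 N) carries the delayed second peak
    north, south = forcings[0], forcings[-1]
    peak_n = np.argmax(north.water_Bq_l[acc:])
    peak_s = np.argmax(south.water_Bq_l[acc:])
    assert peak_s == base.rise_d
    tail_n = north.water_Bq_l[acc + 40 : acc + 80] / north.water_Bq_l[acc:].max()
    tail_s = south.water_Bq_l[acc + 40 : acc + 80] / south.water_Bq_l[acc:].max()
    assert tail_n.max() > tail_s.max()
    assert peak_n == base.rise_d or peak_n >= 40  # either main or secondary peak


def test_forcing_series_validates_axis(daily_axis):
    n = len(daily_axis)
    with pytest.raises(ValueError, match="match the date axis"):
        ForcingSeries("S1", daily_axis, np.zeros(n - 1), np.zeros(n))
    gappy = daily_axis[::2]
    with pytest.raises(ValueError, match="daily"):
        ForcingSeries("S1", gappy, np.zeros(len(gappy)), np.zeros(len(gappy)))
    with pytest.raises(ValueError, match=">= 0"):
        ForcingSeries("S1", daily_axis, np.full(n, -1.0), np.zeros(n))
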