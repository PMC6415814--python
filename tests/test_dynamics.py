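"""Biokinetic balance: oracles, engine behaviour, units."""

import numpy as np
import pandas as pd
import pytest

from pelagics.dynamics import (
    ContaminantParams,
    PlanktonConfig,
    build_cohorts,
    elimination_rate,
    plankton_activity,
    simulate,
    simulate_site,
    steady_state_activity,
    step_activity,
)
from pelagics.scenarios import ForcingSeries


@pytest.fixture()
def cp():
    return ContaminantParams()


def test_elimination_worked_value(cp):
    # 35.5 g fish at 15 degC
    lam = elimination_rate(35.5, 288.15, cp)
    assert lam == pytest.approx(5.32e-3, rel=1e-2)


def test_elimination_rejects_celsius(cp):
    with pytest.raises(ValueError, match="kelvin"):
        elimination_rate(35.5, 15.0, cp)


def test_elimination_monotonicity_grid(cp):
    W = np.geomspace(0.5, 2e5, 25)
    T = np.linspace(275.15, 303.15, 25)
    lam_w = elimination_rate(W, 290.0, cp)
    assert np.all(np.diff(lam_w) < 0)  # decreasing in weight
    lam_t = elimination_rate(100.0, T, cp)
    assert np.all(np.diff(lam_t) > 0)  # increasing in temperature


def test_physical_decay_rate(cp):
    assert cp.lambda_R == pytest.approx(np.log(2) / (30.07 * 365.25), rel=1e-12)


def test_plankton_activity_fixed_ratio(cp):
    assert plankton_activity(40.0, 2e-3) == pytest.approx(8e-5, rel=1e-12)
    with pytest.raises(ValueError):
        plankton_activity(-1.0, 2e-3)


def test_euler_matches_analytic_decay(cp):
    """Pure first-order decay at dt = 1 d stays within 1% of the exact
    exponential over five half-lives."""
    lam = 5e-3  # d^-1, a typical biological elimination rate
    conc = 1.0
    n = int(np.ceil(5 * np.log(2) / lam))  # five half-lives
    for _ in range(n):
        conc = step_activity(
            conc, 0.0, [1.0], [0.0], 0.0, 1.0, 0.0, lam - cp.lambda_R, cp
        )
    exact = np.exp(-lam * n)
    assert conc == pytest.approx(exact, rel=0.01)


def test_euler_fixed_point_is_steady_state(cp):
    """Feeding the analytic equilibrium back through one Euler step
    reproduces it exactly: the discrete and continuous fixed points
    coincide for this linear balance."""
    kwargs = dict(
        water_Bq_per_l=2e-3, diet_row=[0.7, 0.3], prey_concs=[8e-5, 6e-5],
        ration_g=0.5, weight_g=20.0, g_spec=3e-4, lambda_bio=5e-3, cp=cp,
    )
    ss = steady_state_activity(**kwargs)
    stepped = step_activity(ss, **kwargs)
    assert stepped == pytest.approx(ss, rel=1e-14)


def test_steady_state_worked_cf(cp):
    """Water-only pathway: CF = 1000 mu / lambda_tot ~ 96 l kg^-1 for a
    35.5 g fish at 15 degC."""
    lam = elimination_rate(35.5, 288.15, cp)
    ss = steady_state_activity(2e-3, [0.0], [0.0], 0.3, 35.5, 2e-3, lam, cp)
    cf = ss * 1000.0 / 2e-3
    assert cf == pytest.approx(1000 * cp.mu / (lam + cp.lambda_R + 2e-3), rel=1e-12)
    assert cf == pytest.approx(96, rel=0.05)


def test_step_rejects_negative_concentration(cp):
    with pytest.raises(ValueError):
        step_activity(-1.0, 2e-3, [1.0], [0.0], 0.1, 1.0, 0.0, 5e-3, cp)


def test_substepping_keeps_stiff_decay_stable(cp):
    # lambda * dt = 5 would explode in a single explicit step
    conc = step_activity(1.0, 0.0, [1.0], [0.0], 0.0, 1.0, 0.0, 5.0, cp)
    assert 0.0 <= conc < 0.1  # decays, never oscillates negative


def test_plankton_bins_log_spaced():
    pk = PlanktonConfig()
    phyto, zoo = pk.lengths()
    assert len(phyto) == len(zoo) == 4
    assert np.all(np.diff(zoo) > 0)
    ratios = zoo[1:] / zoo[:-1]
    assert np.allclose(ratios, ratios[0])  # geometric spacing
    lo, hi = pk.zoo_range_cm
    assert lo < zoo[0] < zoo[-1] < hi
    single = PlanktonConfig(n_bins=1)
    p1, z1 = single.lengths()
    assert z1.tolist() == [single.zoo_length_cm]


def test_build_cohorts_one_per_species_year(species, daily_axis):
    cohorts = build_cohorts(species, daily_axis, seed=1)
    counts = cohorts.meta.groupby("species_id").size()
    # every species gets (almost) one cohort per calendar year; late
    # spawners of the final partial year may fall beyond the axis
    assert counts.min() >= 11 and counts.max() <= 12
    again = build_cohorts(species, daily_axis, seed=1)
    pd.testing.assert_frame_equal(cohorts.meta, again.meta)
    other = build_cohorts(species, daily_axis, seed=2)
    assert not cohorts.meta.spawn_date.equals(other.meta.spawn_date)


def _small_setup(species, n_days=400, water_level=2e-3):
    keep = {k: species[k] for k in ["anchovy", "sardine", "chub_mackerel"]}
    dates = pd.date_range("2002-01-01", periods=n_days, freq="D")
    temp = np.full(n_days, 15.0)
    water = np.full(n_days, water_level)
    cohorts = build_cohorts(keep, dates, seed=4)
    return ForcingSeries("S1", dates, water, temp), cohorts


def test_simulate_newborns_start_clean(species):
    forcing, cohorts = _small_setup(species)
    res = simulate_site(forcing, cohorts)
    for j, row in cohorts.meta.iterrows():
        first = np.where(cohorts.alive[:, j])[0]
        if len(first) == 0:
            continue
        d0 = first[0]
        assert res.conc[0, d0, j] == 0.0
        if d0 > 0:
            assert np.all(np.isnan(res.conc[0, :d0, j]))


def test_simulate_concentrations_rise_towards_uptake(species):
    forcing, cohorts = _small_setup(species)
    res = simulate_site(forcing, cohorts)
    j = cohorts.meta.index[cohorts.meta.species_id == "anchovy"][0]
    m = cohorts.alive[:, j]
    conc = res.conc[0, m, j]
    assert conc[0] == 0.0
    assert np.all(conc >= 0)
    assert conc[-1] > 0
    # the early approach towards equilibrium is strictly accumulating
    assert np.all(np.diff(conc[:30]) > 0)


def test_simulate_site_equals_multisite(species):
    forcing, cohorts = _small_setup(species)
    a = simulate_site(forcing, cohorts)
    b = simulate([forcing, forcing], cohorts)
    # the multi-site matmul may use a different BLAS kernel, so agreement
    # is to rounding, not bitwise
    np.testing.assert_allclose(a.conc[0], b.conc[0], rtol=1e-12)
    np.testing.assert_allclose(b.conc[0], b.conc[1], rtol=1e-12)


def test_simulate_reporting_unit_conversion(species):
    forcing, cohorts = _small_setup(species)
    res = simulate_site(forcing, cohorts)
    row = cohorts.meta.iloc[0]
    ats = res.series("S1", row.species_id, row.cohort_year)
    frame = res.to_frame()
    sub = frame[
        (frame.species_id == row.species_id) & (frame.cohort_year == row.cohort_year)
    ]
    j = row.name
    m = ~np.isnan(res.conc[0, :, j])
    np.testing.assert_allclose(
        sub.conc_Bq_kg_wet.to_numpy(), res.conc[0, m, j] * 1000.0
    )
    assert np.nanmax(np.abs(ats.conc_Bq_per_kg_wet[m] - res.conc[0, m, j] * 1000.0)) == 0


def test_simulate_forcing_axis_mismatch(species):
    forcing, cohorts = _small_setup(species)
    short = ForcingSeries(
        "S1", forcing.dates[:-1], forcing.water_Bq_l[:-1], forcing.temp_C[:-1]
    )
    with pytest.raises(ValueError, match="date axis"):
        simulate([short], cohorts)


def test_simulate_zero_water_stays_clean(species):
    forcing, cohorts = _small_setup(species, water_level=0.0)
    res = simulate_site(forcing, cohorts)
    assert np.nanmax(res.conc) == 0.0
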