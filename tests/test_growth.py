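"""Growth curves, energy budget and the daily-ration band."""

import numpy as np
import pandas as pd
import pytest

from pelagics.growth import (
    DAYS_PER_YEAR,
    AlignmentError,
    build_cohort_trajectory,
    daily_ration,
    growth_rates,
    length_to_weight,
    respiration_rate,
    vbgm_length,
)
from pelagics.scenarios import ScenarioSpec, temperature_series
from pelagics.species import SpeciesParams


@pytest.fixture()
def ref():
    return SpeciesParams(
        species_id="ref", L_inf=40.0, k_vb=0.4, a0=-0.2, q=0.01, b_lw=3.0,
        a_R=0.0142, b_R=0.8, d_r=2.0, phi=1.0, Q10=2.0,
        gamma=0.15, delta=0.16, beta=0.08, CAL_f=5500.0,
        spawn_peak=100, spawn_sd=15.0, longevity=10.0,
    )


def test_length_zero_at_a0():
    sp = SpeciesParams(
        species_id="pos_a0", L_inf=40.0, k_vb=0.4, a0=0.3, q=0.01, b_lw=3.0,
        a_R=0.05, b_R=0.8, d_r=2.0, phi=1.0, Q10=2.0,
        gamma=0.15, delta=0.16, beta=0.08, CAL_f=5500.0,
        spawn_peak=100, spawn_sd=15.0, longevity=8.0,
    )
    assert vbgm_length(sp.a0, sp) == 0.0
    assert vbgm_length(0.1, sp) == 0.0  # clamped before a0


def test_length_approaches_asymptote(ref):
    age = ref.a0 + 30.0 / ref.k_vb
    assert vbgm_length(age, ref) == pytest.approx(ref.L_inf, rel=1e-6)


def test_length_worked_value(ref):
    assert vbgm_length(1.0, ref) == pytest.approx(15.2487, abs=1e-3)


def test_weight_worked_value(ref):
    L = vbgm_length(1.0, ref)
    assert length_to_weight(L, ref) == pytest.approx(35.456, abs=1e-2)


def test_growth_rate_analytic_worked_value(ref):
    G, g = growth_rates(1.0, ref)
    assert G == pytest.approx(0.189, rel=1e-2)
    assert g == pytest.approx(5.3e-3, rel=1e-2)


def test_growth_rate_matches_finite_difference(ref):
    ages = np.linspace(0.2, 9.0, 40)
    G, _ = growth_rates(ages, ref)
    da = 1.0 / DAYS_PER_YEAR
    W_hi = length_to_weight(vbgm_length(ages + da / 2, ref), ref)
    W_lo = length_to_weight(vbgm_length(ages - da / 2, ref), ref)
    fd = (W_hi - W_lo)  # central difference over 1 day
    assert np.allclose(G, fd, rtol=1e-4)


def test_length_and_mass_monotone(ref):
    ages = np.linspace(0.0, 9.0, 200)
    L = vbgm_length(ages, ref)
    assert np.all(np.diff(L) > 0)
    G, _ = growth_rates(ages, ref)
    assert np.all(G > 0)
    # growth vanishes towards the asymptote
    G_old, _ = growth_rates(ref.a0 + 40.0 / ref.k_vb, ref)
    assert G_old < 1e-4 * G.max()


def test_respiration_worked_value(ref):
    L = vbgm_length(1.0, ref)
    W = length_to_weight(L, ref)
    R = respiration_rate(W, L, 15.0, ref)
    assert R == pytest.approx(0.056, rel=1e-2)


def test_respiration_neutral_factors(ref):
    import dataclasses

    neutral = dataclasses.replace(ref, Q10=1.0, d_r=0.0)
    W = 20.0
    R = respiration_rate(W, 10.0, 25.0, neutral)
    conv = (434.0 / 32.0) * (1.0 / neutral.CAL_f) * 24.0
    assert R == pytest.approx(neutral.a_R * W**neutral.b_R * conv, rel=1e-12)


def test_daily_ration_closes_energy_budget(ref):
    C = daily_ration(0.056, 0.189, ref)
    assert C == pytest.approx((0.056 + 0.189) / (1.0 - ref.eta), rel=1e-12)


def test_ration_rejects_negative_inputs(ref):
    with pytest.raises(ValueError):
        daily_ration(-0.1, 0.1, ref)


def test_trajectory_weight_length_consistent(ref, daily_axis):
    temp = np.full(len(daily_axis), 15.0)
    traj = build_cohort_trajectory(ref, "2004-04-10", daily_axis, temp)
    assert np.allclose(traj.weight_g, ref.q * traj.length_cm**ref.b_lw)
    assert traj.dates[0] == pd.Timestamp("2004-04-10")
    # bounded by longevity
    assert len(traj) <= ref.longevity * DAYS_PER_YEAR + 1


def test_trajectory_spawn_beyond_axis_is_empty(ref, daily_axis):
    temp = np.full(len(daily_axis), 15.0)
    traj = build_cohort_trajectory(ref, "2014-01-01", daily_axis, temp)
    assert len(traj) == 0


def test_trajectory_temperature_misalignment_raises(ref, daily_axis):
    with pytest.raises(AlignmentError):
        build_cohort_trajectory(ref, "2004-04-10", daily_axis, np.zeros(10))


def test_positive_a0_cohort_starts_feeding_late(daily_axis):
    sp = SpeciesParams(
        species_id="pos_a0", L_inf=40.0, k_vb=0.4, a0=0.2, q=0.01, b_lw=3.0,
        a_R=0.05, b_R=0.8, d_r=2.0, phi=1.0, Q10=2.0,
        gamma=0.15, delta=0.16, beta=0.08, CAL_f=5500.0,
        spawn_peak=100, spawn_sd=15.0, longevity=8.0,
    )
    temp = np.full(len(daily_axis), 15.0)
    with pytest.warns(UserWarning, match="zero weight"):
        traj = build_cohort_trajectory(sp, "2004-04-10", daily_axis, temp)
    zero_days = traj.weight_g == 0
    assert zero_days.any() and not zero_days.all()
    assert np.all(traj.ration_g[zero_days] == 0)
    assert np.all(traj.ration_g[~zero_days] > 0)


def test_daily_ration_band_full_community(species):
    """Module invariant: daily rations within 0.5-8 %BW d^-1 for every
    cohort of the shipped table under the seasonal 10-25 degC cycle,
    with species medians inside the 1-6 %BW band."""
    spec = ScenarioSpec()
    dates = spec.date_axis()
    temp = temperature_series(dates, spec)
    medians = {}
    for sid, sp in species.items():
        spawn = pd.Timestamp("2002-01-01") + pd.Timedelta(days=sp.spawn_peak - 1)
        traj = build_cohort_trajectory(sp, spawn, dates, temp)
        m = traj.weight_g > 0
        pct = 100.0 * traj.ration_g[m] / traj.weight_g[m]
        assert pct.min() >= 0.5, f"{sid}: daily ration {pct.min():.2f} %BW < 0.5"
        assert pct.max() <= 8.0, f"{sid}: daily ration {pct.max():.2f} %BW > 8"
        medians[sid] = np.median(pct)
    for sid, med in medians.items():
        assert 1.0 <= med <= 6.0, f"{sid}: median ration {med:.2f} %BW outside 1-6"
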