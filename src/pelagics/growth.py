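"""Cohort growth and the bioenergetics energy budget.

Length follows the Von-Bertalanffy growth model (VBGM)

    L(a) = L_inf * (1 - exp(-k * (a - a0)))

and weight the length-weight power law ``W = q * L**b``.  The daily
food ration closes a balance in which consumption covers metabolism,
wastes and somatic growth:

    C = (R + G) / (1 - eta),     eta = (gamma + beta) * (1 - delta) + delta

where R is respiration converted to a wet-mass food equivalent, G the
mass growth rate, and gamma/delta/beta the specific-dynamic-action,
egestion and excretion fractions.

Respiration is a standard metabolic rate with an activity multiplier
and an exponential (Q10) temperature response:

    R = a_R * W**b_R * exp(d_r * phi * L_m) * conv * exp(ln(Q10)/10 * T)

with ``L_m`` the length in metres (the only place lengths leave cm)
and ``conv = (434/32) * (1/CAL_f) * 24`` converting mg O2 h^-1 to
g(food) d^-1 through the oxycalorific coefficient and the fish energy
density.

The mass growth rate is evaluated analytically from the VBGM and the
length-weight chain rule (rather than by a one-day finite difference,
which is kept as a test oracle):

    dW/da = q * b * L**(b-1) * k * (L_inf - L)

converted from yr^-1 to d^-1 with 365.25 d/yr.  The specific growth
rate ``g = (dW/dt)/W`` (d^-1) is the growth-dilution rate used by the
biokinetic balance; the same symbol is used for both quantities in
parts of the literature, so both are returned explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .species import ParameterError, SpeciesParams

__all__ = [
    "DAYS_PER_YEAR",
    "MIN_TEMP_C",
    "CohortTrajectory",
    "vbgm_length",
    "length_to_weight",
    "growth_rates",
    "respiration_rate",
    "daily_ration",
    "build_cohort_trajectory",
]

DAYS_PER_YEAR = 365.25
#: Respiration temperatures are clamped below at the freezing point of seawater.
MIN_TEMP_C = -2.0
#: Oxycalorific conversion, J per mg O2 (13.56 J/mg = 434/32).
_JOULE_PER_MG_O2 = 434.0 / 32.0


class AlignmentError(ValueError):
    """Date axes of two inputs do not line up."""


def vbgm_length(age_yr, params: SpeciesParams):
    """Von-Bertalanffy length (cm) at ``age_yr`` years.

    Negative values of the raw curve (possible only when ``a0 > 0``)
    are clamped to zero: the fish has no length before its hypothetical
    age at length zero.
    """
    age = np.asarray(age_yr, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_yr must be >= 0")
    L = params.L_inf * (1.0 - np.exp(-params.k_vb * (age - params.a0)))
    return np.maximum(L, 0.0)


def length_to_weight(length_cm, params: SpeciesParams):
    """Wet weight (g) from length (cm) via ``W = q * L**b_lw``."""
    L = np.asarray(length_cm, dtype=float)
    if np.any(L < 0):
        raise ValueError("length_cm must be >= 0")
    return params.q * L ** params.b_lw


def growth_rates(age_yr, params: SpeciesParams):
    """Mass growth rate and specific growth rate at ``age_yr``.

    Returns
    -------
    G_mass : ndarray or float
        dW/dt in g d^-1, from the analytic VBGM/length-weight chain rule.
    g_spec : ndarray or float
        Specific (growth-dilution) rate G_mass/W in d^-1; reported as 0
        where W = 0 (with a warning), which happens only when ``a0 > 0``.
    """
    age = np.asarray(age_yr, dtype=float)
    L = vbgm_length(age, params)
    W = length_to_weight(L, params)
    dL_da = params.k_vb * (params.L_inf - L)  # cm yr^-1, valid where L>0
    G_mass = params.q * params.b_lw * L ** (params.b_lw - 1.0) * dL_da / DAYS_PER_YEAR
    G_mass = np.where(L > 0, G_mass, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_spec = np.where(W > 0, G_mass / np.where(W > 0, W, 1.0), 0.0)
    if np.any(W == 0):
        warnings.warn("zero weight encountered; g_spec reported as 0", stacklevel=2)
    if np.isscalar(age_yr):
        return float(G_mass), float(g_spec)
    return G_mass, g_spec


def respiration_rate(weight_g, length_cm, temp_C, params: SpeciesParams):
    """Respiration in wet-food-mass equivalents (g d^-1).

    Chain of factors: standard metabolic rate ``a_R * W**b_R``
    (mg O2 h^-1), swimming-activity multiplier ``exp(d_r * phi * L_m)``,
    unit conversion through the oxycalorific coefficient and energy
    density, and the Q10 temperature response referenced to 0 degC.
    """
    if params.CAL_f <= 0:
        raise ParameterError("CAL_f must be positive")
    W = np.asarray(weight_g, dtype=float)
    L = np.asarray(length_cm, dtype=float)
    if np.any(W <= 0) or np.any(L <= 0):
        raise ValueError("weight_g and length_cm must be positive")
    T = np.maximum(np.asarray(temp_C, dtype=float), MIN_TEMP_C)
    smr = params.a_R * W ** params.b_R
    activity = np.exp(params.d_r * params.phi * (L / 100.0))
    conv = _JOULE_PER_MG_O2 * (1.0 / params.CAL_f) * 24.0
    c_R = np.log(params.Q10) / 10.0
    f_T = np.exp(c_R * T)
    R = smr * activity * conv * f_T
    return float(R) if np.isscalar(weight_g) and np.isscalar(temp_C) else R


def daily_ration(R, G_mass, params: SpeciesParams):
    """Daily food ration C = (R + G) / (1 - eta), in g d^-1."""
    if params.eta >= 1.0:
        raise ParameterError("eta >= 1: the energy budget cannot balance")
    R = np.asarray(R, dtype=float)
    G = np.asarray(G_mass, dtype=float)
    if np.any(R < 0) or np.any(G < 0):
        raise ValueError("R and G_mass must be >= 0")
    C = (R + G) / (1.0 - params.eta)
    return float(C) if C.ndim == 0 else C


@dataclass
class CohortTrajectory:
    """Daily growth and ration series for one species cohort.

    All arrays share the ``dates`` axis, which runs from the spawn
    date to the earlier of the simulation end and the spawn date plus
    the species longevity.  Weight satisfies ``W = q * L**b_lw``
    exactly at every date by construction.
    """

    species_id: str
    cohort_year: int
    spawn_date: pd.Timestamp
    dates: pd.DatetimeIndex
    age_yr: np.ndarray
    length_cm: np.ndarray
    weight_g: np.ndarray
    G_mass: np.ndarray
    g_spec: np.ndarray
    ration_g: np.ndarray

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_yr": self.age_yr,
                "length_cm": self.length_cm,
                "weight_g": self.weight_g,
                "G_mass_g_d": self.G_mass,
                "g_spec_d": self.g_spec,
                "ration_g_d": self.ration_g,
            },
            index=self.dates,
        )


def build_cohort_trajectory(
    params: SpeciesParams,
    spawn_date,
    date_axis: pd.DatetimeIndex,
    temp_series,
    cohort_year: int | None = None,
) -> CohortTrajectory:
    """Assemble the daily growth/ration series for one cohort.

    ``temp_series`` must be aligned with ``date_axis`` (same length, or
    a pandas Series on the same index).  Days before the spawn date are
    not represented; a spawn date beyond the axis yields an empty
    trajectory.
    """
    spawn = pd.Timestamp(spawn_date)
    if not isinstance(date_axis, pd.DatetimeIndex):
        date_axis = pd.DatetimeIndex(date_axis)
    if isinstance(temp_series, pd.Series):
        if len(temp_series) != len(date_axis) or not temp_series.index.equals(date_axis):
            raise AlignmentError("temperature series index does not match date_axis")
        temp = temp_series.to_numpy(dtype=float)
    else:
        temp = np.asarray(temp_series, dtype=float)
        if temp.shape != (len(date_axis),):
            raise AlignmentError("temperature series length does not match date_axis")

    max_age_days = params.longevity * DAYS_PER_YEAR
    offsets = (date_axis - spawn).days.to_numpy()
    live = (offsets >= 0) & (offsets < max_age_days)
    dates = date_axis[live]
    if cohort_year is None:
        cohort_year = spawn.year
    if len(dates) == 0:
        empty = np.empty(0)
        return CohortTrajectory(
            params.species_id, cohort_year, spawn, dates,
            empty, empty, empty, empty, empty, empty,
        )

    age = offsets[live] / DAYS_PER_YEAR
    L = vbgm_length(age, params)
    W = length_to_weight(L, params)
    G_mass, g_spec = growth_rates(age, params)
    ration = np.zeros_like(W)
    feeding = W > 0
    if np.any(feeding):
        R = respiration_rate(W[feeding], L[feeding], temp[live][feeding], params)
        ration[feeding] = daily_ration(R, G_mass[feeding], params)
    return CohortTrajectory(
        params.species_id, cohort_year, spawn, dates,
        age, L, W, G_mass, g_spec, ration,
    )
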