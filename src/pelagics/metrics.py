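"""Radioecological metrics of contamination curves.

After an accidental release the activity concentration curve of an
organism has an accumulation phase and an elimination phase separated
by the time of the peak:

* ``C_max`` - the maximum activity concentration (Bq kg^-1 wet);
* ``T_max`` - days from the accident to that maximum;
* the ecological half-life ``E = ln 2 / lambda_fit``, with
  ``lambda_fit`` from a one-term exponential (log-linear least
  squares) fit of the elimination phase - it integrates biology and
  the decline of the environment, and is scale-invariant;
* the pre-accident concentration factor ``CF = conc / water``
  (l kg^-1), averaged over a pre-accident window;
* the end/pre-accident activity ratio and the time, in years, still
  needed to return to pre-accident levels, extrapolated with the
  ecological half-life as ``t_return = E * log2(ratio)``.

``trend_fits`` reproduces the cross-species regressions of peak
activity (linear in log10 weight and in trophic level) and of
``T_max`` (one-term exponential in both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContaminationMetrics",
    "peak_metrics",
    "ecological_halflife",
    "concentration_factor",
    "recovery_metrics",
    "trend_fits",
    "metrics_table",
    "species_summary",
]

DAYS_PER_YEAR = 365.25


@dataclass
class ContaminationMetrics:
    """Derived metrics of one cohort's contamination curve at one site."""

    site_id: str
    species_id: str
    cohort_year: int
    C_max: float                 # Bq kg^-1 wet
    T_max_d: float               # days from the accident date
    E_d: float                   # ecological half-life (days), NaN if no fit
    fit_r2: float
    CF_pre: float                # l kg^-1
    end_pre_ratio: float
    t_return_yr: float
    peak_resolved: bool = True

    def as_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "species_id": self.species_id,
            "cohort_year": self.cohort_year,
            "C_max_Bq_kg": self.C_max,
            "T_max_d": self.T_max_d,
            "E_d": self.E_d,
            "fit_r2": self.fit_r2,
            "CF_pre_l_kg": self.CF_pre,
            "end_pre_ratio": self.end_pre_ratio,
            "t_return_yr": self.t_return_yr,
            "peak_resolved": self.peak_resolved,
        }


def _as_series(curve) -> pd.Series:
    if isinstance(curve, pd.Series):
        return curve.dropna()
    raise TypeError("curve must be a pandas Series indexed by date")


def peak_metrics(curve: pd.Series, accident_date) -> tuple[float, float, bool]:
    """Global post-accident maximum and its delay.

    Returns ``(C_max, T_max_d, resolved)``; ties are broken by the
    earliest date, and ``resolved`` is False when the maximum sits on
    the final sample (the peak may lie beyond the series).
    """
    s = _as_series(curve)
    accident = pd.Timestamp(accident_date)
    post = s[s.index >= accident]
    if len(post) == 0:
        raise ValueError("curve does not cover the accident date")
    cmax = float(post.max())
    t_peak = post.index[np.argmax(post.to_numpy())]  # argmax -> earliest tie
    tmax_d = float((t_peak - accident).days)
    resolved = t_peak != post.index[-1]
    return cmax, tmax_d, resolved


def ecological_halflife(
    curve: pd.Series,
    t_max,
    end=None,
    min_samples: int = 30,
) -> tuple[float, float]:
    """One-term exponential fit of the elimination phase.

    Log-linear least squares of ``ln(conc)`` against time (days) on
    ``[t_max, end]``; the ecological half-life is ``ln 2`` over the
    fitted decline rate.  Returns ``(E_d, r2)``; ``E_d`` is NaN (with
    r2 of the fit) when the fitted slope is non-negative
    ("no-decline").
    """
    s = _as_series(curve)
    start = pd.Timestamp(t_max)
    window = s[s.index >= start]
    if end is not None:
        window = window[window.index <= pd.Timestamp(end)]
    if len(window) < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples after T_max, got {len(window)}"
        )
    if np.any(window.to_numpy() <= 0):
        raise ValueError("elimination-phase fit requires positive concentrations")
    t = (window.index - start).days.to_numpy().astype(float)
    y = np.log(window.to_numpy())
    fit = stats.linregress(t, y)
    r2 = float(fit.rvalue**2)
    if fit.slope >= 0:
        return float("nan"), r2
    return float(np.log(2.0) / -fit.slope), r2


def concentration_factor(fish_conc_Bq_kg, water_Bq_l) -> float:
    """CF (l kg^-1): organism activity over water activity.

    Scalar inputs give the instantaneous ratio; series inputs are
    averaged (organism mean over water mean) across the window they
    cover, which is how the pre-accident steady-state CF is reported.
    """
    conc = np.asarray(
        fish_conc_Bq_kg.to_numpy() if isinstance(fish_conc_Bq_kg, pd.Series) else fish_conc_Bq_kg,
        dtype=float,
    )
    water = np.asarray(
        water_Bq_l.to_numpy() if isinstance(water_Bq_l, pd.Series) else water_Bq_l,
        dtype=float,
    )
    wmean = float(np.mean(water))
    if wmean <= 0:
        raise ValueError("water activity must be positive")
    return float(np.mean(conc) / wmean)


def recovery_metrics(
    curve: pd.Series,
    accident_date,
    end_date,
    E_d: float,
    pre_reference=None,
) -> tuple[float, float]:
    """End/pre-accident ratio and years still needed to reach baseline.

    The pre-accident reference concentration is read on
    ``accident_date - 11 days`` (the same calendar day, two years
    before the end of the standard run) unless ``pre_reference`` is
    given.  The return time extrapolates the remaining decline with
    the ecological half-life, ``t = E * log2(ratio)``, clamped at zero
    when the organism is already at or below baseline; it is reported
    relative to ``end_date``.
    """
    s = _as_series(curve)
    accident = pd.Timestamp(accident_date)
    end = pd.Timestamp(end_date)
    ref_date = pd.Timestamp(pre_reference) if pre_reference is not None else accident - pd.Timedelta(days=11)
    for d in (ref_date, end):
        if d not in s.index:
            raise ValueError(f"curve does not contain {d.date()}")
    base = float(s.loc[ref_date])
    if base <= 0:
        raise ValueError("pre-accident baseline concentration is zero")
    ratio = float(s.loc[end]) / base
    if ratio <= 1.0 or not np.isfinite(E_d):
        t_return = 0.0
    else:
        t_return = E_d * np.log2(ratio) / DAYS_PER_YEAR
    return ratio, float(t_return)


def metrics_table(
    result,
    accident_date,
    end_date=None,
    pre_window=("2010-03-01", "2011-02-28"),
) -> pd.DataFrame:
    """One metrics row per site x species x cohort of a simulation result.

    Cohorts born after the accident, or with too short an elimination
    phase to fit, carry NaN in the affected columns.
    """
    accident = pd.Timestamp(accident_date)
    end = pd.Timestamp(end_date) if end_date is not None else result.dates[-1]
    lo, hi = (pd.Timestamp(d) for d in pre_window)
    rows = []
    for s, site in enumerate(result.site_ids):
        forcing = result.forcings.get(site)
        water = (
            pd.Series(forcing.water_Bq_l, index=forcing.dates)
            if forcing is not None
            else None
        )
        for j, meta in result.meta.iterrows():
            conc = result.conc[s, :, j] * 1000.0
            curve = pd.Series(conc, index=result.dates).dropna()
            if len(curve) == 0 or curve.index[0] > accident or curve.index[-1] < accident:
                continue
            cmax, tmax_d, resolved = peak_metrics(curve, accident)
            t_peak = accident + pd.Timedelta(days=tmax_d)
            fit_end = min(end, curve.index[-1])
            try:
                E_d, r2 = ecological_halflife(curve, t_peak, fit_end)
            except ValueError:
                E_d, r2 = float("nan"), float("nan")
            cf = float("nan")
            if water is not None:
                m = (curve.index >= lo) & (curve.index <= hi)
                if m.any():
                    cf = concentration_factor(
                        curve[m], water[(water.index >= lo) & (water.index <= hi)]
                    )
            try:
                ratio, t_return = recovery_metrics(curve, accident, end, E_d)
            except ValueError:
                ratio, t_return = float("nan"), float("nan")
            rows.append(
                ContaminationMetrics(
                    site, meta.species_id, int(meta.cohort_year),
                    cmax, tmax_d, E_d, r2, cf, ratio, t_return, resolved,
                ).as_dict()
            )
    return pd.DataFrame(rows)


def species_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Species means (over sites and cohorts) of the metrics table."""
    cols = ["C_max_Bq_kg", "T_max_d", "E_d", "CF_pre_l_kg", "end_pre_ratio", "t_return_yr"]
    return table.groupby("species_id")[cols].mean()


def trend_fits(
    metrics: pd.DataFrame | None = None,
    weights=None,
    TLs=None,
    cmax=None,
    tmax=None,
) -> pd.DataFrame:
    """Cross-species trends of peak activity and peak delay.

    Ordinary least squares of ``C_max`` against log10(weight) and
    against trophic level, and a one-term exponential fit (log-linear
    transform) of ``T_max`` against the same two predictors.  Needs at
    least five species points; returns slope, intercept and R^2 per
    fit.
    """
    if metrics is not None:
        weights = metrics["weight_g"].to_numpy(dtype=float)
        TLs = metrics["TL"].to_numpy(dtype=float)
        cmax = metrics["C_max_Bq_kg"].to_numpy(dtype=float)
        tmax = metrics["T_max_d"].to_numpy(dtype=float)
    weights = np.asarray(weights, dtype=float)
    TLs = np.asarray(TLs, dtype=float)
    cmax = np.asarray(cmax, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if len(weights) < 5:
        raise ValueError("need at least 5 species points")
    logw = np.log10(weights)
    rows = []
    for yname, y, transform in [
        ("C_max", cmax, "linear"),
        ("T_max", tmax, "exponential"),
    ]:
        for xname, x in [("log10_weight", logw), ("TL", TLs)]:
            if np.ptp(x) == 0:
                raise ValueError(f"degenerate predictor {xname}")
            yy = np.log(y) if transform == "exponential" else y
            fit = stats.linregress(x, yy)
            rows.append(
                {
                    "response": yname,
                    "predictor": xname,
                    "model": transform,
                    "slope": float(fit.slope),
                    "intercept": float(fit.intercept),
                    "r2": float(fit.rvalue**2),
                }
            )
    return pd.DataFrame(rows)
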