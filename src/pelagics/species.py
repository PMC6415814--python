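"""Species life-history and bioenergetics parameter sets.

A :class:`SpeciesParams` instance carries everything the growth and
energy-budget routines need for one species: Von-Bertalanffy growth
constants, the length-weight power law, the respiration model
(standard metabolic rate, swimming-activity multiplier, Q10
temperature response), the waste/SDA fractions that close the energy
budget, and the spawning phenology used to seed one cohort per year.

The shipped default table (``data/species_default.csv``) covers the 14
commercially important pelagic species of the north-western Pacific
coastal food web, from Japanese anchovy up to Pacific bluefin tuna.
The numbers are assembled from literature-typical values (FishBase-style
growth and length-weight constants, Wisconsin-model-style metabolic
constants) and are deliberately easy to replace: any CSV with the same
header is accepted by :func:`load_species_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesParams",
    "SPECIES_CSV_COLUMNS",
    "load_species_table",
    "default_species_table",
    "default_species_path",
]

#: Exact header of a species parameter CSV, one row per species.
SPECIES_CSV_COLUMNS = [
    "species_id",
    "L_inf",
    "k_vb",
    "a0",
    "q",
    "b_lw",
    "a_R",
    "b_R",
    "d_r",
    "phi",
    "Q10",
    "gamma",
    "delta",
    "beta",
    "CAL_f",
    "spawn_peak",
    "spawn_sd",
    "longevity",
]


class ParameterError(ValueError):
    """A species or contaminant parameter is outside its valid domain."""


@dataclass(frozen=True)
class SpeciesParams:
    """Life-history and bioenergetics constants for one species.

    Parameters
    ----------
    species_id : str
        Short name, e.g. ``"anchovy"``.
    L_inf : float
        Asymptotic length of the Von-Bertalanffy growth curve (cm).
    k_vb : float
        Von-Bertalanffy growth rate (yr^-1).
    a0 : float
        Hypothetical age at zero length (yr); usually negative.
    q, b_lw : float
        Length-weight power law ``W = q * L**b_lw`` (g, cm). The
        exponent usually lies between 2.7 and 3.4; values outside that
        range trigger a warning but are accepted.
    a_R : float
        Respiration intercept: oxygen consumption of a resting 1 g fish
        at 0 degC (mg O2 h^-1).
    b_R : float
        Allometric mass exponent of standard metabolism.
    d_r : float
        Coefficient relating swimming speed to metabolism (s m^-1).
    phi : float
        Swimming-speed coefficient (s^-1); cruise speed V = phi * L
        with L in metres.
    Q10 : float
        Factor by which respiration increases per 10 degC warming.
    gamma, delta, beta : float
        Specific dynamic action, egestion and excretion fractions of
        the energy budget; each in [0, 1) and jointly constrained so
        that ``eta = (gamma + beta) * (1 - delta) + delta < 1``.
    CAL_f : float
        Fish energy density (J g^-1 wet weight).
    spawn_peak : int
        Calendar day of year of peak spawning.
    spawn_sd : float
        Spread of spawning dates (days).
    longevity : float
        Maximum age (yr); cohorts leave the simulated pool beyond it.
    """

    species_id: str
    L_inf: float
    k_vb: float
    a0: float
    q: float
    b_lw: float
    a_R: float
    b_R: float
    d_r: float
    phi: float
    Q10: float
    gamma: float
    delta: float
    beta: float
    CAL_f: float
    spawn_peak: int
    spawn_sd: float
    longevity: float

    def __post_init__(self) -> None:
        numeric = [
            self.L_inf, self.k_vb, self.a0, self.q, self.b_lw, self.a_R,
            self.b_R, self.d_r, self.phi, self.Q10, self.gamma, self.delta,
            self.beta, self.CAL_f, self.spawn_peak, self.spawn_sd,
            self.longevity,
        ]
        if not np.all(np.isfinite(numeric)):
            raise ParameterError(f"{self.species_id}: non-finite parameter")
        if self.L_inf <= 0 or self.k_vb <= 0 or self.q <= 0:
            raise ParameterError(
                f"{self.species_id}: L_inf, k_vb and q must be positive"
            )
        if not (2.7 <= self.b_lw <= 3.4):
            warnings.warn(
                f"{self.species_id}: length-weight exponent {self.b_lw} is "
                "outside the usual 2.7-3.4 range",
                stacklevel=2,
            )
        for name in ("gamma", "delta", "beta"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{self.species_id}: {name}={v} not in [0, 1)")
        if self.eta >= 1.0:
            raise ParameterError(
                f"{self.species_id}: eta={self.eta:.3f} >= 1; the energy "
                "budget cannot balance"
            )
        if self.CAL_f <= 0:
            raise ParameterError(f"{self.species_id}: CAL_f must be positive")
        if self.Q10 < 1.0:
            raise ParameterError(f"{self.species_id}: Q10 must be >= 1")
        if self.longevity <= 0:
            raise ParameterError(f"{self.species_id}: longevity must be positive")

    @property
    def eta(self) -> float:
        """Total energy-budget loss fraction, (gamma+beta)(1-delta)+delta."""
        return (self.gamma + self.beta) * (1.0 - self.delta) + self.delta


def _table_from_frame(df: pd.DataFrame) -> dict[str, SpeciesParams]:
    missing = [c for c in SPECIES_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"species table is missing columns: {missing}")
    extra = [c for c in df.columns if c not in SPECIES_CSV_COLUMNS]
    if extra:
        raise ParameterError(f"species table has unknown columns: {extra}")
    out: dict[str, SpeciesParams] = {}
    field_names = [f.name for f in fields(SpeciesParams)]
    for _, row in df.iterrows():
        kwargs = {name: row[name] for name in field_names}
        kwargs["species_id"] = str(kwargs["species_id"])
        kwargs["spawn_peak"] = int(kwargs["spawn_peak"])
        sp = SpeciesParams(**kwargs)
        if sp.species_id in out:
            raise ParameterError(f"duplicate species_id {sp.species_id!r}")
        out[sp.species_id] = sp
    return out


def load_species_table(path) -> dict[str, SpeciesParams]:
    """Read a species parameter CSV into a mapping id -> SpeciesParams."""
    return _table_from_frame(pd.read_csv(path))


def default_species_path():
    """Path-like handle on the packaged 14-species default table."""
    return resources.files("pelagics.data").joinpath("species_default.csv")


def default_species_table() -> dict[str, SpeciesParams]:
    """The shipped 14-species north-western Pacific pelagic community."""
    with resources.as_file(default_species_path()) as p:
        return load_species_table(p)


def species_frame(table: Mapping[str, SpeciesParams]) -> pd.DataFrame:
    """Tabular view of a species mapping (column order of the CSV)."""
    rows = [{c: getattr(sp, c) for c in SPECIES_CSV_COLUMNS} for sp in table.values()]
    return pd.DataFrame(rows, columns=SPECIES_CSV_COLUMNS)
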