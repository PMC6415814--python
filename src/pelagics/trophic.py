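"""Opportunistic, size-ratio-based predation: selectivity, diets, trophic levels.

Predation is assumed fully opportunistic: the probability that a
predator of length ``L_pred`` takes a prey of length ``L_prey``
depends only on the ratio ``r = L_pred / L_prey`` through a product of
two sigmoids forming a unimodal window,

    S(r) = 1 / (1 + exp(beta1 * (rho1 - r)))
           * (1 - 1 / (1 + exp(beta2 * (rho2 - r))))

so that predators take prey roughly between ``1/rho2`` and ``1/rho1``
of their own length.  Diet proportions are the row-normalised
selectivities over the site's prey pool (plankton groups plus every
living fish cohort, self-pairing excluded), and trophic levels follow
from the diet matrix by the fixed point

    TL_i = 1 + sum_j alpha_ij * TL_j

anchored by the plankton groups (phytoplankton TL 1, zooplankton TL 2).

The ratio is oriented predator-over-prey: the window ``[rho1, rho2]``
means predators eat smaller prey, consistent with the biology.  The
shipped defaults (rho1=2, beta1=5, rho2=30, beta2=0.5) give a 2-30x
predator/prey length window and are configuration-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectivityParams",
    "PreyItem",
    "DietMatrix",
    "selectivity",
    "selectivity_matrix",
    "build_diet_matrix",
    "trophic_levels",
    "PHYTO_TL",
    "ZOO_TL",
]

PHYTO_TL = 1.0
ZOO_TL = 2.0


class TrophicError(RuntimeError):
    """Trophic-level fixed point failed to converge."""


@dataclass(frozen=True)
class SelectivityParams:
    """Size-ratio window of the selectivity sigmoid product.

    ``rho1``/``beta1`` set the position and steepness of the lower
    (small-ratio) shoulder, ``rho2``/``beta2`` those of the upper
    shoulder.  All four are dimensionless and positive, with
    ``rho1 < rho2``.
    """

    rho1: float = 2.0
    beta1: float = 5.0
    rho2: float = 30.0
    beta2: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.rho1 < self.rho2):
            raise ValueError("need 0 < rho1 < rho2")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("beta1 and beta2 must be positive")


@dataclass(frozen=True)
class PreyItem:
    """One entry of a prey pool: a fish cohort or a plankton group."""

    item_id: str
    length_cm: float
    is_plankton: bool = False
    base_TL: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError("length_cm must be positive")
        if self.is_plankton and self.base_TL is None:
            raise ValueError("plankton items need a fixed base_TL")


def selectivity(pred_length_cm, prey_length_cm, sel: SelectivityParams):
    """Predation probability from the predator/prey length ratio."""
    pred = np.asarray(pred_length_cm, dtype=float)
    prey = np.asarray(prey_length_cm, dtype=float)
    if np.any(pred <= 0) or np.any(prey <= 0):
        raise ValueError("lengths must be positive")
    r = pred / prey
    lower = 1.0 / (1.0 + np.exp(np.minimum(sel.beta1 * (sel.rho1 - r), 700.0)))
    upper = 1.0 - 1.0 / (1.0 + np.exp(np.minimum(sel.beta2 * (sel.rho2 - r), 700.0)))
    S = lower * upper
    return float(S) if S.ndim == 0 else S


def selectivity_matrix(pred_lengths, prey_lengths, sel: SelectivityParams) -> np.ndarray:
    """Selectivity of every predator (rows) on every prey (columns)."""
    pred = np.asarray(pred_lengths, dtype=float)[:, None]
    prey = np.asarray(prey_lengths, dtype=float)[None, :]
    return selectivity(pred, prey, sel)


@dataclass
class DietMatrix:
    """Normalised diet proportions alpha for each predator over a prey pool.

    Rows with at least one admissible prey sum to one; predators with
    no admissible prey get an all-zero row and are listed in
    ``starved``.
    """

    predator_ids: list[str]
    prey: list[PreyItem]
    alpha: np.ndarray
    date: pd.Timestamp | None = None
    starved: list[str] = field(default_factory=list)

    @property
    def prey_ids(self) -> list[str]:
        return [p.item_id for p in self.prey]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alpha, index=self.predator_ids, columns=self.prey_ids)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format diagnostic dump (date, predator, prey, alpha)."""
        df = self.to_frame().stack().rename("alpha").reset_index()
        df.columns = ["predator", "prey", "alpha"]
        df.insert(0, "date", self.date)
        return df


def build_diet_matrix(
    predators: dict[str, float],
    prey_pool: list[PreyItem],
    sel: SelectivityParams,
    date=None,
) -> DietMatrix:
    """Normalise selectivities into diet proportions.

    ``predators`` maps predator id to its length (cm).  A predator
    appearing in the prey pool under the same id is excluded from its
    own diet (a cohort does not prey on itself; other cohorts of the
    same species remain admissible).
    """
    if not prey_pool:
        raise ValueError("empty prey pool")
    pred_ids = list(predators)
    pred_lengths = np.array([predators[i] for i in pred_ids], dtype=float)
    prey_lengths = np.array([p.length_cm for p in prey_pool], dtype=float)
    S = selectivity_matrix(pred_lengths, prey_lengths, sel)
    prey_ids = [p.item_id for p in prey_pool]
    prey_index = {pid: j for j, pid in enumerate(prey_ids)}
    for i, pid in enumerate(pred_ids):
        j = prey_index.get(pid)
        if j is not None:
            S[i, j] = 0.0
    rowsum = S.sum(axis=1)
    starved = [pid for pid, s in zip(pred_ids, rowsum) if s == 0.0]
    if starved:
        warnings.warn(
            f"predators with no admissible prey: {starved}", stacklevel=2
        )
    safe = np.where(rowsum > 0, rowsum, 1.0)
    alpha = S / safe[:, None]
    ts = pd.Timestamp(date) if date is not None else None
    return DietMatrix(pred_ids, list(prey_pool), alpha, ts, starved)


def trophic_levels(
    diet: DietMatrix,
    base_TLs: dict[str, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> pd.Series:
    """Solve TL_i = 1 + sum_j alpha_ij TL_j by fixed-point iteration.

    Plankton groups (and any id listed in ``base_TLs``) keep their
    fixed trophic level; fish levels are iterated from 1 until the
    update falls below ``tol`` (absolute).  Convergence is guaranteed
    when every diet ultimately grounds on the plankton anchors, since
    the fish-fish diet block is then substochastic.
    """
    fixed: dict[str, float] = {}
    for p in diet.prey:
        if p.is_plankton:
            fixed[p.item_id] = float(p.base_TL)
    if base_TLs:
        fixed.update({k: float(v) for k, v in base_TLs.items()})

    prey_tl_fixed = np.array(
        [fixed.get(pid, np.nan) for pid in diet.prey_ids], dtype=float
    )
    is_fixed = ~np.isnan(prey_tl_fixed)
    pred_pos = {pid: i for i, pid in enumerate(diet.predator_ids)}
    # column j of the prey pool -> row index of the same cohort as predator
    prey_to_pred = np.array(
        [pred_pos.get(pid, -1) for pid in diet.prey_ids], dtype=int
    )
    unresolved = (~is_fixed) & (prey_to_pred < 0)
    if np.any(unresolved & (diet.alpha.sum(axis=0) > 0)):
        bad = [diet.prey_ids[j] for j in np.where(unresolved)[0]]
        raise TrophicError(f"prey items with unknown trophic level: {bad}")

    tl = np.ones(len(diet.predator_ids))
    prey_tl = np.where(is_fixed, prey_tl_fixed, 0.0)
    for _ in range(max_iter):
        idx = prey_to_pred >= 0
        prey_tl[idx] = tl[prey_to_pred[idx]]
        new = 1.0 + diet.alpha @ prey_tl
        # predators with an all-zero diet row carry no defined level
        new = np.where(diet.alpha.sum(axis=1) > 0, new, np.nan)
        with np.errstate(invalid="ignore"):
            resid = np.abs(new - tl)
        step = np.nanmax(resid) if not np.all(np.isnan(resid)) else 0.0
        tl = new
        if step < tol:
            break
    else:
        raise TrophicError(
            "trophic-level fixed point did not converge in "
            f"{max_iter} iterations (spectral issue in the diet matrix)"
        )
    return pd.Series(tl, index=diet.predator_ids, name="TL")
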