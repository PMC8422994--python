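"""Bliss-independence null curves for temperature-antibiotic interactions.

Treating temperature and an antibiotic as two stressors acting on growth,
Bliss independence predicts their combined effect to be multiplicative on
the relative-growth scale.  The drug's own effect is measured at a
reference temperature ``T_ref`` (default: the no-drug optimum, where the
unstressed curve is maximal) as the ratio ``r_a = g_a(T_ref)/g_0(T_ref)``,
and the null temperature response under the drug is

    g~_a(T) = g_0(T) * r_a.

Where the fitted drug curve falls below the null the drug and that
temperature interact synergistically (more growth reduction than
predicted); above it, antagonistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .briere import CanonicalBriereParams, canonical_evaluate, optimal_temperature

__all__ = [
    "InteractionProfile",
    "bliss_null_curve",
    "interaction_profile",
    "DegenerateReferenceError",
]


class DegenerateReferenceError(ValueError):
    """Raised when the no-drug curve vanishes at the reference temperature."""


@dataclass(frozen=True)
class InteractionProfile:
    """Per-temperature observed, null, score and label for one drug condition."""

    temperatures: np.ndarray
    observed: np.ndarray
    null: np.ndarray
    score: np.ndarray
    labels: np.ndarray
    t_ref: float
    tol: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_c": self.temperatures,
                "observed": self.observed,
                "null": self.null,
                "score": self.score,
                "label": self.labels,
            }
        )


def bliss_null_curve(
    g0: CanonicalBriereParams,
    ga: CanonicalBriereParams,
    grid,
    t_ref: float | None = None,
):
    """Null growth curve under the drug on ``grid``; returns (null, r_a, t_ref)."""
    if t_ref is None:
        t_ref = optimal_temperature(g0)
    g0_ref = canonical_evaluate(t_ref, g0)
    if g0_ref <= 0:
        raise DegenerateReferenceError(
            f"no-drug curve is zero at reference temperature {t_ref} degC"
        )
    r_a = canonical_evaluate(t_ref, ga) / g0_ref
    grid = np.asarray(grid, dtype=float)
    null = canonical_evaluate(grid, g0) * r_a
    return null, float(r_a), float(t_ref)


def interaction_profile(
    g0: CanonicalBriereParams,
    ga: CanonicalBriereParams,
    grid=None,
    tol: float | None = None,
    t_ref: float | None = None,
    n_grid: int = 101,
    tol_frac: float = 0.05,
) -> InteractionProfile:
    """Score synergy/antagonism of drug-by-temperature across the grid.

    The default grid spans the overlap of the two curves' supports; ``tol``
    defaults to 5% of the unstressed growth at the reference temperature.
    Scores are ``epsilon(T) = g_a(T) - g~_a(T)``: synergy when
    ``epsilon < -tol``, antagonism when ``epsilon > tol``, independent
    otherwise.
    """
    lo = max(g0.t_min, ga.t_min)
    hi = min(g0.t_max, ga.t_max)
    if not lo < hi:
        raise ValueError("curve supports do not overlap")
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    null, r_a, t_ref = bliss_null_curve(g0, ga, grid, t_ref)
    observed = canonical_evaluate(grid, ga)
    if tol is None:
        tol = tol_frac * canonical_evaluate(t_ref, g0)
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    score = observed - null
    labels = np.where(
        score < -tol, "synergy", np.where(score > tol, "antagonism", "independent")
    )
    return InteractionProfile(
        temperatures=grid,
        observed=observed,
        null=null,
        score=score,
        labels=labels,
        t_ref=t_ref,
        tol=float(tol),
    )
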