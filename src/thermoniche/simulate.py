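"""Study-shaped synthetic growth data with known ground truth.

Emulates the plate design of the study this package models: growth of
E. coli read as OD600 at 24 h across 7 incubation temperatures (22, 25, 30,
37, 41, 44, 46 degC), 4 replicates per condition, a no-drug control, up to
12 single antibiotics and drug pairs.  Noise is drawn from the same Gamma
likelihood the fitting module assumes (mean = the true curve, one standard
deviation per temperature), so parameter-recovery tests are well posed.

The unstressed truth is a curve with optimum 37.7 degC, peak growth 0.5
OD units and a half-max thermal niche of ~15 degC, matching the magnitudes
reported for drug-free E. coli.  Single-drug effects are configurable
left/right optimum shifts, breadth narrowing and peak suppression; pair
curves are constructed to realize requested combination categories (optimum
at the min/mean/max of the singles, or displaced beyond both) so every
downstream stage can be scored against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .briere import (
    CanonicalBriereParams,
    canonical_evaluate,
    niche_summary,
    optimal_temperature,
)
from .data import COLUMNS, ConditionLabel, GrowthDataset
from .fitting import MEAN_FLOOR
from .permutation import DriverTable

__all__ = [
    "STUDY_TEMPERATURES_C",
    "DEFAULT_SIGMAS",
    "DEFAULT_DRUG_EFFECTS",
    "DrugEffect",
    "ScenarioSpec",
    "SyntheticDataset",
    "control_curve",
    "curve_with_niche",
    "apply_drug_effect",
    "pair_curve_for_category",
    "generate_condition",
    "generate_combo_study",
    "generate_driver_table_null",
]

#: Incubation temperatures used throughout the study design.
STUDY_TEMPERATURES_C = (22.0, 25.0, 30.0, 37.0, 41.0, 44.0, 46.0)

#: Per-temperature noise standard deviations (OD units). Mid-range
#: temperatures, where growth is strong, show the largest replicate scatter;
#: near the hot limit growth collapses and so does its spread.
DEFAULT_SIGMAS = {
    22.0: 0.040,
    25.0: 0.050,
    30.0: 0.060,
    37.0: 0.060,
    41.0: 0.050,
    44.0: 0.035,
    46.0: 0.015,
}


def curve_with_niche(
    t_opt: float,
    breadth: float,
    g_max: float,
    t_min: float = 10.0,
    t_max: float = 47.0,
) -> CanonicalBriereParams:
    """Canonical parameters hitting a target optimum and half-max breadth.

    ``alpha`` follows from the optimum's position between the growth limits;
    the steepness ``s`` is solved numerically (breadth decreases
    monotonically in ``s``, from ``t_max - t_min`` at s -> 0 toward 0).
    """
    if not t_min < t_opt < t_max:
        raise ValueError("t_opt must lie strictly between t_min and t_max")
    if not 0.0 < breadth < t_max - t_min:
        raise ValueError("breadth must lie in (0, t_max - t_min)")
    alpha = (t_opt - t_min) / (t_max - t_min)

    def breadth_at(s: float) -> float:
        p = CanonicalBriereParams(g_max=g_max, alpha=alpha, s=s, t_min=t_min, t_max=t_max)
        return niche_summary(p).breadth - breadth

    s = brentq(breadth_at, 1e-3, 500.0, xtol=1e-9)
    return CanonicalBriereParams(g_max=g_max, alpha=alpha, s=s, t_min=t_min, t_max=t_max)


def control_curve(
    t_opt: float = 37.7,
    breadth: float = 15.0,
    g_max: float = 0.5,
    t_min: float = 10.0,
    t_max: float = 47.0,
) -> CanonicalBriereParams:
    """Default unstressed truth (optimum 37.7 degC, niche ~15 degC wide)."""
    return curve_with_niche(t_opt, breadth, g_max, t_min, t_max)


@dataclass(frozen=True)
class DrugEffect:
    """How a single drug reshapes the control curve.

    ``d_topt``: optimum shift in degC (negative = left); ``breadth_factor``:
    multiplicative narrowing of the half-max niche; ``g_max_factor``: peak
    growth retained (sublethal dosing leaves 50-90% of unstressed growth).
    """

    d_topt: float = 0.0
    breadth_factor: float = 0.9
    g_max_factor: float = 0.7


#: Default single-drug effects.  Aminoglycosides (GEN, TOB, STR) and other
#: heat-similar drugs shift the optimum left, most strongly for the
#: aminoglycosides; cold-similar drugs (ERY, LVX, CPR, CLI, TET) leave it
#: unchanged or nudge it right.  All narrow the niche somewhat.
DEFAULT_DRUG_EFFECTS = {
    "GEN": DrugEffect(-5.0, 0.80, 0.55),
    "TOB": DrugEffect(-4.5, 0.80, 0.60),
    "STR": DrugEffect(-4.0, 0.85, 0.60),
    "TMP": DrugEffect(-2.5, 0.85, 0.65),
    "NTR": DrugEffect(-2.0, 0.90, 0.70),
    "FOX": DrugEffect(-1.5, 0.90, 0.65),
    "AMP": DrugEffect(-1.0, 0.90, 0.75),
    "CLI": DrugEffect(0.0, 0.90, 0.70),
    "TET": DrugEffect(0.0, 0.85, 0.70),
    "ERY": DrugEffect(0.5, 0.90, 0.75),
    "LVX": DrugEffect(1.0, 0.95, 0.80),
    "CPR": DrugEffect(1.0, 0.95, 0.80),
}

PAIR_CATEGORIES = ("min", "max", "mean", "attenuated", "elevated")


def apply_drug_effect(
    base: CanonicalBriereParams, effect: DrugEffect
) -> CanonicalBriereParams:
    """Reshape the control curve by a drug's shift/narrowing/suppression."""
    niche = niche_summary(base)
    return curve_with_niche(
        t_opt=niche.t_opt + effect.d_topt,
        breadth=niche.breadth * effect.breadth_factor,
        g_max=base.g_max * effect.g_max_factor,
        t_min=base.t_min,
        t_max=base.t_max,
    )


def pair_curve_for_category(
    px: CanonicalBriereParams,
    py: CanonicalBriereParams,
    category: str,
    displacement: float = 3.0,
    margin: float = 1.0,
) -> CanonicalBriereParams:
    """Construct a pair curve whose optimum realizes the requested category.

    The optimum sits at the min/mean/max of the two single-drug optima, or
    ``displacement`` degC beyond the min (attenuated) / max (elevated).  The
    pair's niche takes the narrower single's breadth slightly reduced, and
    its peak the product of the singles' relative peaks (multiplicative
    suppression).  Requests that would push the optimum within ``margin``
    degC of a growth limit raise a ValueError.
    """
    if category not in PAIR_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    tx, ty = optimal_temperature(px), optimal_temperature(py)
    targets = {
        "min": min(tx, ty),
        "max": max(tx, ty),
        "mean": 0.5 * (tx + ty),
        "attenuated": min(tx, ty) - displacement,
        "elevated": max(tx, ty) + displacement,
    }
    t_opt = targets[category]
    t_min = max(px.t_min, py.t_min)
    t_max = min(px.t_max, py.t_max)
    if not t_min + margin < t_opt < t_max - margin:
        raise ValueError(
            f"category {category!r} would place the optimum at {t_opt:.2f} degC, "
            f"outside the feasible range ({t_min + margin:.2f}, {t_max - margin:.2f})"
        )
    bx = niche_summary(px).breadth
    by = niche_summary(py).breadth
    breadth = 0.95 * min(bx, by)
    g_max = px.g_max * py.g_max / max(px.g_max, py.g_max, 1e-12) * 0.9
    # clip breadth so the half-max niche fits the support around the optimum
    breadth = min(breadth, 1.8 * min(t_opt - t_min, t_max - t_opt))
    return curve_with_niche(t_opt, breadth, g_max, t_min, t_max)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to simulate one study: truth curves, design, noise."""

    conditions: dict
    temperatures: tuple = STUDY_TEMPERATURES_C
    n_replicates: int = 4
    sigmas: dict | None = None
    noise_hyperscale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigmas is None and self.noise_hyperscale is None:
            object.__setattr__(self, "sigmas", dict(DEFAULT_SIGMAS))

    def resolve_sigmas(self, rng: np.random.Generator) -> dict:
        if self.sigmas is not None:
            return {float(t): float(s) for t, s in self.sigmas.items()}
        # draw one sd per temperature from halfCauchy(noise_hyperscale)
        draws = np.abs(
            self.noise_hyperscale * rng.standard_cauchy(len(self.temperatures))
        )
        draws = np.clip(draws, 1e-3, 0.5)
        return {float(t): float(s) for t, s in zip(self.temperatures, draws)}


@dataclass
class SyntheticDataset:
    """Observations plus the generating truth for every condition."""

    observations: GrowthDataset
    truth_params: dict  # ConditionLabel -> CanonicalBriereParams
    truth_categories: dict = field(default_factory=dict)  # pair label -> category
    truth_drivers: dict = field(default_factory=dict)  # pair label -> drug or None
    sigmas: dict = field(default_factory=dict)
    seed: int = 0

    def truth_niche(self, label: ConditionLabel):
        return niche_summary(self.truth_params[label])


def generate_condition(
    params: CanonicalBriereParams,
    temperatures=STUDY_TEMPERATURES_C,
    n_replicates: int = 4,
    sigmas: dict | None = None,
    seed: int = 0,
    label: ConditionLabel | None = None,
) -> pd.DataFrame:
    """Simulate Gamma-noised growth for one condition as a tidy table.

    ``y ~ Gamma(mean = max(g(T), floor), sd = sigma_T)`` independently per
    replicate; byte-reproducible under the seed.
    """
    sigmas = sigmas or DEFAULT_SIGMAS
    label = label or ConditionLabel.control()
    rng = np.random.default_rng(seed)
    rows = []
    d1 = label.drugs[0] if label.n_drugs >= 1 else ""
    d2 = label.drugs[1] if label.n_drugs == 2 else ""
    for t in temperatures:
        mu = max(float(canonical_evaluate(t, params)), MEAN_FLOOR)
        sd = float(sigmas[float(t)])
        shape = mu**2 / sd**2
        scale = sd**2 / mu
        y = rng.gamma(shape, scale, size=n_replicates)
        for r in range(n_replicates):
            rows.append((d1, d2, float(t), r + 1, float(y[r])))
    return pd.DataFrame(rows, columns=COLUMNS)


def _default_pairs(drugs, n_pairs, rng):
    all_pairs = [
        (drugs[i], drugs[j]) for i in range(len(drugs)) for j in range(i + 1, len(drugs))
    ]
    if n_pairs is None or n_pairs >= len(all_pairs):
        return all_pairs
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return [all_pairs[i] for i in sorted(idx)]


def generate_combo_study(
    n_drugs: int = 12,
    shift_profile: dict | None = None,
    seed: int = 0,
    pairs=None,
    n_pairs: int | None = 20,
    pair_categories=None,
    temperatures=STUDY_TEMPERATURES_C,
    n_replicates: int = 4,
    sigmas: dict | None = None,
    base: CanonicalBriereParams | None = None,
    displacement: float = 3.0,
) -> SyntheticDataset:
    """Simulate a full study: control, single drugs, and categorized pairs.

    Pair truths cycle through ``pair_categories`` (default all five models).
    Pairs whose requested category is infeasible (optimum too close to a
    growth limit) are regenerated with the ``mean`` category and recorded as
    such in the truth table.
    """
    if n_drugs < 2:
        raise ValueError("need at least 2 drugs")
    shift_profile = shift_profile or DEFAULT_DRUG_EFFECTS
    drugs = sorted(shift_profile)[:n_drugs]
    base = base or control_curve()
    rng = np.random.default_rng(seed)
    pair_categories = tuple(pair_categories or PAIR_CATEGORIES)

    truth_params = {ConditionLabel.control(): base}
    for d in drugs:
        truth_params[ConditionLabel((d,))] = apply_drug_effect(base, shift_profile[d])

    if pairs is None:
        pairs = _default_pairs(drugs, n_pairs, rng)
    truth_categories, truth_drivers = {}, {}
    for k, (x, y) in enumerate(pairs):
        label = ConditionLabel((x, y))
        px = truth_params[ConditionLabel((x,))]
        py = truth_params[ConditionLabel((y,))]
        category = pair_categories[k % len(pair_categories)]
        try:
            pxy = pair_curve_for_category(px, py, category, displacement)
        except ValueError:
            category = "mean"
            pxy = pair_curve_for_category(px, py, category, displacement)
        truth_params[label] = pxy
        truth_categories[label] = category
        tx, ty = optimal_temperature(px), optimal_temperature(py)
        txy = optimal_temperature(pxy)
        if category == "mean" or abs(txy - tx) == abs(txy - ty):
            truth_drivers[label] = None
        else:
            truth_drivers[label] = x if abs(txy - tx) < abs(txy - ty) else y

    spec = ScenarioSpec(
        conditions=truth_params,
        temperatures=tuple(float(t) for t in temperatures),
        n_replicates=n_replicates,
        sigmas=sigmas,
        seed=seed,
    )
    resolved = spec.resolve_sigmas(rng)
    frames = []
    for i, (label, params) in enumerate(sorted(truth_params.items())):
        frames.append(
            generate_condition(
                params,
                temperatures=spec.temperatures,
                n_replicates=n_replicates,
                sigmas=resolved,
                seed=seed + 1000 + i,
                label=label,
            )
        )
    dataset = GrowthDataset(pd.concat(frames, ignore_index=True))
    return SyntheticDataset(
        observations=dataset,
        truth_params=truth_params,
        truth_categories=truth_categories,
        truth_drivers=truth_drivers,
        sigmas=resolved,
        seed=seed,
    )


def generate_driver_table_null(pairs, seed: int = 0) -> DriverTable:
    """Fair-coin driver assignment per pair (the permutation test's null)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(seed)
    flips = rng.random(len(pairs)) < 0.5
    entries = [
        ((x, y), x if flip else y) for (x, y), flip in zip(pairs, flips)
    ]
    return DriverTable(entries)
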