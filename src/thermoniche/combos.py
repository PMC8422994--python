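"""Five-model selection for the optimal temperature of drug pairs.

Given the fitted single-drug optima ``Topt_X``, ``Topt_Y`` and the fitted
pair optimum ``Topt_XY``, five candidate rules are compared:

* ``min`` / ``max`` — a single drug sets the pair's optimum,
* ``mean``          — both drugs compromise at the average,
* ``attenuated`` / ``elevated`` — the pair's optimum lies beyond both
  single-drug optima (below the min, or above the max, by more than a
  cutoff; default 2.20 degC).

The best of min/mean/max is the one with the smallest absolute prediction
error; when even that error exceeds the cutoff the observation is classed
attenuated or elevated by direction.  For single-driver categories the
*driver* is the drug whose solo optimum is closer to the pair's optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFF_C",
    "ComboPrediction",
    "predict_combo_topt",
    "select_best_model",
    "assign_driver",
    "tabulate_model_frequencies",
    "derive_cutoff",
    "SINGLE_DRIVER_CATEGORIES",
]

DEFAULT_CUTOFF_C = 2.20
TIE_TOL_C = 1e-9
SINGLE_DRIVER_CATEGORIES = frozenset({"min", "max", "attenuated", "elevated"})


@dataclass(frozen=True)
class ComboPrediction:
    """Model-selection result for one drug pair."""

    drug_x: str
    drug_y: str
    t_opt_x: float
    t_opt_y: float
    t_opt_xy: float
    predictions: dict
    abs_errors: dict
    category: str
    driver: str | None
    cutoff: float
    tied_models: tuple = ()
    flags: tuple = ()


def predict_combo_topt(t_opt_x: float, t_opt_y: float) -> dict:
    """min, max and mean predictions for a pair's optimal temperature."""
    if not (np.isfinite(t_opt_x) and np.isfinite(t_opt_y)):
        raise ValueError("single-drug optima must be finite")
    return {
        "min": min(t_opt_x, t_opt_y),
        "max": max(t_opt_x, t_opt_y),
        "mean": 0.5 * (t_opt_x + t_opt_y),
    }


def select_best_model(
    t_opt_x: float,
    t_opt_y: float,
    t_opt_xy: float,
    cutoff: float = DEFAULT_CUTOFF_C,
):
    """Pick the best of the five models for an observed pair optimum.

    Returns ``(category, abs_errors, tied_models, flags)``.  Ties among
    min/mean/max (errors equal within 1e-9 degC) yield category
    ``"multiple"`` with the tied set.  The anomalous case where the smallest
    error exceeds the cutoff but the observed optimum lies *between* the
    single-drug optima keeps the smallest-error category with an
    ``"ambiguous"`` flag (it cannot be attenuated or elevated by definition).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    preds = predict_combo_topt(t_opt_x, t_opt_y)
    errors = {m: abs(t_opt_xy - p) for m, p in preds.items()}
    best_err = min(errors.values())
    tied = tuple(m for m in ("min", "mean", "max") if errors[m] - best_err <= TIE_TOL_C)
    flags: list[str] = []

    if best_err > cutoff:
        if t_opt_xy < preds["min"]:
            return "attenuated", errors, (), tuple(flags)
        if t_opt_xy > preds["max"]:
            return "elevated", errors, (), tuple(flags)
        flags.append("ambiguous")  # large error yet inside [min, max]

    if len(tied) > 1:
        return "multiple", errors, tied, tuple(flags)
    return tied[0], errors, (), tuple(flags)


def assign_driver(
    category: str, drug_x: str, drug_y: str,
    t_opt_x: float, t_opt_y: float, t_opt_xy: float,
):
    """Driver drug for single-driver categories; (driver, tie_flag).

    The driver is the drug whose solo optimum is closer to the pair's
    optimum; ``mean`` and ``multiple`` categories have no driver.  Exact
    equidistance yields no driver with a tie flag.
    """
    if category not in SINGLE_DRIVER_CATEGORIES:
        return None, False
    dx = abs(t_opt_xy - t_opt_x)
    dy = abs(t_opt_xy - t_opt_y)
    if abs(dx - dy) <= TIE_TOL_C:
        return None, True
    return (drug_x, False) if dx < dy else (drug_y, False)


def classify_pair(
    drug_x: str,
    drug_y: str,
    t_opt_x: float,
    t_opt_y: float,
    t_opt_xy: float,
    cutoff: float = DEFAULT_CUTOFF_C,
) -> ComboPrediction:
    """Full classification of one pair: predictions, category, driver, flags."""
    preds = predict_combo_topt(t_opt_x, t_opt_y)
    category, errors, tied, flags = select_best_model(t_opt_x, t_opt_y, t_opt_xy, cutoff)
    driver, tie = assign_driver(category, drug_x, drug_y, t_opt_x, t_opt_y, t_opt_xy)
    if tie:
        flags = flags + ("driver_tie",)
    return ComboPrediction(
        drug_x=drug_x,
        drug_y=drug_y,
        t_opt_x=t_opt_x,
        t_opt_y=t_opt_y,
        t_opt_xy=t_opt_xy,
        predictions=preds,
        abs_errors=errors,
        category=category,
        driver=driver,
        cutoff=cutoff,
        tied_models=tied,
        flags=flags,
    )


def tabulate_model_frequencies(predictions):
    """Category fractions and per-drug driver proportions.

    Returns ``(category_fractions, driver_proportions)``.  A drug's driver
    proportion is the share of its single-driver pairs that it drives.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to tabulate")
    categories = ["min", "max", "mean", "attenuated", "elevated", "multiple"]
    counts = {c: 0 for c in categories}
    for p in predictions:
        counts[p.category] += 1
    n = len(predictions)
    fractions = {c: counts[c] / n for c in categories}

    driven: dict[str, int] = {}
    eligible: dict[str, int] = {}
    for p in predictions:
        if p.category not in SINGLE_DRIVER_CATEGORIES:
            continue
        for d in (p.drug_x, p.drug_y):
            eligible[d] = eligible.get(d, 0) + 1
        if p.driver is not None:
            driven[p.driver] = driven.get(p.driver, 0) + 1
    proportions = {d: driven.get(d, 0) / k for d, k in eligible.items()}
    return fractions, proportions


def derive_cutoff(predictions, percentile: float = 90.0) -> float:
    """Data-driven cutoff: a percentile of the pooled min/mean/max errors."""
    errs = [e for p in predictions for e in p.abs_errors.values()]
    if not errs:
        raise ValueError("no predictions")
    return float(np.percentile(errs, percentile))


def predictions_to_frame(predictions) -> pd.DataFrame:
    """Flatten ComboPredictions to the canonical results table."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "drug_x": p.drug_x,
                "drug_y": p.drug_y,
                "topt_x": p.t_opt_x,
                "topt_y": p.t_opt_y,
                "topt_xy": p.t_opt_xy,
                "pred_min": p.predictions["min"],
                "pred_mean": p.predictions["mean"],
                "pred_max": p.predictions["max"],
                "err_min": p.abs_errors["min"],
                "err_mean": p.abs_errors["mean"],
                "err_max": p.abs_errors["max"],
                "category": p.category,
                "driver": p.driver or "",
                "flags": ";".join(p.flags + (("tied:" + "|".join(p.tied_models),) if p.tied_models else ())),
            }
        )
    return pd.DataFrame(rows)
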