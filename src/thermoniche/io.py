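"""Tidy-table I/O, run configuration and pipeline orchestration.

The canonical exchange format is a tidy CSV with columns
``drug1, drug2, temperature_c, replicate, od600_24h``; a column-mapping
adapter accommodates foreign layouts.  ``run_full_analysis`` chains every
stage: per-condition Bayesian curve fits, credible-interval shift calls
against the no-drug control, combination-optimum model selection, driver
permutation tests, and Bliss interaction profiles — writing one file per
table plus a manifest carrying the seed and a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bliss as bliss_mod
from . import combos as combos_mod
from . import permutation as perm_mod
from .data import ConditionLabel, GrowthDataset, SchemaError
from .fitting import (
    DERIVED_QUANTITIES,
    FitConfig,
    PosteriorSummary,
    classify_shift,
    fit_condition,
    posterior_curve_params,
)

log = logging.getLogger("thermoniche")

__all__ = [
    "RunConfig",
    "load_growth_table",
    "write_growth_table",
    "run_full_analysis",
    "summaries_to_frame",
]

FLOAT_FORMAT = "%.10g"


def load_growth_table(path, column_map: dict | None = None) -> GrowthDataset:
    """Read and validate a tidy growth CSV; drug codes are upper-cased and
    pairs canonicalized to lexicographic order.  ``column_map`` renames
    foreign column names onto the canonical schema before validation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"drug1": "string", "drug2": "string"})
    if column_map:
        df = df.rename(columns=column_map)
    try:
        return GrowthDataset(df)
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from err


def write_growth_table(dataset: GrowthDataset, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run."""

    input_path: str | None = None
    output_dir: str | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    cutoff: float = combos_mod.DEFAULT_CUTOFF_C
    n_perm: int = 10_000
    bliss_tol_frac: float = 0.05
    bliss_grid_points: int = 101
    control_label: str = "control"
    low_growth_frac: float = 0.10
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths and logging excluded)."""
        payload = dataclasses.asdict(self)
        for key in ("input_path", "output_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def summaries_to_frame(summaries: dict) -> pd.DataFrame:
    """One row per condition, point/ci_low/ci_high per derived quantity."""
    rows = []
    for label in sorted(summaries):
        s = summaries[label]
        row = {"condition": str(label), "n_drugs": label.n_drugs}
        for q in DERIVED_QUANTITIES:
            row[f"{q}"] = s.point(q)
            row[f"{q}_ci_low"], row[f"{q}_ci_high"] = s.ci(q)
        row["converged"] = s.converged
        rows.append(row)
    return pd.DataFrame(rows)


def fit_all_conditions(
    dataset: GrowthDataset, fit_cfg: FitConfig, base_seed: int | None = None
) -> dict:
    """Fit every condition with per-condition seeds derived from the base seed."""
    base_seed = fit_cfg.seed if base_seed is None else base_seed
    summaries: dict[ConditionLabel, PosteriorSummary] = {}
    for i, label in enumerate(dataset.conditions):
        temps, growth = dataset.observations(label)
        cfg_i = dataclasses.replace(fit_cfg, seed=(base_seed + 7919 * i) % (2**31 - 1))
        _, summary = fit_condition(temps, growth, cfg_i)
        summaries[label] = summary
        log.info(
            "fitted %s: t_opt=%.2f (%.2f, %.2f) g_max=%.3f converged=%s",
            label, summary.point("t_opt"), *summary.ci("t_opt"),
            summary.point("g_max"), summary.converged,
        )
    return summaries


def run_full_analysis(cfg: RunConfig, dataset: GrowthDataset | None = None) -> dict:
    """Run the complete pipeline; returns the report bundle as a dict.

    Bundle keys: ``summaries`` (DataFrame), ``shifts`` (DataFrame),
    ``combos`` (DataFrame), ``frequencies``/``driver_proportions`` (dicts),
    ``permutation`` (dict), ``bliss`` (dict of DataFrames), ``manifest``.
    Writes files under ``cfg.output_dir`` when set; deterministic under
    ``cfg.seed``.
    """
    logging.basicConfig(level=cfg.log_level)
    if dataset is None:
        if cfg.input_path is None:
            raise ValueError("RunConfig needs input_path or an in-memory dataset")
        dataset = load_growth_table(cfg.input_path)
    control = ConditionLabel.parse(cfg.control_label)
    if control not in dataset.conditions:
        raise ValueError(f"control condition {control} absent from the data")

    fit_cfg = dataclasses.replace(cfg.fit, seed=cfg.seed)
    summaries = fit_all_conditions(dataset, fit_cfg, base_seed=cfg.seed)

    # drop conditions whose peak growth is too small to trust the fit
    g_control = summaries[control].point("g_max")
    dropped = {
        lab
        for lab, s in summaries.items()
        if lab != control and s.point("g_max") < cfg.low_growth_frac * g_control
    }
    for lab in sorted(dropped):
        log.warning("dropping %s: peak growth below %.0f%% of control",
                    lab, 100 * cfg.low_growth_frac)

    shifts_rows = []
    for lab in sorted(summaries):
        if lab == control:
            continue
        for q in ("t_opt", "breadth", "g_max"):
            shifts_rows.append(
                {
                    "condition": str(lab),
                    "quantity": q,
                    "shift": classify_shift(summaries[lab], summaries[control], q),
                    "point": summaries[lab].point(q),
                    "control_point": summaries[control].point(q),
                }
            )
    shifts = pd.DataFrame(shifts_rows)

    # combination model selection on pairs whose singles and pair all survived
    predictions = []
    for lab in sorted(summaries):
        if lab.n_drugs != 2 or lab in dropped:
            continue
        x, y = lab.drugs
        lx, ly = ConditionLabel((x,)), ConditionLabel((y,))
        if lx not in summaries or ly not in summaries or lx in dropped or ly in dropped:
            continue
        predictions.append(
            combos_mod.classify_pair(
                x, y,
                summaries[lx].point("t_opt"),
                summaries[ly].point("t_opt"),
                summaries[lab].point("t_opt"),
                cutoff=cfg.cutoff,
            )
        )
        if "ambiguous" in predictions[-1].flags:
            log.warning("ambiguous combo classification for %s", lab)
    combos_frame = combos_mod.predictions_to_frame(predictions)

    frequencies, proportions, permutation = {}, {}, {}
    if predictions:
        frequencies, proportions = combos_mod.tabulate_model_frequencies(predictions)
        driver_entries = [
            ((p.drug_x, p.drug_y), p.driver)
            for p in predictions
            if p.category in combos_mod.SINGLE_DRIVER_CATEGORIES and p.driver
        ]
        if driver_entries:
            table = perm_mod.DriverTable(driver_entries)
            permutation = {
                "global": perm_mod.permutation_test_global(
                    table, n_perm=cfg.n_perm, seed=cfg.seed
                ).to_dict(),
                "per_drug": perm_mod.permutation_test_per_drug(
                    table, n_perm=cfg.n_perm, seed=cfg.seed
                ).to_dict(),
            }

    # Bliss profiles for surviving single-drug conditions
    bliss_profiles = {}
    g0 = posterior_curve_params(summaries[control])
    for lab in sorted(summaries):
        if lab.n_drugs != 1 or lab in dropped:
            continue
        ga = posterior_curve_params(summaries[lab])
        try:
            profile = bliss_mod.interaction_profile(
                g0, ga, n_grid=cfg.bliss_grid_points, tol_frac=cfg.bliss_tol_frac,
            )
        except ValueError:
            continue
        bliss_profiles[str(lab)] = profile.to_frame()

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_conditions": len(summaries),
        "n_dropped": len(dropped),
        "dropped": [str(d) for d in sorted(dropped)],
        "cutoff_c": cfg.cutoff,
        "fit_method": cfg.fit.method,
    }

    bundle = {
        "summaries": summaries_to_frame(summaries),
        "posterior_summaries": summaries,
        "shifts": shifts,
        "combos": combos_frame,
        "frequencies": frequencies,
        "driver_proportions": proportions,
        "permutation": permutation,
        "bliss": bliss_profiles,
        "manifest": manifest,
    }
    if cfg.output_dir:
        _write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["summaries"].to_csv(outdir / "summaries.csv", index=False,
                               float_format=FLOAT_FORMAT)
    bundle["shifts"].to_csv(outdir / "shifts.csv", index=False,
                            float_format=FLOAT_FORMAT)
    bundle["combos"].to_csv(outdir / "combos.csv", index=False,
                            float_format=FLOAT_FORMAT)
    perm_payload = {
        "frequencies": bundle["frequencies"],
        "driver_proportions": bundle["driver_proportions"],
        **bundle["permutation"],
    }
    (outdir / "permutation.json").write_text(
        json.dumps(perm_payload, indent=2, sort_keys=True) + "\n"
    )
    bliss_dir = outdir / "bliss"
    bliss_dir.mkdir(exist_ok=True)
    for name, frame in bundle["bliss"].items():
        frame.to_csv(bliss_dir / f"{name}.csv", index=False, float_format=FLOAT_FORMAT)
    (outdir / "run_manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, sort_keys=True) + "\n"
    )
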