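"""Growth-data containers: condition labels and tidy observation tables.

The experimental unit is an OD600 reading at 24 h for one antibiotic
condition (no drug, a single drug, or an unordered drug pair) at one
incubation temperature and replicate.  Tables are tidy pandas DataFrames
with columns ``drug1, drug2, temperature_c, replicate, od600_24h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DRUG_CODES",
    "ConditionLabel",
    "GrowthDataset",
    "SchemaError",
    "COLUMNS",
]

#: Controlled vocabulary of antibiotic abbreviations used in the study.
DRUG_CODES = frozenset(
    {"CPR", "GEN", "LVX", "TET", "TOB", "ERY", "AMP", "CLI", "STR", "NTR", "FOX", "TMP"}
)

COLUMNS = ["drug1", "drug2", "temperature_c", "replicate", "od600_24h"]


class SchemaError(ValueError):
    """Raised when a growth table violates the tidy schema."""


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """An unordered set of 0-2 drug codes; the empty set is the no-drug control."""

    drugs: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        drugs = tuple(sorted({d.upper() for d in self.drugs}))
        if len(drugs) > 2:
            raise SchemaError(f"at most 2 drugs per condition, got {drugs}")
        object.__setattr__(self, "drugs", drugs)

    @classmethod
    def control(cls) -> "ConditionLabel":
        return cls(())

    @classmethod
    def parse(cls, text: str) -> "ConditionLabel":
        """Parse labels like ``'control'``, ``'GEN'`` or ``'GEN+TET'``."""
        text = text.strip()
        if text.lower() in ("", "control", "none", "no-drug"):
            return cls(())
        return cls(tuple(part for part in text.split("+") if part))

    @property
    def is_control(self) -> bool:
        return not self.drugs

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def validate_codes(self, vocabulary=DRUG_CODES) -> None:
        unknown = [d for d in self.drugs if d not in vocabulary]
        if unknown:
            raise SchemaError(f"unknown drug codes {unknown}; allowed: {sorted(vocabulary)}")

    def __str__(self) -> str:
        return "+".join(self.drugs) if self.drugs else "control"


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.loc[:, COLUMNS].copy()
    for col in ("drug1", "drug2"):
        df[col] = df[col].fillna("").astype(str).str.strip().str.upper()
    bad2 = df.index[(df["drug2"] != "") & (df["drug1"] == "")]
    if len(bad2):
        raise SchemaError(f"row {bad2[0]}: drug2 set but drug1 empty")
    temps = pd.to_numeric(df["temperature_c"], errors="coerce")
    if temps.isna().any():
        row = df.index[temps.isna()][0]
        raise SchemaError(f"row {row}, column temperature_c: malformed value")
    df["temperature_c"] = temps.astype(float)
    growth = pd.to_numeric(df["od600_24h"], errors="coerce")
    if growth.isna().any():
        row = df.index[growth.isna()][0]
        raise SchemaError(f"row {row}, column od600_24h: malformed value")
    if (growth < 0).any():
        row = df.index[growth < 0][0]
        raise SchemaError(f"row {row}, column od600_24h: negative growth")
    df["od600_24h"] = growth.astype(float)
    df["replicate"] = df["replicate"].astype(int)
    # canonicalize pairs to lexicographic order
    swap = (df["drug2"] != "") & (df["drug1"] > df["drug2"])
    if swap.any():
        d1 = df.loc[swap, "drug2"].to_numpy()
        df.loc[swap, "drug2"] = df.loc[swap, "drug1"].to_numpy()
        df.loc[swap, "drug1"] = d1
    same = (df["drug2"] != "") & (df["drug1"] == df["drug2"])
    if same.any():
        raise SchemaError(f"row {df.index[same][0]}: drug paired with itself")
    return df


@dataclass
class GrowthDataset:
    """A validated tidy growth table with condition-level accessors."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = _validate_frame(self.table)

    @property
    def conditions(self) -> list[ConditionLabel]:
        labels = {
            ConditionLabel(tuple(d for d in (r.drug1, r.drug2) if d))
            for r in self.table.itertuples()
        }
        return sorted(labels, key=lambda c: (c.n_drugs, c.drugs))

    def condition_table(self, label: ConditionLabel) -> pd.DataFrame:
        d1 = label.drugs[0] if label.n_drugs >= 1 else ""
        d2 = label.drugs[1] if label.n_drugs == 2 else ""
        mask = (self.table["drug1"] == d1) & (self.table["drug2"] == d2)
        return self.table.loc[mask]

    def observations(self, label: ConditionLabel) -> tuple[np.ndarray, np.ndarray]:
        """(temperatures, growth) arrays for one condition."""
        sub = self.condition_table(label)
        return (
            sub["temperature_c"].to_numpy(float),
            sub["od600_24h"].to_numpy(float),
        )

    def __len__(self) -> int:
        return len(self.table)
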