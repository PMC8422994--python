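"""Permutation tests: are some antibiotics drivers more often than chance?

Restricts to pairs classified under a single-driver model, then tests the
global dispersion of driver counts (D statistic) and each drug's own count
(M statistic, Benjamini-Hochberg corrected) against the fair-coin null that
either member of a pair is equally likely to drive its optimum.  Writes
results/permutation/permutation.json.
"""

import json
from pathlib import Path

import pandas as pd

from thermoniche.combos import SINGLE_DRIVER_CATEGORIES
from thermoniche.permutation import (
    DriverTable,
    permutation_test_global,
    permutation_test_per_drug,
)

SEED = 23
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    combos = pd.read_csv(ROOT / "combos" / "combos.csv")
    entries = [
        ((row.drug_x, row.drug_y), row.driver)
        for row in combos.itertuples()
        if row.category in SINGLE_DRIVER_CATEGORIES and isinstance(row.driver, str)
    ]
    if not entries:
        print("no single-driver pairs; nothing to test")
        return
    table = DriverTable(entries)
    global_res = permutation_test_global(table, n_perm=10_000, seed=SEED)
    per_drug = permutation_test_per_drug(table, n_perm=10_000, seed=SEED)

    out = ROOT / "permutation"
    out.mkdir(parents=True, exist_ok=True)
    (out / "permutation.json").write_text(
        json.dumps({"global": global_res.to_dict(), "per_drug": per_drug.to_dict()},
                   indent=2, sort_keys=True) + "\n"
    )

    print(f"{len(table)} single-driver pairs across {len(table.drugs)} drugs")
    print(f"global D = {global_res.observed:.2f} "
          f"(null mean {global_res.null_mean:.2f}), P = {global_res.p_value:.4g}")
    sig = [d for d, e in per_drug.per_drug.items() if e["p_adjusted"] < 0.05]
    print("individually significant drugs after correction: "
          + (", ".join(sig) if sig else "none"))


if __name__ == "__main__":
    main()
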