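"""Classify antibiotic-induced shifts of the optimum and thermal niche.

Compares each condition's 95% credible interval to the no-drug control's:
non-overlapping intervals are called left (lower) or right (higher) shifts.
Writes results/shifts/shifts.csv and summarizes the direction pattern
(heat-similar drugs should shift the optimum left; cold-similar drugs
should leave it unchanged or nudge it right).
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def classify(row, ctrl) -> str:
    if row["ci_low"] <= ctrl["ci_high"] and ctrl["ci_low"] <= row["ci_high"]:
        return "overlap"
    return "higher" if row["point"] > ctrl["point"] else "lower"


def main() -> None:
    frame = pd.read_csv(ROOT / "fits" / "summaries.csv")
    out_rows = []
    ctrl_row = frame[frame["condition"] == "control"].iloc[0]
    for quantity in ("t_opt", "breadth", "g_max"):
        ctrl = {
            "point": ctrl_row[quantity],
            "ci_low": ctrl_row[f"{quantity}_ci_low"],
            "ci_high": ctrl_row[f"{quantity}_ci_high"],
        }
        for _, row in frame[frame["condition"] != "control"].iterrows():
            r = {
                "point": row[quantity],
                "ci_low": row[f"{quantity}_ci_low"],
                "ci_high": row[f"{quantity}_ci_high"],
            }
            out_rows.append(
                {
                    "condition": row["condition"],
                    "n_drugs": row["n_drugs"],
                    "quantity": quantity,
                    "shift": classify(r, ctrl),
                    "point": r["point"],
                    "control_point": ctrl["point"],
                }
            )
    shifts = pd.DataFrame(out_rows)
    out = ROOT / "shifts"
    out.mkdir(parents=True, exist_ok=True)
    shifts.to_csv(out / "shifts.csv", index=False, float_format="%.10g")

    t_opt = shifts[(shifts["quantity"] == "t_opt") & (shifts["n_drugs"] == 1)]
    counts = t_opt["shift"].value_counts().to_dict()
    print(f"single-drug optimum shifts vs control: {counts}")
    breadth = shifts[(shifts["quantity"] == "breadth") & (shifts["n_drugs"] == 1)]
    print(f"single-drug breadth calls: {breadth['shift'].value_counts().to_dict()}")
    print(f"wrote {len(shifts)} rows -> {out / 'shifts.csv'}")


if __name__ == "__main__":
    main()
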