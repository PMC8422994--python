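"""Bliss-independence profiles: where do temperature and drug interact?

For each single drug, builds the null curve g~_a(T) = g_0(T) * r_a (the
control curve scaled by the drug's effect at the unstressed optimum) from
the fitted posterior-mean parameters and scores synergy (growth reduced
more than predicted) or antagonism per temperature.  Writes one CSV per
drug under results/bliss/ and summarizes the sign pattern around the
unstressed optimum.
"""

from pathlib import Path

import pandas as pd

from thermoniche.bliss import interaction_profile
from thermoniche.briere import CanonicalBriereParams

ROOT = Path(__file__).resolve().parents[1] / "results"


def params_from_row(row) -> CanonicalBriereParams:
    return CanonicalBriereParams(
        g_max=row["g_max"], alpha=row["alpha"], s=row["s"],
        t_min=row["t_min"], t_max=row["t_max"],
    )


def main() -> None:
    frame = pd.read_csv(ROOT / "fits" / "summaries.csv").set_index("condition")
    g0 = params_from_row(frame.loc["control"])
    out = ROOT / "bliss"
    out.mkdir(parents=True, exist_ok=True)

    patterns = {}
    for condition in frame.index:
        if condition == "control" or "+" in condition:
            continue
        profile = interaction_profile(g0, params_from_row(frame.loc[condition]))
        profile.to_frame().to_csv(out / f"{condition}.csv", index=False,
                                  float_format="%.10g")
        t, score = profile.temperatures, profile.score
        hot = score[(t > profile.t_ref) & (t < profile.t_ref + 6)].mean()
        cold = score[(t < profile.t_ref) & (t > profile.t_ref - 10)].mean()
        patterns[condition] = (
            "hot-synergy" if hot < -profile.tol else
            "hot-antagonism" if hot > profile.tol else "hot-independent",
            "cold-synergy" if cold < -profile.tol else
            "cold-antagonism" if cold > profile.tol else "cold-independent",
        )

    print(f"wrote {len(patterns)} interaction profiles -> {out}")
    for condition, (hot, cold) in sorted(patterns.items()):
        print(f"  {condition}: {hot}, {cold}")


if __name__ == "__main__":
    main()
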