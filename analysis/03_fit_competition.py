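#!/usr/bin/env python
"""Fit per-day selection coefficients to the GFP-competition series.

Reads results/data/competition.tsv, fits logit(p) ~ day per replicate,
classifies each construct by the one-sided upper confidence bound of s,
and reports the fitted coefficients alongside the day-35 projection.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirhts import io
from mirhts.competition import CompetitionSeries, classify_inhibitory, fit_selection, project


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    tab = io.read_table(args.data / "competition.tsv",
                        required_columns=["label", "replicate", "day", "pct_gfp"])
    rows = []
    for (label, rep), sub in tab.groupby(["label", "replicate"]):
        sub = sub.sort_values("day")
        fit = fit_selection(
            CompetitionSeries(days=sub["day"].tolist(), pct_gfp=sub["pct_gfp"].tolist(),
                              replicate=int(rep), label=label)
        )
        rows.append({
            "label": label, "replicate": rep, "s_per_day": fit.s, "se": fit.se,
            "p0_hat": fit.p0_hat, "inhibitory": classify_inhibitory(fit),
            "pct_gfp_day35_projected": 100 * project(fit.p0_hat, fit.s, 35),
        })
    fits = pd.DataFrame(rows)
    io.write_table(fits, args.out / "competition_fits.tsv")
    for label, sub in fits.groupby("label"):
        print(f"{label}: mean s = {sub['s_per_day'].mean():+.4f}/day, "
              f"day-35 projection {sub['pct_gfp_day35_projected'].mean():.1f}% GFP+, "
              f"inhibitory in {int(sub['inhibitory'].sum())}/{len(sub)} replicates")


if __name__ == "__main__":
    main()
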