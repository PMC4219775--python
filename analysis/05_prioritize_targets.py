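#!/usr/bin/env python
"""Run the target-prioritization funnel over the prediction universe.

Reads predictions/expression/annotations from results/data/, builds the
three gene sets (hit-miR predictions, non-hit-miR predictions, expressed
genes), intersects and excludes, then shortlists growth-related survivors
by literature flag or dual-source prediction support and ranks them by
prediction strength.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mirhts import io
from mirhts.simulate import HIT_MIRS, NON_HIT_MIRS
from mirhts.target_filter import annotate_and_shortlist, build_sets, filter_targets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    predictions = io.read_table(args.data / "predictions.tsv",
                                required_columns=["gene", "mir", "source", "score"])
    expression = io.read_table(args.data / "expression.tsv", required_columns=["gene", "call"])
    annotations = io.read_table(
        args.data / "annotations.tsv",
        required_columns=["gene", "growth_related", "leukemia_oncogenesis_literature"],
    )

    set1, set2, set3 = build_sets(predictions, HIT_MIRS, NON_HIT_MIRS, expression)
    survivors = filter_targets(set1, set2, set3)
    shortlist = annotate_and_shortlist(survivors, annotations, predictions, HIT_MIRS)

    io.write_table(pd.DataFrame({"gene": sorted(survivors)}), args.out / "filter_survivors.tsv")
    io.write_table(shortlist, args.out / "shortlist.tsv")

    n_short = int(shortlist["shortlisted"].sum()) if not shortlist.empty else 0
    print(f"funnel: |Set1|={len(set1)} hit-predicted, |Set2|={len(set2)} non-hit-predicted, "
          f"|Set3|={len(set3)} expressed")
    print(f"  -> {len(survivors)} survivors -> {len(shortlist)} growth-related "
          f"-> {n_short} shortlisted")
    top = shortlist[shortlist["shortlisted"]].head(3)
    for r in top.itertuples():
        ctx = f"{r.best_context_score:.2f}" if np.isfinite(r.best_context_score) else "n/a"
        tgt = f"{r.best_target_score:.0f}" if np.isfinite(r.best_target_score) else "n/a"
        print(f"  top: {r.gene} (context score {ctx}, target score {tgt})")


if __name__ == "__main__":
    main()
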