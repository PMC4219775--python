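#!/usr/bin/env python
"""Absolute miR quantitation: standard curve to copies per cell.

Reads the dilution series and the triplicate sample plate from
results/data/, fits the log-linear standard curve, averages replicate Cts
per assay, inverts to copies per reaction and divides by the 800 cell
equivalents of a 10-ng RNA input (12.5 pg total RNA per cell).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mirhts import io
from mirhts.quantitation import (
    CellEquivalents,
    below_detection,
    copies_per_cell,
    ct_to_copies,
    fit_standard_curve,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    standards = io.read_table(args.data / "standards.tsv", required_columns=["copies", "ct"])
    curve = fit_standard_curve(list(zip(standards["copies"], standards["ct"])))
    print(f"standard curve: slope {curve.slope:.4f}, intercept {curve.intercept:.2f}, "
          f"R^2 {curve.r2:.4f}, efficiency {curve.efficiency:.3f}")

    cells = CellEquivalents(rna_input_ng=10.0, rna_per_cell_pg=12.5)
    plate = io.read_table(args.data / "plate.tsv", required_columns=["assay", "well", "ct"])
    rows = []
    for assay, sub in plate.groupby("assay"):
        mean_ct = float(np.mean(sub["ct"]))
        per_rxn = ct_to_copies(mean_ct, curve)
        rows.append({
            "assay": assay, "mean_ct": mean_ct,
            "copies_per_reaction": per_rxn,
            "copies_per_cell": copies_per_cell(per_rxn, cells),
            "below_detection": below_detection(per_rxn, curve),
        })
    table = pd.DataFrame(rows)
    io.write_table(table, args.out / "copies_per_cell.tsv")
    for r in rows:
        print(f"{r['assay']}: {r['copies_per_cell']:.0f} copies/cell "
              f"(mean Ct {r['mean_ct']:.2f}, {cells.cells:.0f} cell equivalents/reaction)")


if __name__ == "__main__":
    main()
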