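#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes, under results/data/: three replicate pooled-screen detection
tables (578 constructs, days 4/12/20/28, 5 planted growth-inhibitory
constructs), GFP-competition series for an empty-vector and an inhibitory
construct, a qPCR dilution series and a triplicate sample plate, the
prediction/expression/annotation tables of a 1,000-gene universe with 3
planted true targets, and an 803-nt UTR carrying two planted seed sites.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirhts import io
from mirhts.quantitation import StandardCurve
from mirhts.simulate import (
    CompetitionScenario,
    plant_utr_sites,
    planted_screen_scenario,
    simulate_competition,
    simulate_prediction_universe,
    simulate_qpcr_plate,
    simulate_screen,
)

MIR_SEQ = "UGAUUGGUACGUCUGUGGGUAG"  # synthetic mature-miR stand-in


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out

    scenario = planted_screen_scenario(rng_seed=io.stage_seed(args.seed, "screen"))
    dataset = simulate_screen(scenario)
    for i, tab in enumerate(dataset.replicates, start=1):
        io.write_table(tab, out / f"screen_rep{i}.tsv")
    io.write_table(
        pd.DataFrame(
            {"construct": list(dataset.truth_fitness), "fitness": list(dataset.truth_fitness.values())}
        ),
        out / "screen_truth.tsv",
    )
    print(f"screen: {scenario.library_size} constructs x {len(scenario.timepoints)} timepoints x "
          f"{scenario.n_replicates} replicates; transduced fraction {scenario.transduced_fraction:.3f}")

    rows = []
    for label, p0, s in (("empty-vector", 0.5, 0.0), ("inhibitory-miR", 0.46, -0.0582)):
        series = simulate_competition(
            CompetitionScenario(p0=p0, s=s, label=label,
                                rng_seed=io.stage_seed(args.seed, f"comp:{label}"))
        )
        rows += [
            {"label": sr.label, "replicate": sr.replicate, "day": d, "pct_gfp": 100 * p}
            for sr in series
            for d, p in zip(sr.days, sr.pct_gfp)
        ]
    io.write_table(pd.DataFrame(rows), out / "competition.tsv")
    print("competition: 2 conditions x 3 replicates, weekly for 35 days")

    curve = StandardCurve(slope=-3.3219, intercept=37.0)
    standards = [10.0**k for k in range(1, 8)]
    io.write_table(
        pd.DataFrame({"copies": standards,
                      "ct": simulate_qpcr_plate(standards, curve, ct_sd=0.0)}),
        out / "standards.tsv",
    )
    truths = {"miR-509-5p": 1814.0, "miR-509-3p": 3656.0, "miR-18a": 1415.0}
    plate = []
    for assay, per_cell in truths.items():
        cts = simulate_qpcr_plate([per_cell * 800.0] * 3, curve, ct_sd=0.1,
                                  rng_seed=io.stage_seed(args.seed, f"plate:{assay}"))
        plate += [{"assay": assay, "well": w, "ct": ct} for w, ct in enumerate(cts, start=1)]
    io.write_table(pd.DataFrame(plate), out / "plate.tsv")
    print(f"qPCR: 7-point standard curve + triplicate Cts for {len(truths)} assays")

    predictions, expression, annotations = simulate_prediction_universe(
        n_genes=1000, planted_targets=["TARGET1", "TARGET2", "TARGET3"],
        rng_seed=io.stage_seed(args.seed, "universe"),
    )
    io.write_table(predictions, out / "predictions.tsv")
    io.write_table(expression, out / "expression.tsv")
    io.write_table(annotations, out / "annotations.tsv")
    print(f"universe: {len(expression)} genes, {len(predictions)} prediction rows, 3 planted targets")

    record = plant_utr_sites(803, MIR_SEQ, [66, 759], ["7mer-m8", "8mer-A1"],
                             rng_seed=io.stage_seed(args.seed, "utr"))
    io.write_fasta([record], out / "utr.fasta")
    print(f"UTR: {len(record.seq)} nt with planted sites at 66 (7mer-m8) and 759 (8mer-A1)")


if __name__ == "__main__":
    main()
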