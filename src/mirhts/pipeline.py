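"""End-to-end synthetic pipeline driver.

Runs every stage on generated data — screen simulation and candidate
calling, GFP-competition fitting, absolute qPCR quantitation, target
prioritization with UTR site scanning, and the validation-assay
arithmetic — writing tidy TSV/JSON artifacts plus a manifest with the
config echo, the global seed and content hashes. Same config and seed
reproduce byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirhts import assays, competition, io, quantitation, screen, simulate, target_filter


@dataclass
class PipelineConfig:
    """Parameters of the all-synthetic demonstration run.

    Screen, competition and quantitation defaults follow the study
    conditions the generators emulate; the miR sequence is a synthetic
    stand-in (real analyses must supply the mature sequence of interest).
    """

    out_dir: str = "results/pipeline"
    rng_seed: int = 0
    # screen stage
    library_size: int = 578
    n_planted: int = 5
    w_inhibitory: float = 0.85
    dropout_floor: float = 30.0
    depletion_ratio: float = 0.5
    min_later_tps: int = 2
    min_screens: int = 2
    # competition stage
    competition_p0: float = 0.46
    competition_s: float = -0.0582
    events_per_measurement: int = 10_000
    competition_replicates: int = 3
    # quantitation stage
    copies_per_cell_truth: dict = field(
        default_factory=lambda: {
            "miR-509-5p": 1814.0,
            "miR-509-3p": 3656.0,
            "miR-18a": 1415.0,
        }
    )
    ct_sd: float = 0.1
    rna_input_ng: float = 10.0
    rna_per_cell_pg: float = 12.5
    # target-prioritization stage
    n_genes: int = 1000
    planted_targets: tuple = ("TARGET1", "TARGET2", "TARGET3")
    # UTR stage (synthetic miR sequence; supply a real mature sequence in use)
    mir_sequence: str = "UGAUUGGUACGUCUGUGGGUAG"
    utr_length: int = 803
    site_positions: tuple = (66, 759)
    site_types: tuple = ("7mer-m8", "8mer-A1")

    @classmethod
    def known_keys(cls) -> list[str]:
        return [f.name for f in cls.__dataclass_fields__.values()]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_config(path, cls.known_keys())
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    artifacts: dict[str, Path] = {}
    summary: dict = {"rng_seed": seed}

    # --- screen simulation and candidate calling
    scenario = simulate.planted_screen_scenario(
        rng_seed=io.stage_seed(seed, "screen"),
        n_planted=config.n_planted,
        w_inhibitory=config.w_inhibitory,
        dropout_floor=config.dropout_floor,
        library_size=config.library_size,
    )
    dataset = simulate.simulate_screen(scenario)
    for i, tab in enumerate(dataset.replicates, start=1):
        artifacts[f"screen_rep{i}"] = io.write_table(tab, out / f"screen_rep{i}.tsv")
    calls = screen.call_candidates(
        dataset,
        depletion_ratio=config.depletion_ratio,
        min_later_tps=config.min_later_tps,
        min_screens=config.min_screens,
    )
    artifacts["candidates"] = io.write_table(
        screen.calls_to_frame(calls), out / "candidates.tsv"
    )
    truth = dataset.truth_fitness
    planted = {c for c, w in truth.items() if w < 1.0}
    called = {c.construct for c in calls if c.consensus}
    neutral = set(truth) - planted
    summary["screen"] = {
        "n_planted": len(planted),
        "n_called": len(called),
        "recall": len(called & planted) / len(planted) if planted else float("nan"),
        "false_positive_rate": len(called & neutral) / len(neutral),
    }

    # --- GFP competition
    series_all: list[competition.CompetitionSeries] = []
    for label, p0, s in (
        ("empty-vector", 0.5, 0.0),
        ("inhibitory-miR", config.competition_p0, config.competition_s),
    ):
        series_all.extend(
            simulate.simulate_competition(
                simulate.CompetitionScenario(
                    p0=p0,
                    s=s,
                    events_per_measurement=config.events_per_measurement,
                    n_replicates=config.competition_replicates,
                    label=label,
                    rng_seed=io.stage_seed(seed, f"competition:{label}"),
                )
            )
        )
    comp_rows = [
        {"label": sr.label, "replicate": sr.replicate, "day": d, "pct_gfp": 100.0 * p}
        for sr in series_all
        for d, p in zip(sr.days, sr.pct_gfp)
    ]
    artifacts["competition"] = io.write_table(
        pd.DataFrame(comp_rows), out / "competition.tsv"
    )
    fit_rows = []
    for sr in series_all:
        fit = competition.fit_selection(sr)
        fit_rows.append(
            {
                "label": fit.label,
                "replicate": fit.replicate,
                "s_per_day": fit.s,
                "se": fit.se,
                "p0_hat": fit.p0_hat,
                "inhibitory": competition.classify_inhibitory(fit),
            }
        )
    artifacts["competition_fits"] = io.write_table(
        pd.DataFrame(fit_rows), out / "competition_fits.tsv"
    )
    fits = pd.DataFrame(fit_rows)
    summary["competition"] = {
        label: float(fits.loc[fits["label"] == label, "s_per_day"].mean())
        for label in fits["label"].unique()
    }

    # --- absolute qPCR quantitation
    curve_truth = quantitation.StandardCurve(slope=-3.3219, intercept=37.0)
    standards = [10.0**k for k in range(1, 8)]
    curve_cts = simulate.simulate_qpcr_plate(
        standards, curve_truth, ct_sd=0.0, rng_seed=io.stage_seed(seed, "curve")
    )
    curve = quantitation.fit_standard_curve(list(zip(standards, curve_cts)))
    cells = quantitation.CellEquivalents(
        rna_input_ng=config.rna_input_ng, rna_per_cell_pg=config.rna_per_cell_pg
    )
    assay_names = sorted(config.copies_per_cell_truth)
    # triplicate reactions per assay; replicate Cts averaged before inversion
    true_rxn = [
        config.copies_per_cell_truth[a] * cells.cells for a in assay_names for _ in range(3)
    ]
    plate_cts = simulate.simulate_qpcr_plate(
        true_rxn, curve_truth, ct_sd=config.ct_sd, rng_seed=io.stage_seed(seed, "plate")
    )
    quant_rows = []
    for i, name in enumerate(assay_names):
        ct = float(np.mean(plate_cts[3 * i : 3 * i + 3]))
        per_rxn = quantitation.ct_to_copies(ct, curve)
        quant_rows.append(
            {
                "assay": name,
                "ct": ct,
                "copies_per_reaction": per_rxn,
                "copies_per_cell": quantitation.copies_per_cell(per_rxn, cells),
            }
        )
    artifacts["quantitation"] = io.write_table(
        pd.DataFrame(quant_rows), out / "quantitation.tsv"
    )
    summary["quantitation"] = {
        r["assay"]: r["copies_per_cell"] for r in quant_rows
    } | {"cells_per_reaction": cells.cells, "efficiency": curve.efficiency}

    # --- target prioritization
    predictions, expression, annotations = simulate.simulate_prediction_universe(
        n_genes=config.n_genes,
        planted_targets=config.planted_targets,
        rng_seed=io.stage_seed(seed, "universe"),
    )
    set1, set2, set3 = target_filter.build_sets(
        predictions, simulate.HIT_MIRS, simulate.NON_HIT_MIRS, expression
    )
    survivors = target_filter.filter_targets(set1, set2, set3)
    shortlist = target_filter.annotate_and_shortlist(
        survivors, annotations, predictions, simulate.HIT_MIRS
    )
    artifacts["predictions"] = io.write_table(predictions, out / "predictions.tsv")
    artifacts["survivors"] = io.write_table(
        pd.DataFrame({"gene": sorted(survivors)}), out / "filter_survivors.tsv"
    )
    artifacts["shortlist"] = io.write_table(shortlist, out / "shortlist.tsv")
    summary["target_filter"] = {
        "set1": len(set1),
        "set2": len(set2),
        "set3": len(set3),
        "survivors": len(survivors),
        "growth_related": int(len(shortlist)),
        "shortlisted": int(shortlist["shortlisted"].sum()) if not shortlist.empty else 0,
        "planted_recovered": sorted(set(config.planted_targets) & survivors),
    }

    # --- UTR seed sites
    record = simulate.plant_utr_sites(
        config.utr_length,
        config.mir_sequence,
        list(config.site_positions),
        list(config.site_types),
        rng_seed=io.stage_seed(seed, "utr"),
    )
    artifacts["utr"] = io.write_fasta([record], out / "utr.fasta")
    sites = target_filter.find_seed_sites(str(record.seq), config.mir_sequence, "query-miR")
    artifacts["sites"] = io.write_table(
        target_filter.sites_to_frame(sites, gene=record.id), out / "sites.tsv"
    )
    summary["seed_sites"] = [
        {"start": s.start, "end": s.end, "site_class": s.site_class} for s in sites
    ]

    # --- validation-assay arithmetic on synthetic event tables
    apoptosis = simulate.simulate_quadrant_events(
        20_000, (0.80, 0.10, 0.04, 0.06), rng_seed=io.stage_seed(seed, "apoptosis")
    )
    cycle = simulate.simulate_cell_cycle_events(
        20_000,
        {"subG1": 0.05, "G0/G1": 0.55, "S": 0.30, "G2/M": 0.10},
        rng_seed=io.stage_seed(seed, "cycle"),
    )
    summary["assays"] = {
        "apoptosis_quadrants": assays.quadrant_frequencies(apoptosis),
        "cell_cycle": assays.cell_cycle_fractions(cycle),
    }

    artifacts["summary"] = io.write_json(summary, out / "summary.json")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "rng_seed": seed,
        "artifacts": {
            name: {"path": str(p), "sha256": io.file_sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
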