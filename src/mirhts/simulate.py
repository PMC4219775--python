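"""Generators for every input the analysis pipeline consumes.

The pooled-screen generator mirrors the screened system: a library of 578
miR constructs transduced into 1.8 million pre-B leukemia cells at MOI 0.3
(single-hit Poisson, so an expected 1 - e^-0.3 ~ 25.9% of cells carry a
provirus; "~30%" is the linear approximation of that fraction). Each
transduced clone grows exponentially at a per-day relative fitness w
(w = 1 neutral); 2 million cells are sampled at days 4, 12, 20 and 28 in
each of 3 replicate screens, and per-construct template copies are the
transduced cells of that construct among the sample. Detection emulates
the sporadic amplification of scarce templates (the Monte Carlo effect):
the probability of calling a construct detected falls logistically in
log10(copies) around a configurable floor.

Competition series follow the two-population model used by the fitting
module; qPCR plates follow the log-linear standard-curve model; the
prediction universe plants true targets that survive the prioritization
funnel by construction while decoys populate every other Venn region; and
planted-UTR sequences carry seed matches at requested positions on an
otherwise match-free random background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirhts.competition import CompetitionSeries, project
from mirhts.quantitation import UNDETERMINED, StandardCurve
from mirhts.screen import ScreenDataset
from mirhts.target_filter import SeedSite, find_seed_sites, site_sequences

VENN_REGIONS = ("s1", "s2", "s3", "s1s2", "s1s3", "s2s3", "s1s2s3")

HIT_MIRS = ("miR-509-5p", "miR-509-3p")
NON_HIT_MIRS = ("miR-381", "miR-550a", "miR-873", "miR-432")


# ---------------------------------------------------------------------------
# pooled dropout screen


@dataclass
class ScreenScenario:
    """Conditions of one pooled dropout screen.

    Defaults are the screened system's: 578 constructs, 1.8e6 cells at
    MOI 0.3, sampling 2e6 cells at days 4/12/20/28, 3 replicate screens,
    uniform library representation and neutral fitness unless overridden.
    ``dropout_floor`` is the template copy number at which detection
    probability crosses 1/2 (0 disables stochastic detection).
    """

    library_size: int = 578
    n_cells_infected: int = 1_800_000
    moi: float = 0.3
    timepoints: Sequence[float] = (4.0, 12.0, 20.0, 28.0)
    n_replicates: int = 3
    cells_sampled_per_tp: int = 2_000_000
    fitness_map: Mapping[str, float] | None = None
    representation: Mapping[str, float] | None = None
    dropout_floor: float = 0.0
    detection_slope: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        if self.moi < 0:
            raise ValueError("moi must be non-negative")
        tps = np.asarray(self.timepoints, dtype=float)
        if len(tps) < 1 or np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.fitness_map is not None:
            unknown = set(self.fitness_map) - set(self.constructs)
            if unknown:
                raise ValueError(f"fitness_map names unknown constructs {sorted(unknown)}")
            if any(w <= 0 for w in self.fitness_map.values()):
                raise ValueError("all fitness values must be positive")
        if self.representation is not None:
            fracs = self.representation_vector()
            if abs(fracs.sum() - 1.0) > 1e-9:
                raise ValueError("representation must sum to 1")

    @property
    def constructs(self) -> list[str]:
        return [f"lenti-miR-{i:04d}" for i in range(1, self.library_size + 1)]

    @property
    def transduced_fraction(self) -> float:
        """Poisson single-hit zero-class complement, 1 - e^-MOI."""
        return 1.0 - math.exp(-self.moi)

    def fitness_vector(self) -> np.ndarray:
        fm = self.fitness_map or {}
        return np.array([fm.get(c, 1.0) for c in self.constructs], dtype=float)

    def representation_vector(self) -> np.ndarray:
        if self.representation is None:
            return np.full(self.library_size, 1.0 / self.library_size)
        return np.array(
            [self.representation.get(c, 0.0) for c in self.constructs], dtype=float
        )


def detection_probability(
    copies: np.ndarray, dropout_floor: float, slope: float = 4.0
) -> np.ndarray:
    """Logistic in log10(copies) centered at the floor; zero copies never
    amplify, and a floor of 0 makes any template certain to amplify."""
    copies = np.asarray(copies, dtype=float)
    p = np.zeros_like(copies)
    pos = copies > 0
    if dropout_floor <= 0:
        p[pos] = 1.0
        return p
    ratio = np.power(copies[pos] / dropout_floor, slope)
    p[pos] = ratio / (1.0 + ratio)
    return p


def simulate_screen(scenario: ScreenScenario) -> ScreenDataset:
    """Simulate replicate dropout screens and retain ground truth.

    Stochasticity enters through Poisson transduction (library assignment
    of transduced cells), subsampling at each harvest, and the detection
    flag; growth between timepoints is deterministic exponential per clone.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    w = scenario.fitness_vector()
    rep_frac = scenario.representation_vector()
    tps = np.asarray(scenario.timepoints, dtype=float)
    constructs = scenario.constructs

    tables = []
    for _ in range(scenario.n_replicates):
        n_transduced = rng.binomial(
            scenario.n_cells_infected, scenario.transduced_fraction
        )
        counts0 = rng.multinomial(n_transduced, rep_frac)
        n_untransduced = scenario.n_cells_infected - n_transduced
        rows = []
        for t in tps:
            weights = counts0 * np.power(w, t)
            total = n_untransduced + weights.sum()
            shares = np.append(weights, n_untransduced) / total
            sampled = rng.multinomial(scenario.cells_sampled_per_tp, shares)[:-1]
            p_det = detection_probability(
                sampled, scenario.dropout_floor, scenario.detection_slope
            )
            detected = rng.random(len(sampled)) < p_det
            for c, copies, det in zip(constructs, sampled, detected):
                rows.append((c, float(t), float(copies), bool(det)))
        tables.append(
            pd.DataFrame(
                rows, columns=["construct", "timepoint_day", "abundance", "detected"]
            )
        )

    return ScreenDataset(
        replicates=tables,
        reference_timepoint=float(tps[0]),
        cell_line_label="synthetic",
        truth_fitness=dict(zip(constructs, w)),
        metadata={
            "transduction_model": "Poisson single-hit",
            "transduced_fraction_expected": scenario.transduced_fraction,
            "note": "MOI 0.3 gives 1-e^-0.3 = 0.259 transduced; '~30%' is its linear approximation",
            "rng_seed": scenario.rng_seed,
        },
    )


def planted_screen_scenario(
    rng_seed: int = 0,
    n_planted: int = 5,
    w_inhibitory: float = 0.85,
    dropout_floor: float = 30.0,
    **overrides,
) -> ScreenScenario:
    """The default planted scenario: a full-size library with a handful of
    growth-inhibitory constructs (w = 0.85/day) among neutral ones."""
    base = ScreenScenario(rng_seed=rng_seed, **overrides)
    planted = base.constructs[:n_planted]
    fitness = {c: w_inhibitory for c in planted}
    return ScreenScenario(
        library_size=base.library_size,
        n_cells_infected=base.n_cells_infected,
        moi=base.moi,
        timepoints=base.timepoints,
        n_replicates=base.n_replicates,
        cells_sampled_per_tp=base.cells_sampled_per_tp,
        fitness_map=fitness,
        representation=base.representation,
        dropout_floor=dropout_floor,
        detection_slope=base.detection_slope,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# GFP competition


@dataclass
class CompetitionScenario:
    """Conditions of a GFP-competition experiment: mixing near 50% GFP+ at
    day 0, weekly flow measurements of 10^4 events over 35 days."""

    p0: float = 0.5
    s: float = 0.0
    days: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0, 35.0)
    events_per_measurement: int = 10_000
    n_replicates: int = 3
    label: str = ""
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        days = np.asarray(self.days, dtype=float)
        if days[0] != 0:
            raise ValueError("days must start at 0 (mixing day)")
        if self.events_per_measurement < 1:
            raise ValueError("events_per_measurement must be positive")


def simulate_competition(scenario: CompetitionScenario) -> list[CompetitionSeries]:
    """Binomial flow sampling around the deterministic competition curve."""
    rng = np.random.default_rng(scenario.rng_seed)
    days = np.asarray(scenario.days, dtype=float)
    truth = np.array([project(scenario.p0, scenario.s, t) for t in days])
    out = []
    for rep in range(scenario.n_replicates):
        counts = rng.binomial(scenario.events_per_measurement, truth)
        observed = counts / scenario.events_per_measurement
        out.append(
            CompetitionSeries(
                days=days.tolist(),
                pct_gfp=observed.tolist(),
                replicate=rep,
                label=scenario.label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(
    true_copies: Sequence[float],
    curve: StandardCurve,
    ct_sd: float = 0.0,
    rng_seed: int = 0,
) -> list[float]:
    """Cts from the log-linear curve plus Gaussian cycle noise; zero-copy
    reactions come back undetermined (NaN)."""
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    cts = []
    for c in true_copies:
        if c < 0:
            raise ValueError("true copies must be non-negative")
        if c == 0:
            cts.append(UNDETERMINED)
            continue
        ct = curve.intercept + curve.slope * math.log10(c)
        if ct_sd > 0:
            ct += rng.normal(0.0, ct_sd)
        cts.append(float(ct))
    return cts


# ---------------------------------------------------------------------------
# prediction universe


def simulate_prediction_universe(
    n_genes: int,
    planted_targets: Iterable[str],
    overlap_rates: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    hit_mirs: Sequence[str] = HIT_MIRS,
    non_hit_mirs: Sequence[str] = NON_HIT_MIRS,
    growth_related_rate: float = 0.2,
    literature_rate: float = 0.3,
    dual_source_rate: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Prediction, expression-call and growth-annotation tables with planted
    true targets guaranteed to survive the prioritization funnel.

    Planted targets are predicted for a hit miR by both sources with strong
    scores, called present, growth-annotated and literature-flagged, and
    never predicted for non-hit miRs. Decoy genes land in the seven Venn
    regions of (hit-predicted, non-hit-predicted, expressed) at
    ``overlap_rates`` (region keys "s1", "s2", "s3", "s1s2", "s1s3",
    "s2s3", "s1s2s3"; remainder of the mass stays outside all sets).
    """
    planted = [g.strip().upper() for g in planted_targets]
    if len(set(planted)) != len(planted):
        raise ValueError("planted targets must be unique")
    if len(planted) > n_genes:
        raise ValueError("planted targets exceed gene universe")
    if overlap_rates is None:
        overlap_rates = {
            "s1": 0.10, "s2": 0.10, "s3": 0.25,
            "s1s2": 0.05, "s1s3": 0.10, "s2s3": 0.10, "s1s2s3": 0.05,
        }
    unknown = set(overlap_rates) - set(VENN_REGIONS)
    if unknown:
        raise ValueError(f"unknown Venn regions {sorted(unknown)}")
    probs = np.array([overlap_rates.get(r, 0.0) for r in VENN_REGIONS], dtype=float)
    if probs.min() < 0 or probs.sum() > 1 + 1e-12:
        raise ValueError("overlap rates must be non-negative and sum to <= 1")

    rng = np.random.default_rng(rng_seed)
    decoys = [f"GENE{i:05d}" for i in range(1, n_genes - len(planted) + 1)]
    all_regions = list(VENN_REGIONS) + ["none"]
    region_p = np.append(probs, 1.0 - probs.sum())

    pred_rows: list[dict] = []
    expr_rows: list[dict] = []
    ann_rows: list[dict] = []

    def add_prediction(gene: str, mir: str, sources: Sequence[str]) -> None:
        for src in sources:
            if src == "predictorA":
                score = float(rng.uniform(-0.8, -0.05))
            else:
                score = float(rng.uniform(50.0, 100.0))
            pred_rows.append({"gene": gene, "mir": mir, "source": src, "score": score})

    for gene in planted:
        mir = hit_mirs[int(rng.integers(len(hit_mirs)))]
        for src, score in (
            ("predictorA", float(rng.uniform(-0.9, -0.5))),
            ("predictorB", float(rng.uniform(85.0, 99.0))),
        ):
            pred_rows.append({"gene": gene, "mir": mir, "source": src, "score": score})
        expr_rows.append({"gene": gene, "call": "present"})
        ann_rows.append(
            {"gene": gene, "growth_related": True, "leukemia_oncogenesis_literature": True}
        )

    for gene in decoys:
        region = all_regions[int(rng.choice(len(all_regions), p=region_p))]
        in1 = "1" in region
        in2 = "2" in region
        in3 = "3" in region
        if in1:
            mir = hit_mirs[int(rng.integers(len(hit_mirs)))]
            both = rng.random() < dual_source_rate
            sources = (
                ["predictorA", "predictorB"]
                if both
                else [["predictorA", "predictorB"][int(rng.integers(2))]]
            )
            add_prediction(gene, mir, sources)
        if in2:
            mir = non_hit_mirs[int(rng.integers(len(non_hit_mirs)))]
            src = ["predictorA", "predictorB"][int(rng.integers(2))]
            add_prediction(gene, mir, [src])
        if in3:
            call = "present" if rng.random() < 0.8 else "marginal"
        else:
            call = "absent"
        expr_rows.append({"gene": gene, "call": call})
        growth = bool(rng.random() < growth_related_rate)
        lit = bool(growth and rng.random() < literature_rate)
        ann_rows.append(
            {"gene": gene, "growth_related": growth, "leukemia_oncogenesis_literature": lit}
        )

    predictions = pd.DataFrame(pred_rows, columns=["gene", "mir", "source", "score"])
    expression = pd.DataFrame(expr_rows, columns=["gene", "call"])
    annotations = pd.DataFrame(
        ann_rows, columns=["gene", "growth_related", "leukemia_oncogenesis_literature"]
    )
    return predictions, expression, annotations


# ---------------------------------------------------------------------------
# planted 3'UTR sequences

_BASES = np.array(list("ACGT"))


def plant_utr_sites(
    utr_length: int,
    mir_seq: str,
    site_positions: Sequence[int],
    site_types: Sequence[str],
    rng_seed: int = 0,
    record_id: str = "synthetic_utr",
) -> SeqRecord:
    """A random-background UTR carrying seed matches only where requested.

    Sites are planted at the given 1-based starts with the requested
    classes; background positions are re-drawn until a scan reports exactly
    the planted sites, so spurious matches cannot arise.
    """
    sites = site_sequences(mir_seq)
    requested: list[tuple[int, str, str]] = []
    spans: list[tuple[int, int]] = []
    if len(site_positions) != len(site_types):
        raise ValueError("site_positions and site_types must align")
    for start, cls in zip(site_positions, site_types):
        if cls not in sites:
            raise ValueError(f"unknown site class {cls!r}")
        end = start + len(sites[cls]) - 1
        if start < 1 or end > utr_length:
            raise ValueError(f"site {cls} at {start} exceeds UTR bounds")
        for a, b in spans:
            if start <= b and end >= a:
                raise ValueError("planted sites overlap")
        spans.append((start, end))
        requested.append((start, end, cls))

    rng = np.random.default_rng(rng_seed)
    seq = rng.choice(len(_BASES), size=utr_length)
    background = np.ones(utr_length, dtype=bool)
    site_arr = {cls: np.array([("ACGT".index(b)) for b in s]) for cls, s in sites.items()}
    for start, end, cls in requested:
        seq[start - 1 : end] = site_arr[cls]
        background[start - 1 : end] = False

    want = {(s, e, c) for s, e, c in requested}
    for _ in range(500):
        text = "".join(_BASES[seq])
        found = {(m.start, m.end, m.site_class) for m in find_seed_sites(text, mir_seq)}
        spurious = found - want
        if not spurious and want <= found:
            sites_out = sorted(requested)
            desc = "planted sites: " + "; ".join(
                f"{c} {s}-{e}" for s, e, c in sites_out
            )
            return SeqRecord(Seq(text), id=record_id, description=desc)
        # re-draw the background positions of each spurious window
        for s, e, _ in spurious:
            idx = np.arange(s - 1, e)
            idx = idx[background[idx]]
            seq[idx] = rng.choice(len(_BASES), size=len(idx))
    raise RuntimeError("could not build a spurious-match-free background")


# ---------------------------------------------------------------------------
# flow-event fixtures for the validation assays


def simulate_quadrant_events(
    n_events: int,
    weights: Sequence[float],
    thresholds: tuple[float, float] = (100.0, 100.0),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Two-channel event table (e.g. Annexin V vs 7-AAD) drawn from a
    4-component mixture with quadrant weights (-/-, +/-, -/+, +/+)."""
    w = np.asarray(weights, dtype=float)
    if len(w) != 4 or w.min() < 0 or abs(w.sum() - 1) > 1e-9:
        raise ValueError("weights must be 4 non-negative fractions summing to 1")
    rng = np.random.default_rng(rng_seed)
    tx, ty = thresholds
    quadrant = rng.choice(4, size=n_events, p=w)
    x_neg = rng.uniform(tx * 0.1, tx * 0.9, size=n_events)
    x_pos = rng.uniform(tx * 1.1, tx * 5.0, size=n_events)
    y_neg = rng.uniform(ty * 0.1, ty * 0.9, size=n_events)
    y_pos = rng.uniform(ty * 1.1, ty * 5.0, size=n_events)
    x = np.where(np.isin(quadrant, (1, 3)), x_pos, x_neg)
    y = np.where(np.isin(quadrant, (2, 3)), y_pos, y_neg)
    return pd.DataFrame({"channel_x": x, "channel_y": y})


def simulate_cell_cycle_events(
    n_events: int,
    fractions: Mapping[str, float],
    rng_seed: int = 0,
) -> pd.DataFrame:
    """DNA-content / BrdU event table from a mixture over cell-cycle phases
    {subG1, G0/G1, S, G2/M}; 2N DNA content sits at 100, 4N at 200."""
    phases = ("subG1", "G0/G1", "S", "G2/M")
    w = np.array([fractions.get(p, 0.0) for p in phases], dtype=float)
    if w.min() < 0 or abs(w.sum() - 1) > 1e-9:
        raise ValueError("phase fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(rng_seed)
    phase = rng.choice(4, size=n_events, p=w)
    dna = np.empty(n_events)
    brdu = np.empty(n_events)
    dna[phase == 0] = rng.uniform(30, 75, size=(phase == 0).sum())
    dna[phase == 1] = rng.normal(100, 5, size=(phase == 1).sum())
    dna[phase == 2] = rng.uniform(95, 205, size=(phase == 2).sum())
    dna[phase == 3] = rng.normal(200, 6, size=(phase == 3).sum())
    brdu[phase != 2] = rng.uniform(1, 15, size=(phase != 2).sum())
    brdu[phase == 2] = rng.uniform(60, 200, size=(phase == 2).sum())
    return pd.DataFrame({"dna": dna, "brdu": brdu})
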