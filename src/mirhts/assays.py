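"""Normalization arithmetic for the validation assays.

Dual-luciferase reporters (firefly normalized to renilla, mimic vs
construct-only), alamarBlue growth folds against the empty-vector
baseline, flow-cytometry quadrant and cell-cycle phase frequencies,
western-blot densitometry against a loading control, and the
ORF-co-expression rescue comparison. All are ratios of means or means of
ratios, so every statistic here is invariant to global instrument gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReporterWell:
    """One dual-luciferase well."""

    firefly: float
    renilla: float
    construct: str = ""
    mimic: str | None = None

    def __post_init__(self) -> None:
        if not self.renilla > 0:
            raise ValueError("renilla signal must be positive")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla


def relative_luciferase(
    wells_with_mimic: Sequence[ReporterWell],
    wells_construct_only: Sequence[ReporterWell],
) -> float:
    """Mean firefly/renilla ratio of mimic-co-transfected wells over that of
    wells carrying only the reporter construct.

    Aggregation is the mean of well-level ratios (not the ratio of summed
    signals), so each well's transfection efficiency is normalized first.
    """
    if not wells_with_mimic or not wells_construct_only:
        raise ValueError("both well groups must be non-empty")
    constructs = {w.construct for w in wells_with_mimic} | {
        w.construct for w in wells_construct_only
    }
    if len(constructs) > 1:
        raise ValueError("well groups mix reporter constructs")
    num = float(np.mean([w.ratio for w in wells_with_mimic]))
    den = float(np.mean([w.ratio for w in wells_construct_only]))
    return num / den


def growth_fold(
    readings_test: Sequence[float],
    readings_reference: Sequence[float],
    blank: float = 0.0,
) -> float:
    """Blank-subtracted mean fluorescence of a test culture over the
    empty-vector reference (alamarBlue-style readout)."""
    ref = float(np.mean(readings_reference))
    if ref <= blank:
        raise ValueError("reference mean must exceed the blank")
    return (float(np.mean(readings_test)) - blank) / (ref - blank)


def quadrant_frequencies(
    events: pd.DataFrame,
    x_channel: str = "channel_x",
    y_channel: str = "channel_y",
    x_threshold: float = 100.0,
    y_threshold: float = 100.0,
) -> dict[str, float]:
    """Event fractions per quadrant of a two-channel plot.

    Keys: '--' (double negative), '+-' (x positive only), '-+' (y positive
    only), '++' (double positive). Fractions sum to 1.
    """
    if events.empty:
        raise ValueError("event table is empty")
    x_pos = events[x_channel].to_numpy() > x_threshold
    y_pos = events[y_channel].to_numpy() > y_threshold
    n = len(events)
    return {
        "--": float((~x_pos & ~y_pos).sum() / n),
        "+-": float((x_pos & ~y_pos).sum() / n),
        "-+": float((~x_pos & y_pos).sum() / n),
        "++": float((x_pos & y_pos).sum() / n),
    }


def cell_cycle_fractions(
    events: pd.DataFrame,
    dna_channel: str = "dna",
    brdu_channel: str = "brdu",
    brdu_threshold: float = 30.0,
    subg1_max: float = 80.0,
    g1_max: float = 150.0,
) -> dict[str, float]:
    """BrdU/DNA-content phase frequencies.

    S phase is all BrdU+ events; BrdU- events split by DNA content into
    subG1 (below the 2N window), G0/G1 (2N) and G2/M (4N). Fractions sum
    to 1.
    """
    if events.empty:
        raise ValueError("event table is empty")
    dna = events[dna_channel].to_numpy()
    s_phase = events[brdu_channel].to_numpy() > brdu_threshold
    n = len(events)
    neg = ~s_phase
    return {
        "subG1": float((neg & (dna < subg1_max)).sum() / n),
        "G0/G1": float((neg & (dna >= subg1_max) & (dna < g1_max)).sum() / n),
        "S": float(s_phase.sum() / n),
        "G2/M": float((neg & (dna >= g1_max)).sum() / n),
    }


def densitometry_relative(
    band: float, loading: float, ref_band: float, ref_loading: float
) -> float:
    """Loading-normalized band intensity relative to the reference lane."""
    if loading <= 0 or ref_loading <= 0:
        raise ValueError("loading-control intensities must be positive")
    return (band / loading) / (ref_band / ref_loading)


def rescue_effect(
    growth_mir_plus_ev: float,
    growth_mir_plus_orf: float,
    growth_ev_ev: float,
) -> dict[str, float]:
    """Rescue comparison for ORF co-expression.

    Returns percent growth gained by the ORF over the miR-plus-empty-vector
    condition, and the miR condition's percent growth deficit against the
    double-empty-vector baseline.
    """
    if growth_mir_plus_ev <= 0:
        raise ValueError("miR + empty-vector growth must be positive")
    rescue = 100.0 * (growth_mir_plus_orf - growth_mir_plus_ev) / growth_mir_plus_ev
    deficit = 100.0 * (1.0 - growth_mir_plus_ev / growth_ev_ev)
    return {"pct_rescue": rescue, "pct_deficit_vs_baseline": deficit}


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Convenience two-sample Student's t (plumbing; equal variances)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
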