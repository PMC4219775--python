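"""Candidate calling for pooled lentiviral miR dropout screens.

Each replicate screen tracks every construct's qPCR-detected abundance at a
reference timepoint (day 4 after infection) and several later timepoints.
A construct whose abundance collapses at the later timepoints was carried
by cells that were out-grown, i.e. the miR it encodes inhibits growth.
Two calling rules operate per replicate:

* depletion — detected at the reference timepoint, then falling below a
  ratio threshold of the reference abundance at enough later timepoints
  (non-detection counts as zero abundance);
* never-detected rescue — absent at every timepoint here but detected at
  the reference timepoint in another cell line screened with the same
  library batch, consistent with inhibition too strong to ever observe.

Candidates are consensus calls across replicate screens, and validation
bookkeeping tracks the fraction of consensus candidates confirmed by
follow-up growth assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Columns of one replicate's tidy detection table.
DETECTION_COLUMNS = ("construct", "timepoint_day", "abundance", "detected")


class ValidationStatus(str, Enum):
    UNTESTED = "untested"
    VALIDATED = "validated"
    NOT_VALIDATED = "not-validated"


@dataclass
class ScreenDataset:
    """Multi-replicate pooled-screen detection tables plus provenance.

    replicates            one tidy DataFrame per replicate screen with
                          columns (construct, timepoint_day, abundance,
                          detected)
    reference_timepoint   day used as the depletion baseline
    cell_line_label       screened cell line
    cross_line_reference  constructs detected at the reference timepoint in
                          other cell lines screened with the same library
    truth_fitness         simulation ground truth (construct -> per-day w),
                          present only for synthetic datasets
    metadata              free-form provenance (scenario echo, model notes)
    """

    replicates: list[pd.DataFrame]
    reference_timepoint: float = 4.0
    cell_line_label: str = ""
    cross_line_reference: frozenset[str] = frozenset()
    truth_fitness: Mapping[str, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("dataset needs at least one replicate table")
        ref = None
        for i, tab in enumerate(self.replicates):
            missing = set(DETECTION_COLUMNS) - set(tab.columns)
            if missing:
                raise ValueError(f"replicate {i} missing columns {sorted(missing)}")
            key = (
                frozenset(tab["construct"].unique()),
                frozenset(tab["timepoint_day"].unique()),
            )
            if ref is None:
                ref = key
            elif key != ref:
                raise ValueError("replicates must cover identical constructs and timepoints")
        if self.reference_timepoint not in ref[1]:
            raise ValueError("reference_timepoint absent from timepoints")

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.replicates[0]["timepoint_day"].unique())

    @property
    def constructs(self) -> list[str]:
        return sorted(self.replicates[0]["construct"].unique())


@dataclass
class CandidateCall:
    """One construct's calling record across replicate screens."""

    construct: str
    per_replicate_depleted: list[bool]
    per_replicate_rescued: list[bool]
    consensus: bool
    validation: ValidationStatus = ValidationStatus.UNTESTED

    @property
    def per_replicate_positive(self) -> list[bool]:
        return [
            d or r
            for d, r in zip(self.per_replicate_depleted, self.per_replicate_rescued)
        ]


def call_depleted(
    replicate_table: pd.DataFrame,
    reference_timepoint: float,
    depletion_ratio: float = 0.5,
    min_later_tps: int = 2,
) -> set[str]:
    """Constructs detected at the reference timepoint whose abundance falls to
    <= depletion_ratio of the reference at >= min_later_tps later timepoints.

    Non-detection counts as zero abundance, so a construct detected only at
    the reference timepoint is called (the pattern sporadic low-template
    amplification produces). Ties at exactly the threshold count as depleted.
    """
    if not 0 < depletion_ratio <= 1:
        raise ValueError("depletion_ratio must lie in (0, 1]")
    tab = replicate_table
    tps = sorted(tab["timepoint_day"].unique())
    if reference_timepoint not in tps:
        raise ValueError("reference timepoint not present in table")
    later = [t for t in tps if t > reference_timepoint]
    wide_ab = tab.pivot_table(index="construct", columns="timepoint_day", values="abundance")
    wide_det = tab.pivot_table(index="construct", columns="timepoint_day", values="detected")
    effective = wide_ab.where(wide_det.astype(bool), other=0.0)
    at_ref = wide_det[reference_timepoint].astype(bool)
    ref_ab = effective[reference_timepoint]
    n_below = (effective[later].le(depletion_ratio * ref_ab, axis=0)).sum(axis=1)
    called = at_ref & (n_below >= min_later_tps)
    return set(called.index[called])


def rescue_never_detected(
    replicate_table: pd.DataFrame, cross_line_reference: Iterable[str]
) -> set[str]:
    """Flag constructs never detected in this screen that the same library
    batch did yield at the reference timepoint in another cell line."""
    cross = set(cross_line_reference)
    det = replicate_table.groupby("construct")["detected"].any()
    never = set(det.index[~det.astype(bool)])
    return never & cross


def consensus_candidates(
    per_replicate_calls: Sequence[set[str]], min_screens: int = 2
) -> set[str]:
    """Constructs called positive in at least ``min_screens`` replicates."""
    if not per_replicate_calls:
        raise ValueError("no replicate call sets given")
    if min_screens > len(per_replicate_calls):
        raise ValueError("min_screens exceeds number of replicates")
    counts: dict[str, int] = {}
    for calls in per_replicate_calls:
        for c in calls:
            counts[c] = counts.get(c, 0) + 1
    return {c for c, n in counts.items() if n >= min_screens}


def call_candidates(
    dataset: ScreenDataset,
    depletion_ratio: float = 0.5,
    min_later_tps: int = 2,
    min_screens: int = 2,
) -> list[CandidateCall]:
    """Run both per-replicate rules and take the replicate consensus."""
    depleted = [
        call_depleted(tab, dataset.reference_timepoint, depletion_ratio, min_later_tps)
        for tab in dataset.replicates
    ]
    rescued = [
        rescue_never_detected(tab, dataset.cross_line_reference)
        for tab in dataset.replicates
    ]
    positive = [d | r for d, r in zip(depleted, rescued)]
    consensus = consensus_candidates(positive, min_screens)
    calls = []
    for c in dataset.constructs:
        calls.append(
            CandidateCall(
                construct=c,
                per_replicate_depleted=[c in s for s in depleted],
                per_replicate_rescued=[c in s for s in rescued],
                consensus=c in consensus,
            )
        )
    return calls


def validation_rate(calls: Iterable[CandidateCall]) -> float:
    """Percent of tested consensus candidates that validated in follow-up."""
    tested = [
        c
        for c in calls
        if c.consensus and c.validation is not ValidationStatus.UNTESTED
    ]
    if not tested:
        raise ValueError("no tested consensus candidates")
    validated = sum(c.validation is ValidationStatus.VALIDATED for c in tested)
    return 100.0 * validated / len(tested)


def calls_to_frame(calls: Iterable[CandidateCall]) -> pd.DataFrame:
    """Tidy candidate table for writing to TSV."""
    rows = []
    for c in calls:
        row = {"construct": c.construct}
        for i, (d, r) in enumerate(
            zip(c.per_replicate_depleted, c.per_replicate_rescued), start=1
        ):
            row[f"rep{i}_depleted"] = d
            row[f"rep{i}_rescued"] = r
        row["consensus"] = c.consensus
        row["validation"] = c.validation.value
        rows.append(row)
    return pd.DataFrame(rows)
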