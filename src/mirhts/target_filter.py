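"""Multi-source miR-target prioritization and 3'UTR seed-site scanning.

The prioritization funnel intersects three gene sets — predicted targets
of the growth-inhibitory (hit) miRs from either prediction source, minus
predicted targets of miRs shown not to inhibit growth, restricted to genes
with detectable expression in the screened cell line — then shortlists the
survivors by growth-regulation annotation and by prediction strength
(dual-source support, context scores).

The seed-site scanner locates canonical miR seed matches on a 3'UTR sense
strand: sites are reverse complements of miR positions 2-7/2-8, with an
adenine opposite miR position 1 defining the A1 classes. Site classes in
decreasing strength: 8mer-A1, 7mer-m8, 7mer-A1; the longest class wins at
a locus. Coordinates are 1-based inclusive on the UTR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

PREDICTION_COLUMNS = ("gene", "mir", "source", "score")
EXPRESSION_COLUMNS = ("gene", "call")
ANNOTATION_COLUMNS = ("gene", "growth_related", "leukemia_oncogenesis_literature")

EXPRESSION_CALLS = ("absent", "marginal", "present")
SITE_CLASSES = ("8mer-A1", "7mer-m8", "7mer-A1")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


@dataclass(frozen=True)
class SeedSite:
    """A located seed match, 1-based inclusive on the UTR sense strand."""

    start: int
    end: int
    site_class: str
    mir: str = ""

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.end - self.start + 1 not in (7, 8):
            raise ValueError("seed sites span 7 or 8 nucleotides")


def _norm_symbol(gene: str) -> str:
    return gene.strip().upper()


def _normalize_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    missing = set(PREDICTION_COLUMNS) - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns {sorted(missing)}")
    tab = predictions.copy()
    tab["gene"] = tab["gene"].map(_norm_symbol)
    if tab.duplicated(["gene", "mir", "source"]).any():
        raise ValueError("(gene, mir, source) rows must be unique")
    return tab


def build_sets(
    predictions: pd.DataFrame,
    hit_mirs: Iterable[str],
    non_hit_mirs: Iterable[str],
    expression: pd.DataFrame,
) -> tuple[set[str], set[str], set[str]]:
    """The three gene sets of the prioritization funnel.

    Set 1: predicted targets of any hit miR, either source.
    Set 2: predicted targets of any non-hit miR, either source. A miR whose
           overexpression could not be confirmed belongs in neither group
           and simply contributes no targets.
    Set 3: genes whose expression call is marginal or present.
    """
    hits, non_hits = set(hit_mirs), set(non_hit_mirs)
    if hits & non_hits:
        raise ValueError(f"miRs in both groups: {sorted(hits & non_hits)}")
    tab = _normalize_predictions(predictions)
    set1 = set(tab.loc[tab["mir"].isin(hits), "gene"])
    set2 = set(tab.loc[tab["mir"].isin(non_hits), "gene"])
    missing = set(EXPRESSION_COLUMNS) - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    expr = expression.copy()
    bad = set(expr["call"]) - set(EXPRESSION_CALLS)
    if bad:
        raise ValueError(f"unknown expression calls {sorted(bad)}")
    expr["gene"] = expr["gene"].map(_norm_symbol)
    set3 = set(expr.loc[expr["call"].isin(("marginal", "present")), "gene"])
    return set1, set2, set3


def filter_targets(set1: set[str], set2: set[str], set3: set[str]) -> set[str]:
    """Expressed predicted hit-miR targets not shared with non-hit miRs:
    (Set1 ∩ Set3) \\ Set2."""
    return (set1 & set3) - set2


def annotate_and_shortlist(
    genes: Iterable[str],
    annotations: pd.DataFrame,
    predictions: pd.DataFrame,
    hit_mirs: Iterable[str],
) -> pd.DataFrame:
    """Reduce funnel survivors to a ranked shortlist.

    Keeps genes annotated growth-related (genes absent from the annotation
    table count as not growth-related). Within those, a gene is shortlisted
    when it is (a) literature-linked to leukemia/oncogenesis, or (b)
    predicted for at least one hit miR by both sources. Shortlisted genes
    are ranked by best (most negative) predictorA context score, ties by
    best (highest) predictorB target score, then alphabetically.

    Returns a DataFrame over the growth-related genes with boolean columns
    ``literature``, ``both_sources`` and ``shortlisted``, sorted with the
    shortlist first in rank order.
    """
    genes = {_norm_symbol(g) for g in genes}
    hits = set(hit_mirs)
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    ann = annotations.copy()
    ann["gene"] = ann["gene"].map(_norm_symbol)
    ann = ann.set_index("gene")
    tab = _normalize_predictions(predictions)
    tab = tab[tab["mir"].isin(hits) & tab["gene"].isin(genes)]

    rows = []
    for gene in sorted(genes):
        growth = bool(ann.at[gene, "growth_related"]) if gene in ann.index else False
        if not growth:
            continue
        lit = (
            bool(ann.at[gene, "leukemia_oncogenesis_literature"])
            if gene in ann.index
            else False
        )
        sub = tab[tab["gene"] == gene]
        # dual-source support must come from a single hit miR
        both = bool(
            (sub.groupby("mir")["source"].nunique() >= 2).any()
        )
        score_a = sub.loc[sub["source"] == "predictorA", "score"].min()
        score_b = sub.loc[sub["source"] == "predictorB", "score"].max()
        rows.append(
            {
                "gene": gene,
                "literature": lit,
                "both_sources": both,
                "shortlisted": lit or both,
                "best_context_score": score_a if pd.notna(score_a) else float("inf"),
                "best_target_score": score_b if pd.notna(score_b) else float("-inf"),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "literature",
            "both_sources",
            "shortlisted",
            "best_context_score",
            "best_target_score",
        ],
    )
    if frame.empty:
        return frame
    frame = frame.sort_values(
        by=["shortlisted", "best_context_score", "best_target_score", "gene"],
        ascending=[False, True, False, True],
    ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# seed-site scanning


def _clean_seq(seq: str, what: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise ValueError(f"empty {what}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def site_sequences(mir_seq: str) -> dict[str, str]:
    """The UTR sense-strand (5'->3') match sequence for each site class.

    The site is the reverse complement of miR positions 2-7 (7mer-A1) or
    2-8 (7mer-m8, 8mer-A1); the A1 classes add an adenine at the UTR
    position opposite miR position 1, which sits 3' of the seed complement.
    """
    mir = _clean_seq(mir_seq, "miR sequence")
    if len(mir) < 8:
        raise ValueError("miR sequence must be at least 8 nt")
    seed27 = mir[1:7]
    seed28 = mir[1:8]
    return {
        "8mer-A1": reverse_complement(seed28) + "A",
        "7mer-m8": reverse_complement(seed28),
        "7mer-A1": reverse_complement(seed27) + "A",
    }


def find_seed_sites(utr: str, mir_seq: str, mir_id: str = "") -> list[SeedSite]:
    """Scan a 3'UTR for canonical seed matches to one miR.

    Classes are assigned longest-first: a 7mer match whose span lies inside
    an 8mer-A1 span is the same locus and is suppressed. Windows containing
    ambiguous bases are skipped with a warning.
    """
    seq = _clean_seq(utr, "UTR sequence")
    sites = site_sequences(mir_seq)
    valid = set("ACGT")
    if set(seq) - valid:
        warnings.warn("UTR contains ambiguous bases; those positions are skipped")

    found: list[SeedSite] = []
    spans8: list[tuple[int, int]] = []
    n = len(seq)
    for start in range(n - 8 + 1):
        window = seq[start : start + 8]
        if set(window) - valid:
            continue
        if window == sites["8mer-A1"]:
            found.append(SeedSite(start + 1, start + 8, "8mer-A1", mir_id))
            spans8.append((start + 1, start + 8))

    def inside_8mer(a: int, b: int) -> bool:
        return any(a >= s and b <= e for s, e in spans8)

    classes_7 = ["7mer-m8"]
    # degenerate miRs can make both 7mer patterns identical; m8 outranks A1
    if sites["7mer-A1"] != sites["7mer-m8"]:
        classes_7.append("7mer-A1")
    for cls in classes_7:
        target = sites[cls]
        for start in range(n - 7 + 1):
            window = seq[start : start + 7]
            if set(window) - valid:
                continue
            if window == target and not inside_8mer(start + 1, start + 7):
                found.append(SeedSite(start + 1, start + 7, cls, mir_id))
    found.sort(key=lambda s: (s.start, s.end))
    return found


def apply_site_deletion(utr: str, site: SeedSite) -> str:
    """Excise a site's span from the UTR (the deletion-construct design)."""
    seq = utr.strip()
    if site.start < 1 or site.end > len(seq):
        raise ValueError("site out of UTR bounds")
    return seq[: site.start - 1] + seq[site.end :]


def sites_to_frame(sites: Iterable[SeedSite], gene: str = "") -> pd.DataFrame:
    rows = [
        {
            "gene": gene,
            "mir": s.mir,
            "start": s.start,
            "end": s.end,
            "site_class": s.site_class,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["gene", "mir", "start", "end", "site_class"])
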