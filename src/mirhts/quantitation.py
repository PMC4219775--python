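"""qPCR arithmetic: standard-curve absolute quantitation and relative expression.

The standard-curve model is the usual log-linear one: for starting template
``c`` copies per reaction, Ct = intercept + slope * log10(c), with slope
near -3.32 for a perfectly efficient assay (efficiency = 10^(-1/slope) - 1).
Absolute quantitation inverts the fitted line and divides by the number of
cell equivalents in the reverse-transcription input (10 ng total RNA at
12.5 pg/cell = 800 cells). Relative expression uses base-2 fold changes:
the delta-delta-Ct statistic against an endogenous control and a reference
sample, or a plain 2^-(target - control) ratio.

Undetermined Cts (no amplification) are represented as NaN; ``cap_ct``
assigns them the cap, and absolute quantitation reports them as
below-detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Sentinel for a reaction that never crossed threshold.
UNDETERMINED = float("nan")

#: Default Ct cap for relative quantitation.
CT_CAP = 35.0


def is_undetermined(ct: float) -> bool:
    return isinstance(ct, float) and math.isnan(ct)


@dataclass
class StandardCurve:
    """Fitted log-linear Ct-vs-copies relation.

    slope      Ct per log10(copies); negative (more template -> earlier Ct).
    intercept  Ct at a single copy.
    r2         coefficient of determination of the fit.
    lowest_standard  smallest copy number among the calibration points;
                     absolute calls below it are flagged below-detection.
    """

    slope: float
    intercept: float
    r2: float = 1.0
    lowest_standard: float = 1.0

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError("standard-curve slope must be negative")
        eff = self.efficiency
        if not 0 < eff <= 1.2:
            warnings.warn(
                f"amplification efficiency {eff:.3f} outside (0, 1.2]",
                stacklevel=2,
            )

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 1.0 for perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class CellEquivalents:
    """Cell equivalents in a reverse-transcription input."""

    rna_input_ng: float
    rna_per_cell_pg: float = 12.5

    @property
    def cells(self) -> float:
        cells = self.rna_input_ng * 1000.0 / self.rna_per_cell_pg
        if not cells > 0:
            raise ValueError("cell equivalents must be positive")
        return cells


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies) over dilution-series points.

    Requires at least 3 points spanning at least 2 decades of template.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    copies = np.array([c for c, _ in points], dtype=float)
    cts = np.array([ct for _, ct in points], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("standard-curve copies must be positive")
    x = np.log10(copies)
    if x.max() - x.min() < 2.0:
        raise ValueError("standard curve must span >= 2 log10 decades")
    if np.allclose(cts, cts[0]):
        raise ValueError("identical Cts at all dilutions: singular fit")
    res = stats.linregress(x, cts)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        lowest_standard=float(copies.min()),
    )


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies per reaction = 10^((ct-b)/m).

    An undetermined Ct returns NaN (below detection); callers that need a
    printable value should compare against ``curve.lowest_standard``.
    """
    if is_undetermined(ct):
        return UNDETERMINED
    if not math.isfinite(ct):
        raise ValueError("Ct must be finite")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def below_detection(copies_per_reaction: float, curve: StandardCurve) -> bool:
    """True when a call falls under the curve's calibrated range."""
    return is_undetermined(copies_per_reaction) or copies_per_reaction < curve.lowest_standard


def copies_per_cell(copies_per_reaction: float, cells: CellEquivalents) -> float:
    if is_undetermined(copies_per_reaction):
        return UNDETERMINED
    return copies_per_reaction / cells.cells


def cap_ct(ct: float, cap: float = CT_CAP) -> float:
    """Assign the cap to late or undetermined Cts for fold-change work."""
    if is_undetermined(ct):
        return cap
    return min(ct, cap)


def ddct_fold(
    target_ct: float,
    control_ct: float,
    ref_target_ct: float,
    ref_control_ct: float,
) -> float:
    """Fold change 2^-ddCt of target vs an endogenous control, relative to a
    reference sample. Cts are expected to be capped already."""
    ddct = (target_ct - control_ct) - (ref_target_ct - ref_control_ct)
    return 2.0 ** (-ddct)


def ratio_to_control(target_ct: float, control_ct: float) -> float:
    """Within-sample expression ratio 2^-(target - control)."""
    return 2.0 ** (-(target_ct - control_ct))
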