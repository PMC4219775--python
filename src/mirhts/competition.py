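"""Selection-coefficient estimation from GFP-competition time series.

A culture mixing transduced (GFP+) and untransduced cells is a
two-population exponential competition: if the transduced population has
per-day log relative fitness ``s``, the GFP+ fraction follows

    p_t = p0 * exp(s*t) / (p0 * exp(s*t) + (1 - p0))

which is exactly linear on the logit scale, logit(p_t) = logit(p0) + s*t.
Ordinary least squares of logit(p) on day therefore recovers ``s`` as the
slope and the day-0 fraction from the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit


@dataclass
class CompetitionSeries:
    """%GFP+ measurements over days for one culture.

    ``pct_gfp`` may be given as proportions in [0, 1] or as percentages in
    [0, 100]; fitting normalizes either to proportions, so the estimated
    slope does not depend on the unit.
    """

    days: Sequence[float]
    pct_gfp: Sequence[float]
    replicate: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(days) < 0):
            raise ValueError("days must be non-decreasing")
        frac = np.asarray(self.pct_gfp, dtype=float)
        if frac.shape != days.shape:
            raise ValueError("days and pct_gfp must have equal length")


@dataclass
class SelectionFit:
    """Fitted per-day selection coefficient for one competition series."""

    s: float
    se: float
    p0_hat: float
    n_points: int
    label: str = ""
    replicate: int = 0


def _as_proportions(values: np.ndarray) -> np.ndarray:
    if np.nanmax(values) > 1.0:
        return values / 100.0
    return values


def fit_selection(series: CompetitionSeries, pseudo: float = 5e-5) -> SelectionFit:
    """Estimate the per-day selection coefficient by logit-linear OLS.

    Fractions are clamped to [pseudo, 1 - pseudo] so observed 0% or 100%
    measurements stay finite on the logit scale. The default pseudo-count
    corresponds to half an event out of 10^4 flow events per measurement.
    """
    days = np.asarray(series.days, dtype=float)
    frac = _as_proportions(np.asarray(series.pct_gfp, dtype=float))
    if len(np.unique(days)) < 2:
        raise ValueError("need measurements on at least 2 distinct days")
    if not 0 < pseudo < 0.5:
        raise ValueError("pseudo must lie in (0, 0.5)")
    clamped = np.clip(frac, pseudo, 1.0 - pseudo)
    if np.all(clamped <= pseudo) or np.all(clamped >= 1.0 - pseudo):
        raise ValueError("series degenerate after clamping (all 0 or all 1)")
    y = logit(clamped)
    res = stats.linregress(days, y)
    se = float(res.stderr) if len(days) > 2 else float("nan")
    return SelectionFit(
        s=float(res.slope),
        se=se,
        p0_hat=float(expit(res.intercept)),
        n_points=int(len(days)),
        label=series.label,
        replicate=series.replicate,
    )


def project(p0: float, s: float, t: float) -> float:
    """Forward-model the GFP+ fraction at day ``t`` under the fitted model."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    # logit-space form avoids overflow for extreme s*t
    return float(expit(logit(p0) + s * np.asarray(t, dtype=float)))


def classify_inhibitory(
    fit: SelectionFit, alpha: float = 0.05, s_threshold: float = 0.0
) -> bool:
    """Call a construct growth-inhibitory when the one-sided upper confidence
    bound of its selection coefficient falls below ``s_threshold``.

    A fit with undefined standard error (two-point series) cannot be
    classified and returns False.
    """
    if not np.isfinite(fit.s):
        raise ValueError("fit has non-finite selection coefficient")
    if not np.isfinite(fit.se):
        return False
    z = stats.norm.ppf(1.0 - alpha)
    return bool(fit.s + z * fit.se < s_threshold)
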