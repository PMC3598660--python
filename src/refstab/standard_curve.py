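"""Standard-curve fitting and amplification-efficiency estimation.

A qPCR standard curve is an ordinary least-squares fit of mean Cq against
log10 of the template input amount over a serial dilution.  For an assay
amplifying by a factor ``1 + E/100`` each cycle, a 10-fold dilution shifts
Cq by ``-1/log10(1 + E/100)`` cycles, so the slope ``m`` of the fitted line
determines the percent efficiency

    E = (10 ** (-1/m) - 1) * 100,

with m = -3.3219 corresponding to perfect doubling (E = 100%).

Real dilution series often lose linearity at the extremes: the most dilute
points drop below the detection limit and the most concentrated ones
saturate the reaction.  :func:`select_linear_range` automates the usual
manual trimming by scanning every contiguous sub-range of the series and
keeping the one with the best coefficient of determination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, SingularFitError
from .io import DilutionPoint

#: Efficiencies outside this band are flagged (not rejected) in summaries.
EFFICIENCY_WARN_BAND = (90.0, 110.0)


@dataclass(frozen=True)
class StandardCurveFit:
    """Result of fitting one gene's standard curve.

    slope is in cycles per log10 dilution step (negative for a valid
    assay); intercept is the predicted Cq at 1 unit of input amount;
    ``efficiency_percent`` always equals the slope pushed through
    :func:`efficiency_from_slope`; ``range_used`` is (min, max) input
    amount of the points that entered the fit.
    """

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    range_used: tuple[float, float]
    n_points: int

    @property
    def efficiency_in_typical_band(self) -> bool:
        lo, hi = EFFICIENCY_WARN_BAND
        return lo <= self.efficiency_percent <= hi


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    Computes ``(10 ** (-1/slope) - 1) * 100``.  The value is not clamped:
    efficiencies above 100% (slope shallower than -3.32) are reported as-is,
    since they are routinely observed and diagnostically meaningful.

    Raises :class:`DomainError` for non-negative or non-finite slopes.
    """
    if not math.isfinite(slope) or slope >= 0:
        raise DomainError(
            f"efficiency is undefined for non-negative slope (got {slope});"
            " a valid standard curve has Cq decreasing with input amount"
        )
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def _usable_points(points: list[DilutionPoint]) -> list[DilutionPoint]:
    """Points with at least one non-missing replicate, descending amount."""
    usable = [p for p in points if p.mean_cq is not None]
    return sorted(usable, key=lambda p: -p.input_amount)


def fit_standard_curve(points: list[DilutionPoint]) -> StandardCurveFit:
    """OLS fit of per-amount mean Cq on log10(input amount) for one gene.

    Replicate Cq values are averaged per amount before fitting, so each
    concentration contributes one point regardless of replicate count.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 amounts with at least one detected replicate.
    SingularFitError
        All usable amounts identical (zero spread in log10 amount).
    """
    if not points:
        raise InsufficientDataError("no dilution points supplied")
    gene_id = points[0].gene_id
    usable = _usable_points(points)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"gene {gene_id}: {len(usable)} usable amounts, need >= 3"
        )
    x = np.log10([p.input_amount for p in usable])
    y = np.array([p.mean_cq for p in usable])
    if np.ptp(x) == 0:
        raise SingularFitError(f"gene {gene_id}: zero variance in log10 amounts")
    res = stats.linregress(x, y)
    return StandardCurveFit(
        gene_id=gene_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency_percent=efficiency_from_slope(float(res.slope)),
        range_used=(usable[-1].input_amount, usable[0].input_amount),
        n_points=len(usable),
    )


def select_linear_range(
    points: list[DilutionPoint], min_points: int = 4
) -> tuple[list[DilutionPoint], StandardCurveFit]:
    """Pick the contiguous sub-range of a dilution series that fits best.

    Amounts whose Cq is entirely missing (non-detects at the dilute end)
    are dropped first.  Every contiguous sub-range of the remaining
    amounts, ordered by amount, with at least ``min_points`` points is
    fitted; the sub-range with the highest R-squared wins.  Ties (within
    1e-9) are resolved toward the wider range, then toward the range with
    larger amounts, which preserves dynamic range.

    Returns the winning points (descending amount) and their fit.
    """
    usable = _usable_points(points)
    if len(usable) < min_points:
        raise InsufficientDataError(
            f"{len(usable)} usable amounts, need >= {min_points}"
        )
    candidates: list[tuple[float, int, float, list[DilutionPoint]]] = []
    n = len(usable)
    for start in range(n):
        for stop in range(start + min_points, n + 1):
            sub = usable[start:stop]
            fit = fit_standard_curve(sub)
            candidates.append((fit.r_squared, len(sub), sub[0].input_amount, sub))
    best_r2 = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] >= best_r2 - 1e-9]
    tied.sort(key=lambda c: (c[1], c[2]), reverse=True)
    _, _, _, winner = tied[0]
    return winner, fit_standard_curve(winner)
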