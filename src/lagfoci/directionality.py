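"""Directionality index: which channel of a pair leads the other.

For an ordered pair (p, q), let a = r_pq(delta) be the lagged correlation
with q delayed and b = r_qp(delta) the reverse.  The directionality measure
is the maximum over admissible lags of the symmetric relative difference,

    directionality [%] = max_delta  2 |a - b| / (a + b) * 100,

and the channel whose forward correlation is larger at the maximising lag is
inferred to be the source: if a > b, p leads and q repeats it after delta.
Lags where either coefficient is non-positive or the denominator nearly
vanishes are excluded, since the ratio is unstable there.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import UndefinedDirectionalityError
from .lagcorr import LagCurve, LagGrid, correlation_curve
from .signal_io import Recording

__all__ = ["DirectionalityResult", "directionality", "pairwise_directionality"]

#: Minimum value of r_pq + r_qp for a lag to enter the maximisation.
MIN_COEFF_SUM = 0.05


@dataclasses.dataclass
class DirectionalityResult:
    """Directionality percentage, maximising lag, and inferred source."""

    pair: tuple[str, str]
    percent: float
    lag_ms: float
    source: str

    def __post_init__(self):
        if self.percent < 0:
            raise ValueError("directionality percentage cannot be negative")
        if self.source not in self.pair:
            raise ValueError("source must be one of the pair members")


def directionality(
    curve_pq: LagCurve, curve_qp: LagCurve, min_sum: float = MIN_COEFF_SUM
) -> DirectionalityResult:
    """Directionality of a pair from its two opposite-order lag curves.

    ``curve_pq`` holds r with q delayed against p, ``curve_qp`` the reverse
    order.  Ties in the maximisation are broken toward the smallest lag (the
    shorter physiological path); a fully symmetric pair therefore reports
    0 % with the locked channel as source by convention.
    """
    if not np.array_equal(curve_pq.lags_ms, curve_qp.lags_ms):
        raise ValueError("both curves must share one lag grid")
    p, q = curve_pq.pair
    if curve_qp.pair != (q, p):
        raise ValueError(
            f"curves must be the two orders of one pair, got {curve_pq.pair} and {curve_qp.pair}"
        )
    a = curve_pq.r
    b = curve_qp.r
    admissible = (
        np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0) & (a + b > min_sum)
    )
    if not np.any(admissible):
        raise UndefinedDirectionalityError(
            f"no admissible lag for pair ({p}, {q}): all coefficients non-positive "
            f"or sums below {min_sum}"
        )
    values = np.full(len(a), -np.inf)
    values[admissible] = 2.0 * np.abs(a - b)[admissible] / (a + b)[admissible] * 100.0
    best = np.flatnonzero(values == values.max())[0]  # smallest lag on ties
    source = p if a[best] >= b[best] else q
    return DirectionalityResult(
        (p, q), float(values[best]), float(curve_pq.lags_ms[best]), source
    )


def pairwise_directionality(
    rec: Recording,
    pairs: list[tuple[str, str]],
    grid: LagGrid | None = None,
    min_sum: float = MIN_COEFF_SUM,
) -> list[DirectionalityResult]:
    """Directionality for each ordered pair, in input order."""
    grid = grid or LagGrid()
    results = []
    for p, q in pairs:
        curve_pq = correlation_curve(rec, p, q, grid)
        curve_qp = correlation_curve(rec, q, p, grid)
        results.append(directionality(curve_pq, curve_qp, min_sum=min_sum))
    return results
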