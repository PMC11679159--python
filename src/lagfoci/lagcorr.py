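"""Lagged Bravais-Pearson correlation over a preset latency grid.

For an ordered pair of channels — the *locked* channel ``p`` and the
*delayed* channel ``q`` — and a latency ``delta`` the statistic is the
product-moment correlation of the aligned value pairs (p_i, q_{i+delta}):

    r_pq(delta) = cov(p_i, q_{i+delta}) / (sd(p_i) * sd(q_{i+delta}))

with means and standard deviations taken over the overlapping segment.
``r = +1`` means the delayed channel repeats the locked one after ``delta``,
``r = -1`` an anti-phase repeat, and values near zero incoherence.  Latencies
are evaluated on a preset grid (default 10-500 ms) realised as whole sample
shifts at the working rate; negative lags are expressed by swapping the pair
order rather than by a signed delta.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import (
    InsufficientOverlapError,
    UndefinedCorrelationError,
)
from .signal_io import Recording

__all__ = [
    "DEFAULT_LAGS_MS",
    "LagGrid",
    "LagCurve",
    "WindowedLagCurves",
    "lagged_correlation",
    "correlation_curve",
    "windowed_correlation",
    "latency_at_threshold",
]

#: Preset latency grid in milliseconds.
DEFAULT_LAGS_MS = (10.0, 20.0, 30.0, 50.0, 70.0, 100.0, 200.0, 250.0, 300.0, 400.0, 500.0)

_VAR_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class LagGrid:
    """Ordered latency grid in milliseconds."""

    lags_ms: tuple[float, ...] = DEFAULT_LAGS_MS

    def __post_init__(self):
        lags = tuple(float(l) for l in self.lags_ms)
        object.__setattr__(self, "lags_ms", lags)
        if not lags:
            raise ValueError("lag grid must not be empty")
        if any(l < 0 for l in lags):
            raise ValueError("lags must be non-negative; swap the pair for negative lags")
        if any(b <= a for a, b in zip(lags, lags[1:])):
            raise ValueError("lags must be strictly increasing")

    def shifts(self, rate: float) -> np.ndarray:
        """Whole-sample shifts realising each lag at ``rate`` Hz."""
        exact = np.asarray(self.lags_ms) * rate / 1000.0
        shifts = np.round(exact).astype(int)
        if np.any(np.abs(exact - shifts) > 1e-6):
            bad = [l for l, e, s in zip(self.lags_ms, exact, shifts) if abs(e - s) > 1e-6]
            raise ValueError(
                f"lags {bad} ms are not whole sample shifts at {rate} Hz"
            )
        return shifts


@dataclasses.dataclass
class LagCurve:
    """Correlation coefficient as a function of lag for one ordered pair."""

    pair: tuple[str, str]  # (locked p, delayed q)
    lags_ms: np.ndarray
    r: np.ndarray
    n: np.ndarray  # sample pairs used per lag

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.lags_ms) == len(self.r) == len(self.n)):
            raise ValueError("lags, r and n must align")
        finite = self.r[np.isfinite(self.r)]
        if np.any(np.abs(finite) > 1 + 1e-9):
            raise ValueError("correlation coefficients must lie in [-1, 1]")


@dataclasses.dataclass
class WindowedLagCurves:
    """Sliding-window lag curves: one row of coefficients per window."""

    pair: tuple[str, str]
    window_ms: float
    step_ms: float
    lags_ms: np.ndarray
    times: np.ndarray  # window start times (s)
    r: np.ndarray  # (n_windows, n_lags); NaN marks undefined windows
    n: int  # sample pairs per window

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.times), len(self.lags_ms)):
            raise ValueError("r must be (n_windows, n_lags)")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("window times must be strictly increasing")


def _whole_shift(lag_ms: float, rate: float) -> int:
    exact = lag_ms * rate / 1000.0
    shift = int(round(exact))
    if abs(exact - shift) > 1e-6:
        raise ValueError(f"lag {lag_ms} ms is not a whole sample shift at {rate} Hz")
    return shift


def lagged_correlation(p, q, lag_ms: float, rate: float) -> float:
    """Correlation of (p_i, q_{i+lag}) over the full overlap.

    Raises
    ------
    InsufficientOverlapError
        If fewer than 3 sample pairs remain after shifting.
    UndefinedCorrelationError
        If either aligned segment is constant (the coefficient has a zero
        denominator; this is reported, never silently mapped to 0).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    shift = _whole_shift(lag_ms, rate)
    n = min(len(p), len(q) - shift)
    if n < 3:
        raise InsufficientOverlapError(
            f"lag {lag_ms} ms leaves {max(n, 0)} aligned pairs; need >= 3"
        )
    x = p[:n]
    y = q[shift : shift + n]
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    scale = max(float(x @ x), float(y @ y), 1.0)
    if vx <= _VAR_EPS * scale or vy <= _VAR_EPS * scale:
        raise UndefinedCorrelationError(
            f"constant aligned segment at lag {lag_ms} ms: correlation undefined"
        )
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_curve(
    rec: Recording, p: str, q: str, grid: LagGrid | None = None
) -> LagCurve:
    """Full-record lag curve for the ordered pair (locked ``p``, delayed ``q``)."""
    grid = grid or LagGrid()
    xs = rec.channel(p)
    ys = rec.channel(q)
    shifts = grid.shifts(rec.rate)
    r = np.empty(len(shifts))
    n = np.empty(len(shifts), dtype=int)
    for k, (lag, shift) in enumerate(zip(grid.lags_ms, shifts)):
        r[k] = lagged_correlation(xs, ys, lag, rec.rate)
        n[k] = min(len(xs), len(ys) - shift)
    return LagCurve((p, q), np.asarray(grid.lags_ms), r, n)


def _cumsum0(a: np.ndarray) -> np.ndarray:
    out = np.empty(len(a) + 1)
    out[0] = 0.0
    np.cumsum(a, out=out[1:])
    return out


def windowed_correlation(
    rec: Recording,
    p: str,
    q: str,
    grid: LagGrid | None = None,
    window_ms: float = 500.0,
    step_ms: float = 10.0,
) -> WindowedLagCurves:
    """Sliding-window lag curves.

    Window ``w`` at lag ``delta`` correlates pairs (p_i, q_{i+delta}) for
    ``i`` inside the window; the delayed samples may extend past the window
    end, so only windows for which the largest lag still finds samples are
    emitted.  Windows whose aligned segments are constant yield NaN (the
    coefficient is undefined there) and are excluded from downstream epoch
    statistics.
    """
    grid = grid or LagGrid()
    xs = rec.channel(p)
    ys = rec.channel(q)
    shifts = grid.shifts(rec.rate)
    wn = _whole_shift(window_ms, rec.rate)
    st = _whole_shift(step_ms, rec.rate)
    if wn < 3:
        raise ValueError(f"window of {window_ms} ms holds {wn} samples; need >= 3")
    if st < 1:
        raise ValueError("step must be at least one sample")
    n = rec.n_samples
    max_shift = int(shifts.max())
    last_start = n - wn - max_shift
    if last_start < 0:
        raise ValueError(
            f"record too short: window {window_ms} ms plus largest lag "
            f"{grid.lags_ms[-1]} ms exceeds the record"
        )
    starts = np.arange(0, last_start + 1, st)
    r = np.empty((len(starts), len(shifts)))

    i0, i1 = starts, starts + wn
    sx_c = _cumsum0(xs)
    sxx_c = _cumsum0(xs * xs)
    sx = sx_c[i1] - sx_c[i0]
    sxx = sxx_c[i1] - sxx_c[i0]
    vx = sxx - sx * sx / wn
    scale_x = np.maximum(sxx, 1.0)
    for k, shift in enumerate(shifts):
        y = ys[shift : shift + n - shift]
        sy_c = _cumsum0(y)
        syy_c = _cumsum0(y * y)
        sxy_c = _cumsum0(xs[: n - shift] * y)
        sy = sy_c[i1] - sy_c[i0]
        syy = syy_c[i1] - syy_c[i0]
        sxy = sxy_c[i1] - sxy_c[i0]
        vy = syy - sy * sy / wn
        cov = sxy - sx * sy / wn
        scale = np.maximum(scale_x, np.maximum(syy, 1.0))
        bad = (vx <= _VAR_EPS * scale) | (vy <= _VAR_EPS * scale)
        with np.errstate(invalid="ignore", divide="ignore"):
            col = cov / np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
        col[bad] = np.nan
        r[:, k] = np.clip(col, -1.0, 1.0)

    times = rec.t0 + starts / rec.rate
    return WindowedLagCurves(
        (p, q), float(window_ms), float(step_ms), np.asarray(grid.lags_ms), times, r, wn
    )


def latency_at_threshold(curve: LagCurve, threshold: float = 0.7) -> float:
    """Largest grid lag whose coefficient reaches ``threshold``; 0 if none.

    This is the "latency at r = 0.7" summary: the longest preset latency at
    which the pair still correlates at or above the confidence threshold.
    """
    qualifying = curve.lags_ms[np.isfinite(curve.r) & (curve.r >= threshold)]
    return float(qualifying.max()) if len(qualifying) else 0.0
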