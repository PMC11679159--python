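"""Segmentation of alternating correlation regimes.

EEG lag curves alternate between spans where short latencies (10-70 ms)
dominate the correlation and spans where the long latencies (200-500 ms)
strengthen while the short ones collapse.  This module operationalises those
epochs: per-window mean correlation over a short and a long latency band,
the sign of their difference defines the state, maximal same-state runs form
epochs (with a debounce against single-window flicker), and the alternation
period is the mean duration of one full short+long cycle.

When several channel pairs are analysed, their band-strength series are
averaged before segmentation, so the epochs describe the shared regime of
the analysed region rather than a single pairing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import InsufficientDataError
from .lagcorr import WindowedLagCurves

__all__ = [
    "SHORT_BAND_MS",
    "LONG_BAND_MS",
    "Epoch",
    "band_strength",
    "aggregate_band_strength",
    "segment_epochs",
    "alternation_period",
]

SHORT_BAND_MS = (10.0, 70.0)
LONG_BAND_MS = (200.0, 500.0)

SHORT_DOMINANT = "short_dominant"
LONG_DOMINANT = "long_dominant"


@dataclasses.dataclass
class Epoch:
    """One contiguous span of a dominant latency band."""

    start: float  # s
    end: float  # s
    state: str  # short_dominant | long_dominant
    mean_short: float
    mean_long: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("epoch end must exceed its start")
        if self.state not in (SHORT_DOMINANT, LONG_DOMINANT):
            raise ValueError(f"unknown epoch state {self.state!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _band_cols(lags_ms: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if not hi >= lo:
        raise ValueError(f"band {band} is empty")
    cols = (lags_ms >= lo) & (lags_ms <= hi)
    if not np.any(cols):
        raise ValueError(f"band {band} ms contains no grid lag (grid: {lags_ms})")
    return cols


def band_strength(
    wlc: WindowedLagCurves,
    short_band: tuple[float, float] = SHORT_BAND_MS,
    long_band: tuple[float, float] = LONG_BAND_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean r over the short and long latency bands.

    Windows whose coefficients are missing (undefined correlation) propagate
    as NaN.
    """
    short_cols = _band_cols(wlc.lags_ms, short_band)
    long_cols = _band_cols(wlc.lags_ms, long_band)
    return wlc.r[:, short_cols].mean(axis=1), wlc.r[:, long_cols].mean(axis=1)


def aggregate_band_strength(
    curves: list[WindowedLagCurves],
    short_band: tuple[float, float] = SHORT_BAND_MS,
    long_band: tuple[float, float] = LONG_BAND_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band strengths averaged across pairs; returns (short, long, times).

    All curves must share one window layout.  A window missing in some pairs
    is averaged over the pairs where it is defined; it stays missing only
    where no pair defines it.
    """
    if not curves:
        raise ValueError("need at least one windowed curve set")
    times = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, times):
            raise ValueError("all pairs must share the same window times")
    shorts, longs = [], []
    for c in curves:
        s, l = band_strength(c, short_band, long_band)
        shorts.append(s)
        longs.append(l)
    with np.errstate(invalid="ignore"):
        return (
            np.nanmean(np.vstack(shorts), axis=0),
            np.nanmean(np.vstack(longs), axis=0),
            times,
        )


def segment_epochs(
    short_series,
    long_series,
    times,
    debounce_ms: float = 50.0,
) -> list[Epoch]:
    """Segment the analysed span into alternating dominance epochs.

    The state at each window is the sign of (short - long); maximal runs of
    one state become epochs, except that runs shorter than ``debounce_ms``
    are merged into the preceding epoch to suppress single-window flicker.
    Windows where both band strengths are missing inherit the preceding
    state.  The returned epochs tile the span from the first to one step
    past the last valid window, alternate in state, and never overlap.
    """
    short_series = np.asarray(short_series, dtype=float)
    long_series = np.asarray(long_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (len(short_series) == len(long_series) == len(times)):
        raise ValueError("series and times must align")
    diff = short_series - long_series
    valid = np.isfinite(diff)
    if not np.any(valid):
        return []
    first, last = np.flatnonzero(valid)[[0, -1]]
    step = float(np.median(np.diff(times))) if len(times) > 1 else 0.01

    idx = np.arange(first, last + 1)
    d = diff[idx]
    t = times[idx]
    state = np.empty(len(d), dtype=bool)
    prev = d[np.isfinite(d)][0] > 0
    for i, v in enumerate(d):
        if np.isfinite(v):
            prev = v > 0
        state[i] = prev  # missing windows inherit the running state

    # maximal runs
    runs: list[list] = []  # [start_idx, end_idx_exclusive, state]
    s0 = 0
    for i in range(1, len(state) + 1):
        if i == len(state) or state[i] != state[s0]:
            runs.append([s0, i, bool(state[s0])])
            s0 = i
    # debounce: short runs merge into the preceding run (first run into the next)
    debounced: list[list] = []
    for run in runs:
        dur_ms = (t[run[1] - 1] + step - t[run[0]]) * 1000.0
        if debounced and dur_ms < debounce_ms:
            debounced[-1][1] = run[1]
        elif not debounced and dur_ms < debounce_ms and len(runs) > 1:
            runs[runs.index(run) + 1][0] = run[0]
        else:
            debounced.append(run)
    # merging may have joined same-state neighbours; coalesce
    merged: list[list] = []
    for run in debounced:
        if merged and merged[-1][2] == run[2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    epochs = []
    for a, b, st in merged:
        sl = idx[a : b]
        with np.errstate(invalid="ignore"):
            ms = float(np.nanmean(short_series[sl])) if np.any(np.isfinite(short_series[sl])) else float("nan")
            ml = float(np.nanmean(long_series[sl])) if np.any(np.isfinite(long_series[sl])) else float("nan")
        epochs.append(
            Epoch(
                start=float(t[a]),
                end=float(t[b - 1] + step),
                state=SHORT_DOMINANT if st else LONG_DOMINANT,
                mean_short=ms,
                mean_long=ml,
            )
        )
    return epochs


def alternation_period(epochs: list[Epoch]) -> float:
    """Mean duration of one full short+long cycle, in milliseconds.

    With alternating epochs this equals twice the mean epoch duration, which
    also handles an odd trailing epoch gracefully.
    """
    if len(epochs) < 3:  # fewer than two state changes
        raise InsufficientDataError(
            f"{len(epochs)} epoch(s) provide fewer than 2 state changes"
        )
    durations = np.array([e.duration for e in epochs])
    return float(2.0 * durations.mean() * 1000.0)
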