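"""Synthetic multichannel recordings with known propagation structure.

Every analysis stage in this package is validated against data whose ground
truth is known by construction.  The generative model follows the working
assumption behind latency analysis of scalp potentials: each channel is a
superposition of *delayed* copies of shared source signals (the neuronally
propagated component), an *instantaneous* field component (volume
conduction, arriving without delay), and additive sensor noise:

    channel_k(t) = sum_s [ g_k * a_s * s(t - d_ks) + h_k * a_s * s(t) ] + noise

with d_ks = distance(source s, electrode k) / velocity (+ synaptic delays),
rounded to the nearest sample at the generation rate, so the analysis
pipeline - including downsampling and lag quantisation - is exercised
end to end.

Delays of tens to hundreds of milliseconds between nearby scalp sites
correspond to polysynaptic loops or slow intracortical (traveling-wave)
propagation, not to straight-line axonal conduction at 30-70 m/s;
correlation-scale fixtures therefore use slow effective velocities, while
triangulation fixtures use the axonal range.

:func:`generate_alternating` emulates the alternation between short-latency
and long-latency correlation regimes: per channel pair, two independent
sources drive a fast pathway (branch delays in the 10-70 ms band) and a
slow pathway (branch delays in the 200-500 ms band), and a square-wave
schedule multiplexes which pathway the source feeds.  The gate is applied
at the *source* time, so the correlation observed at each matched lag is in
phase with the switch schedule regardless of the cycle length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy import signal as _sig

from .signal_io import ElectrodeArray, Recording
from .triangulation import PropagationModel, transit_time

__all__ = [
    "SourceSpec",
    "SynthConfig",
    "AlternatingConfig",
    "GroundTruth",
    "TriangulationCase",
    "generate_recording",
    "generate_alternating",
    "generate_triangulation_case",
]


# ---------------------------------------------------------------------------
# waveforms (unit standard deviation; shapes are this module's choices)


def _alpha_like(n: int, rate: float, rng: np.random.Generator, freq_hz: float = 10.0):
    """10 Hz sinusoid with random phase jitter (slow phase random walk)."""
    jitter = rng.standard_normal(n) / np.sqrt(rate)  # ~1 rad drift per second
    phase = 2.0 * np.pi * freq_hz * np.arange(n) / rate + np.cumsum(jitter)
    return np.sqrt(2.0) * np.sin(phase)


def _bandlimited_noise(n, rate, rng, cutoff_hz: float = 40.0):
    """White noise low-passed at ``cutoff_hz`` (4th-order zero-phase)."""
    sos = _sig.butter(4, cutoff_hz, btype="low", fs=rate, output="sos")
    y = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    return y / y.std()


def _broadband_noise(n, rate, rng, sigma_ms: float = 5.0):
    """Gaussian-smoothed white noise: smooth but with a non-ringing,
    narrow autocorrelation - the workhorse for delay-recovery fixtures."""
    y = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma_ms * rate / 1000.0)
    return y / y.std()


def _ictal_spike_train(n, rate, rng, freq_hz: float = 20.0):
    """Periodic biphasic spikes at up to 200 Hz."""
    if not 0 < freq_hz <= 200:
        raise ValueError("spike rate must be in (0, 200] Hz")
    period = max(int(round(rate / freq_hz)), 1)
    train = np.zeros(n)
    start = int(rng.integers(0, period))
    train[start::period] = 1.0
    w1 = max(int(round(0.002 * rate)), 1)  # 2 ms depolarising lobe
    w2 = max(int(round(0.004 * rate)), 1)  # 4 ms half-amplitude rebound
    kernel = np.concatenate([np.ones(w1), -0.5 * np.ones(w2)])
    y = np.convolve(train, kernel)[:n]
    sd = y.std()
    return y / sd if sd > 0 else y


_WAVEFORMS = {
    "alpha_like": _alpha_like,
    "bandlimited_noise": _bandlimited_noise,
    "broadband_noise": _broadband_noise,
    "ictal_spike_train": _ictal_spike_train,
}


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclasses.dataclass
class SourceSpec:
    """One shared source: position (mm), waveform name, amplitude (µV sd)."""

    position: tuple[float, float, float]
    waveform: str = "bandlimited_noise"
    amplitude_uv: float = 50.0
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.waveform not in _WAVEFORMS:
            raise ValueError(
                f"unknown waveform {self.waveform!r}; have {sorted(_WAVEFORMS)}"
            )


@dataclasses.dataclass
class SynthConfig:
    """Configuration of a geometric propagated-EEG simulation."""

    channels: ElectrodeArray
    sources: list[SourceSpec]
    duration_s: float
    rate: float = 1000.0
    model: PropagationModel = dataclasses.field(default_factory=PropagationModel)
    delayed_gain: float | dict[str, float] = 1.0
    instantaneous_gain: float | dict[str, float] = 0.0
    noise_sd_uv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.rate > 0 and self.duration_s > 0):
            raise ValueError("rate and duration must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv cannot be negative")

    def gain(self, which: str, label: str) -> float:
        g = self.delayed_gain if which == "delayed" else self.instantaneous_gain
        return float(g.get(label, 0.0)) if isinstance(g, dict) else float(g)


@dataclasses.dataclass
class AlternatingConfig:
    """Configuration of the regime-alternation simulation.

    Each of ``n_pairs`` channel pairs (A*, B*) carries two pathways fed by
    independent sources; ``cycle_ms`` is the full short+long alternation
    cycle (half-period per regime).  ``cycle_ms=None`` disables alternation
    (the short pathway stays on throughout).  ``snr`` is the per-source
    signal-to-noise amplitude ratio.
    """

    duration_s: float = 30.0
    rate: float = 1000.0
    cycle_ms: float | None = 280.0
    n_pairs: int = 24
    short_delays_ms: tuple[float, ...] = (10.0, 30.0, 50.0)
    long_delays_ms: tuple[float, ...] = (250.0, 300.0, 400.0)
    snr: float = 5.0
    source_sigma_ms: float = 5.0
    amplitude_uv: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.cycle_ms is not None and not self.cycle_ms > 20.0:
            raise ValueError("alternation cycle must exceed twice the 10 ms window step")
        if self.n_pairs < 1:
            raise ValueError("need at least one channel pair")
        if not self.snr > 0:
            raise ValueError("snr must be positive")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(f"A{k:02d}", f"B{k:02d}") for k in range(self.n_pairs)]


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually imposed (the oracle for recovery tests)."""

    delays_ms: dict[str, tuple[float, ...]]  # per channel, one delay per source/pathway
    source_positions: np.ndarray | None
    switch_times_s: np.ndarray | None = None
    pairs: list[tuple[str, str]] | None = None


@dataclasses.dataclass
class TriangulationCase:
    """Transit-time measurement set for a known source."""

    electrodes: ElectrodeArray
    times_ms: np.ndarray  # absolute transit times
    tdoas_ms: np.ndarray  # differences vs electrode 0
    source: np.ndarray  # true position (mm)
    model: PropagationModel


# ---------------------------------------------------------------------------
# generators


def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Simulate delayed + instantaneous superposition with additive noise.

    Deterministic given ``cfg.seed`` (bit-identical output on repeat calls).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    labels = list(cfg.channels.labels)

    delays = np.empty((len(labels), len(cfg.sources)))
    for j, src in enumerate(cfg.sources):
        for i, label in enumerate(labels):
            delays[i, j] = transit_time(src.position, cfg.channels.position(label), cfg.model)
    shifts = np.round(delays * cfg.rate / 1000.0).astype(int)
    if shifts.max(initial=0) >= n:
        raise ValueError(
            f"largest delay ({delays.max():.1f} ms) exceeds the record duration"
        )
    pad = int(shifts.max(initial=0))

    data = np.zeros((len(labels), n))
    for j, src in enumerate(cfg.sources):
        wave = _WAVEFORMS[src.waveform](n + pad, cfg.rate, rng, **src.params)
        for i, label in enumerate(labels):
            gd = cfg.gain("delayed", label)
            gi = cfg.gain("instantaneous", label)
            k = shifts[i, j]
            if gd:
                data[i] += gd * src.amplitude_uv * wave[pad - k : pad - k + n]
            if gi:
                data[i] += gi * src.amplitude_uv * wave[pad : pad + n]
    if cfg.noise_sd_uv > 0:
        data += cfg.noise_sd_uv * rng.standard_normal(data.shape)

    truth = GroundTruth(
        delays_ms={label: tuple(delays[i]) for i, label in enumerate(labels)},
        source_positions=np.array([s.position for s in cfg.sources], dtype=float),
    )
    return Recording(labels, data, cfg.rate), truth


def generate_alternating(cfg: AlternatingConfig) -> tuple[Recording, GroundTruth]:
    """Simulate alternating short-lag / long-lag correlation regimes.

    For pair k, channel ``A`` receives both sources undelayed; channel ``B``
    receives the short-pathway source through branch delays
    ``short_delays_ms`` while the gate is up and the long-pathway source
    through ``long_delays_ms`` while it is down.  Branch gains are 1/sqrt(m)
    so each pathway delivers unit power.  Switch times are recorded in the
    ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    all_delays = tuple(cfg.short_delays_ms) + tuple(cfg.long_delays_ms)
    pad = int(np.ceil(max(all_delays) * cfg.rate / 1000.0))
    if pad >= n:
        raise ValueError("largest pathway delay exceeds the record duration")

    # gate over padded time axis, evaluated at the source (emission) time
    t_padded = (np.arange(n + pad) - pad) / cfg.rate
    if cfg.cycle_ms is None:
        gate = np.ones(n + pad)
        switch_times = None
    else:
        half_s = cfg.cycle_ms / 2000.0
        gate = ((t_padded % (2 * half_s)) < half_s).astype(float)
        switch_times = np.arange(0.0, cfg.duration_s, half_s)

    noise_sd = cfg.amplitude_uv / cfg.snr
    labels: list[str] = []
    rows: list[np.ndarray] = []
    delays_ms: dict[str, tuple[float, ...]] = {}
    for pa, pb in cfg.pairs:
        s1 = _broadband_noise(n + pad, cfg.rate, rng, cfg.source_sigma_ms)
        s2 = _broadband_noise(n + pad, cfg.rate, rng, cfg.source_sigma_ms)
        g1 = gate * s1
        g2 = (1.0 - gate) * s2
        a = s1[pad:] + s2[pad:]
        b = np.zeros(n)
        for d in cfg.short_delays_ms:
            k = int(round(d * cfg.rate / 1000.0))
            b += g1[pad - k : pad - k + n] / np.sqrt(len(cfg.short_delays_ms))
        for d in cfg.long_delays_ms:
            k = int(round(d * cfg.rate / 1000.0))
            b += g2[pad - k : pad - k + n] / np.sqrt(len(cfg.long_delays_ms))
        labels += [pa, pb]
        rows.append(cfg.amplitude_uv * a + noise_sd * rng.standard_normal(n))
        rows.append(cfg.amplitude_uv * b + noise_sd * rng.standard_normal(n))
        delays_ms[pa] = (0.0, 0.0)
        delays_ms[pb] = all_delays

    truth = GroundTruth(
        delays_ms=delays_ms,
        source_positions=None,
        switch_times_s=switch_times,
        pairs=cfg.pairs,
    )
    return Recording(labels, np.vstack(rows), cfg.rate), truth


def generate_triangulation_case(
    array: ElectrodeArray,
    source,
    model: PropagationModel | None = None,
    timing_noise_sd_ms: float = 0.0,
    seed: int = 0,
) -> TriangulationCase:
    """Transit times (and differences vs electrode 0) for a known source."""
    model = model or PropagationModel()
    source = np.asarray(source, dtype=float)
    times = np.array(
        [transit_time(source, pos, model) for pos in array.positions]
    )
    if timing_noise_sd_ms > 0:
        rng = np.random.default_rng(seed)
        times = times + timing_noise_sd_ms * rng.standard_normal(len(times))
    tdoas = times[1:] - times[0]
    return TriangulationCase(array, times, tdoas, source, model)
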