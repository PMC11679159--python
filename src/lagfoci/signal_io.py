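"""Recording and montage I/O, resampling, and result tables.

A :class:`Recording` is the unit every analysis consumes: a channel-by-sample
matrix of scalp potentials in microvolts with a sampling rate.  Recordings can
be read from EDF or BrainVision files (via :mod:`mne`) or from a self-contained
delimited text dialect used for fixtures::

    # rate=<Hz>
    label1,label2,...
    <one row of samples per line>

An :class:`ElectrodeArray` maps channel labels to 3D positions in millimetres.
The builtin ``"10-10"`` montage resolves labels through mne's packaged
standard montage; planar grids for triangulation are built with
:func:`planar_grid`.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .exceptions import ChannelLookupError, FormatError

__all__ = [
    "Recording",
    "ElectrodeArray",
    "read_recording",
    "write_recording",
    "downsample",
    "load_montage",
    "planar_grid",
    "write_table",
]


@dataclasses.dataclass
class Recording:
    """Multichannel sampled potentials.

    Parameters
    ----------
    labels : list of str
        Unique channel names, in file order.
    data : ndarray, shape (n_channels, n_samples)
        Potential samples in microvolts.
    rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start offset of the first sample in seconds.
    """

    labels: list[str]
    data: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.rate

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ChannelLookupError(
                f"channel {label!r} not in recording (have {self.labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """Return the sample series of one channel (a view)."""
        return self.data[self.index(label)]


@dataclasses.dataclass
class ElectrodeArray:
    """Labelled electrode positions in millimetres (right-handed axes)."""

    labels: list[str]
    positions: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.labels) != len(self.positions):
            raise ValueError("one label per position required")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ChannelLookupError(f"duplicate montage label(s): {dupes}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        d = self.positions[:, None, :] - self.positions[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() <= 0:
            raise ValueError("electrode positions must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.labels)

    def position(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise ChannelLookupError(f"montage label {label!r} not found") from None
        return self.positions[i]

    def subset(self, labels: list[str]) -> "ElectrodeArray":
        return ElectrodeArray(list(labels), np.array([self.position(l) for l in labels]))


# ---------------------------------------------------------------------------
# reading


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".vhdr":
        return "brainvision"
    return "delimited"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a multichannel recording.

    Parameters
    ----------
    path : path
        File to read.  BrainVision recordings are addressed by their ``.vhdr``
        header file.
    format : {"edf", "brainvision", "delimited"}, optional
        Force a format; inferred from the file suffix when omitted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    if fmt == "delimited":
        return _read_delimited(path)
    if fmt in ("edf", "brainvision"):
        return _read_mne(path, fmt)
    raise ValueError(f"unknown recording format: {fmt!r}")


def _read_mne(path: Path, fmt: str) -> Recording:
    import mne  # deferred: heavy import

    try:
        if fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    except FileNotFoundError as exc:
        raise IOError(f"missing file referenced by {path.name}: {exc}") from exc
    except Exception as exc:  # noqa: BLE001 - normalise mne's parse failures
        raise IOError(f"cannot read {fmt} recording {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne holds SI volts internally
    return Recording(list(raw.ch_names), data_uv, float(raw.info["sfreq"]))


def _read_delimited(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# rate="):
            raise FormatError(
                f"{path}: first line must be '# rate=<Hz>', got {header!r}"
            )
        try:
            rate = float(header.split("=", 1)[1])
        except ValueError:
            raise FormatError(f"{path}: unparsable rate in header {header!r}") from None
        labels = [s.strip() for s in fh.readline().strip().split(",")]
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != len(labels):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(labels)} values, got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric sample") from None
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    return Recording(labels, np.asarray(rows, dtype=float).T, rate)


# ---------------------------------------------------------------------------
# writing


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as delimited text or EDF.

    The delimited dialect round-trips samples exactly.  EDF stores 16-bit
    samples; data are quantised to the channel's physical range (exact for
    integer-valued microvolt data within +/-32767).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "delimited":
        with open(path, "w") as fh:
            fh.write(f"# rate={rec.rate:.10g}\n")
            fh.write(",".join(rec.labels) + "\n")
            np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported output format: {fmt!r}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    # Minimal EDF: one data record per second, 16-bit little-endian samples.
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF output requires an integer sampling rate")
    rate = int(round(rate))
    if rec.n_samples % rate != 0:
        raise ValueError("EDF output requires a whole number of seconds")
    n_records = rec.n_samples // rate
    nch = rec.n_channels

    dig_min, dig_max = -32768, 32767
    scales = []
    phys_ranges = []
    for ch in rec.data:
        top = float(np.max(np.abs(ch)))
        if top <= dig_max:
            # 1 µV resolution: exact for integer-valued microvolt data
            pmin, pmax = float(dig_min), float(dig_max)
        else:
            scale = top / dig_max
            # round-trip through the 8-char header fields so the scaling the
            # reader reconstructs is exactly the one used for quantisation
            pmin = float(str(dig_min * scale)[:8])
            pmax = float(str(dig_max * scale)[:8])
        phys_ranges.append((pmin, pmax))
        scales.append((pmax - pmin) / (dig_max - dig_min))

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + nch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(nch, 4)
    header += b"".join(_edf_field(l, 16) for l in rec.labels)
    header += b"".join(_edf_field("", 80) for _ in range(nch))
    header += b"".join(_edf_field("uV", 8) for _ in range(nch))
    header += b"".join(_edf_field(f"{p[0]:.8g}"[:8], 8) for p in phys_ranges)
    header += b"".join(_edf_field(f"{p[1]:.8g}"[:8], 8) for p in phys_ranges)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(nch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(nch))
    header += b"".join(_edf_field("", 80) for _ in range(nch))
    header += b"".join(_edf_field(rate, 8) for _ in range(nch))
    header += b"".join(_edf_field("", 32) for _ in range(nch))

    digital = np.empty((nch, rec.n_samples), dtype="<i2")
    for i, ch in enumerate(rec.data):
        pmin, _ = phys_ranges[i]
        dig = np.round((ch - pmin) / scales[i]) + dig_min
        digital[i] = np.clip(dig, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * rate : (r + 1) * rate]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# resampling


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Anti-aliased downsampling to ``target_rate``.

    When ``target_rate`` divides the rate, a zero-phase 8th-order Butterworth
    low-pass at ``0.4 * target_rate`` is applied before decimation, so no
    group delay is introduced that would bias latency estimates.  Other
    rational ratios fall back to polyphase resampling.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate >= rec.rate:
        raise ValueError(
            f"target_rate ({target_rate} Hz) must be below the rate ({rec.rate} Hz)"
        )
    ratio = rec.rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        sos = _sig.butter(8, 0.4 * target_rate, btype="low", fs=rec.rate, output="sos")
        filtered = _sig.sosfiltfilt(sos, rec.data, axis=1)
        data = filtered[:, ::q]
    else:
        frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
        data = _sig.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(list(rec.labels), data, float(target_rate), rec.t0)


# ---------------------------------------------------------------------------
# montages

_BUILTIN_MONTAGES = {"10-10": "standard_1005", "10-20": "standard_1020"}


def load_montage(source: str | Path) -> ElectrodeArray:
    """Load an electrode montage.

    ``source`` is either a builtin name (``"10-10"``, ``"10-20"``) resolved
    through mne's packaged standard montages (positions scaled to mm), or a
    CSV file with columns ``label,x_mm,y_mm,z_mm``.
    """
    if isinstance(source, str) and source in _BUILTIN_MONTAGES:
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mont = mne.channels.make_standard_montage(_BUILTIN_MONTAGES[source])
        pos = mont.get_positions()["ch_pos"]
        # deprecated aliases (T3/T4/T5/T6 for T7/T8/P7/P8) share positions
        # with the modern labels listed first; keep the first label per site
        labels: list[str] = []
        positions: list[np.ndarray] = []
        seen: set[tuple] = set()
        for label, p in pos.items():
            key = tuple(np.round(p, 9))
            if key in seen:
                continue
            seen.add(key)
            labels.append(label)
            positions.append(p)
        return ElectrodeArray(labels, np.array(positions) * 1000.0)  # m -> mm

    path = Path(source)
    if not path.exists():
        raise IOError(f"montage file not found: {path}")
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:4]] != [
            "label",
            "x_mm",
            "y_mm",
            "z_mm",
        ]:
            raise FormatError(f"{path}: expected header 'label,x_mm,y_mm,z_mm'")
        for row in reader:
            if not row:
                continue
            label = row[0].strip()
            if label in labels:
                raise ChannelLookupError(f"{path}: duplicate montage label {label!r}")
            labels.append(label)
            try:
                rows.append([float(v) for v in row[1:4]])
            except ValueError:
                raise FormatError(f"{path}: non-numeric coordinate for {label!r}") from None
    return ElectrodeArray(labels, np.asarray(rows))


def planar_grid(nx: int, ny: int, pitch_mm: float = 10.0, prefix: str = "E") -> ElectrodeArray:
    """Equidistant planar electrode grid in the z = 0 scalp plane.

    Electrodes are numbered row-major starting at the origin, so ``E0`` sits
    at (0, 0, 0) and ``E{nx-1}`` at ((nx-1) * pitch, 0, 0).
    """
    if nx < 1 or ny < 1 or not pitch_mm > 0:
        raise ValueError("grid needs nx, ny >= 1 and a positive pitch")
    labels, positions = [], []
    k = 0
    for j in range(ny):
        for i in range(nx):
            labels.append(f"{prefix}{k}")
            positions.append((i * pitch_mm, j * pitch_mm, 0.0))
            k += 1
    return ElectrodeArray(labels, np.asarray(positions))


# ---------------------------------------------------------------------------
# result tables


def _format_value(key: str, value):
    if isinstance(value, bool) or value is None or isinstance(value, (int, np.integer)):
        return value
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return ""
        digits = 1 if ("percent" in key or key.endswith("_pct")) else 3
        return f"{value:.{digits}f}"
    return value


def write_table(rows, path: str | Path, format: str = "csv", fieldnames=None) -> None:
    """Write homogeneous result records with bit-stable formatting.

    Floats are rendered with 3 decimals (1 decimal for percentage fields), in
    a fixed column order, so re-running a pipeline reproduces files byte for
    byte.  ``rows`` may be dicts or dataclass instances; ``fieldnames``
    supplies the header when ``rows`` is empty.
    """
    records = []
    for row in rows:
        if dataclasses.is_dataclass(row):
            row = dataclasses.asdict(row)
        records.append(dict(row))
    if records:
        keys = list(records[0])
        for r in records:
            if list(r) != keys:
                raise ValueError("rows must share one column layout")
    else:
        keys = list(fieldnames or [])

    path = Path(path)
    formatted = [{k: _format_value(k, v) for k, v in r.items()} for r in records]
    try:
        if format == "csv":
            with open(path, "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=keys, lineterminator="\n")
                writer.writeheader()
                writer.writerows(formatted)
        elif format == "json":
            with open(path, "w") as fh:
                json.dump(formatted, fh, indent=2)
                fh.write("\n")
        else:
            raise ValueError(f"unsupported table format: {format!r}")
    except OSError as exc:
        raise IOError(f"cannot write table {path}: {exc}") from exc
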