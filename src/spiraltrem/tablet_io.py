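"""Pen-tablet recording I/O and stroke segmentation.

Recordings are stored in an SVC-style plain-text dialect: one sample per
line with seven whitespace-separated fields in the order

    x  y  t  pen_status  azimuth  altitude  pressure

where ``t`` is the timestamp in milliseconds, ``pen_status`` is 1 when the
pen touches the surface and 0 when it moves in the air, ``azimuth`` is in
degrees [0, 360), ``altitude`` in degrees [0, 90] and ``pressure`` in device
units [0, p_max].  An optional first line holding a single integer gives the
sample count.  Lines starting with ``#`` are comments.

In-air samples keep their coordinates but carry pressure 0 — this mirrors
how digitizing tablets report hover samples and is enforced as an invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SvcParseError, ValidationError

#: Default pressure ceiling (device units).  Typical 11-bit quantization for
#: the consumer tablet generation the recordings come from; correlations are
#: scale-invariant so the exact ceiling only matters for clipping.
DEFAULT_P_MAX = 2047.0

#: Nominal acquisition rate (Hz) of the spiral task.
DEFAULT_FS = 100.0

_COLUMNS = ("x", "y", "t", "pen_status", "azimuth", "altitude", "pressure")

ON_SURFACE = 1
IN_AIR = 0


@dataclass
class PenRecording:
    """One spiral trial: uniformly sampled multichannel pen time series.

    All channel arrays are float64 of equal length except ``pen_status``
    which is int64 with values in {0, 1}.  Timestamps are milliseconds and
    must be strictly increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pen_status: np.ndarray
    azimuth: np.ndarray
    altitude: np.ndarray
    pressure: np.ndarray
    fs: float = DEFAULT_FS
    p_max: float = DEFAULT_P_MAX
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pen_status = np.asarray(self.pen_status, dtype=np.int64)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.altitude = np.asarray(self.altitude, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        n = len(self.t)
        if n == 0:
            raise ValidationError("recording is empty")
        for name in ("x", "y", "pen_status", "azimuth", "altitude", "pressure"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"channel {name!r} has length {len(getattr(self, name))}, expected {n}"
                )
        if np.any(self.t < 0):
            raise ValidationError("timestamps must be non-negative")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise ValidationError(f"timestamps not strictly increasing at sample {bad}")
        bad_status = ~np.isin(self.pen_status, (IN_AIR, ON_SURFACE))
        if np.any(bad_status):
            raise ValidationError(
                f"pen_status must be 0 or 1 (sample {int(np.argmax(bad_status))})"
            )
        if np.any(self.pressure < 0) or np.any(self.pressure > self.p_max):
            raise ValidationError(f"pressure outside [0, {self.p_max}]")
        air = self.pen_status == IN_AIR
        if np.any(self.pressure[air] != 0):
            bad = int(np.flatnonzero(air & (self.pressure != 0))[0])
            raise ValidationError(f"in-air sample {bad} has non-zero pressure")
        if np.any(self.azimuth < 0) or np.any(self.azimuth >= 360):
            raise ValidationError("azimuth outside [0, 360)")
        if np.any(self.altitude < 0) or np.any(self.altitude > 90):
            raise ValidationError("altitude outside [0, 90]")
        for name in ("x", "y", "azimuth", "altitude", "pressure"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"channel {name!r} contains non-finite values")


@dataclass(frozen=True)
class Stroke:
    """Maximal run of constant pen status, as a half-open sample range."""

    kind: str  # "surface" | "air"
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def infer_fs(t_ms: np.ndarray) -> float:
    """Nominal sampling rate from the median timestamp spacing (ms)."""
    if len(t_ms) < 2:
        return DEFAULT_FS
    return 1000.0 / float(np.median(np.diff(t_ms)))


def read_svc(path, p_max: float = DEFAULT_P_MAX, expected_fs: float | None = DEFAULT_FS) -> PenRecording:
    """Read a recording from an SVC-style text file.

    The nominal sampling rate is inferred from the median timestamp spacing
    and stored both on the recording and under ``meta['fs_inferred']``.  A
    warning (not an error) is emitted when the inferred rate deviates more
    than 5% from ``expected_fs``.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    declared = None
    # optional leading count line: a single integer token
    for i, line in enumerate(lines):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        toks = s.split()
        if len(toks) == 1:
            try:
                declared = int(toks[0])
            except ValueError:
                raise SvcParseError(f"line {i + 1}: expected sample count or data line, got {s!r}")
            start = i + 1
        break
    for i, line in enumerate(lines[start:], start=start + 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        toks = s.split()
        if len(toks) != 7:
            raise SvcParseError(f"line {i}: expected 7 fields, got {len(toks)}")
        try:
            rows.append([float(v) for v in toks])
        except ValueError as exc:
            raise SvcParseError(f"line {i}: non-numeric field ({exc})")
    if not rows:
        raise ValidationError(f"{path}: no samples found")
    if declared is not None and declared != len(rows):
        warnings.warn(
            f"{path}: header declares {declared} samples, file has {len(rows)}",
            stacklevel=2,
        )
    arr = np.asarray(rows, dtype=float)
    cols = dict(zip(_COLUMNS, arr.T))
    fs = infer_fs(cols["t"])
    rec = PenRecording(
        t=cols["t"],
        x=cols["x"],
        y=cols["y"],
        pen_status=cols["pen_status"].astype(np.int64),
        azimuth=cols["azimuth"],
        altitude=cols["altitude"],
        pressure=cols["pressure"],
        fs=fs,
        p_max=p_max,
        meta={"path": str(path), "fs_inferred": fs},
    )
    if expected_fs is not None and abs(fs - expected_fs) / expected_fs > 0.05:
        warnings.warn(
            f"{path}: inferred sampling rate {fs:.2f} Hz deviates >5% from nominal {expected_fs} Hz",
            stacklevel=2,
        )
    return rec


def _fmt(v: float) -> str:
    """Integer-valued fields without decimals; floats via shortest round-trip repr."""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_svc(recording: PenRecording, path, header_count: bool = True) -> None:
    """Write a recording in the dialect accepted by :func:`read_svc`.

    Validates the recording first so an invariant-violating object is never
    serialized.  Round-trips bit-for-bit through :func:`read_svc` (float64
    repr is exact).
    """
    recording.validate()
    with open(path, "w") as fh:
        if header_count:
            fh.write(f"{len(recording)}\n")
        for i in range(len(recording)):
            fields = (
                _fmt(recording.x[i]),
                _fmt(recording.y[i]),
                _fmt(recording.t[i]),
                str(int(recording.pen_status[i])),
                _fmt(recording.azimuth[i]),
                _fmt(recording.altitude[i]),
                _fmt(recording.pressure[i]),
            )
            fh.write(" ".join(fields) + "\n")


def segment_strokes(recording: PenRecording) -> list[Stroke]:
    """Split a recording into maximal on-surface / in-air runs.

    The returned ranges are ordered, non-overlapping and cover [0, n): their
    concatenation reproduces the recording.
    """
    status = recording.pen_status
    n = len(status)
    boundaries = np.flatnonzero(np.diff(status)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return [
        Stroke(kind="surface" if status[s] == ON_SURFACE else "air", start=int(s), end=int(e))
        for s, e in zip(starts, ends)
    ]
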