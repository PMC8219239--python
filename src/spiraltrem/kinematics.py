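"""Derived pen time series and per-trial feature summaries.

From the raw channels (x, y, pressure, azimuth, altitude) this module
derives, by finite differencing:

* channel variations Δ and ΔΔ (raw adjacent-sample differences),
* velocity components and speed (fs-scaled first differences, units/s),
* acceleration components and magnitude (units/s²),
* instantaneous trajectory angle atan2(Δy, Δx),
* instantaneous movement √(Δx² + Δy²) (per-sample displacement),
* tangential acceleration Δ(speed)·fs,
* curvature radius ρ = |v|³ / |vx·ay − vy·ax| and centripetal
  acceleration |v|²/ρ.

Physical kinematic series are scaled by the sampling rate so their units are
per-second; the named Δ/ΔΔ channel features are kept as raw adjacent
differences.  Pearson correlations are invariant to the constant fs factor,
so this choice is cosmetic for downstream statistics and is documented here
once.

Per-trial summaries are the mean and sample standard deviation (n−1
denominator) of each series.  By default only on-surface samples enter the
summaries and differences are never taken across stroke boundaries: the
spiral task is drawn on-surface, and in-air pressure is identically zero and
would deflate the pressure-variability features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .tablet_io import PenRecording, Stroke, segment_strokes

#: Cross-product magnitude below this is treated as zero curvature (straight).
CROSS_EPS = 1e-12
#: Curvature-radius cap for near-straight segments; keeps summaries bounded.
RHO_MAX = 1e6
#: Speed below this yields zero centripetal acceleration.
SPEED_EPS = 1e-12

#: Ordered list of the per-trial feature names produced by :func:`summarize`.
FEATURE_CHANNELS = (
    "x", "y", "p", "az", "alt",
    "dx", "dy", "dp", "daz", "dalt",
    "ddx", "ddy", "ddp", "ddaz", "ddalt",
    "speed", "accel", "angle", "movement",
    "tangential_accel", "curvature_radius", "centripetal_accel",
)
FEATURE_NAMES = tuple(
    f"{stat}_{ch}" for ch in FEATURE_CHANNELS for stat in ("mean", "std")
)


@dataclass
class DerivedSeries:
    """A derived time series aligned to its parent recording.

    ``valid_from`` is the index of the first parent sample the series refers
    to; each order of differencing shortens the series by one and advances
    the offset.
    """

    name: str
    values: np.ndarray
    valid_from: int = 0

    def __len__(self) -> int:
        return len(self.values)


def delta(series, name: str = "delta", valid_from: int = 1) -> DerivedSeries:
    """Adjacent-element differences out[i] = in[i+1] − in[i]; length n−1."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValidationError("delta requires a 1-d series of length >= 2")
    return DerivedSeries(name=name, values=np.diff(arr), valid_from=valid_from)


def _require(recording: PenRecording, n_min: int, what: str) -> None:
    if len(recording) < n_min:
        raise ValidationError(f"{what} requires >= {n_min} samples, got {len(recording)}")


def velocity(recording: PenRecording):
    """Velocity components and speed, units/s (fs-scaled differences)."""
    _require(recording, 2, "velocity")
    fs = recording.fs
    vx = np.diff(recording.x) * fs
    vy = np.diff(recording.y) * fs
    speed = np.hypot(vx, vy)
    return (
        DerivedSeries("vx", vx, 1),
        DerivedSeries("vy", vy, 1),
        DerivedSeries("speed", speed, 1),
    )


def acceleration(recording: PenRecording):
    """Acceleration components and magnitude, units/s²; length n−2."""
    _require(recording, 3, "acceleration")
    fs = recording.fs
    vx, vy, _ = velocity(recording)
    ax = np.diff(vx.values) * fs
    ay = np.diff(vy.values) * fs
    mag = np.hypot(ax, ay)
    return (
        DerivedSeries("ax", ax, 2),
        DerivedSeries("ay", ay, 2),
        DerivedSeries("accel", mag, 2),
    )


def trajectory_angle(recording: PenRecording) -> DerivedSeries:
    """Instantaneous trajectory angle θ[i] = atan2(Δy, Δx) ∈ (−π, π].

    Samples with zero displacement carry the angle forward from the previous
    valid sample (0 if none precedes).
    """
    _require(recording, 2, "trajectory_angle")
    dx = np.diff(recording.x)
    dy = np.diff(recording.y)
    theta = np.arctan2(dy, dx)
    still = (dx == 0) & (dy == 0)
    if np.any(still):
        theta = theta.copy()
        last = 0.0
        for i in range(len(theta)):
            if still[i]:
                theta[i] = last
            else:
                last = theta[i]
    return DerivedSeries("angle", theta, 1)


def instantaneous_movement(recording: PenRecording) -> DerivedSeries:
    """Per-sample displacement magnitude √(Δx² + Δy²) (raw, not fs-scaled)."""
    _require(recording, 2, "instantaneous_movement")
    return DerivedSeries(
        "movement", np.hypot(np.diff(recording.x), np.diff(recording.y)), 1
    )


def tangential_acceleration(recording: PenRecording) -> DerivedSeries:
    """Rate of change of speed, Δ(speed)·fs, units/s²; length n−2."""
    _require(recording, 3, "tangential_acceleration")
    _, _, speed = velocity(recording)
    return DerivedSeries("tangential_accel", np.diff(speed.values) * recording.fs, 2)


def curvature_and_centripetal(
    recording: PenRecording,
    rho_max: float = RHO_MAX,
    eps: float = CROSS_EPS,
):
    """Curvature radius and centripetal acceleration, aligned to the
    acceleration series.

    ρ = |v|³ / |vx·ay − vy·ax|, capped at ``rho_max`` where the cross
    product vanishes (straight-line motion); centripetal = |cross|/|v|,
    set to 0 where the speed vanishes.
    """
    _require(recording, 3, "curvature_and_centripetal")
    vx, vy, speed = velocity(recording)
    ax, ay, _ = acceleration(recording)
    # align velocity (valid_from=1) with acceleration (valid_from=2)
    vxa, vya, sa = vx.values[1:], vy.values[1:], speed.values[1:]
    cross = np.abs(vxa * ay.values - vya * ax.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(cross < eps, rho_max, sa**3 / np.maximum(cross, eps))
        centripetal = np.where(sa < SPEED_EPS, 0.0, cross / np.maximum(sa, SPEED_EPS))
    rho = np.minimum(rho, rho_max)
    return (
        DerivedSeries("curvature_radius", rho, 2),
        DerivedSeries("centripetal_accel", centripetal, 2),
    )


def _surface_strokes(recording: PenRecording) -> list[Stroke]:
    return [s for s in segment_strokes(recording) if s.kind == "surface"]


def _slice(recording: PenRecording, stroke: Stroke) -> PenRecording:
    sl = slice(stroke.start, stroke.end)
    return PenRecording(
        t=recording.t[sl],
        x=recording.x[sl],
        y=recording.y[sl],
        pen_status=recording.pen_status[sl],
        azimuth=recording.azimuth[sl],
        altitude=recording.altitude[sl],
        pressure=recording.pressure[sl],
        fs=recording.fs,
        p_max=recording.p_max,
        meta=dict(recording.meta),
    )


def _mean_std(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    mean = float(np.mean(v))
    std = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return mean, std


def summarize(recording: PenRecording, surface_only: bool = True) -> dict[str, float]:
    """Per-trial feature vector: mean and sample std of every derived channel.

    With ``surface_only`` (the default) only on-surface strokes contribute,
    and all differences are computed within strokes, never across the in-air
    gaps between them.  Raises :class:`ValidationError` when no contributing
    segment is long enough for the second-order channels, listing the
    missing channels.
    """
    if surface_only:
        segments = [
            _slice(recording, s) for s in _surface_strokes(recording) if len(s) >= 1
        ]
        if not segments:
            raise ValidationError("no on-surface samples in recording")
    else:
        segments = [recording]

    raw = {name: [] for name in FEATURE_CHANNELS}
    for seg in segments:
        raw["x"].append(seg.x)
        raw["y"].append(seg.y)
        raw["p"].append(seg.pressure)
        raw["az"].append(seg.azimuth)
        raw["alt"].append(seg.altitude)
        if len(seg) >= 2:
            for key, chan in (
                ("dx", seg.x), ("dy", seg.y), ("dp", seg.pressure),
                ("daz", seg.azimuth), ("dalt", seg.altitude),
            ):
                raw[key].append(np.diff(chan))
            _, _, sp = velocity(seg)
            raw["speed"].append(sp.values)
            raw["angle"].append(trajectory_angle(seg).values)
            raw["movement"].append(instantaneous_movement(seg).values)
        if len(seg) >= 3:
            for key, chan in (
                ("ddx", seg.x), ("ddy", seg.y), ("ddp", seg.pressure),
                ("ddaz", seg.azimuth), ("ddalt", seg.altitude),
            ):
                raw[key].append(np.diff(chan, n=2))
            _, _, acc = acceleration(seg)
            raw["accel"].append(acc.values)
            raw["tangential_accel"].append(tangential_acceleration(seg).values)
            rho, cen = curvature_and_centripetal(seg)
            raw["curvature_radius"].append(rho.values)
            raw["centripetal_accel"].append(cen.values)

    missing = [name for name, chunks in raw.items() if not chunks]
    if missing:
        raise ValidationError(
            "recording too short for channels: " + ", ".join(sorted(missing))
        )

    features: dict[str, float] = {}
    for name in FEATURE_CHANNELS:
        mean, std = _mean_std(np.concatenate(raw[name]))
        features[f"mean_{name}"] = mean
        features[f"std_{name}"] = std
    return features
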