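"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spiraltrem import PenRecording

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(
    x,
    y,
    pressure=None,
    pen_status=None,
    fs: float = 100.0,
    azimuth=None,
    altitude=None,
) -> PenRecording:
    """Build a valid recording from coordinate arrays with sane defaults."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    t = np.arange(n) * (1000.0 / fs)
    pen = np.ones(n, dtype=np.int64) if pen_status is None else np.asarray(pen_status, dtype=np.int64)
    p = np.full(n, 500.0) if pressure is None else np.asarray(pressure, dtype=float)
    p = np.where(pen == 0, 0.0, p)
    return PenRecording(
        t=t,
        x=x,
        y=np.asarray(y, dtype=float),
        pen_status=pen,
        azimuth=np.full(n, 180.0) if azimuth is None else np.asarray(azimuth, dtype=float),
        altitude=np.full(n, 60.0) if altitude is None else np.asarray(altitude, dtype=float),
        pressure=p,
        fs=fs,
    )


def circle_recording(radius: float, omega: float, fs: float = 100.0, duration: float = 5.0) -> PenRecording:
    """Uniform circular motion at angular velocity omega (rad/s)."""
    t = np.arange(round(fs * duration)) / fs
    return make_recording(radius * np.cos(omega * t), radius * np.sin(omega * t), fs=fs)


def random_recording(rng: np.random.Generator, n: int | None = None) -> PenRecording:
    """A random structurally-valid recording (for round-trip properties)."""
    if n is None:
        n = int(rng.integers(2, 60))
    t = np.cumsum(rng.integers(1, 20, size=n)).astype(float)
    pen = rng.integers(0, 2, size=n)
    pressure = np.where(pen == 1, rng.uniform(0, 2047, size=n), 0.0)
    return PenRecording(
        t=t,
        x=rng.normal(size=n) * 100,
        y=rng.normal(size=n) * 100,
        pen_status=pen,
        azimuth=rng.uniform(0, 359.999, size=n),
        altitude=rng.uniform(0, 90, size=n),
        pressure=pressure,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
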