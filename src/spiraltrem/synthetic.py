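"""Synthetic spiral trials and cohorts with planted correlation structure.

Real spiral-drawing recordings from tremor patients are not publicly
available, so verification rests on simulation.  Two generators are
provided:

* :func:`gen_spiral` draws an Archimedean spiral r(θ) = a + bθ at constant
  angular velocity and superimposes an action-tremor-like radial sinusoid
  in the classic essential-tremor band (4–12 Hz).  Pen pressure is a
  baseline plus an oscillation whose amplitude grows linearly with the
  tremor amplitude (clipped to the device range), plus white noise — the
  simplest mechanism that makes pressure variability (std-p and its
  differences) increase monotonically with tremor severity.

* :func:`gen_cohort` simulates a cohort of subjects with integer clinical
  tremor scores, Gaussian total brain volumes, per-subject spiral trials
  whose tremor amplitude scales with the score, and regional morphometry
  values linearly coupled to score and brain volume plus Gaussian noise.

:func:`plant_partial_correlation` draws (x, y, z) from a trivariate
Gaussian constructed so the population partial correlation of x and y
given z equals a requested value: x = γ·z + u and y = γ·z + v where the
residuals (u, v) are standard bivariate normal with correlation ρ.
Conditioning on z leaves exactly corr(u, v) = ρ, whatever γ.

All generators take an explicit integer seed and are bit-for-bit
reproducible: identical config + seed reproduces identical output, byte
identical after serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kinematics import summarize
from .roi_io import RoiTable, classify_region
from .tablet_io import DEFAULT_P_MAX, PenRecording

_SEED_MAX = 2**31  # child seeds stay below 2^31


@dataclass(frozen=True)
class SpiralSimConfig:
    """Parameters of one simulated spiral trial.

    Geometry: the ideal pen path is the Archimedean spiral r(θ) = a + bθ
    traversed at constant angular velocity from θ = 0 to 2π·n_turns.
    Tremor: an additive radial sinusoid of amplitude ``tremor_amplitude``
    (tablet units) at ``tremor_freq_hz`` with a per-seed random phase.
    Pressure: ``pressure_base`` plus an oscillation of amplitude
    ``pressure_tremor_gain × tremor_amplitude`` plus white noise of sd
    ``noise_sd``, clipped to [0, p_max].  The same ``noise_sd`` is also
    added to the radial coordinate as sensor noise.
    """

    spiral_a: float = 10.0        # inner offset (tablet units)
    spiral_b: float = 6.0         # radial growth per radian (tablet units/rad)
    n_turns: int = 4
    duration_s: float = 10.0
    fs: float = 100.0             # sampling rate (Hz)
    tremor_amplitude: float = 0.0  # radial tremor amplitude (tablet units)
    tremor_freq_hz: float = 5.0   # essential-tremor band 4-12 Hz
    pressure_base: float = 1000.0  # device units
    pressure_tremor_gain: float = 30.0  # device units per tablet unit of tremor
    noise_sd: float = 0.5         # white-noise sd (tablet / device units)
    p_max: float = DEFAULT_P_MAX
    n_lifts: int = 0              # optional in-air gaps (pen lifts)
    lift_duration_s: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        checks = (
            ("fs", self.fs > 0, "must be > 0"),
            ("duration_s", self.duration_s > 0, "must be > 0"),
            ("n_turns", self.n_turns >= 1, "must be >= 1"),
            ("tremor_amplitude", self.tremor_amplitude >= 0, "must be >= 0"),
            ("tremor_freq_hz", self.tremor_freq_hz > 0, "must be > 0"),
            ("noise_sd", self.noise_sd >= 0, "must be >= 0"),
            ("pressure_base", 0 <= self.pressure_base <= self.p_max,
             f"must lie in [0, p_max={self.p_max}]"),
            ("n_lifts", self.n_lifts >= 0, "must be >= 0"),
            ("spiral_b", self.spiral_b > 0, "must be > 0"),
        )
        for name, ok, msg in checks:
            if not ok:
                raise ConfigurationError(f"{name} {msg} (got {getattr(self, name)})")


def gen_spiral(config: SpiralSimConfig) -> PenRecording:
    """Simulate one spiral trial; see :class:`SpiralSimConfig` for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = round(config.fs * config.duration_s)
    t_s = np.arange(n) / config.fs
    theta = 2 * np.pi * config.n_turns * t_s / config.duration_s

    phase_r = rng.uniform(0, 2 * np.pi)
    phase_p = rng.uniform(0, 2 * np.pi)
    tremor = config.tremor_amplitude * np.sin(
        2 * np.pi * config.tremor_freq_hz * t_s + phase_r
    )
    r = config.spiral_a + config.spiral_b * theta + tremor
    if config.noise_sd > 0:
        r = r + rng.normal(0, config.noise_sd, n)
    # fixed margin keeps coordinates positive without coupling the mean pen
    # position to the tremor amplitude
    r_max = config.spiral_a + config.spiral_b * theta[-1]
    center = r_max + 60.0
    x = center + r * np.cos(theta)
    y = center + r * np.sin(theta)

    pressure = config.pressure_base + (
        config.pressure_tremor_gain * config.tremor_amplitude
    ) * np.sin(2 * np.pi * config.tremor_freq_hz * t_s + phase_p)
    if config.noise_sd > 0:
        pressure = pressure + rng.normal(0, config.noise_sd, n)
    pressure = np.clip(pressure, 0, config.p_max)

    pen_status = np.ones(n, dtype=np.int64)
    if config.n_lifts > 0:
        gap = max(1, round(config.lift_duration_s * config.fs))
        # evenly spaced interior lifts; never at the very start or end
        for c in np.linspace(0, n, config.n_lifts + 2)[1:-1]:
            lo = int(c) - gap // 2
            hi = lo + gap
            pen_status[max(lo, 1):min(hi, n - 1)] = 0
    pressure[pen_status == 0] = 0.0

    azimuth = (np.degrees(theta) + 90.0) % 360.0
    altitude = np.clip(60.0 + 5.0 * np.sin(2 * np.pi * 0.2 * t_s), 0.0, 90.0)

    return PenRecording(
        t=t_s * 1000.0,
        x=x,
        y=y,
        pen_status=pen_status,
        azimuth=azimuth,
        altitude=altitude,
        pressure=pressure,
        fs=config.fs,
        p_max=config.p_max,
        meta={"generator": "gen_spiral", "seed": config.seed},
    )


def plant_partial_correlation(n: int, rho: float, seed: int):
    """Trivariate Gaussian sample whose partial corr(x, y | z) equals rho.

    Construction: z ~ N(0,1); (u, v) bivariate standard normal with
    corr(u, v) = rho (v = rho·u + √(1−rho²)·w); x = 0.5·z + u,
    y = 0.5·z + v.  Returns (x, y, z), each of length n.
    """
    if n < 4:
        raise ConfigurationError(f"n must be >= 4 (df = n - 3 >= 1), got {n}")
    if not abs(rho) < 1:
        raise ConfigurationError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    u = rng.normal(size=n)
    w = rng.normal(size=n)
    v = rho * u + np.sqrt(1 - rho * rho) * w
    gamma = 0.5
    return gamma * z + u, gamma * z + v, z


@dataclass(frozen=True)
class RoiEffect:
    """Linear model for one synthetic region:
    value = intercept + beta_level·level + beta_brainvol·brain_volume + N(0, noise_sd²)."""

    beta_level: float
    beta_brainvol: float
    noise_sd: float
    intercept: float | None = None  # default chosen per measure family


#: Baseline intercepts per region family, in that family's natural units
#: (mm^3 for volumes, mm for thickness).
_DEFAULT_INTERCEPT = {
    "cortical_cv": 2000.0,
    "cortical_ct": 2.5,
    "subcortical": 5000.0,
    "network": 10000.0,
}
_FAMILY_MEASURE = {
    "cortical_cv": "CV",
    "cortical_ct": "CT",
    "subcortical": "subcortical_volume",
    "network": "network_volume",
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of a simulated cohort.

    Tremor scores are integers drawn uniformly on ``level_range`` (a
    clinical rating scale is an integer sum of items); total brain volumes
    are Normal(brainvol_mean, brainvol_sd²).  Each subject performs one
    spiral trial whose tremor amplitude is ``tremor_per_level × level``,
    from which handwriting features are extracted.  ``roi_effects`` maps
    region names to linear couplings (see :class:`RoiEffect`); regions are
    grouped into morphometry tables by their name family.  When
    ``planted_partial_rho`` is set, an extra feature column ``planted_x``
    and a CT region ``lh_ct_precentral_part1`` are generated from a
    trivariate Gaussian (with z mapped affinely onto brain volume) whose
    partial correlation given brain volume equals the requested value.
    """

    n_subjects: int = 19
    level_range: tuple[int, int] = (2, 45)
    brainvol_mean: float = 1.1e6   # mm^3
    brainvol_sd: float = 1.0e5
    tremor_per_level: float = 0.15  # tablet units of tremor per score point
    subject_gain_sd: float = 0.3   # sd of per-subject log tremor gain
    roi_effects: dict[str, RoiEffect] = field(default_factory=dict)
    planted_partial_rho: float | None = None
    spiral: SpiralSimConfig = field(default_factory=SpiralSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError(
                f"n_subjects must be >= 4 (df = n - 3 >= 1), got {self.n_subjects}"
            )
        lo, hi = self.level_range
        if not (0 <= lo < hi):
            raise ConfigurationError(f"level_range must satisfy 0 <= lo < hi, got {self.level_range}")
        if self.brainvol_mean <= 0 or self.brainvol_sd <= 0:
            raise ConfigurationError("brainvol_mean and brainvol_sd must be > 0")
        if self.subject_gain_sd < 0:
            raise ConfigurationError(f"subject_gain_sd must be >= 0, got {self.subject_gain_sd}")
        if self.planted_partial_rho is not None and not abs(self.planted_partial_rho) < 1:
            raise ConfigurationError(
                f"planted_partial_rho must satisfy |rho| < 1, got {self.planted_partial_rho}"
            )
        for name, eff in self.roi_effects.items():
            if eff.noise_sd <= 0:
                raise ConfigurationError(f"roi_effects[{name!r}].noise_sd must be > 0")
            if classify_region(name) == "unknown":
                raise ConfigurationError(f"roi_effects region {name!r} not in any vocabulary")
        self.spiral.validate()


@dataclass(frozen=True)
class Subject:
    """One simulated subject: id, covariates and handwriting features."""

    subject: str
    tremor_level: float
    brain_volume: float
    features: dict[str, float]


def gen_cohort(config: CohortSimConfig):
    """Simulate a cohort; returns (subjects, roi_tables).

    ``subjects`` is a list of :class:`Subject`; ``roi_tables`` maps family
    name (cortical_cv, cortical_ct, subcortical, network, and optionally
    planted) to :class:`RoiTable`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.level_range
    levels = rng.integers(lo, hi + 1, size=n).astype(float)
    brainvol = rng.normal(config.brainvol_mean, config.brainvol_sd, size=n)
    brainvol = np.maximum(brainvol, 1.0)  # volumes must stay positive

    planted_feature = None
    planted_roi = None
    if config.planted_partial_rho is not None:
        px, py, pz = plant_partial_correlation(
            n, config.planted_partial_rho, seed=int(rng.integers(_SEED_MAX))
        )
        # map the z component affinely onto brain volume; partial correlation
        # is invariant under affine transforms of the control
        brainvol = config.brainvol_mean + config.brainvol_sd * pz
        brainvol = np.maximum(brainvol, 1.0)
        planted_feature = px
        planted_roi = 2.5 + 0.2 * py  # CT-scaled; affine, so rho is preserved

    trial_seeds = rng.integers(_SEED_MAX, size=n)
    # inter-subject variability in tremor expression: multiplicative
    # log-normal gain so identical scores still yield different amplitudes
    gains = np.exp(rng.normal(0.0, config.subject_gain_sd, size=n))
    subjects: list[Subject] = []
    for i in range(n):
        spiral_cfg = replace(
            config.spiral,
            tremor_amplitude=config.tremor_per_level * levels[i] * gains[i],
            seed=int(trial_seeds[i]),
        )
        feats = summarize(gen_spiral(spiral_cfg), surface_only=True)
        if planted_feature is not None:
            feats["planted_x"] = float(planted_feature[i])
        subjects.append(
            Subject(
                subject=f"S{i + 1:03d}",
                tremor_level=float(levels[i]),
                brain_volume=float(brainvol[i]),
                features=feats,
            )
        )

    ids = [s.subject for s in subjects]
    by_family: dict[str, dict[str, np.ndarray]] = {}
    for region, eff in config.roi_effects.items():
        family = classify_region(region)
        intercept = eff.intercept if eff.intercept is not None else _DEFAULT_INTERCEPT[family]
        values = (
            intercept
            + eff.beta_level * levels
            + eff.beta_brainvol * brainvol
            + rng.normal(0, eff.noise_sd, size=n)
        )
        by_family.setdefault(family, {})[region] = values

    roi_tables: dict[str, RoiTable] = {}
    for family, cols in by_family.items():
        regions = list(cols)
        roi_tables[family] = RoiTable(
            measure=_FAMILY_MEASURE[family],
            subjects=ids,
            regions=regions,
            values=np.column_stack([cols[r] for r in regions]),
        )
    if planted_roi is not None:
        roi_tables["planted"] = RoiTable(
            measure="CT",
            subjects=ids,
            regions=["lh_ct_precentral_part1"],
            values=planted_roi[:, None],
        )
    return subjects, roi_tables


def subjects_to_frames(subjects: list[Subject]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a subject list into (covariates, features) DataFrames keyed by id."""
    idx = pd.Index([s.subject for s in subjects], name="subject")
    cov = pd.DataFrame(
        {
            "tremor_level": [s.tremor_level for s in subjects],
            "brain_volume": [s.brain_volume for s in subjects],
        },
        index=idx,
    )
    feat = pd.DataFrame([s.features for s in subjects], index=idx)
    return cov, feat
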