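"""Regional morphometry tables and cohort alignment.

The neuroimaging side of the analysis is consumed as plain tabular files —
one row per subject, one column per named region — produced upstream by a
surface-reconstruction pipeline that is out of scope here.  Four measures
are supported: cortical volume (CV) and cortical thickness (CT) on a
fine-grained ~308-parcel subdivision of the Desikan–Killiany atlas,
subcortical structure volumes, and cerebellar volumes of the Yeo 7/17
functional networks.

Region names follow the conventions of those upstream tables:

* cortical parcels: ``lh_precentral_part7`` (thickness: ``lh_ct_precentral_part7``)
* subcortical: ``rh_Thalamus``
* cerebellar networks: ``lh_Somato_Motor_A``

Validation checks names against packaged vocabularies so typos surface
early without requiring any neuroimaging software to be installed.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import SampleSizeError, ValidationError

log = logging.getLogger(__name__)

MEASURES = ("CV", "CT", "subcortical_volume", "network_volume")

_PART_RE = re.compile(r"^(?P<base>[a-z]+)(?:_part(?P<part>\d+))?$")


def _load_names(fname: str) -> frozenset[str]:
    text = resources.files("spiraltrem.data").joinpath(fname).read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


DK_CORTICAL = _load_names("dk_cortical_regions.txt")
SUBCORTICAL = _load_names("subcortical_regions.txt")
YEO7 = _load_names("yeo7_networks.txt")
YEO17 = _load_names("yeo17_networks.txt")


def classify_region(name: str) -> str:
    """Classify a region name into a vocabulary family.

    Returns one of ``"cortical_cv"``, ``"cortical_ct"``, ``"subcortical"``,
    ``"network"`` or ``"unknown"``.  Hemisphere prefixes lh_/rh_ are
    required; cortical thickness parcels carry an additional ct_ prefix.
    """
    m = re.match(r"^(lh|rh)_(.+)$", name)
    if not m:
        return "unknown"
    rest = m.group(2)
    family = "cortical_cv"
    if rest.startswith("ct_"):
        family = "cortical_ct"
        rest = rest[3:]
    pm = _PART_RE.match(rest)
    if pm and pm.group("base") in DK_CORTICAL:
        return family
    if family == "cortical_ct":
        return "unknown"
    if rest in SUBCORTICAL:
        return "subcortical"
    if rest in YEO7 or rest in YEO17:
        return "network"
    return "unknown"


@dataclass
class RoiTable:
    """Subjects × regions matrix of one morphometry measure."""

    measure: str
    subjects: list[str]
    regions: list[str]
    values: np.ndarray

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("duplicate subject ids in ROI table")
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("duplicate region names in ROI table")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.regions)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.regions)} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ROI values must be finite")
        if self.measure != "CT" and np.any(self.values <= 0):
            raise ValidationError(f"{self.measure} volumes must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subjects, name="subject"),
                            columns=self.regions)

    def reindex(self, subjects: list[str]) -> "RoiTable":
        frame = self.to_frame().loc[subjects]
        return RoiTable(self.measure, list(frame.index), self.regions, frame.to_numpy())


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject scalar covariates for the correlation analyses."""

    subject: str
    tremor_level: float  # clinical tremor-severity score, >= 0
    brain_volume: float  # total brain volume (mm^3), > 0

    def __post_init__(self):
        if self.tremor_level < 0:
            raise ValidationError(f"{self.subject}: tremor_level must be >= 0")
        if self.brain_volume <= 0:
            raise ValidationError(f"{self.subject}: brain_volume must be > 0")


def read_roi_table(path, measure: str, strict: bool = False) -> RoiTable:
    """Read a delimiter-separated ROI table (first column = subject id).

    Region names are checked against the packaged vocabularies; unknown
    names produce a warning, or an error in ``strict`` mode.  Non-numeric
    cells raise a parse error naming the offending (subject, region)
    coordinates.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected subject column plus >= 1 region column")
    id_col = df.columns[0]
    subjects = df[id_col].astype(str).tolist()
    if len(set(subjects)) != len(subjects):
        dupes = sorted({s for s in subjects if subjects.count(s) > 1})
        raise ValidationError(f"{path}: duplicated subject ids: {dupes}")
    regions = list(df.columns[1:])
    unknown = [r for r in regions if classify_region(r) == "unknown"]
    if unknown:
        msg = f"{path}: unrecognized region names: {unknown}"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    values = np.empty((len(subjects), len(regions)))
    for j, r in enumerate(regions):
        for i, cell in enumerate(df[r]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric cell at subject {subjects[i]!r}, region {r!r}: {cell!r}"
                )
    return RoiTable(measure=measure, subjects=subjects, regions=regions, values=values)


def read_covariates(path) -> list[SubjectCovariates]:
    """Read per-subject covariates from a table with columns
    subject, tremor_level, brain_volume (extra columns ignored)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject", "tremor_level", "brain_volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        SubjectCovariates(str(row.subject), float(row.tremor_level), float(row.brain_volume))
        for row in df.itertuples()
    ]


@dataclass
class AlignedCohort:
    """Listwise-complete analysis set shared across all inputs.

    ``covariates`` has columns tremor_level and brain_volume; ``features``
    one column per handwriting feature; ``roi_tables`` maps family name to
    a subject-aligned :class:`RoiTable`.  Row order is the order of the
    covariate input, so alignment is deterministic and idempotent.
    """

    subjects: list[str]
    covariates: pd.DataFrame
    features: pd.DataFrame
    roi_tables: dict[str, RoiTable]


def align_cohort(
    subjects: list[SubjectCovariates],
    features: pd.DataFrame,
    roi_tables: dict[str, RoiTable],
) -> AlignedCohort:
    """Intersect subject ids across covariates, features and ROI tables.

    Subjects missing from any source are dropped (and logged); fewer than 4
    shared subjects is an error since the partial-correlation df would fall
    below 1.  Order follows the covariate input, so re-aligning an aligned
    cohort is the identity.
    """
    ids = [s.subject for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject ids in covariates")
    shared = set(ids) & set(map(str, features.index))
    for table in roi_tables.values():
        shared &= set(table.subjects)
    kept = [s for s in ids if s in shared]
    dropped = sorted(set(ids) - shared)
    if dropped:
        log.info("align_cohort: dropped %d subject(s) missing from a source: %s",
                 len(dropped), dropped)
    if len(kept) < 4:
        raise SampleSizeError(
            f"only {len(kept)} subjects shared across inputs; need >= 4 (df >= 1)"
        )
    cov = pd.DataFrame(
        {
            "tremor_level": [s.tremor_level for s in subjects if s.subject in shared],
            "brain_volume": [s.brain_volume for s in subjects if s.subject in shared],
        },
        index=pd.Index(kept, name="subject"),
    )
    feat = features.loc[kept]
    rois = {name: table.reindex(kept) for name, table in roi_tables.items()}
    return AlignedCohort(subjects=kept, covariates=cov, features=feat, roi_tables=rois)
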