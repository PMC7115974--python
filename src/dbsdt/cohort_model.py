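"""Patient records, cohort file I/O, neurophysiology coding and outcome labels.

A cohort is a list of per-patient records carrying six candidate prognostic
features (sex, etiology, baseline BFMDRS-m severity, cranial MRI class, CMCT
status, SEP status), the 1-year outcome (follow-up BFMDRS-m score and/or the
percentage change it implies) and an optional COPM change.

CMCT and SEP are recorded per limb (up to four limbs each) and collapsed to a
patient-level Normal / Abnormal / Not-available status: a single abnormal limb
makes the patient abnormal; a patient with no technically satisfactory limb
recording is Not available (NA).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "LimbStatus",
    "NeurophysStatus",
    "PatientRecord",
    "FeatureSpec",
    "Cohort",
    "CohortError",
    "SEX_LEVELS",
    "ETIOLOGY_LEVELS",
    "ACQUIRED_GROUPS",
    "GENETIC_GROUPS",
    "DEFAULT_MRI_LEVELS",
    "NEUROPHYS_LEVELS",
    "default_schema",
    "code_limb_status",
    "percent_improvement",
    "binarize_outcome",
    "binarize_copm",
    "filter_etiology",
    "filter_feature_available",
    "read_cohort",
    "write_cohort",
]

BFM_MAX = 120.0  # BFMDRS-m motor subscore range is 0-120


class CohortError(ValueError):
    """Raised for schema violations, out-of-range scores or malformed files."""


class LimbStatus(str, Enum):
    """Status of a single limb's neurophysiology recording."""

    NORMAL = "normal"
    ABNORMAL = "abnormal"
    UNSATISFACTORY = "unsatisfactory"


class NeurophysStatus(str, Enum):
    """Patient-level CMCT or SEP status after binary limb coding."""

    NORMAL = "normal"
    ABNORMAL = "abnormal"
    NA = "NA"


SEX_LEVELS = ("M", "F")
ETIOLOGY_LEVELS = (
    "isolated_genetic",
    "complex_genetic",
    "acquired_cp",
    "acquired_metabolic",
    "acquired_other",
    "acquired_degenerative",
)
GENETIC_GROUPS = frozenset({"isolated_genetic", "complex_genetic"})
ACQUIRED_GROUPS = frozenset(
    {"acquired_cp", "acquired_metabolic", "acquired_other", "acquired_degenerative"}
)
DEFAULT_MRI_LEVELS = ("normal", "abnormal")
NEUROPHYS_LEVELS = ("normal", "abnormal", "NA")


def code_limb_status(limbs: Sequence[LimbStatus]) -> NeurophysStatus:
    """Collapse per-limb recordings to a patient-level status.

    The patient is ``abnormal`` if one or more limbs are abnormal,
    ``NA`` if no limb yielded a satisfactory recording (including an empty
    list: nothing was recorded), and ``normal`` otherwise.  Technically
    unsatisfactory limbs never contribute evidence either way.
    """
    limbs = [LimbStatus(l) for l in limbs]
    if len(limbs) > 4:
        raise CohortError(f"at most 4 limbs per patient, got {len(limbs)}")
    if any(l is LimbStatus.ABNORMAL for l in limbs):
        return NeurophysStatus.ABNORMAL
    if all(l is LimbStatus.UNSATISFACTORY for l in limbs):
        # covers the empty list: no satisfactory recording exists
        return NeurophysStatus.NA
    return NeurophysStatus.NORMAL


def percent_improvement(baseline: float, followup: float) -> float:
    """Percentage improvement in BFMDRS-m from baseline to follow-up.

    ``100 * (baseline - followup) / baseline``; positive values mean the
    dystonia score fell (improvement), negative values mean worsening.
    """
    if baseline <= 0:
        raise CohortError(
            f"percent improvement undefined for baseline {baseline!r} (must be > 0)"
        )
    return 100.0 * (baseline - followup) / baseline


def binarize_outcome(pct: float, threshold: float = 0.0, mode: str = "strict_gt") -> int:
    """Binary outcome label from a % change in BFMDRS-m.

    ``strict_gt`` labels positive iff ``pct > threshold`` (the "any
    improvement, > 0%" convention); ``ge`` labels positive iff
    ``pct >= threshold`` (the literature's ">= 20%" cut-off convention).
    """
    if mode == "strict_gt":
        return int(pct > threshold)
    if mode == "ge":
        return int(pct >= threshold)
    raise CohortError(f"unknown outcome mode {mode!r}; expected 'strict_gt' or 'ge'")


def binarize_copm(copm_change: Optional[float], threshold: float = 2.0) -> int:
    """Binary label from a COPM change; >= 2 points is clinically significant."""
    if copm_change is None or (isinstance(copm_change, float) and math.isnan(copm_change)):
        raise CohortError("COPM change is missing; cannot binarize")
    return int(copm_change >= threshold)


@dataclass(frozen=True)
class FeatureSpec:
    """One feature of the cohort schema."""

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise CohortError(f"feature kind must be categorical/continuous, got {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise CohortError(f"categorical feature {self.name!r} needs levels")


def default_schema(mri_levels: Sequence[str] = DEFAULT_MRI_LEVELS) -> tuple[FeatureSpec, ...]:
    """The six-feature schema used throughout the analysis.

    MRI is an opaque categorical label whose levels are user-defined
    (default normal/abnormal); CMCT and SEP carry NA as an ordinary level.
    """
    return (
        FeatureSpec("sex", "categorical", SEX_LEVELS),
        FeatureSpec("etiology", "categorical", ETIOLOGY_LEVELS),
        FeatureSpec("baseline_bfm", "continuous"),
        FeatureSpec("mri", "categorical", tuple(mri_levels)),
        FeatureSpec("cmct", "categorical", NEUROPHYS_LEVELS),
        FeatureSpec("sep", "categorical", NEUROPHYS_LEVELS),
    )


@dataclass
class PatientRecord:
    """One child's clinical features, limb-level neurophysiology and outcome."""

    id: str
    sex: str
    etiology: str
    mri: str
    baseline_bfm: float
    followup_bfm: Optional[float] = None
    pct_change: Optional[float] = None
    copm_change: Optional[float] = None
    cmct_limbs: Optional[tuple[LimbStatus, ...]] = None
    sep_limbs: Optional[tuple[LimbStatus, ...]] = None
    cmct: NeurophysStatus = NeurophysStatus.NA
    sep: NeurophysStatus = NeurophysStatus.NA

    def resolved_pct_change(self) -> Optional[float]:
        """The % change, preferring an explicit value over the score pair."""
        if self.pct_change is not None:
            return self.pct_change
        if self.followup_bfm is not None:
            return percent_improvement(self.baseline_bfm, self.followup_bfm)
        return None

    def feature_value(self, name: str):
        if name in ("cmct", "sep"):
            return getattr(self, name).value
        return getattr(self, name)

    def validate(self, schema: Sequence[FeatureSpec]) -> None:
        for score_name in ("baseline_bfm", "followup_bfm"):
            v = getattr(self, score_name)
            if v is not None and not (0.0 <= v <= BFM_MAX):
                raise CohortError(
                    f"record {self.id!r}: {score_name} = {v} outside [0, {BFM_MAX:g}]"
                )
        for spec in schema:
            if spec.kind != "categorical":
                continue
            v = self.feature_value(spec.name)
            if v not in spec.levels:
                raise CohortError(
                    f"record {self.id!r}: {spec.name} level {v!r} not in {spec.levels}"
                )
        for limbs, status, label in (
            (self.cmct_limbs, self.cmct, "cmct"),
            (self.sep_limbs, self.sep, "sep"),
        ):
            if limbs is not None and code_limb_status(limbs) is not status:
                raise CohortError(
                    f"record {self.id!r}: {label} status {status.value!r} inconsistent "
                    f"with limb data {[l.value for l in limbs]}"
                )


@dataclass
class Cohort:
    """Ordered collection of patient records with a feature schema.

    ``labels`` (optional) are binary outcomes aligned 1:1 with ``records``.
    """

    records: list[PatientRecord]
    feature_schema: tuple[FeatureSpec, ...] = field(default_factory=default_schema)
    labels: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise CohortError(
                f"{len(self.labels)} labels for {len(self.records)} records"
            )

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        for i, rec in enumerate(self.records):
            try:
                rec.validate(self.feature_schema)
            except CohortError as exc:
                raise CohortError(f"row {i}: {exc}") from exc

    def feature_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.feature_schema)

    def pct_changes(self) -> list[Optional[float]]:
        return [r.resolved_pct_change() for r in self.records]

    def with_labels(self, threshold: float = 0.0, mode: str = "strict_gt") -> "Cohort":
        """Return a copy labelled by binarizing each record's % change."""
        labels = []
        for i, pct in enumerate(self.pct_changes()):
            if pct is None:
                raise CohortError(f"row {i}: no outcome (followup_bfm/pct_change both missing)")
            labels.append(binarize_outcome(pct, threshold, mode))
        return Cohort(list(self.records), self.feature_schema, labels)

    def with_copm_labels(self, threshold: float = 2.0) -> "Cohort":
        """Return a copy labelled by the COPM >= threshold rule, dropping
        records without COPM data."""
        kept, labels = [], []
        for r in self.records:
            if r.copm_change is None:
                continue
            kept.append(r)
            labels.append(binarize_copm(r.copm_change, threshold))
        return Cohort(kept, self.feature_schema, labels)

    def subset(self, keep: Sequence[bool]) -> "Cohort":
        recs = [r for r, k in zip(self.records, keep) if k]
        labs = (
            [l for l, k in zip(self.labels, keep) if k] if self.labels is not None else None
        )
        return Cohort(recs, self.feature_schema, labs)


def filter_etiology(cohort: Cohort, groups: Iterable[str]) -> Cohort:
    """Keep only records whose etiology lies in ``groups`` (order preserved)."""
    groups = frozenset(groups)
    if not groups:
        raise CohortError("etiology filter needs a non-empty group set")
    unknown = groups - set(ETIOLOGY_LEVELS)
    if unknown:
        raise CohortError(f"unknown etiology group(s): {sorted(unknown)}")
    return cohort.subset([r.etiology in groups for r in cohort.records])


def filter_feature_available(cohort: Cohort, feature: str) -> Cohort:
    """Drop records whose CMCT (or SEP) status is Not available."""
    if feature not in ("cmct", "sep"):
        raise CohortError(f"{feature!r} is not a neurophysiology status feature")
    return cohort.subset(
        [getattr(r, feature) is not NeurophysStatus.NA for r in cohort.records]
    )


# ---------------------------------------------------------------------------
# File I/O.  UTF-8 delimited text, header row, one row per patient.  Missing
# values are empty strings; the literal "NA" in the cmct/sep columns is the
# Not-available *level*, not a missing value.  Floats are written with repr so
# a write -> read -> write cycle is byte-identical.
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "id",
    "sex",
    "etiology",
    "mri",
    "baseline_bfm",
    "followup_bfm",
    "pct_change",
    "copm_change",
    "cmct",
    "sep",
]
_LIMB_COLUMNS = [f"{t}_limb{i}" for t in ("cmct", "sep") for i in (1, 2, 3, 4)]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(float(value))
    return str(value)


def _parse_float(text: str, column: str, row: int) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortError(f"row {row}: column {column!r} is not numeric: {text!r}")


def _parse_limbs(row_map: dict, prefix: str, row: int) -> Optional[tuple[LimbStatus, ...]]:
    cells = [row_map.get(f"{prefix}_limb{i}", "") for i in (1, 2, 3, 4)]
    filled = [c for c in cells if c != ""]
    if not filled:
        return None
    try:
        return tuple(LimbStatus(c) for c in filled)
    except ValueError:
        raise CohortError(f"row {row}: bad {prefix} limb status among {filled!r}")


def read_cohort(
    path: Union[str, Path],
    schema: Optional[Sequence[FeatureSpec]] = None,
    delimiter: str = ",",
) -> Cohort:
    """Read and validate a cohort file.

    Rows violating record invariants are rejected with a row-indexed message.
    Limb columns (``cmct_limb1..4``/``sep_limb1..4``) are optional; when
    present they must re-code to the patient-level status.
    """
    schema = tuple(schema) if schema is not None else default_schema()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _BASE_COLUMNS if c not in header]
        if missing:
            raise CohortError(f"missing column(s): {missing}")
        records = []
        for i, row_map in enumerate(reader):
            cmct_limbs = _parse_limbs(row_map, "cmct", i)
            sep_limbs = _parse_limbs(row_map, "sep", i)
            cmct_text = row_map["cmct"]
            sep_text = row_map["sep"]
            try:
                cmct = (
                    NeurophysStatus(cmct_text)
                    if cmct_text
                    else code_limb_status(cmct_limbs or ())
                )
                sep = (
                    NeurophysStatus(sep_text)
                    if sep_text
                    else code_limb_status(sep_limbs or ())
                )
            except ValueError as exc:
                raise CohortError(f"row {i}: {exc}")
            baseline = _parse_float(row_map["baseline_bfm"], "baseline_bfm", i)
            if baseline is None:
                raise CohortError(f"row {i}: baseline_bfm is required")
            rec = PatientRecord(
                id=row_map["id"],
                sex=row_map["sex"],
                etiology=row_map["etiology"],
                mri=row_map["mri"],
                baseline_bfm=baseline,
                followup_bfm=_parse_float(row_map["followup_bfm"], "followup_bfm", i),
                pct_change=_parse_float(row_map["pct_change"], "pct_change", i),
                copm_change=_parse_float(row_map["copm_change"], "copm_change", i),
                cmct_limbs=cmct_limbs,
                sep_limbs=sep_limbs,
                cmct=cmct,
                sep=sep,
            )
            try:
                rec.validate(schema)
            except CohortError as exc:
                raise CohortError(f"row {i}: {exc}")
            records.append(rec)
    return Cohort(records, schema)


def write_cohort(cohort: Cohort, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a cohort in the dialect :func:`read_cohort` reads.

    Limb columns are emitted only when at least one record carries limb data.
    """
    has_limbs = any(r.cmct_limbs is not None or r.sep_limbs is not None for r in cohort.records)
    columns = _BASE_COLUMNS + (_LIMB_COLUMNS if has_limbs else [])
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(columns)
        for r in cohort.records:
            row = [
                r.id,
                r.sex,
                r.etiology,
                r.mri,
                _fmt(r.baseline_bfm),
                _fmt(r.followup_bfm),
                _fmt(r.pct_change),
                _fmt(r.copm_change),
                r.cmct.value,
                r.sep.value,
            ]
            if has_limbs:
                for limbs in (r.cmct_limbs, r.sep_limbs):
                    cells = [l.value for l in limbs] if limbs is not None else []
                    row.extend(cells + [""] * (4 - len(cells)))
            writer.writerow(row)
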