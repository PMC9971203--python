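"""Domain types and file I/O for bilateral carotid pulse-wave screening.

The screening method works on *differential* pulse waves: the piezoelectric
sensor senses skin-surface velocity, so each recording is the time derivative
of the displacement pulse wave, sampled simultaneously at the left and right
common carotid arteries.  This module defines the containers the rest of the
pipeline passes around (subject metadata, raw recordings, averaged cycles,
feature vectors, cohorts) and the plain-text formats they are stored in:

* cohort table — CSV with columns ``subject_id, age, sex, occlusion_side,
  ico_neck, ico_intra, mco`` (flags are 0/1; side is L, R or empty);
* recording — CSV with a commented key/value header (``# fs: 1000`` etc.)
  followed by ``left,right`` sample columns;
* feature sets and evaluation reports — JSON (see :mod:`pulsescreen.inference`).
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulseScreenError",
    "ValidationError",
    "FormatError",
    "InsufficientCyclesError",
    "AnnotationError",
    "StructuralValidityError",
    "SubjectMeta",
    "RawRecording",
    "AveragedCycle",
    "FeatureVector",
    "CohortTable",
    "read_cohort_table",
    "write_cohort_table",
    "load_table1_cohort",
    "read_recording",
    "write_recording",
]

Side = Literal["L", "R", "none"]
OcclusionType = Literal["ICO_neck", "ICO_intra", "MCO", "none"]


class PulseScreenError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PulseScreenError):
    """Cohort-table row violates the subject-metadata invariants."""


class FormatError(PulseScreenError):
    """Recording or table file is malformed."""


class InsufficientCyclesError(PulseScreenError):
    """Too few cardiac cycles for beat detection / averaging."""


class AnnotationError(PulseScreenError):
    """An averaged cycle lacks the peak structure the features require."""


class StructuralValidityError(PulseScreenError):
    """Simulator parameters destroy the dominant positive/negative peak pair."""


# --------------------------------------------------------------------------
# Subject metadata
# --------------------------------------------------------------------------

_OCCLUSION_FLAGS: tuple[OcclusionType, ...] = ("ICO_neck", "ICO_intra", "MCO")


@dataclass(frozen=True)
class SubjectMeta:
    """One subject's demographic and diagnostic metadata.

    ``group`` is derived: a subject is a patient iff exactly one occlusion
    flag is set and an occlusion side is given.  Age and sex are carried for
    bookkeeping only — the classifier uses the three waveform features alone.
    """

    subject_id: str
    age: int
    sex: Literal["male", "female"]
    occlusion_side: Side = "none"
    occlusion_type: OcclusionType = "none"
    device: str | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"{self.subject_id}: age must be > 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.subject_id}: bad sex {self.sex!r}")
        side_none = self.occlusion_side == "none"
        type_none = self.occlusion_type == "none"
        if side_none != type_none:
            raise ValidationError(
                f"{self.subject_id}: occlusion side ({self.occlusion_side}) and "
                f"type ({self.occlusion_type}) must both be set or both be none"
            )
        if self.occlusion_side not in ("L", "R", "none"):
            raise ValidationError(f"{self.subject_id}: bad side {self.occlusion_side!r}")
        if self.occlusion_type not in _OCCLUSION_FLAGS + ("none",):
            raise ValidationError(f"{self.subject_id}: bad type {self.occlusion_type!r}")

    @property
    def group(self) -> Literal["healthy", "patient"]:
        return "healthy" if self.occlusion_type == "none" else "patient"

    @property
    def label(self) -> Literal["Positive", "Negative"]:
        """Classification label: patients are Positive."""
        return "Positive" if self.group == "patient" else "Negative"


@dataclass
class RawRecording:
    """Bilateral raw differential pulse-wave signals for one subject.

    ``left`` / ``right`` are sensor samples in arbitrary units (the method is
    amplitude-invariant); ``fs`` is the sampling frequency in Hz (1000 for the
    reference acquisition chain).
    """

    meta: SubjectMeta
    fs: float
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"{self.meta.subject_id}: fs must be > 0, got {self.fs}")
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.size == 0 or self.right.size == 0:
            raise FormatError(f"{self.meta.subject_id}: empty signal")
        if self.left.shape != self.right.shape:
            raise FormatError(
                f"{self.meta.subject_id}: left/right lengths differ "
                f"({self.left.size} vs {self.right.size})"
            )


@dataclass
class AveragedCycle:
    """A single preprocessed, averaged, peak-normalized differential cycle.

    The positive-peak amplitude is 1 by the normalization contract; the DC
    component was removed from the raw average *before* normalization, so the
    cycle is not necessarily zero-mean.  ``pos_peak_index`` is the main
    positive peak (A) and ``last_neg_peak_index`` the last strong negative
    peak (B) preceding the dicrotic notch.
    """

    samples: np.ndarray
    fs: float
    pos_peak_index: int
    last_neg_peak_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isclose(self.samples.max(), 1.0, atol=1e-9):
            raise ValidationError(
                f"normalization contract violated: max={self.samples.max()!r}"
            )
        n = self.samples.size
        if not (0 <= self.pos_peak_index < self.last_neg_peak_index < n):
            raise ValidationError(
                "peak indices out of order: "
                f"A={self.pos_peak_index}, B={self.last_neg_peak_index}, len={n}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class FeatureVector:
    """The three dynamic features x = [x1, x2, x3] = [MCC, DNP, DPA].

    x1 — maximum of the left/right cross-correlation, in [-1, 1];
    x2 — absolute left/right difference in the count of small peaks between
         the main positive and last negative peaks (integer >= 0);
    x3 — absolute left/right difference of the post-dicrotic-notch peak
         amplitude (>= 0, dimensionless after normalization).
    """

    x1: float
    x2: int
    x3: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.x1 <= 1.0 + 1e-9:
            raise ValidationError(f"x1 (MCC) out of [-1, 1]: {self.x1}")
        if self.x2 < 0:
            raise ValidationError(f"x2 (DNP) negative: {self.x2}")
        if self.x3 < 0:
            raise ValidationError(f"x3 (DPA) negative: {self.x3}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, float(self.x2), self.x3])


@dataclass
class CohortTable:
    """Ordered cohort of subjects with optional per-subject features.

    Labels are derived from the metadata (patient -> Positive), matching the
    convention that the positive class is "occlusion present".
    """

    subjects: list[SubjectMeta]
    features: dict[str, FeatureVector] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectMeta]:
        return iter(self.subjects)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.subjects]

    @property
    def n_positive(self) -> int:
        return sum(s.group == "patient" for s in self.subjects)

    @property
    def n_negative(self) -> int:
        return sum(s.group == "healthy" for s in self.subjects)

    def counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in _OCCLUSION_FLAGS}
        for s in self.subjects:
            if s.occlusion_type != "none":
                out[s.occlusion_type] += 1
        return out

    def feature_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (X, y, subject_ids) for subjects that have features.

        y is 1 for Positive (patient), 0 for Negative.
        """
        ids = [s.subject_id for s in self.subjects if s.subject_id in self.features]
        X = np.array([self.features[i].as_array() for i in ids])
        by_id = {s.subject_id: s for s in self.subjects}
        y = np.array([1 if by_id[i].group == "patient" else 0 for i in ids])
        return X, y, ids


# --------------------------------------------------------------------------
# Cohort table I/O
# --------------------------------------------------------------------------

_COHORT_COLUMNS = ["subject_id", "age", "sex", "occlusion_side", "ico_neck", "ico_intra", "mco"]
_FLAG_TO_TYPE = {"ico_neck": "ICO_neck", "ico_intra": "ICO_intra", "mco": "MCO"}


def read_cohort_table(path: str | Path | io.TextIOBase) -> CohortTable:
    """Read a cohort table CSV and validate every row.

    Raises :class:`ValidationError` naming the offending row when a healthy
    subject carries an occlusion flag, a patient carries two, or a flag is set
    without a side (and vice versa); raises :class:`FormatError` on schema
    problems (missing columns, empty file).
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "occlusion_side": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty cohort table: {path}") from exc
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"cohort table has no rows: {path}")

    subjects: list[SubjectMeta] = []
    for idx, row in df.iterrows():
        sid = str(row["subject_id"])
        flags = [name for name in _FLAG_TO_TYPE if int(row[name] or 0) == 1]
        side_raw = row["occlusion_side"]
        side = "none" if (pd.isna(side_raw) or str(side_raw).strip() == "") else str(side_raw).strip()
        if len(flags) > 1:
            raise ValidationError(f"row {idx} ({sid}): multiple occlusion flags {flags}")
        occ_type = _FLAG_TO_TYPE[flags[0]] if flags else "none"
        try:
            meta = SubjectMeta(
                subject_id=sid,
                age=int(row["age"]),
                sex=str(row["sex"]).strip().lower(),  # type: ignore[arg-type]
                occlusion_side=side,  # type: ignore[arg-type]
                occlusion_type=occ_type,  # type: ignore[arg-type]
                device=str(row["device"]) if "device" in df.columns and not pd.isna(row.get("device")) else None,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        subjects.append(meta)
    return CohortTable(subjects=subjects)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "occlusion_side": "" if s.occlusion_side == "none" else s.occlusion_side,
                "ico_neck": int(s.occlusion_type == "ICO_neck"),
                "ico_intra": int(s.occlusion_type == "ICO_intra"),
                "mco": int(s.occlusion_type == "MCO"),
            }
        )
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def load_table1_cohort() -> CohortTable:
    """Load the packaged 53-subject reference cohort (30 healthy, 23 patients)."""
    ref = importlib.resources.files("pulsescreen").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as p:
        return read_cohort_table(p)


# --------------------------------------------------------------------------
# Recording I/O — self-describing CSV with a commented header
# --------------------------------------------------------------------------


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as CSV: ``# key: value`` header lines, then left,right."""
    m = rec.meta
    lines = [
        f"# fs: {rec.fs!r}",
        f"# subject_id: {m.subject_id}",
        f"# age: {m.age}",
        f"# sex: {m.sex}",
        f"# occlusion_side: {m.occlusion_side}",
        f"# occlusion_type: {m.occlusion_type}",
    ]
    if m.device is not None:
        lines.append(f"# device: {m.device}")
    lines.append("left,right")
    body = "\n".join(
        f"{float(l)!r},{float(r)!r}" for l, r in zip(rec.left, rec.right)
    )
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording CSV written by :func:`write_recording`.

    The round-trip ``read_recording(write_recording(rec))`` preserves metadata
    exactly and samples to full double precision (``repr`` serialization).
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
        else:
            data_start = i
            break
    else:
        raise FormatError(f"{path}: no data section")

    if "fs" not in header or "subject_id" not in header:
        raise FormatError(f"{path}: header must declare fs and subject_id")
    try:
        fs = float(header["fs"])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric fs {header['fs']!r}") from exc
    if fs <= 0:
        raise FormatError(f"{path}: fs must be > 0, got {fs}")

    try:
        df = pd.read_csv(io.StringIO("".join(lines[data_start:])),
                         float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no sample data") from exc
    for col in ("left", "right"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric samples in column {col!r}")

    meta = SubjectMeta(
        subject_id=header["subject_id"],
        age=int(header.get("age", "1")),
        sex=header.get("sex", "male"),  # type: ignore[arg-type]
        occlusion_side=header.get("occlusion_side", "none"),  # type: ignore[arg-type]
        occlusion_type=header.get("occlusion_type", "none"),  # type: ignore[arg-type]
        device=header.get("device"),
    )
    return RawRecording(
        meta=meta,
        fs=fs,
        left=df["left"].to_numpy(dtype=float),
        right=df["right"].to_numpy(dtype=float),
    )
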