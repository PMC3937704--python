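"""Domain types, validation and CSV I/O for cohort tables.

The pipeline operates on three aligned per-subject tables:

* ``subjects.csv`` — demographics and group membership,
* ``morphometry.csv`` — intracranial volume plus one column per brain region
  (cortical thickness in mm; striatal volumes in mm^3, normalized to
  volume/ICV ratios on read),
* ``cognition.csv`` — five continuous cognitive outcome scores.

One CSV dialect is accepted: comma-separated, UTF-8, ``.`` decimal, mandatory
header row, missing values as empty cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRIATAL_SUFFIX = "_vol_mm3"

#: Cognitive outcome columns, in canonical order.
COGNITIVE_OUTCOMES = (
    "sdmt",
    "letter_number",
    "hvlt_immediate",
    "negative_emotions",
    "timing_precision",
)

#: Covariates used by the main (cognition) analyses.
COVARIATES = ("age", "sex", "education", "visit_count")

SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education_years",
    "visit_count",
    "cag_repeats",
    "motor_score",
)


class SchemaError(ValueError):
    """A CSV header does not match the documented schema."""


class ParseError(ValueError):
    """A cell that must be numeric could not be parsed."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class SampleSizeError(ValueError):
    """Too few subjects for the requested operation."""


class DegenerateDataWarning(UserWarning):
    """Data are degenerate (e.g. zero variance) for the requested statistic."""


class Group(str, Enum):
    CONTROL = "control"
    CASE = "case"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class RegionKind(str, Enum):
    THICKNESS = "thickness"
    VOLUME_RATIO = "volume_ratio"


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's demographics, group label and covariates."""

    subject_id: str
    group: Group
    age: float
    sex: Sex
    education: float
    visit_count: int
    cag_repeats: Optional[int] = None
    motor_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age is not None and not np.isnan(self.age) and self.age <= 0:
            raise ValidationError(f"subject {self.subject_id}: age must be positive")
        if (
            self.education is not None
            and not np.isnan(self.education)
            and self.education < 0
        ):
            raise ValidationError(
                f"subject {self.subject_id}: education must be non-negative"
            )
        if self.visit_count is not None and self.visit_count < 1:
            raise ValidationError(
                f"subject {self.subject_id}: visit_count must be a positive integer"
            )
        if self.cag_repeats is not None and self.cag_repeats < 1:
            raise ValidationError(
                f"subject {self.subject_id}: cag_repeats must be positive"
            )
        if self.motor_score is not None and self.motor_score < 0:
            raise ValidationError(
                f"subject {self.subject_id}: motor_score must be non-negative"
            )


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records with subject_id as index; covariate column names match
    :data:`COVARIATES` (``education`` rather than the on-disk ``education_years``)."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "age": s.age,
                "sex": s.sex.value,
                "education": s.education,
                "visit_count": s.visit_count,
                "cag_repeats": s.cag_repeats,
                "motor_score": s.motor_score,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


@dataclass
class MorphometryTable:
    """Subjects x regions matrix of thickness (mm) and volume/ICV ratios.

    ``values`` is indexed by subject_id with one column per region; ``kinds``
    labels each region as thickness or volume_ratio; ``icv`` (mm^3) and the
    optional raw striatal volumes are retained for provenance so writing a
    cohort back to disk is lossless.
    """

    values: pd.DataFrame
    kinds: pd.Series
    icv: pd.Series
    raw_striatal: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated subject_id rows: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated region names: {dupes}")
        missing = set(self.values.columns) - set(self.kinds.index)
        if missing:
            raise ValidationError(f"regions without a kind label: {sorted(missing)}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("morphometry values must be finite")
        for region in self.values.columns:
            col = self.values[region].to_numpy(dtype=float)
            if self.kinds[region] == RegionKind.THICKNESS.value:
                if np.any(col <= 0):
                    raise ValidationError(f"non-positive thickness in region {region}")
            else:
                if np.any(col <= 0) or np.any(col >= 1):
                    raise ValidationError(
                        f"volume ratio outside (0, 1) in region {region}"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, subject_ids: Sequence[str]) -> "MorphometryTable":
        """Row-subset (and reorder) to the given subjects."""
        raw = None
        if self.raw_striatal is not None:
            raw = self.raw_striatal.loc[list(subject_ids)]
        return MorphometryTable(
            values=self.values.loc[list(subject_ids)],
            kinds=self.kinds,
            icv=self.icv.loc[list(subject_ids)],
            raw_striatal=raw,
        )


@dataclass
class CognitiveScores:
    """Per-subject scores on the five cognitive outcomes.

    The four count-based measures are non-negative integers; timing precision
    (reciprocal of the intertap-interval SD, 1/ms) is a positive real.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COGNITIVE_OUTCOMES) - set(self.values.columns)
        if missing:
            raise SchemaError(f"cognition table missing columns: {sorted(missing)}")
        for col in COGNITIVE_OUTCOMES[:-1]:
            v = self.values[col].dropna()
            if (v < 0).any():
                raise ValidationError(f"negative count in {col}")
            if not np.allclose(v, np.round(v)):
                raise ValidationError(f"non-integer count in {col}")
        tp = self.values["timing_precision"].dropna()
        if (tp <= 0).any():
            raise ValidationError("timing_precision must be positive")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ResidualTable:
    """Observed-minus-predicted morphometry under the normative model.

    Residuals keep the units of the source measure (mm or ratio).  Control
    residuals are the normative reference set; case residuals carry the
    group atrophy signal, so atrophy appears as mean(control) > mean(case).
    """

    residuals: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.residuals.to_numpy(dtype=float))):
            raise ValidationError("residuals must be finite")
        if not self.residuals.index.equals(self.group_labels.index):
            raise ValidationError("residuals and group_labels must share an index")

    @property
    def region_names(self) -> list[str]:
        return list(self.residuals.columns)

    def by_group(self, region: str) -> tuple[np.ndarray, np.ndarray]:
        """(control residuals, case residuals) for one region."""
        col = self.residuals[region]
        return (
            col[self.group_labels == Group.CONTROL.value].to_numpy(dtype=float),
            col[self.group_labels == Group.CASE.value].to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize_striatal_volumes(
    raw_volumes: np.ndarray, icv: np.ndarray
) -> np.ndarray:
    """Divide raw subcortical volumes (mm^3) by intracranial volume (mm^3).

    Head size varies substantially between subjects; expressing striatal
    volumes as dimensionless volume/ICV ratios removes that scale.
    """
    raw_volumes = np.asarray(raw_volumes, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(~np.isfinite(icv)) or np.any(icv <= 0):
        bad = np.nonzero(~(icv > 0))[0]
        raise ValidationError(f"non-positive ICV for subject index {bad.tolist()}")
    if np.any(raw_volumes < 0):
        raise ValidationError("raw volumes must be non-negative")
    if raw_volumes.ndim == 1:
        return raw_volumes / icv
    return raw_volumes / icv[:, None]


def _read_csv_strict(path: Path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        raw = df[col]
        # parse with Python float(): exact shortest-repr round trip, unlike
        # pandas' default fast float parser
        parsed = np.empty(len(raw))
        for row, cell in enumerate(raw):
            if cell == "":
                parsed[row] = np.nan
                continue
            try:
                parsed[row] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric value {cell!r} "
                    f"in column {col!r}, row {row + 2}"
                ) from None
        df[col] = parsed
    return df


def read_cohort(
    subjects_path: str | Path,
    morphometry_path: str | Path,
    cognition_path: str | Path,
) -> tuple[list[SubjectRecord], MorphometryTable, CognitiveScores]:
    """Read and align the three cohort tables.

    Striatal columns (suffix ``_vol_mm3``) are normalized by ICV on read and
    renamed without the suffix.  Subjects present in one file but absent from
    another are dropped; the count is logged.
    """
    subjects_path = Path(subjects_path)
    morphometry_path = Path(morphometry_path)
    cognition_path = Path(cognition_path)

    sdf = _read_csv_strict(
        subjects_path,
        required=[c for c in SUBJECT_COLUMNS if c not in ("cag_repeats", "motor_score")],
        numeric=["age", "education_years", "visit_count", "cag_repeats", "motor_score"],
    )
    mdf = _read_csv_strict(morphometry_path, required=["subject_id", "icv_mm3"], numeric=[])
    region_cols = [c for c in mdf.columns if c not in ("subject_id",)]
    mdf = _read_csv_strict(morphometry_path, required=["subject_id", "icv_mm3"], numeric=region_cols)
    cdf = _read_csv_strict(
        cognition_path,
        required=["subject_id", *COGNITIVE_OUTCOMES],
        numeric=list(COGNITIVE_OUTCOMES),
    )

    for name, df in (("subjects", sdf), ("morphometry", mdf), ("cognition", cdf)):
        if df["subject_id"].duplicated().any():
            raise ValidationError(f"{name}.csv: duplicated subject_id")

    shared = [
        sid
        for sid in sdf["subject_id"]
        if sid in set(mdf["subject_id"]) and sid in set(cdf["subject_id"])
    ]
    n_dropped = (
        len(set(sdf["subject_id"]) | set(mdf["subject_id"]) | set(cdf["subject_id"]))
        - len(shared)
    )
    if n_dropped:
        logger.warning(
            "dropped %d subject(s) not present in all three files", n_dropped
        )

    sdf = sdf.set_index("subject_id").loc[shared]
    mdf = mdf.set_index("subject_id").loc[shared]
    cdf = cdf.set_index("subject_id").loc[shared]

    subjects = []
    for sid, row in sdf.iterrows():
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                group=Group(row["group"]),
                age=float(row["age"]),
                sex=Sex(row["sex"]),
                education=float(row["education_years"]),
                visit_count=int(row["visit_count"]),
                cag_repeats=None if pd.isna(row.get("cag_repeats")) else int(row["cag_repeats"]),
                motor_score=None if pd.isna(row.get("motor_score")) else float(row["motor_score"]),
            )
        )

    icv = mdf["icv_mm3"].astype(float)
    striatal_cols = [c for c in mdf.columns if c.endswith(STRIATAL_SUFFIX)]
    thickness_cols = [c for c in mdf.columns if c not in striatal_cols + ["icv_mm3"]]
    values = mdf[thickness_cols].astype(float)
    raw_striatal = mdf[striatal_cols].astype(float)
    kinds = {c: RegionKind.THICKNESS.value for c in thickness_cols}
    for col in striatal_cols:
        region = col[: -len(STRIATAL_SUFFIX)]
        values[region] = normalize_striatal_volumes(
            raw_striatal[col].to_numpy(), icv.to_numpy()
        )
        kinds[region] = RegionKind.VOLUME_RATIO.value

    morph = MorphometryTable(
        values=values,
        kinds=pd.Series(kinds),
        icv=icv,
        raw_striatal=raw_striatal if striatal_cols else None,
    )
    cognition = CognitiveScores(values=cdf[list(COGNITIVE_OUTCOMES)].astype(float))
    return subjects, morph, cognition


def write_cohort(
    out_dir: str | Path,
    subjects: Sequence[SubjectRecord],
    morphometry: MorphometryTable,
    cognition: CognitiveScores,
    metadata: Optional[dict] = None,
) -> dict[str, Path]:
    """Write subjects/morphometry/cognition CSVs (+ JSON metadata sidecar).

    Striatal regions are written back as raw mm^3 volumes (columns suffixed
    ``_vol_mm3``), reproducing the input schema of :func:`read_cohort`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sdf = subjects_to_frame(subjects).reset_index()
    sdf = sdf.rename(columns={"education": "education_years"})
    paths = {"subjects": out_dir / "subjects.csv"}
    sdf.to_csv(paths["subjects"], index=False)

    mdf = pd.DataFrame(index=morphometry.values.index)
    mdf["icv_mm3"] = morphometry.icv
    for region in morphometry.region_names:
        if morphometry.kinds[region] == RegionKind.THICKNESS.value:
            mdf[region] = morphometry.values[region]
    if morphometry.raw_striatal is not None:
        for col in morphometry.raw_striatal.columns:
            mdf[col] = morphometry.raw_striatal[col]
    else:
        for region in morphometry.region_names:
            if morphometry.kinds[region] == RegionKind.VOLUME_RATIO.value:
                mdf[region + STRIATAL_SUFFIX] = (
                    morphometry.values[region] * morphometry.icv
                )
    paths["morphometry"] = out_dir / "morphometry.csv"
    mdf.reset_index(names="subject_id").to_csv(paths["morphometry"], index=False)

    paths["cognition"] = out_dir / "cognition.csv"
    cog = cognition.values.copy()
    for col in COGNITIVE_OUTCOMES[:-1]:
        cog[col] = cog[col].astype("Int64")
    cog.reset_index(names="subject_id").to_csv(paths["cognition"], index=False)

    meta = dict(metadata or {})
    meta.setdefault("n_subjects", len(subjects))
    paths["metadata"] = out_dir / "cohort_meta.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths


def complete_case_mask(
    subjects_frame: pd.DataFrame, required: Sequence[str] = COVARIATES
) -> pd.Series:
    """Boolean mask of subjects with no missing value among ``required``.

    Excluded counts are logged; the study data carry occasional incomplete
    batteries and the analyses drop affected subjects per-analysis.
    """
    mask = subjects_frame[list(required)].notna().all(axis=1)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("excluding %d subject(s) with missing covariates", n_bad)
    return mask
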