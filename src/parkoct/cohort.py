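"""Domain model for per-eye OCT morphometry cohorts.

A cohort is a set of subjects (one row per person, with diagnostic group
and clinical covariates) plus a set of eye records (one row per scanned
eye, with scan quality and the full layer panel).  Subjects and eyes are
stored as two normalized pandas DataFrames joined on ``subject_id``;
lightweight dataclass views (:class:`Subject`, :class:`EyeRecord`,
:class:`LayerPanel`) are provided for record-level access.

Missing measurements are NaN in memory and empty cells on disk; zeros are
never accepted as thicknesses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .params_table import GROUPS, PANEL_FIELDS, VOLUME_FIELDS

SIDES = ("left", "right")

SUBJECT_COLUMNS = (
    "subject_id", "group", "age", "sex", "duration_months",
    "followup_months", "hy", "updrs_on", "updrs_off", "visual_acuity",
)
EYE_COLUMNS = ("subject_id", "side", "quality_db") + PANEL_FIELDS

_THICKNESS_FIELDS = tuple(f for f in PANEL_FIELDS if f not in VOLUME_FIELDS)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the domain invariants.

    The message names the offending row (0-based data row index) and field.
    """


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class LayerPanel:
    """All layer measurements from one scan session of one eye.

    Thicknesses in µm, macular volumes in mm³.  Any field may be NaN
    (missing); present thicknesses must lie in (0, 1000) µm and volumes
    in (0, 10) mm³.
    """

    rnfl_mean: float = math.nan
    rnfl_temporal: float = math.nan
    rnfl_nasal: float = math.nan
    rnfl_superior: float = math.nan
    rnfl_inferior: float = math.nan
    mt_total: float = math.nan
    mt_central: float = math.nan
    mt_peripheral: float = math.nan
    mt_superior_peripheral: float = math.nan
    mt_inferior_peripheral: float = math.nan
    mt_temporal_peripheral: float = math.nan
    mt_nasal_peripheral: float = math.nan
    mt_superior_central: float = math.nan
    mt_inferior_central: float = math.nan
    mt_temporal_central: float = math.nan
    mt_nasal_central: float = math.nan
    mv_total: float = math.nan
    mv_central: float = math.nan
    mv_peripheral: float = math.nan
    mv_superior_peripheral: float = math.nan
    mv_inferior_peripheral: float = math.nan
    mv_temporal_peripheral: float = math.nan
    mv_nasal_peripheral: float = math.nan
    mv_superior_central: float = math.nan
    mv_inferior_central: float = math.nan
    mv_temporal_central: float = math.nan
    mv_nasal_central: float = math.nan
    rgc_ipl_nasal: float = math.nan
    rgc_ipl_temporal: float = math.nan
    inl_nasal: float = math.nan
    inl_temporal: float = math.nan
    opl_nasal: float = math.nan
    opl_temporal: float = math.nan
    onl_central: float = math.nan

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if _isnan(v):
                continue
            hi = 10.0 if f.name in VOLUME_FIELDS else 1000.0
            if not 0.0 < v < hi:
                unit = "mm³" if f.name in VOLUME_FIELDS else "µm"
                raise CohortValidationError(
                    f"{f.name}={v} outside (0, {hi:g}) {unit}")


@dataclass(frozen=True)
class EyeRecord:
    """One scanned eye: identity, scan quality in dB, and the layer panel."""

    subject_id: str
    side: str
    quality_db: float
    panel: LayerPanel = field(default_factory=LayerPanel)

    def __post_init__(self):
        if self.side not in SIDES:
            raise CohortValidationError(f"side={self.side!r} not in {SIDES}")
        if not _isnan(self.quality_db) and self.quality_db < 0:
            raise CohortValidationError(f"quality_db={self.quality_db} < 0")


@dataclass(frozen=True)
class Subject:
    """One study participant with diagnostic group and clinical covariates."""

    subject_id: str
    group: str
    age: float = math.nan
    sex: str = ""
    duration_months: float = math.nan
    followup_months: float = math.nan
    hy: float = math.nan
    updrs_on: float = math.nan
    updrs_off: float = math.nan
    visual_acuity: float = math.nan

    def __post_init__(self):
        if self.group not in GROUPS:
            raise CohortValidationError(f"group={self.group!r} not in {GROUPS}")
        if not _isnan(self.age) and self.age <= 0:
            raise CohortValidationError(f"age={self.age} must be > 0")
        if not _isnan(self.visual_acuity) and not 0 < self.visual_acuity <= 2:
            raise CohortValidationError(
                f"visual_acuity={self.visual_acuity} outside (0, 2]")


class Cohort:
    """A validated cohort: a subjects table and an eyes table.

    Parameters
    ----------
    subjects, eyes : pandas.DataFrame
        Tables with :data:`SUBJECT_COLUMNS` / :data:`EYE_COLUMNS`.
        Validated on construction: group labels, eye sides, value ranges,
        at most one eye per (subject, side), at most two eyes per subject,
        and referential integrity of ``subject_id``.
    """

    def __init__(self, subjects: pd.DataFrame, eyes: pd.DataFrame):
        self.subjects = _normalize_table(subjects, SUBJECT_COLUMNS)
        self.eyes = _normalize_table(eyes, EYE_COLUMNS)
        self._validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, subjects: list[Subject], eyes: list[EyeRecord]) -> "Cohort":
        srows = [{c: getattr(s, c) for c in SUBJECT_COLUMNS} for s in subjects]
        erows = []
        for e in eyes:
            row = {"subject_id": e.subject_id, "side": e.side,
                   "quality_db": e.quality_db}
            row.update({f: getattr(e.panel, f) for f in PANEL_FIELDS})
            erows.append(row)
        return cls(pd.DataFrame(srows, columns=list(SUBJECT_COLUMNS)),
                   pd.DataFrame(erows, columns=list(EYE_COLUMNS)))

    # -- record views --------------------------------------------------
    def iter_subjects(self) -> Iterator[Subject]:
        for row in self.subjects.itertuples(index=False):
            d = row._asdict()
            kwargs = {}
            for k in SUBJECT_COLUMNS:
                v = d[k]
                if k in ("subject_id", "group", "sex"):
                    kwargs[k] = "" if pd.isna(v) else str(v)
                else:
                    kwargs[k] = math.nan if pd.isna(v) else float(v)
            yield Subject(**kwargs)

    def iter_eyes(self) -> Iterator[EyeRecord]:
        for row in self.eyes.itertuples(index=False):
            d = row._asdict()
            panel = LayerPanel(**{f: float(d[f]) if not pd.isna(d[f]) else math.nan
                                  for f in PANEL_FIELDS})
            yield EyeRecord(str(d["subject_id"]), str(d["side"]),
                            float(d["quality_db"]), panel)

    # -- basics --------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.subjects.reset_index(drop=True),
                other.subjects.reset_index(drop=True), check_dtype=False)
            pd.testing.assert_frame_equal(
                self.eyes.reset_index(drop=True),
                other.eyes.reset_index(drop=True), check_dtype=False)
        except AssertionError:
            return False
        return True

    def __repr__(self) -> str:
        counts = self.subjects["group"].value_counts().to_dict()
        return f"Cohort({self.n_subjects} subjects, {self.n_eyes} eyes, {counts})"

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        subs, eyes = self.subjects, self.eyes
        bad = ~subs["group"].isin(GROUPS)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"subjects row {i}: group={subs['group'].iloc[i]!r} "
                f"is not one of {GROUPS}")
        dup = subs["subject_id"].duplicated()
        if dup.any():
            i = int(np.flatnonzero(dup)[0])
            raise CohortValidationError(
                f"subjects row {i}: duplicate subject_id="
                f"{subs['subject_id'].iloc[i]!r}")
        bad = subs["age"].notna() & (subs["age"] <= 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(f"subjects row {i}: age must be > 0")
        va = subs["visual_acuity"]
        bad = va.notna() & ~((va > 0) & (va <= 2))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"subjects row {i}: visual_acuity outside (0, 2]")

        bad = ~eyes["side"].isin(SIDES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"eyes row {i}: side={eyes['side'].iloc[i]!r} not in {SIDES}")
        bad = eyes["quality_db"].notna() & (eyes["quality_db"] < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(f"eyes row {i}: quality_db < 0")
        dup = eyes.duplicated(subset=["subject_id", "side"])
        if dup.any():
            i = int(np.flatnonzero(dup)[0])
            raise CohortValidationError(
                f"eyes row {i}: duplicate eye "
                f"({eyes['subject_id'].iloc[i]!r}, {eyes['side'].iloc[i]!r})")
        unknown = ~eyes["subject_id"].isin(subs["subject_id"])
        if unknown.any():
            i = int(np.flatnonzero(unknown)[0])
            raise CohortValidationError(
                f"eyes row {i}: subject_id={eyes['subject_id'].iloc[i]!r} "
                "does not resolve to any subject")

        for f in PANEL_FIELDS:
            hi = 10.0 if f in VOLUME_FIELDS else 1000.0
            col = eyes[f]
            bad = col.notna() & ~((col > 0) & (col < hi))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise CohortValidationError(
                    f"eyes row {i}: {f}={col.iloc[i]} outside (0, {hi:g})")


def _normalize_table(df: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    out = df.loc[:, list(columns)].reset_index(drop=True).copy()
    for c in columns:
        if c in ("subject_id", "group", "side", "sex"):
            out[c] = out[c].astype("string").fillna("").astype(str)
        else:
            out[c] = pd.to_numeric(out[c], errors="coerce").astype(float)
    return out


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------

def read_cohort(subjects_path: str | Path, eyes_path: str | Path) -> Cohort:
    """Read and validate a cohort from two CSV files.

    Missing numeric cells become NaN, never zero.  Raises
    :class:`CohortValidationError` naming the row on any invariant
    violation (unknown group, duplicate eye, unresolvable subject_id, ...).
    """
    subjects = pd.read_csv(subjects_path, dtype={"subject_id": str})
    eyes = pd.read_csv(eyes_path, dtype={"subject_id": str})
    return Cohort(subjects, eyes)


def write_cohort(cohort: Cohort, subjects_path: str | Path,
                 eyes_path: str | Path) -> None:
    """Write a cohort to two CSVs, re-readable by :func:`read_cohort`.

    Missing values are written as empty cells.
    """
    cohort.subjects.to_csv(subjects_path, index=False)
    cohort.eyes.to_csv(eyes_path, index=False)


# ---------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------

def qc_filter(cohort: Cohort, min_quality_db: float = 20.0,
              min_acuity: float = 0.6) -> tuple[Cohort, list[dict]]:
    """Apply the study's scan-quality and visual-acuity exclusions.

    Eyes with signal quality below ``min_quality_db`` (default 20 dB) are
    removed; subjects whose corrected visual acuity is recorded and below
    ``min_acuity`` (default 0.6, i.e. 6/10) are removed together with all
    their eyes.  Subjects without a recorded acuity are kept.  Returns the
    filtered cohort and an exclusion log (one dict per exclusion with
    ``kind``, ``subject_id``, optionally ``side``, and ``reason``).
    """
    log: list[dict] = []
    subs, eyes = cohort.subjects, cohort.eyes

    low_acuity = subs["visual_acuity"].notna() & (subs["visual_acuity"] < min_acuity)
    for i in np.flatnonzero(low_acuity.to_numpy()):
        log.append({"kind": "subject", "subject_id": subs["subject_id"].iloc[i],
                    "reason": f"acuity<{min_acuity:g}"})
    keep_subs = subs.loc[~low_acuity]
    excluded_ids = set(subs.loc[low_acuity, "subject_id"])

    low_q = eyes["quality_db"] < min_quality_db
    for i in np.flatnonzero(low_q.to_numpy()):
        if eyes["subject_id"].iloc[i] in excluded_ids:
            continue  # already gone with its subject
        log.append({"kind": "eye", "subject_id": eyes["subject_id"].iloc[i],
                    "side": eyes["side"].iloc[i],
                    "reason": f"quality<{min_quality_db:g}dB"})
    keep_eyes = eyes.loc[~low_q & ~eyes["subject_id"].isin(excluded_ids)]

    out = Cohort(keep_subs, keep_eyes)
    if out.n_eyes == 0 and cohort.n_eyes > 0:
        log.append({"kind": "warning", "subject_id": "",
                    "reason": "all eyes excluded"})
    return out, log


# ---------------------------------------------------------------------
# Eye averaging
# ---------------------------------------------------------------------

def subject_eye_means(cohort: Cohort) -> pd.DataFrame:
    """Collapse eyes to one row per subject (mean of the two eyes).

    For each panel field the subject value is the mean of the values
    present across that subject's eyes: two eyes → their mean, one eye
    (or one missing value) → the present value, missing in all eyes →
    NaN, leaving the subject to be excluded per-analysis downstream.
    Subjects with zero eyes are dropped.

    Returns a DataFrame with columns ``subject_id``, ``group``, then all
    panel fields.
    """
    eyes = cohort.eyes
    means = eyes.groupby("subject_id", sort=False)[list(PANEL_FIELDS)].mean()
    out = cohort.subjects.loc[:, ["subject_id", "group"]].merge(
        means, left_on="subject_id", right_index=True, how="inner")
    return out.reset_index(drop=True)
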