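"""Tabular data model and CSV I/O.

The interchange format is a long-format CSV with one row per
subject-visit and regional thickness as wide ``ct_``-prefixed columns —
the shape a FreeSurfer ROI export naturally takes. A
:class:`LongitudinalTable` wraps the pandas DataFrame and enforces the
structural invariants (unique subject-visit pairs, a baseline row per
subject, strictly increasing ages, a common ROI set). An
:class:`AtlasMap` resolves each ROI to a hemisphere and one of the six
lobes used for lobe-level aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, MappingError, SchemaError, ValidationError

VISITS = ("baseline", "y2", "y4")
SEXES = ("F", "M")
HEMISPHERES = ("L", "R")
LOBES = ("occipital", "frontal", "temporal", "parietal", "insular", "cingulate")
ROI_PREFIX = "ct_"

MANDATORY_COLUMNS = (
    "subject_id",
    "sex",
    "site_id",
    "visit",
    "age_months",
    "bmi",
    "euler_number",
    "pds_mean",
)
OPTIONAL_COLUMNS = ("family_id", "ses")


@dataclass(frozen=True)
class AtlasMap:
    """Maps ``roi_name -> (hemisphere, lobe)``."""

    table: pd.DataFrame  # index roi_name, columns hemisphere, lobe

    def __post_init__(self):
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate roi_name entries in atlas: {dups}")
        bad = set(self.table["lobe"]) - set(LOBES)
        if bad:
            raise ValidationError(f"unknown lobe labels {sorted(bad)}; expected {LOBES}")
        bad_h = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_h:
            raise ValidationError(f"unknown hemisphere labels {sorted(bad_h)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def roi_names(self) -> list:
        return list(self.table.index)

    def hemisphere(self, roi: str) -> str:
        return self._lookup(roi, "hemisphere")

    def lobe(self, roi: str) -> str:
        return self._lookup(roi, "lobe")

    def lobe_hemi(self, roi: str) -> str:
        """Combined label, e.g. ``'L_occipital'`` — 12 levels in a full atlas."""
        return f"{self.hemisphere(roi)}_{self.lobe(roi)}"

    def _lookup(self, roi: str, col: str) -> str:
        try:
            return self.table.at[roi, col]
        except KeyError:
            raise MappingError(f"ROI {roi!r} not present in atlas map") from None

    def require(self, rois) -> None:
        missing = [r for r in rois if r not in self.table.index]
        if missing:
            raise MappingError(f"ROIs absent from atlas map: {missing[:5]}"
                               + ("..." if len(missing) > 5 else ""))


def read_atlas_map(path) -> AtlasMap:
    """Read an atlas CSV with columns roi_name, hemisphere, lobe."""
    df = pd.read_csv(path, dtype=str)
    for col in ("roi_name", "hemisphere", "lobe"):
        if col not in df.columns:
            raise SchemaError(f"atlas map is missing mandatory column {col!r}")
    return AtlasMap(df.set_index("roi_name")[["hemisphere", "lobe"]])


class LongitudinalTable:
    """Validated subject-visit table with wide per-ROI thickness columns."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    # -- construction --------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, atlas: AtlasMap | None = None,
                       validate: bool = True) -> "LongitudinalTable":
        tbl = cls(df, validate=validate)
        if atlas is not None:
            atlas.require(tbl.roi_names)
        return tbl

    def _validate(self) -> None:
        df = self.df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"table is missing mandatory column {col!r}")
        bad_visit = set(df["visit"]) - set(VISITS)
        if bad_visit:
            raise ValidationError(f"unknown visit labels {sorted(bad_visit)}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex codes {sorted(bad_sex)}")
        dup = df.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "visit"]].values.tolist()
            raise IntegrityError(f"duplicate (subject_id, visit) rows: {pairs[:5]}")
        if not self.roi_names:
            raise SchemaError(f"no thickness columns (prefix {ROI_PREFIX!r}) found")
        no_baseline = set(df["subject_id"]) - set(
            df.loc[df["visit"] == "baseline", "subject_id"]
        )
        if no_baseline:
            raise IntegrityError(
                f"subjects lacking a baseline row: {sorted(no_baseline)[:5]}"
            )
        order = {v: i for i, v in enumerate(VISITS)}
        srt = df.assign(_v=df["visit"].map(order)).sort_values(["subject_id", "_v"])
        diffs = srt.groupby("subject_id")["age_months"].diff().dropna()
        if (diffs <= 0).any():
            bad = srt.loc[diffs.index[diffs <= 0], "subject_id"].unique()
            raise IntegrityError(
                f"age not strictly increasing across visits for subjects {list(bad)[:5]}"
            )

    # -- accessors ------------------------------------------------------
    @property
    def roi_names(self) -> list:
        return [c[len(ROI_PREFIX):] for c in self.df.columns if c.startswith(ROI_PREFIX)]

    @property
    def roi_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith(ROI_PREFIX)]

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def visit_rows(self, visit: str) -> pd.DataFrame:
        if visit not in VISITS:
            raise ValidationError(f"unknown visit {visit!r}")
        return self.df[self.df["visit"] == visit]

    def sex_subset(self, sex: str) -> "LongitudinalTable":
        if sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        return LongitudinalTable(self.df[self.df["sex"] == sex], validate=False)

    def subject_subset(self, subject_ids) -> "LongitudinalTable":
        keep = self.df["subject_id"].isin(set(subject_ids))
        return LongitudinalTable(self.df[keep], validate=False)

    def thickness(self, roi: str) -> pd.Series:
        col = ROI_PREFIX + roi
        if col not in self.df.columns:
            raise MappingError(f"ROI {roi!r} not present in table")
        return self.df[col]


def read_long_table(path, atlas: AtlasMap | None = None) -> LongitudinalTable:
    """Read and validate a long-format cohort CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site_id": str, "family_id": str})
    return LongitudinalTable.from_dataframe(df, atlas=atlas)


def write_table(obj, path) -> None:
    """Write any result table (or LongitudinalTable) as CSV.

    Column order is preserved; floats are serialized with 17 significant
    digits so read-back reproduces values to < 1e-12 relative error.
    """
    df = obj.df if isinstance(obj, LongitudinalTable) else obj
    df.to_csv(path, index=False, float_format="%.17g")


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
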