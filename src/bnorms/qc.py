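"""Exclusion cascade, group-wise outlier screens, and the train/test split.

The cascade removes *participants* (all of a subject's rows), in order:
(1) subjects with only a single visit; (2) subjects with any BMI below 10
or above 50 (boundaries retained); (3) subjects lacking a PDS rating or
any regional thickness value at a retained visit. After splitting by
visit availability, a 6-SD screen removes subjects whose Euler number is
extreme relative to their scan-site, then subjects with an extreme
thickness value in any region. Group statistics use the sample SD
(ddof=1), include the candidate value, and are computed in a single pass
(no iterative re-screening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .data import LongitudinalTable, VISITS, warn
from .exceptions import ValidationError

__all__ = [
    "ExclusionLog",
    "compute_pds_mean",
    "apply_exclusions",
    "sd_outlier_mask",
    "qc_filter",
    "split_train_test",
    "one_per_family",
]


@dataclass
class ExclusionLog:
    """Ordered record of cascade stages; counts telescope stage to stage."""

    stages: list = field(default_factory=list)

    def record(self, name: str, n_before: int, removed_ids) -> None:
        removed_ids = sorted(set(removed_ids))
        self.stages.append(
            {
                "stage": name,
                "n_before": n_before,
                "n_removed": len(removed_ids),
                "removed_subject_ids": removed_ids,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s["stage"],
                "n_before": s["n_before"],
                "n_removed": s["n_removed"],
                "removed_subject_ids": ";".join(map(str, s["removed_subject_ids"])),
            }
            for s in self.stages
        ]
        return pd.DataFrame(rows, columns=["stage", "n_before", "n_removed", "removed_subject_ids"])


def compute_pds_mean(items, sex: str) -> float:
    """Mean PDS across available items; NaN items are excluded from the mean.

    Ratings must lie in {1, 2, 3, 4}; returns NaN if every item is missing.
    ``sex`` selects the item schema (both sexes rate 5 caregiver items).
    """
    arr = np.asarray(items, dtype=float)
    avail = ~np.isnan(arr)
    vals = arr[avail]
    if vals.size and (np.any(vals < 1) | np.any(vals > 4) | np.any(vals != np.rint(vals))):
        raise ValidationError(f"PDS ratings must be integers in 1..4, got {vals}")
    if sex not in ("F", "M"):
        raise ValidationError(f"unknown sex {sex!r}")
    if not vals.size:
        return float("nan")
    return float(vals.mean())


def apply_exclusions(table: LongitudinalTable, cfg: Config) -> tuple[LongitudinalTable, ExclusionLog]:
    """Apply the three participant-level exclusion stages, logging each."""
    df = table.df
    log = ExclusionLog()

    # stage 1: only a single measurement
    n_visits = df.groupby("subject_id")["visit"].size()
    single = set(n_visits.index[n_visits < 2])
    log.record("single_visit", df["subject_id"].nunique(), single)
    df = df[~df["subject_id"].isin(single)]

    # stage 2: implausible BMI (strictly outside [10, 50])
    bad_bmi_rows = (df["bmi"] < cfg.bmi_min) | (df["bmi"] > cfg.bmi_max)
    bad_bmi = set(df.loc[bad_bmi_rows, "subject_id"])
    log.record("bmi_bounds", df["subject_id"].nunique(), bad_bmi)
    df = df[~df["subject_id"].isin(bad_bmi)]

    # stage 3: missing PDS or any thickness at a retained visit
    roi_cols = table.roi_columns
    missing_rows = df["pds_mean"].isna() | df[roi_cols].isna().any(axis=1)
    bad_missing = set(df.loc[missing_rows, "subject_id"])
    log.record("missing_pds_or_ct", df["subject_id"].nunique(), bad_missing)
    df = df[~df["subject_id"].isin(bad_missing)]

    if df.empty:
        warn("exclusion cascade removed every subject")
    return LongitudinalTable(df, validate=False), log


def sd_outlier_mask(values, groups, k: float) -> np.ndarray:
    """Flag entries more than ``k`` group sample-SDs (ddof=1) from the group mean.

    Statistics include the candidate value itself (single-pass screen).
    A constant group yields no flags; a group of size 1 is an error.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups)).reset_index(drop=True)
    sizes = groups.value_counts()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValidationError(f"groups of size 1 cannot be screened: {small}")
    gmean = values.groupby(groups).transform("mean")
    gsd = values.groupby(groups).transform(lambda s: s.std(ddof=1))
    return ((values - gmean).abs() > k * gsd).to_numpy()


def qc_filter(table: LongitudinalTable, cfg: Config) -> tuple[LongitudinalTable, ExclusionLog]:
    """6-SD screens within a split subset: Euler by scan-site, thickness by ROI.

    A subject is removed wholesale if any visit's Euler number is flagged
    within its site, or any visit's thickness in any ROI is flagged within
    that (ROI, visit) group. The thickness screen runs on the survivors of
    the Euler screen, mirroring the cascade order.
    """
    df = table.df
    log = ExclusionLog()

    euler_mask = sd_outlier_mask(df["euler_number"].to_numpy(), df["site_id"].to_numpy(), cfg.sd_k)
    bad_euler = set(df.loc[euler_mask, "subject_id"])
    log.record("euler_6sd", df["subject_id"].nunique(), bad_euler)
    df = df[~df["subject_id"].isin(bad_euler)]

    bad_ct = set()
    roi_cols = table.roi_columns
    for visit in VISITS:
        sub = df[df["visit"] == visit]
        if len(sub) < 2:
            continue
        X = sub[roi_cols].to_numpy(float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        flagged = np.abs(X - mean) > cfg.sd_k * sd
        bad_ct.update(sub.loc[flagged.any(axis=1), "subject_id"])
    log.record("thickness_6sd", df["subject_id"].nunique(), bad_ct)
    df = df[~df["subject_id"].isin(bad_ct)]

    return LongitudinalTable(df, validate=False), log


def split_train_test(table: LongitudinalTable) -> tuple[LongitudinalTable, LongitudinalTable]:
    """Split by visit availability: {baseline, y2} -> train; all three -> test."""
    df = table.df
    visit_sets = df.groupby("subject_id")["visit"].agg(frozenset)
    train_ids = set(visit_sets.index[visit_sets == frozenset({"baseline", "y2"})])
    test_ids = set(visit_sets.index[visit_sets == frozenset({"baseline", "y2", "y4"})])
    other = set(visit_sets.index) - train_ids - test_ids
    if other:
        warn(
            f"{len(other)} subjects with an uncovered visit pattern "
            "(e.g. baseline + 4-year only) were dropped from both splits"
        )
    train = LongitudinalTable(df[df["subject_id"].isin(train_ids)], validate=False)
    test = LongitudinalTable(df[df["subject_id"].isin(test_ids)], validate=False)
    return train, test


def one_per_family(table: LongitudinalTable, seed: int) -> LongitudinalTable:
    """Retain one uniformly chosen subject per family; deterministic given seed."""
    df = table.df
    if "family_id" not in df.columns or df["family_id"].isna().all():
        warn("family_id absent; one_per_family is a no-op")
        return table
    rng = np.random.default_rng(seed)
    keep = []
    fam_members = df.groupby("family_id")["subject_id"].agg(lambda s: sorted(set(s)))
    for fam in sorted(fam_members.index):
        members = fam_members[fam]
        keep.append(members[rng.integers(len(members))])
    return LongitudinalTable(df[df["subject_id"].isin(set(keep))], validate=False)
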