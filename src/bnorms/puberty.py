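"""Validation of deviation scores against pubertal development.

Three analyses, mirroring the validation design of the study:

1. **Association**: per region, a Gaussian identity-link GLM of the mean
   PDS score on the deviation score at the matching follow-up (variants:
   plain; BMI x SES covariate-adjusted; raw thickness change as the
   predictor), with Benjamini-Hochberg correction across the regional
   tests within each model kind, sex and timepoint.
2. **Stage subgroups**: subjects staged pre/early/mid/late/post-pubertal
   from their PDS; extreme deviations (|z| > 1.96) counted per
   lobe-hemisphere; Kruskal-Wallis omnibus tests across stages per
   (lobe-hemisphere, deviation sign, model, timepoint), BH-corrected
   within sex, with tie-corrected Dunn's z post-hoc tests
   (Bonferroni-adjusted) on significant cells.
3. **Percentile shifts**: subjects classified per region as negative
   (zDiff < -1), stable or positive (zDiff > 1) by the change in z
   between follow-ups; Kruskal-Wallis on the change in PDS across the
   three groups, BH-corrected across regions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Config
from .data import AtlasMap, LongitudinalTable, warn
from .exceptions import ValidationError

__all__ = [
    "bh_adjust",
    "associate_pds",
    "assign_pubertal_stage",
    "lobe_deviation_counts",
    "stage_group_tests",
    "percentile_shift_analysis",
    "dunn_posthoc",
]

STAGES = ("pre", "early", "mid", "late", "post")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pds_at(cohort: LongitudinalTable, timepoint: str) -> pd.Series:
    rows = cohort.visit_rows(timepoint)
    return rows.set_index("subject_id")["pds_mean"]


def associate_pds(
    dev: pd.DataFrame,
    cohort: LongitudinalTable,
    model_kind: str,
    variant: str = "plain",
    cfg: Config | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-region GLM of PDS on the deviation score (or raw thickness change).

    ``dev`` is a deviation table for one sex and model kind (one or both
    follow-ups). ``variant`` is ``"plain"`` (PDS ~ z),
    ``"covariate"`` (PDS ~ z * BMI * SES, full factorial) or
    ``"raw_diff"`` (predictor is the raw thickness change from baseline).
    BH correction is applied across regions within each timepoint.
    """
    if variant not in ("plain", "covariate", "raw_diff"):
        raise ValidationError(f"unknown association variant {variant!r}")
    cfg = cfg or Config()
    rows = []
    for tp, dtp in dev.groupby("timepoint", sort=True):
        pds = _pds_at(cohort, tp)
        visit_rows = cohort.visit_rows(tp).set_index("subject_id")
        base_rows = cohort.visit_rows("baseline").set_index("subject_id")
        for roi, grp in dtp.groupby("roi_name", sort=True):
            grp = grp.set_index("subject_id")
            common = grp.index.intersection(pds.index)
            y = pds.loc[common].to_numpy(float)
            if variant == "raw_diff":
                x = (
                    visit_rows.loc[common, "ct_" + roi].to_numpy(float)
                    - base_rows.loc[common, "ct_" + roi].to_numpy(float)
                )
            else:
                x = grp.loc[common, "z"].to_numpy(float)
            keep = np.isfinite(y) & np.isfinite(x)
            row = {
                "roi_name": roi,
                "sex": grp["sex"].iat[0],
                "model_kind": model_kind,
                "timepoint": tp,
                "n": int(keep.sum()),
            }
            if keep.sum() < min_n:
                row.update(slope=np.nan, z_stat=np.nan, p=np.nan,
                           df_model=np.nan, df_resid=np.nan,
                           scale=np.nan, deviance=np.nan, flagged=True)
                rows.append(row)
                continue
            if variant == "covariate":
                bmi = visit_rows.loc[common, "bmi"].to_numpy(float)[keep]
                ses = visit_rows.loc[common, "ses"].to_numpy(float)[keep]
                xk = x[keep]
                X = np.column_stack([
                    xk, bmi, ses, xk * bmi, xk * ses, bmi * ses, xk * bmi * ses,
                ])
            else:
                X = x[keep, None]
            X = sm.add_constant(X)
            res = sm.GLM(y[keep], X, family=sm.families.Gaussian()).fit()
            row.update(
                slope=float(res.params[1]),
                z_stat=float(res.tvalues[1]),
                p=float(res.pvalues[1]),
                df_model=int(res.df_model),
                df_resid=int(res.df_resid),
                scale=float(res.scale),
                deviance=float(res.deviance),
                flagged=False,
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    for tp in out["timepoint"].unique():
        sel = (out["timepoint"] == tp) & ~out["p"].isna()
        if sel.any():
            out.loc[sel, "p_bh"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out


def assign_pubertal_stage(pds_mean: float, sex: str, thresholds: dict | None = None) -> str | None:
    """Map a mean PDS score to one of the five pubertal stages.

    The default rule is a documented threshold stand-in on the mean
    score (< 1.5 pre, < 2.25 early, < 3 mid, < 3.75 late, else post);
    item-pattern rules can be supplied as a different threshold table.
    Returns None (unstaged) for a missing score.
    """
    if sex not in ("F", "M"):
        raise ValidationError(f"unknown sex {sex!r}")
    if pds_mean is None or (isinstance(pds_mean, float) and np.isnan(pds_mean)):
        return None
    thresholds = thresholds or Config().stage_thresholds
    for stage in STAGES[:-1]:
        if pds_mean < thresholds[stage]:
            return stage
    return "post"


def lobe_deviation_counts(
    dev: pd.DataFrame,
    atlas: AtlasMap,
    threshold: float,
    cohort: LongitudinalTable | None = None,
    model_kind: str = "",
    stage_thresholds: dict | None = None,
) -> pd.DataFrame:
    """Count extreme deviations per subject and lobe-hemisphere.

    ``pos_count`` counts regions with z strictly above +threshold,
    ``neg_count`` strictly below -threshold (|z| equal to the threshold
    is not extreme). If ``cohort`` is given, each row also gets the
    subject's pubertal stage at the matching timepoint.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    atlas.require(dev["roi_name"].unique())
    d = dev.copy()
    d["lobe_hemi"] = [atlas.lobe_hemi(r) for r in d["roi_name"]]
    d["pos"] = d["z"] > threshold
    d["neg"] = d["z"] < -threshold
    counts = (
        d.groupby(["subject_id", "sex", "timepoint", "lobe_hemi"], sort=True)[["pos", "neg"]]
        .sum()
        .astype(int)
        .rename(columns={"pos": "pos_count", "neg": "neg_count"})
        .reset_index()
    )
    counts["model_kind"] = model_kind
    if cohort is not None:
        stage = {}
        for tp in counts["timepoint"].unique():
            pds = _pds_at(cohort, tp)
            sex_map = cohort.visit_rows(tp).set_index("subject_id")["sex"]
            for sid in counts.loc[counts["timepoint"] == tp, "subject_id"].unique():
                stage[(sid, tp)] = assign_pubertal_stage(
                    pds.get(sid, np.nan), sex_map.get(sid, "F"), stage_thresholds
                )
        counts["stage"] = [
            stage.get((s, t)) for s, t in zip(counts["subject_id"], counts["timepoint"])
        ]
        n_unstaged = counts["stage"].isna().sum()
        if n_unstaged:
            warn(f"{n_unstaged} count rows without a pubertal stage were dropped")
            counts = counts[~counts["stage"].isna()]
    return counts


def dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Tie-corrected Dunn's pairwise z tests with Bonferroni adjustment.

    ``groups`` maps label -> 1-d sample. Uses the large-sample normal
    approximation on mean ranks with the tie correction
    ``T = sum(t^3 - t) / (12 (N - 1))`` subtracted from ``N (N + 1)/12``.
    """
    labels = list(groups)
    sizes = {k: len(v) for k, v in groups.items()}
    pooled = np.concatenate([np.asarray(groups[k], float) for k in labels])
    ranks = stats.rankdata(pooled)
    n_tot = len(pooled)
    mean_ranks, i = {}, 0
    for k in labels:
        mean_ranks[k] = ranks[i: i + sizes[k]].mean()
        i += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(combinations(labels, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "group_a": a, "group_b": b, "z": float(z),
            "p": float(p), "p_bonf": float(min(1.0, p * len(pairs))),
        })
    return pd.DataFrame(rows)


def _kruskal(groups):
    """Kruskal-Wallis H, df, p; H = 0, p = 1 when all values are identical."""
    arrays = [np.asarray(g, float) for g in groups]
    df = len(arrays) - 1
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def stage_group_tests(counts: pd.DataFrame, fdr_q: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis omnibus tests of deviation counts across pubertal stages.

    One test per (sex, lobe-hemisphere, deviation sign, model kind,
    timepoint) cell; empty stages are dropped (df shrinks accordingly)
    and cells with fewer than 2 usable stages are skipped. BH correction
    runs across all cells within a sex; Dunn's post-hoc tests are
    reported for BH-significant cells.
    """
    omnibus_rows, posthoc_frames = [], []
    for sign, col in (("positive", "pos_count"), ("negative", "neg_count")):
        keys = ["sex", "lobe_hemi", "model_kind", "timepoint"]
        for key, grp in counts.groupby(keys, sort=True):
            groups = {
                s: g[col].to_numpy(float)
                for s, g in grp.groupby("stage")
                if len(g) >= 2
            }
            cell = dict(zip(keys, key), sign=sign)
            if len(groups) < 2:
                warn(f"cell {cell} skipped: fewer than 2 usable stages")
                continue
            h, df, p = _kruskal(list(groups.values()))
            cell.update(H=h, df=df, p=p, stages=",".join(sorted(groups)))
            omnibus_rows.append((cell, groups))
    cols = ["sex", "lobe_hemi", "model_kind", "timepoint", "sign",
            "H", "df", "p", "stages", "p_fdr"]
    if not omnibus_rows:
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["group_a", "group_b", "z", "p", "p_bonf",
                                      "sex", "lobe_hemi", "model_kind",
                                      "timepoint", "sign"]))
    out = pd.DataFrame([c for c, _ in omnibus_rows])
    out["p_fdr"] = np.nan
    for sex in out["sex"].unique():
        sel = out["sex"] == sex
        out.loc[sel, "p_fdr"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    for (cell, groups), (_, row) in zip(omnibus_rows, out.iterrows()):
        if row["p_fdr"] < fdr_q:
            ph = dunn_posthoc(groups)
            for k in ("sex", "lobe_hemi", "model_kind", "timepoint", "sign"):
                ph[k] = cell[k]
            posthoc_frames.append(ph)
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(columns=["group_a", "group_b", "z", "p", "p_bonf",
                                   "sex", "lobe_hemi", "model_kind", "timepoint", "sign"])
    )
    return out, posthoc


def percentile_shift_analysis(
    dev_y2: pd.DataFrame,
    dev_y4: pd.DataFrame,
    cohort: LongitudinalTable,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify subjects by zDiff = z(y4) - z(y2) per region and test delta-PDS.

    Groups are negative (zDiff < -threshold), positive (zDiff >
    threshold) and stable (the closed interval between); Kruskal-Wallis
    compares the change in PDS (4-year minus 2-year) across the non-empty
    groups, with BH correction across regions.
    """
    pds2, pds4 = _pds_at(cohort, "y2"), _pds_at(cohort, "y4")
    dpds = (pds4 - pds2).dropna()
    z2 = dev_y2.set_index(["subject_id", "roi_name"])["z"]
    z4 = dev_y4.set_index(["subject_id", "roi_name"])["z"]
    zdiff = (z4 - z2).dropna().rename("zdiff").reset_index()
    sex_map = dev_y2.drop_duplicates("subject_id").set_index("subject_id")["sex"]
    rows = []
    for roi, grp in zdiff.groupby("roi_name", sort=True):
        g = grp.set_index("subject_id")["zdiff"]
        common = g.index.intersection(dpds.index)
        g, d = g.loc[common], dpds.loc[common]
        neg, pos = g < -threshold, g > threshold
        stable = ~neg & ~pos
        groups = [d[m].to_numpy() for m in (neg, stable, pos) if m.sum() > 0]
        row = {
            "roi_name": roi,
            "sex": sex_map.iloc[0] if len(sex_map) else None,
            "n_negative": int(neg.sum()),
            "n_stable": int(stable.sum()),
            "n_positive": int(pos.sum()),
        }
        if len(groups) < 2:
            row.update(H=np.nan, df=np.nan, p=np.nan)
        else:
            h, df, p = _kruskal(groups)
            row.update(H=h, df=df, p=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = ~out["p"].isna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out
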