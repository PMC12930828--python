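"""Per-region normative model sets: design construction, fitting, scoring.

Two families of norms are supported, each fitted separately per sex and
per region with the warped BLR engine:

* **C-Norm** (cross-sectional): thickness ~ age + site. Variants
  ``cnorm_2year`` (trained on 2-year rows) and ``cnorm_bl2year``
  (baseline and 2-year rows stacked independently) exist as age-range
  controls.
* **B-Norm** (baseline-conditioned): follow-up thickness ~ baseline
  thickness (same region) + baseline age + follow-up age + site,
  trained on (baseline, 2-year) pairs and applied at either follow-up
  by setting the follow-up age accordingly.

Scoring a test table produces a deviation table: one row per subject,
region and follow-up with the observed and median-predicted thickness,
the warped-space predictive SD, the deviation z-score and its centile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .blr import WarpedBLR, WarpedBLRResults
from .config import MODEL_KINDS, Config
from .data import ROI_PREFIX, LongitudinalTable, warn
from .exceptions import ValidationError

__all__ = [
    "DesignMatrix",
    "NormSet",
    "build_design",
    "fit_norms",
    "score_norms",
    "site_registry_of",
    "DEV_COLUMNS",
]

DEV_COLUMNS = [
    "subject_id", "sex", "roi_name", "timepoint",
    "y_obs", "y_median_pred", "s_w", "z", "centile",
]

DEFAULT_FIT_TIMEPOINTS = {
    "cnorm": ("baseline",),
    "cnorm_2year": ("y2",),
    "cnorm_bl2year": ("baseline", "y2"),
    "bnorm": ("y2",),
}


@dataclass
class DesignMatrix:
    """Numeric design with labelled columns and an ordered site registry."""

    X: np.ndarray
    labels: list
    site_registry: list
    continuous_cols: list

    def __post_init__(self):
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("design matrix contains non-finite entries")
        site_block = self.X[:, [self.labels.index(f"site_{s}") for s in self.site_registry]]
        sums = site_block.sum(axis=1)
        if not np.all((sums == 1) | (sums == 0)):
            raise ValidationError("site block is not one-hot")


def site_registry_of(table: LongitudinalTable) -> list:
    return sorted(table.df["site_id"].unique())


def _site_onehot(site_ids, registry, fallback: str) -> np.ndarray:
    idx = {s: j for j, s in enumerate(registry)}
    out = np.zeros((len(site_ids), len(registry)))
    unseen = sorted({s for s in site_ids if s not in idx})
    if unseen:
        if fallback == "error":
            raise ValidationError(
                f"sites {unseen} were not seen in training; "
                "set site_fallback='reference' to map them to the zero vector"
            )
        warn(f"unseen sites {unseen} mapped to the reference (all-zero) site vector")
    for i, s in enumerate(site_ids):
        if s in idx:
            out[i, idx[s]] = 1.0
    return out


def _age_columns(age: np.ndarray, name: str, degree: int):
    cols, labels = [], []
    for d in range(1, degree + 1):
        cols.append(age**d)
        labels.append(name if d == 1 else f"{name}^{d}")
    return cols, labels


def build_design(
    table: LongitudinalTable,
    model_kind: str,
    roi: str,
    site_registry: list,
    cfg: Config,
    timepoints=None,
):
    """Build (design, response, row metadata) for one region and model kind.

    For the C-Norm variants each selected visit row contributes
    ``[age, site]`` with the thickness at that visit as response. For the
    B-Norm each (baseline, follow-up) pair contributes
    ``[ct_baseline, age_baseline, age_follow_up, site]`` with the
    follow-up thickness as response; subjects lacking the follow-up are
    skipped (their count is recorded in ``meta.attrs['n_skipped']``).
    """
    if model_kind not in MODEL_KINDS:
        raise ValidationError(f"unknown model_kind {model_kind!r}")
    df = table.df
    col = ROI_PREFIX + roi
    deg = cfg.age_degree

    if model_kind != "bnorm":
        tps = tuple(timepoints) if timepoints else DEFAULT_FIT_TIMEPOINTS[model_kind]
        sub = df[df["visit"].isin(tps)]
        age = sub["age_months"].to_numpy(float)
        cols, labels = _age_columns(age, "age", deg)
        site = _site_onehot(sub["site_id"].tolist(), site_registry, cfg.site_fallback)
        X = np.column_stack(cols + [site])
        labels += [f"site_{s}" for s in site_registry]
        y = sub[col].to_numpy(float)
        meta = sub[["subject_id", "sex", "visit", "age_months"]].reset_index(drop=True)
        meta = meta.rename(columns={"visit": "timepoint"})
        meta.attrs["n_skipped"] = 0
    else:
        tps = tuple(timepoints) if timepoints else ("y2", "y4")
        base = df[df["visit"] == "baseline"].set_index("subject_id")
        parts, metas, n_skipped = [], [], 0
        for tp in tps:
            fu = df[df["visit"] == tp]
            have = fu["subject_id"].isin(base.index)
            n_skipped += int((~have).sum())
            fu = fu[have]
            if fu.empty:
                continue
            b = base.loc[fu["subject_id"]]
            age_bl = b["age_months"].to_numpy(float)
            age_fu = fu["age_months"].to_numpy(float)
            c_bl, l_bl = _age_columns(age_bl, "age_bl", deg)
            c_fu, l_fu = _age_columns(age_fu, "age_fu", deg)
            site = _site_onehot(fu["site_id"].tolist(), site_registry, cfg.site_fallback)
            X_tp = np.column_stack([b[col].to_numpy(float)] + c_bl + c_fu + [site])
            parts.append((X_tp, fu[col].to_numpy(float)))
            m = fu[["subject_id", "sex", "age_months"]].reset_index(drop=True)
            m["timepoint"] = tp
            metas.append(m)
        if not parts:
            raise ValidationError(f"no usable (baseline, follow-up) pairs for {tps}")
        labels = (["ct_bl"] + _age_columns(np.zeros(1), "age_bl", deg)[1]
                  + _age_columns(np.zeros(1), "age_fu", deg)[1]
                  + [f"site_{s}" for s in site_registry])
        X = np.vstack([p[0] for p in parts])
        y = np.concatenate([p[1] for p in parts])
        meta = pd.concat(metas, ignore_index=True)
        meta.attrs["n_skipped"] = n_skipped

    n_site = len(site_registry)
    continuous = list(range(X.shape[1] - n_site))
    dm = DesignMatrix(X=X, labels=labels, site_registry=list(site_registry),
                      continuous_cols=continuous)
    return dm, y, meta


@dataclass
class NormSet:
    """A per-region collection of fitted norms for one sex and model kind."""

    model_kind: str
    sex: str
    site_registry: list
    models: dict = field(default_factory=dict)   # roi -> WarpedBLRResults
    failures: dict = field(default_factory=dict)  # roi -> error message

    @property
    def roi_names(self) -> list:
        return list(self.models)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "model_kind": self.model_kind,
            "sex": self.sex,
            "site_registry": self.site_registry,
            "rois": self.roi_names,
            "failures": self.failures,
        }
        (d / "normset.json").write_text(json.dumps(manifest, indent=1))
        for roi, model in self.models.items():
            model.save_json(d / f"{roi}.json")

    @classmethod
    def load(cls, directory) -> "NormSet":
        d = Path(directory)
        manifest = json.loads((d / "normset.json").read_text())
        ns = cls(
            model_kind=manifest["model_kind"],
            sex=manifest["sex"],
            site_registry=manifest["site_registry"],
            failures=manifest.get("failures", {}),
        )
        for roi in manifest["rois"]:
            ns.models[roi] = WarpedBLRResults.load_json(d / f"{roi}.json")
        return ns


def fit_norms(
    train: LongitudinalTable,
    model_kind: str,
    sex: str,
    cfg: Config,
    rois=None,
) -> NormSet:
    """Fit one warped BLR per region on the sex-restricted training rows."""
    sub = train.sex_subset(sex)
    if len(sub) == 0:
        raise ValidationError(f"no training rows for sex={sex!r}")
    registry = site_registry_of(sub)
    rois = list(rois) if rois is not None else train.roi_names
    ns = NormSet(model_kind=model_kind, sex=sex, site_registry=registry)
    for roi in rois:
        try:
            dm, y, _ = build_design(sub, model_kind, roi, registry, cfg)
            res = WarpedBLR(
                y, dm.X, column_names=dm.labels, continuous_cols=dm.continuous_cols,
                fix_warp=(cfg.warp == "identity"),
            ).fit(xtol=cfg.optimizer_xtol, ftol=cfg.optimizer_ftol,
                  maxiter=cfg.optimizer_maxiter)
            ns.models[roi] = res
        except (ValidationError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            ns.failures[roi] = str(exc)
    if not ns.models:
        raise ValidationError("every per-region fit failed")
    return ns


def score_norms(
    normset: NormSet,
    test: LongitudinalTable,
    timepoint: str,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Score a test table at one follow-up; returns the deviation table.

    For C-Norm variants the age covariate at scoring time is the age at
    the scored follow-up. For B-Norms the (baseline, follow-up) pair is
    used with the follow-up age.
    """
    cfg = cfg or Config()
    if timepoint not in ("y2", "y4"):
        raise ValidationError("timepoint must be 'y2' or 'y4'")
    sub = test.sex_subset(normset.sex)
    frames = []
    for roi, model in normset.models.items():
        dm, y_obs, meta = build_design(
            sub, normset.model_kind, roi, normset.site_registry, cfg,
            timepoints=(timepoint,),
        )
        mu_w, s_w = model.predictive_moments(dm.X)
        z = model.deviation_scores(dm.X, y_obs)
        frames.append(pd.DataFrame({
            "subject_id": meta["subject_id"],
            "sex": normset.sex,
            "roi_name": roi,
            "timepoint": timepoint,
            "y_obs": y_obs,
            "y_median_pred": model.predict(dm.X),
            "s_w": s_w,
            "z": z,
            "centile": 100.0 * stats.norm.cdf(z),
        }))
    return pd.concat(frames, ignore_index=True)[DEV_COLUMNS]
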