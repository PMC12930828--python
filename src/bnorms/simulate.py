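"""Synthetic ABCD-like longitudinal cohorts with known ground truth.

The generator emulates the structure the downstream pipeline needs from
the real study: a multi-site cohort scanned at baseline (age ~ 119 +/- 7.4
months), 2-year and 4-year follow-ups ~24 months apart; per-region mean
thickness in the 2.0-3.5 mm range with mild age-related thinning; strong
within-subject tracking via subject-by-region random intercepts;
optionally skewed (sinh-arcsinh) residuals; caregiver PDS ratings rising
with age along sex-specific logistic curves (girls earlier); and
plantable quality-control outliers (extreme Euler numbers, thickness
spikes, implausible BMI).

The mean-thickness model for subject i, region r, visit v is

    ct = mu_r + site_offset + u_{ir} + beta_age * (age - age0)
         - kappa_r * pds_excess_i   (follow-up visits only)
         + sigma * ginv(eps),   eps ~ N(0, 1),

where ``ginv`` is the inverse sinh-arcsinh warp with true parameters
(a_true, b_true) (identity when a=0, b=1), and ``pds_excess`` is the
subject's pubertal-tempo deviation from the age-expected PDS. The
coupling kappa acts only on follow-up thickness, so the signal lives in
developmental change between visits — baseline-conditioned norms, not
baseline thickness, carry it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .data import LOBES, ROI_PREFIX, AtlasMap, LongitudinalTable
from .exceptions import ValidationError
from .shash import shash_inverse

__all__ = [
    "SimParams",
    "TruthRecord",
    "OutlierSpec",
    "default_atlas",
    "simulate_cohort",
    "null_cohort",
    "plant_outliers",
    "kappa_for_f2",
    "pds_expected",
]

#: PDS item labels per sex (5 caregiver items each; menarche is binary 1/4)
PDS_ITEMS = {
    "F": ("growth", "body_hair", "skin", "breast", "menarche"),
    "M": ("growth", "body_hair", "skin", "voice", "facial_hair"),
}


@dataclass(frozen=True)
class SimParams:
    n_subjects: int = 800
    n_rois: int = 20
    n_sites: int = 5
    female_fraction: float = 0.47
    baseline_age_mean: float = 119.0      # months
    baseline_age_sd: float = 7.4
    baseline_age_range: tuple = (96.0, 144.0)
    visit_gap_mean: float = 24.0          # months
    visit_gap_sd: float = 2.0
    y4_missing_frac: float = 0.5          # fraction of subjects lacking y4 (-> train split)
    ct_mean_range: tuple = (2.0, 3.5)     # per-ROI mean thickness draw (mm)
    beta_age: float = -0.002              # mm/month, mild thinning
    tau: float = 0.12                     # subject-by-ROI intercept SD (mm)
    site_sd: float = 0.03                 # site offset SD (mm)
    sigma: float = 0.06                   # residual SD (mm); with tau=0.12 the
                                          # within-subject tracking ICC is 0.8
    a_true: float = 0.0                   # residual warp skew (0 = symmetric)
    b_true: float = 1.0                   # residual warp shape (1 = Gaussian)
    pds_midpoint: dict = field(default_factory=lambda: {"F": 145.0, "M": 160.0})
    pds_slope: float = 0.06               # per month, logistic steepness
    pds_tempo_sd: float = 0.4             # subject pubertal-tempo SD (PDS units)
    pds_item_noise_sd: float = 0.3
    kappa: float = 0.0                    # mm thinning per PDS-excess unit
    coupled_fraction: float = 0.0         # fraction of ROIs receiving kappa
    euler_mean: float = -60.0
    euler_site_sd: float = 10.0
    euler_sd: float = 20.0
    bmi_mean: float = 18.0
    bmi_sd: float = 2.5
    sibling_fraction: float = 0.0         # fraction of subjects paired into 2-child families

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        if self.b_true <= 0:
            raise ValidationError("b_true must be positive")
        if not 0 < self.female_fraction <= 1:
            raise ValidationError("female_fraction must lie in (0, 1]")
        if not 0 <= self.y4_missing_frac <= 1:
            raise ValidationError("y4_missing_frac must lie in [0, 1]")
        if self.n_subjects < 1 or self.n_rois < 1 or self.n_sites < 1:
            raise ValidationError("n_subjects, n_rois, n_sites must be positive")


@dataclass
class TruthRecord:
    """Ground-truth parameters behind a simulated cohort."""

    roi_names: list
    mu: np.ndarray                # per-ROI mean thickness
    beta_age: float
    kappa: np.ndarray             # per-ROI coupling (0 for uncoupled)
    coupled_rois: list
    tau: float
    sigma: float
    a_true: float
    b_true: float
    site_offsets: dict            # site_id -> offset (mm)
    subject_intercepts: pd.DataFrame  # subjects x ROIs
    pds_tempo: pd.Series          # per-subject tempo deviation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_name": self.roi_names,
                "mu": self.mu,
                "beta_age": self.beta_age,
                "kappa": self.kappa,
                "tau": self.tau,
                "sigma": self.sigma,
                "a_true": self.a_true,
                "b_true": self.b_true,
            }
        )


def default_atlas(n_rois: int) -> AtlasMap:
    """Toy atlas: ROIs alternate hemispheres and cycle through the six lobes."""
    names, hemis, lobes = [], [], []
    for i in range(n_rois):
        h = "L" if i % 2 == 0 else "R"
        lobe = LOBES[(i // 2) % len(LOBES)]
        names.append(f"{h}_roi{i:03d}")
        hemis.append(h)
        lobes.append(lobe)
    return AtlasMap(
        pd.DataFrame({"hemisphere": hemis, "lobe": lobes}, index=pd.Index(names, name="roi_name"))
    )


def pds_expected(age_months, sex: str, params: SimParams):
    """Age-expected mean PDS along the sex-specific logistic curve (in [1, 4])."""
    mid = params.pds_midpoint[sex]
    return 1.0 + 3.0 * expit(params.pds_slope * (np.asarray(age_months, float) - mid))


def _roi_names(n_rois: int) -> list:
    return default_atlas(n_rois).roi_names


def simulate_cohort(params: SimParams, seed: int) -> tuple[LongitudinalTable, TruthRecord]:
    """Draw a full synthetic cohort; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    n, R = params.n_subjects, params.n_rois
    rois = _roi_names(R)
    subjects = [f"S{i:05d}" for i in range(n)]

    # family structure: optionally pair consecutive subjects
    family = {}
    fam_idx = 0
    i = 0
    n_paired = int(round(params.sibling_fraction * n))
    while i < n:
        fam = f"F{fam_idx:05d}"
        family[subjects[i]] = fam
        if i + 1 < n and i < n_paired:
            family[subjects[i + 1]] = fam
            i += 2
        else:
            i += 1
        fam_idx += 1

    sex = np.where(rng.random(n) < params.female_fraction, "F", "M")
    sites = np.array([f"site{rng.integers(params.n_sites):02d}" for _ in range(n)])
    site_ids = sorted({f"site{k:02d}" for k in range(params.n_sites)})
    site_off = {s: o for s, o in zip(site_ids, rng.normal(0, params.site_sd, len(site_ids)))}
    euler_site_mean = {
        s: params.euler_mean + o
        for s, o in zip(site_ids, rng.normal(0, params.euler_site_sd, len(site_ids)))
    }

    lo, hi = params.baseline_age_range
    a_, b_ = (
        (lo - params.baseline_age_mean) / params.baseline_age_sd,
        (hi - params.baseline_age_mean) / params.baseline_age_sd,
    )
    age_bl = truncnorm.rvs(
        a_, b_, loc=params.baseline_age_mean, scale=params.baseline_age_sd,
        size=n, random_state=rng,
    )
    gap1 = np.clip(rng.normal(params.visit_gap_mean, params.visit_gap_sd, n), 6.0, None)
    gap2 = np.clip(rng.normal(params.visit_gap_mean, params.visit_gap_sd, n), 6.0, None)
    ages = np.column_stack([age_bl, age_bl + gap1, age_bl + gap1 + gap2])

    mu = rng.uniform(*params.ct_mean_range, R)
    n_coupled = int(round(params.coupled_fraction * R))
    coupled = rois[:n_coupled]
    kappa_vec = np.where(np.isin(rois, coupled), params.kappa, 0.0)
    u = rng.normal(0, params.tau, (n, R))
    tempo = rng.normal(0, params.pds_tempo_sd, n)
    bmi_base = np.clip(rng.normal(params.bmi_mean, params.bmi_sd, n), 11.0, 45.0)
    ses = rng.normal(0, 1, n)

    has_y4 = np.ones(n, dtype=bool)
    n_missing = int(round(params.y4_missing_frac * n))
    has_y4[rng.permutation(n)[:n_missing]] = False

    rows = []
    visit_names = ("baseline", "y2", "y4")
    for i in range(n):
        sx = sex[i]
        items = PDS_ITEMS[sx]
        for v, visit in enumerate(visit_names):
            if visit == "y4" and not has_y4[i]:
                continue
            age = ages[i, v]
            expected = pds_expected(age, sx, params)
            pds_mean = float(np.clip(expected + tempo[i], 1.0, 4.0))
            excess = pds_mean - expected
            eps = rng.standard_normal(R)
            noise = params.sigma * shash_inverse(eps, params.a_true, params.b_true)
            ct = (
                mu
                + site_off[sites[i]]
                + u[i]
                + params.beta_age * (age - params.baseline_age_mean)
                + noise
            )
            if visit != "baseline":
                ct = ct - kappa_vec * excess
            row = {
                "subject_id": subjects[i],
                "family_id": family[subjects[i]],
                "sex": sx,
                "site_id": sites[i],
                "visit": visit,
                "age_months": age,
                "bmi": float(np.clip(bmi_base[i] + rng.normal(0, 0.4), 11.0, 45.0)),
                "euler_number": int(round(rng.normal(euler_site_mean[sites[i]], params.euler_sd))),
                "ses": ses[i],
                "pds_mean": pds_mean,
            }
            item_vals = np.clip(
                np.rint(pds_mean + rng.normal(0, params.pds_item_noise_sd, len(items))),
                1, 4,
            ).astype(int)
            for k, name in enumerate(items):
                if name == "menarche":  # binary caregiver item: 1 (no) or 4 (yes)
                    item_vals[k] = 4 if pds_mean >= 2.5 else 1
                row[f"pds_item_{k + 1}"] = item_vals[k]
            for r, roi in enumerate(rois):
                row[ROI_PREFIX + roi] = ct[r]
            rows.append(row)

    df = pd.DataFrame(rows)
    truth = TruthRecord(
        roi_names=rois,
        mu=mu,
        beta_age=params.beta_age,
        kappa=kappa_vec,
        coupled_rois=list(coupled),
        tau=params.tau,
        sigma=params.sigma,
        a_true=params.a_true,
        b_true=params.b_true,
        site_offsets=site_off,
        subject_intercepts=pd.DataFrame(u, index=subjects, columns=rois),
        pds_tempo=pd.Series(tempo, index=subjects),
    )
    return LongitudinalTable(df), truth


def null_cohort(params: SimParams, seed: int) -> LongitudinalTable:
    """Cohort with coupling and warp disabled (kappa=0, a=0, b=1) — a type-I-error control."""
    null_params = replace(params, kappa=0.0, coupled_fraction=0.0, a_true=0.0, b_true=1.0)
    table, _ = simulate_cohort(null_params, seed)
    return table


@dataclass(frozen=True)
class OutlierSpec:
    """How many QC outliers to plant and how extreme they are."""

    n_bmi: int = 0
    bmi_value: float = 55.0
    n_euler: int = 0
    euler_value: int = -1500
    n_thickness: int = 0
    thickness_sd_offset: float = 12.0   # in sample SDs of the target ROI
    thickness_roi: str | None = None    # default: first ROI in the table


def plant_outliers(
    table: LongitudinalTable, spec: OutlierSpec, seed: int
) -> tuple[LongitudinalTable, list]:
    """Overwrite designated rows with extreme values; returns exact planted positions.

    Each planted entry is a dict with keys ``kind``, ``row`` (positional
    index into the table), ``subject_id`` and ``column``.
    """
    df = table.df.copy()
    total = spec.n_bmi + spec.n_euler + spec.n_thickness
    if total > len(df):
        raise ValidationError(
            f"requested {total} outliers but table has only {len(df)} rows"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(df))[:total]
    planted = []
    pos = 0
    for _ in range(spec.n_bmi):
        r = int(chosen[pos]); pos += 1
        df.iloc[r, df.columns.get_loc("bmi")] = spec.bmi_value
        planted.append({"kind": "bmi", "row": r,
                        "subject_id": df.iloc[r]["subject_id"], "column": "bmi"})
    for _ in range(spec.n_euler):
        r = int(chosen[pos]); pos += 1
        df.iloc[r, df.columns.get_loc("euler_number")] = spec.euler_value
        planted.append({"kind": "euler", "row": r,
                        "subject_id": df.iloc[r]["subject_id"], "column": "euler_number"})
    roi_col = (
        ROI_PREFIX + spec.thickness_roi
        if spec.thickness_roi is not None
        else table.roi_columns[0]
    )
    for _ in range(spec.n_thickness):
        r = int(chosen[pos]); pos += 1
        sd = float(df[roi_col].std(ddof=1))
        df.iloc[r, df.columns.get_loc(roi_col)] = (
            float(df[roi_col].mean()) + spec.thickness_sd_offset * sd
        )
        planted.append({"kind": "thickness", "row": r,
                        "subject_id": df.iloc[r]["subject_id"], "column": roi_col})
    return LongitudinalTable(df, validate=False), planted


def kappa_for_f2(f2: float, params: SimParams, sex: str = "F") -> float:
    """Coupling strength giving a target Cohen f^2 for the PDS ~ z association.

    A baseline-conditioned norm predicts follow-up thickness from the
    *noisy* baseline measurement, so its residual carries both the
    follow-up noise and the propagated baseline noise: with tracking
    ICC = tau^2 / (tau^2 + sigma^2) the effective residual variance is
    sigma^2 (1 + ICC). The deviation score is then approximately
    (eps - kappa * tempo) / s with s^2 = sigma_eff^2 +
    kappa^2 * tempo_sd^2, while observed PDS is the age-expected curve
    plus tempo. Solving corr(z, PDS)^2 = f2 / (1 + f2) for kappa gives a
    closed form in the simulator's variance components; the age spread
    at the 2-year visit sets the curve-driven PDS variance.
    """
    if f2 <= 0:
        raise ValidationError("f2 must be positive")
    r2 = f2 / (1.0 + f2)
    icc = params.tau**2 / (params.tau**2 + params.sigma**2)
    sigma_eff = params.sigma * np.sqrt(1.0 + icc)
    ages = np.linspace(
        params.baseline_age_mean + params.visit_gap_mean - 3 * params.baseline_age_sd,
        params.baseline_age_mean + params.visit_gap_mean + 3 * params.baseline_age_sd,
        201,
    )
    w = np.exp(-0.5 * ((ages - ages.mean()) / params.baseline_age_sd) ** 2)
    w /= w.sum()
    curve = pds_expected(ages, sex, params)
    var_curve = float(np.sum(w * curve**2) - np.sum(w * curve) ** 2)
    s_p2 = var_curve + params.pds_tempo_sd**2
    t2 = params.pds_tempo_sd**2
    # c = kappa * tempo_sd solves r^2 = c^2 * t2 / ((sigma^2 + c^2) * s_p2)
    if t2 <= r2 * s_p2:
        raise ValidationError(
            "target f2 unattainable: tempo variance too small relative to PDS variance"
        )
    c2 = r2 * sigma_eff**2 * s_p2 / (t2 - r2 * s_p2)
    return float(np.sqrt(c2) / params.pds_tempo_sd)
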