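"""Pipeline configuration with paper-derived defaults.

Defaults encode the constants of the analysis: BMI plausibility bounds
(10, 50) kg/m^2, the 6-SD screens for Euler numbers and regional
thickness, the |z| = 1.96 extreme-deviation threshold, the |zDiff| = 1
percentile-shift threshold, the plotted centile set, and a Benjamini-
Hochberg FDR level of q = 0.05. Configuration files are TOML; absent
keys take the defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace

from .exceptions import ValidationError

MODEL_KINDS = ("cnorm", "cnorm_2year", "cnorm_bl2year", "bnorm")

#: default pubertal-stage rule on the mean PDS score (a documented
#: stand-in for questionnaire-item staging rules; see docs/methods.md)
DEFAULT_STAGE_THRESHOLDS = {"pre": 1.5, "early": 2.25, "mid": 3.0, "late": 3.75}


@dataclass(frozen=True)
class Config:
    """All tunable thresholds and switches of the pipeline."""

    bmi_min: float = 10.0
    bmi_max: float = 50.0
    sd_k: float = 6.0                      # group-wise outlier screen, in SDs
    z_extreme: float = 1.96                # extreme-deviation threshold on |z|
    zdiff_threshold: float = 1.0           # percentile-shift grouping on |zDiff|
    centiles: tuple = (1.0, 5.0, 25.0, 50.0, 75.0, 95.0, 99.0)  # percent
    fdr_q: float = 0.05
    model_kind: str = "bnorm"
    warp: str = "shash"                    # or "identity": plain Bayesian ridge
    age_degree: int = 1                    # polynomial expansion of age covariates
    site_fallback: str = "error"           # or "reference": unseen site -> zero vector
    optimizer_xtol: float = 1e-6
    optimizer_ftol: float = 1e-6
    optimizer_maxiter: int = 500
    stage_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_THRESHOLDS))
    seed: int = 0

    def __post_init__(self):
        for name in ("bmi_min", "bmi_max", "sd_k", "z_extreme", "zdiff_threshold", "fdr_q"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)):
                raise ValidationError(f"config value {name!r} must be numeric, got {v!r}")
            if v <= 0:
                raise ValidationError(f"config value {name!r} must be positive, got {v}")
        if not (0 < self.fdr_q < 1):
            raise ValidationError("fdr_q must lie in (0, 1)")
        for c in self.centiles:
            if not 0 < c < 100:
                raise ValidationError(f"centile {c} outside (0, 100)")
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(
                f"unknown model_kind {self.model_kind!r}; expected one of {MODEL_KINDS}"
            )
        if self.warp not in ("shash", "identity"):
            raise ValidationError("warp must be 'shash' or 'identity'")
        if self.site_fallback not in ("error", "reference"):
            raise ValidationError("site_fallback must be 'error' or 'reference'")
        if self.age_degree < 1:
            raise ValidationError("age_degree must be >= 1")

    def with_(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


def load_config(path) -> Config:
    """Read a TOML config file; missing keys fall back to defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "centiles" in raw:
        raw["centiles"] = tuple(float(c) for c in raw["centiles"])
    return Config(**raw)
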