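"""Per-region fit metrics and the model-by-timepoint repeated-measures ANOVA.

Metrics per region, sex, model kind and follow-up: Pearson r between
observed and median-predicted thickness, RMSE, standardized MSE (MSE
divided by the test variance, so predicting the test mean scores exactly
1), explained variance (1 - var(residual)/var(observed)), mean
standardized log-loss relative to a trivial Gaussian built from training
statistics, sample skewness and excess kurtosis of the deviation scores,
and a BIC whose parameter count is the design-column count plus the
three free likelihood hyperparameters.

Model comparison follows the study design: a 2-factor repeated-measures
ANOVA with within factors MODEL and TIMEPOINT and the regions as the
repeated-measures identifier, plus paired-t post-hoc contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .data import warn
from .exceptions import ValidationError
from .shash import shash_log_deriv

__all__ = ["fit_metrics", "metrics_table", "compare_models_rmanova"]

METRIC_COLUMNS = [
    "roi_name", "sex", "model_kind", "timepoint",
    "r", "rmse", "smse", "ev", "msll", "skew", "excess_kurtosis", "bic", "n",
]


def _model_log_density(dev: pd.DataFrame, model) -> np.ndarray:
    """Predictive log-density per deviation-table row, from (z, s_w) + warp."""
    z = dev["z"].to_numpy(float)
    s_w = dev["s_w"].to_numpy(float)
    y_std = (dev["y_obs"].to_numpy(float) - model.y_mean) / model.y_sd
    return (
        -0.5 * np.log(2 * np.pi)
        - np.log(s_w)
        - 0.5 * z**2
        + shash_log_deriv(y_std, model.a, model.b)
        - np.log(model.y_sd)
    )


def fit_metrics(dev: pd.DataFrame, model) -> dict:
    """Metrics for one region's deviation rows under its fitted model."""
    if len(dev) < 3:
        raise ValidationError("need at least 3 rows to compute fit metrics")
    y = dev["y_obs"].to_numpy(float)
    yhat = dev["y_median_pred"].to_numpy(float)
    z = dev["z"].to_numpy(float)
    n = len(y)

    mse = float(np.mean((y - yhat) ** 2))
    var_y = float(np.var(y))
    if var_y == 0:
        warn("zero test variance; SMSE/EV undefined")
        smse = ev = r = float("nan")
    else:
        smse = mse / var_y
        ev = 1.0 - float(np.var(y - yhat)) / var_y
        if np.var(yhat) == 0:
            # evidence can drive a no-signal model to constant predictions
            warn(f"constant predictions for {dev['roi_name'].iat[0]}; r undefined")
            r = float("nan")
        else:
            r = float(stats.pearsonr(y, yhat)[0])

    logp = _model_log_density(dev, model)
    log_trivial = stats.norm.logpdf(
        y, loc=model.trivial_mean, scale=np.sqrt(model.trivial_var)
    )
    msll = float(np.mean(-logp + log_trivial))
    k = len(model.coef) + 3
    bic = k * np.log(n) - 2.0 * float(np.sum(logp))

    row = dict(zip(
        ["roi_name", "sex", "model_kind", "timepoint"],
        [dev["roi_name"].iat[0], dev["sex"].iat[0], None, dev["timepoint"].iat[0]],
    ))
    row.update(
        r=r,
        rmse=float(np.sqrt(mse)),
        smse=smse,
        ev=ev,
        msll=msll,
        skew=float(stats.skew(z, bias=False)),
        excess_kurtosis=float(stats.kurtosis(z, fisher=True, bias=False)),
        bic=float(bic),
        n=n,
    )
    return row


def metrics_table(dev: pd.DataFrame, normset) -> pd.DataFrame:
    """One MetricsRow per (region, timepoint) in a deviation table."""
    rows = []
    for (roi, tp), grp in dev.groupby(["roi_name", "timepoint"], sort=True):
        row = fit_metrics(grp, normset.models[roi])
        row["model_kind"] = normset.model_kind
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def compare_models_rmanova(metrics: pd.DataFrame, metric: str, sex: str):
    """2x2 repeated-measures ANOVA (MODEL x TIMEPOINT) over regions.

    Returns ``(anova, posthoc)``. The ANOVA frame has F tests for the
    MODEL and TIMEPOINT main effects and their interaction with
    numerator df 1 and denominator df n_regions - 1, plus partial
    eta-squared. Post-hoc paired t-tests contrast timepoints within each
    model and models within each timepoint.
    """
    sub = metrics[metrics["sex"] == sex]
    kinds = sorted(sub["model_kind"].unique())
    tps = sorted(sub["timepoint"].unique())
    if len(kinds) != 2 or len(tps) != 2:
        raise ValidationError(
            f"need exactly 2 model kinds and 2 timepoints, got {kinds} x {tps}"
        )
    pivot = sub.pivot_table(
        index="roi_name", columns=["model_kind", "timepoint"], values=metric
    )
    incomplete = pivot.index[pivot.isna().any(axis=1)].tolist()
    if incomplete or pivot.shape[1] != 4:
        raise ValidationError(f"unbalanced cells; incomplete regions: {incomplete[:10]}")

    long = sub[["roi_name", "model_kind", "timepoint", metric]].copy()
    aov = pg.rm_anova(
        data=long, dv=metric, within=["model_kind", "timepoint"],
        subject="roi_name", detailed=True,
    )
    aov = aov.rename(columns={"Source": "effect", "p_unc": "p"})
    # degenerate 0/0 case (metric identical across cells): define F = 0, p = 1
    zero = np.isclose(aov["SS"].to_numpy(float), 0.0, atol=1e-12)
    aov.loc[zero, "F"] = 0.0
    aov.loc[zero, "p"] = 1.0
    aov["partial_eta_sq"] = (aov["F"] * aov["ddof1"]) / (
        aov["F"] * aov["ddof1"] + aov["ddof2"]
    )
    anova = aov[["effect", "ddof1", "ddof2", "F", "p", "partial_eta_sq"]]

    posthoc_rows = []
    for kind in kinds:
        a, b = pivot[(kind, tps[0])], pivot[(kind, tps[1])]
        t, p = stats.ttest_rel(a, b)
        posthoc_rows.append({
            "contrast": f"{kind}: {tps[0]} vs {tps[1]}",
            "mean_diff": float((a - b).mean()), "t": float(t), "p": float(p),
        })
    for tp in tps:
        a, b = pivot[(kinds[0], tp)], pivot[(kinds[1], tp)]
        t, p = stats.ttest_rel(a, b)
        posthoc_rows.append({
            "contrast": f"{tp}: {kinds[0]} vs {kinds[1]}",
            "mean_diff": float((a - b).mean()), "t": float(t), "p": float(p),
        })
    return anova, pd.DataFrame(posthoc_rows)
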