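"""Fish-health indices and tank-position behaviour statistics.

Health indices:
  * condition factor        k   = 100 * body weight (g) / fork length (cm)^3
  * hepatosomatic index     HSI = 100 * liver (mg) / (total (mg) - liver (mg))
  * brain-body ratio        BBR = 100 * brain (mg) / (total (mg) - liver (mg))

The BBR denominator subtracts the liver weight; that is the definition used
by this analysis and it is kept verbatim.

Behaviour: per fish and recording session, minute-by-minute tank-zone
observations (bottom/middle/top) are summed to counts out of
``n_observations``; days are treated as independent observations.  For each
zone x session type the zone count is modelled by ordinary least squares on
exposure + sex + week; the exposure effect is an F test for the multi-level
factor (dosed analysis) or a t test for the two-level control contrast.
The Bonferroni threshold defaults to 0.05/18 (3 zones x 3 session types x
2 analyses).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .connectivity import bonferroni_threshold

__all__ = [
    "condition_factor",
    "hepatosomatic_index",
    "brain_body_ratio",
    "derive_health_metrics",
    "health_tests",
    "behaviour_tests",
]

ZONES = ("bottom", "middle", "top")
SESSION_TYPES = ("spawning", "feeding", "general")
HEALTH_METRICS = ("body_weight_g", "fork_length_cm", "k", "hsi", "bbr")


def condition_factor(weight_g, length_cm):
    """k = 100 * weight / length^3 (weight in g, length in cm)."""
    weight_g = np.asarray(weight_g, dtype=float)
    length_cm = np.asarray(length_cm, dtype=float)
    if np.any(weight_g <= 0) or np.any(length_cm <= 0):
        raise ValueError("weight and length must be positive")
    return 100.0 * weight_g / length_cm**3


def hepatosomatic_index(liver_mg, total_mg):
    """HSI = 100 * liver / (total - liver), weights in mg."""
    liver_mg = np.asarray(liver_mg, dtype=float)
    total_mg = np.asarray(total_mg, dtype=float)
    if np.any(liver_mg < 0):
        raise ValueError("liver weight must be non-negative")
    if np.any(total_mg <= liver_mg):
        raise ValueError("total weight must exceed liver weight")
    return 100.0 * liver_mg / (total_mg - liver_mg)


def brain_body_ratio(brain_mg, total_mg, liver_mg):
    """BBR = 100 * brain / (total - liver), weights in mg."""
    brain_mg = np.asarray(brain_mg, dtype=float)
    total_mg = np.asarray(total_mg, dtype=float)
    liver_mg = np.asarray(liver_mg, dtype=float)
    if np.any(brain_mg <= 0):
        raise ValueError("brain weight must be positive")
    if np.any(total_mg <= liver_mg):
        raise ValueError("total weight must exceed liver weight")
    return 100.0 * brain_mg / (total_mg - liver_mg)


def derive_health_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append k, HSI and BBR to a raw fish-metrics table."""
    out = metrics.copy()
    total_mg = out["body_weight_g"] * 1000.0
    out["k"] = condition_factor(out["body_weight_g"], out["fork_length_cm"])
    out["hsi"] = hepatosomatic_index(out["liver_weight_mg"], total_mg)
    out["bbr"] = brain_body_ratio(out["brain_weight_mg"], total_mg, out["liver_weight_mg"])
    return out


def _exposure_anova_p(data: pd.DataFrame, response: str, covariates: list[str]) -> tuple[float, float]:
    """F statistic and p-value for the multi-level exposure factor in an OLS
    of ``response`` on exposure + covariates."""
    if data[response].nunique() <= 1:
        raise ValueError(f"degenerate model for {response}: response is constant")
    rhs = " + ".join(["C(group)"] + [f"C({c})" for c in covariates])
    fit = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if fit.df_resid < 1 or fit.ssr <= 0:
        raise ValueError(f"degenerate model for {response}: no residual variation")
    table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(group)", "F"]), float(table.loc["C(group)", "PR(>F)"])


def _control_contrast_p(data: pd.DataFrame, response: str, covariates: list[str]) -> tuple[float, float]:
    """t statistic and p-value of the two-level exposure contrast."""
    levels = list(pd.unique(data["group"].astype(str)))
    if len(levels) != 2:
        raise ValueError("control contrast requires exactly two exposure levels")
    if data[response].nunique() <= 1:
        raise ValueError(f"degenerate model for {response}: response is constant")
    rhs = " + ".join(["C(group)"] + [f"C({c})" for c in covariates])
    fit = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if fit.df_resid < 1 or fit.ssr <= 0:
        raise ValueError(f"degenerate model for {response}: no residual variation")
    name = next(nm for nm in fit.params.index if nm.startswith("C(group)"))
    return float(fit.tvalues[name]), float(fit.pvalues[name])


def health_tests(
    metrics: pd.DataFrame,
    analysis: str = "exposure",
    metrics_to_test: tuple[str, ...] = HEALTH_METRICS,
) -> pd.DataFrame:
    """Per-sex, per-metric exposure tests on the health metrics.

    ``analysis='exposure'``: one-way ANOVA of each metric on the multi-level
    exposure factor plus week, run separately in females and males.
    ``analysis='control'``: two-level linear-regression contrast (e.g. water
    vs vehicle) with the same covariate.  A table of F/t statistics and
    p-values is returned.
    """
    data = metrics.copy()
    data["group"] = data["group"].astype(str)
    rows = []
    for sex, sub in data.groupby("sex"):
        if sub.groupby("group").size().min() < 2:
            raise ValueError(f"need at least 2 fish per group for sex {sex!r}")
        for metric in metrics_to_test:
            if analysis == "exposure":
                stat, p = _exposure_anova_p(sub, metric, ["week"])
            elif analysis == "control":
                stat, p = _control_contrast_p(sub, metric, ["week"])
            else:
                raise ValueError(f"unknown analysis {analysis!r}")
            rows.append({"sex": sex, "metric": metric, "statistic": stat, "pvalue": p})
    return pd.DataFrame(rows)


def behaviour_tests(
    records: pd.DataFrame,
    analysis: str = "exposure",
    n_tests: int = 18,
    alpha: float = 0.05,
    include_tank: bool = False,
) -> pd.DataFrame:
    """Zone-count models per zone x session type.

    Each record is one fish x session with zone counts out of a fixed number
    of observations.  The count is regressed on exposure + sex + week
    (optionally + tank); the exposure effect is an F test (``'exposure'``)
    or a two-level t test (``'control'``).  Rows with missing zone counts are
    dropped listwise with a warning.  Significance is flagged against the
    Bonferroni threshold alpha / n_tests (default 0.05/18 for 3 zones x
    3 session types x 2 analyses).
    """
    needed = list(ZONES) + ["group", "sex", "week", "session_type"]
    data = records.copy()
    data["group"] = data["group"].astype(str)
    missing = data[needed].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} records with missing values",
            RuntimeWarning,
            stacklevel=2,
        )
        data = data.loc[~missing]
    covariates = ["sex", "week"] + (["tank"] if include_tank else [])
    threshold = bonferroni_threshold(n_tests, alpha)
    rows = []
    for session in pd.unique(data["session_type"]):
        sub = data[data["session_type"] == session]
        for zone in ZONES:
            if analysis == "exposure":
                stat, p = _exposure_anova_p(sub, zone, covariates)
            elif analysis == "control":
                stat, p = _control_contrast_p(sub, zone, covariates)
            else:
                raise ValueError(f"unknown analysis {analysis!r}")
            rows.append(
                {
                    "session_type": session,
                    "zone": zone,
                    "statistic": stat,
                    "pvalue": p,
                    "bonferroni_threshold": threshold,
                    "significant": p < threshold,
                }
            )
    return pd.DataFrame(rows)
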