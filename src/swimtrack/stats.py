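"""Statistical battery for treatment-group comparisons of swimming trials.

The design the pipeline serves is a small repeated-measures study: a few
individuals per treatment group (sham-operated controls and two spinal
transection levels), several swimming trials per individual, and a
continuous per-individual covariate (percent axon regeneration) available
only for the transected animals.  The battery is:

* parametric-assumption diagnostics (Shapiro-Wilk per group, Levene),
  advisory only — they never auto-switch the test;
* one-way ANOVA across treatments, run on individual means so that the
  repeated trials of one animal do not masquerade as independent samples;
* Holm-Sidak step-down adjusted pairwise comparisons;
* ordinary least-squares regressions of responses on percent regeneration
  (individual means, transected animals only);
* a linear mixed model of swimming speed on tail-beat frequency, percent
  regeneration and their interaction, with a random intercept per
  individual, fitted by REML — this runs on trials, which is exactly the
  correlation structure the random effect exists to absorb.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import ValidationError

__all__ = [
    "AssumptionDiagnostics",
    "AnovaResult",
    "RegressionResult",
    "MixedModelResult",
    "check_parametric_assumptions",
    "one_way_anova",
    "holm_sidak_adjust",
    "holm_sidak_posthoc",
    "regress_on_regeneration",
    "mixed_model_speed",
    "individual_means",
]

ALPHA = 0.05


def individual_means(
    table: pd.DataFrame,
    response: str,
    keep: tuple[str, ...] = ("treatment", "regeneration_pct"),
) -> pd.DataFrame:
    """Collapse a trial table to one row per individual (mean response)."""
    cols = {response: "mean"}
    for k in keep:
        if k in table.columns:
            cols[k] = "first"
    return table.groupby("individual_id", as_index=False).agg(cols)


@dataclass
class AssumptionDiagnostics:
    response: str
    shapiro: pd.DataFrame  # group, n, statistic, p, pass / underpowered flag
    levene_stat: float
    levene_p: float
    normality_ok: bool
    homoscedastic: bool
    alpha: float = ALPHA


def check_parametric_assumptions(
    table: pd.DataFrame, response: str, factor: str = "treatment",
    alpha: float = ALPHA,
) -> AssumptionDiagnostics:
    """Shapiro-Wilk per group and Levene across groups; advisory only."""
    groups = [(g, np.asarray(sub[response].dropna(), float))
              for g, sub in table.groupby(factor)]
    if len(groups) < 2 or any(len(v) < 2 for _, v in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    rows = []
    for g, v in groups:
        if len(v) < 3:
            rows.append({"group": g, "n": len(v), "statistic": np.nan,
                         "p": np.nan, "flag": "underpowered"})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = sps.shapiro(v)
        rows.append({"group": g, "n": len(v), "statistic": float(w),
                     "p": float(p), "flag": "ok" if p >= alpha else "non-normal"})
    shapiro = pd.DataFrame(rows)
    lev_stat, lev_p = sps.levene(*[v for _, v in groups])
    tested = shapiro[shapiro["flag"] != "underpowered"]
    return AssumptionDiagnostics(
        response=response,
        shapiro=shapiro,
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        normality_ok=bool((tested["p"] >= alpha).all()) if len(tested) else True,
        homoscedastic=bool(lev_p >= alpha),
        alpha=alpha,
    )


@dataclass
class AnovaResult:
    response: str
    factor: str
    df_between: int
    df_within: int
    f_stat: float
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)


def one_way_anova(
    table: pd.DataFrame, response: str, factor: str = "treatment"
) -> AnovaResult:
    """Standard between/within variance decomposition across factor levels."""
    groups = [(g, np.asarray(sub[response].dropna(), float))
              for g, sub in table.groupby(factor)]
    groups = [(g, v) for g, v in groups if len(v) > 0]
    k = len(groups)
    n_total = sum(len(v) for _, v in groups)
    if k < 2 or n_total <= k:
        raise ValidationError("ANOVA needs >= 2 groups and residual df > 0")
    if all(np.allclose(v, v.mean()) for _, v in groups):
        raise ValidationError(
            "zero within-group variance in every group; F is degenerate"
        )
    f_stat, p = sps.f_oneway(*[v for _, v in groups])
    return AnovaResult(
        response=response,
        factor=factor,
        df_between=k - 1,
        df_within=n_total - k,
        f_stat=float(f_stat),
        p_value=float(p),
        group_means={g: float(v.mean()) for g, v in groups},
    )


def holm_sidak_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjustment of a family of p-values.

    The i-th smallest of m raw p-values is adjusted to
    1 - (1 - p)^(m - i + 1), with running maxima enforcing monotonicity
    down the sorted list, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def holm_sidak_posthoc(
    table: pd.DataFrame, response: str, factor: str = "treatment",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """All pairwise two-sample t comparisons with Holm-Sidak adjustment.

    Returns a table with one row per pair: raw p, adjusted p, significance
    at ``alpha``.  A single pair reduces to the single-step Sidak (which for
    m=1 is the raw p).
    """
    groups = {g: np.asarray(sub[response].dropna(), float)
              for g, sub in table.groupby(factor)}
    names = [g for g, v in groups.items() if len(v) >= 2]
    if len(names) < 2:
        raise ValidationError("post hoc needs >= 2 groups with >= 2 observations")
    rows = []
    for a, b in itertools.combinations(names, 2):
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        rows.append({"pair": f"{a} vs {b}", "t_stat": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out


@dataclass
class RegressionResult:
    response: str
    predictor: str
    slope: float
    intercept: float
    df_model: int
    df_resid: int
    f_stat: float
    p_value: float
    r_squared: float
    n: int


def regress_on_regeneration(table: pd.DataFrame, response: str) -> RegressionResult:
    """OLS of a response on percent axon regeneration (individual means).

    Sham animals carry no regeneration value and are excluded automatically;
    repeated trials are collapsed to individual means first.
    """
    sub = table.dropna(subset=["regeneration_pct"])
    means = individual_means(sub, response)
    if len(means) < 3:
        raise ValidationError(
            "regression needs >= 3 individuals with a regeneration value"
        )
    x = means["regeneration_pct"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError("all regeneration values identical; slope undefined")
    fit = smf.ols(f"{response} ~ regeneration_pct", data=means).fit()
    return RegressionResult(
        response=response,
        predictor="regeneration_pct",
        slope=float(fit.params["regeneration_pct"]),
        intercept=float(fit.params["Intercept"]),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        f_stat=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        n=len(means),
    )


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # term, estimate, se, z, p, ci_low, ci_high
    random_intercept_var: float
    residual_var: float
    method: str  # "mixedlm" or "ols_fallback"
    n_individuals: int
    n_trials: int
    converged: bool
    warning: str | None = None


def mixed_model_speed(
    table: pd.DataFrame,
    response: str = "speed_bl_s",
    frequency: str = "frequency_hz",
) -> MixedModelResult:
    """Speed ~ frequency * regeneration with a random intercept per individual.

    Fitted by REML; fixed-effect p-values are Wald tests from the single
    fit.  Sham rows (no regeneration value) are excluded.  If every
    individual contributed only one trial the random intercept is not
    identifiable and the model silently degrades to OLS, recorded in
    ``method`` and ``warning``.
    """
    data = table.dropna(subset=["regeneration_pct", response, frequency]).copy()
    counts = data.groupby("individual_id").size()
    if len(counts) < 3:
        raise ValidationError("mixed model needs >= 3 individuals")
    formula = f"{response} ~ {frequency} * regeneration_pct"

    if (counts <= 1).all():
        fit = smf.ols(formula, data=data).fit()
        fe = pd.DataFrame({
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        })
        ci = fit.conf_int()
        fe["ci_low"], fe["ci_high"] = ci[0].to_numpy(), ci[1].to_numpy()
        return MixedModelResult(
            fixed_effects=fe,
            random_intercept_var=0.0,
            residual_var=float(fit.mse_resid),
            method="ols_fallback",
            n_individuals=len(counts),
            n_trials=len(data),
            converged=True,
            warning="single trial per individual: random intercept "
                    "unidentifiable, fell back to OLS",
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["individual_id"])
        fit = model.fit(reml=True)
    k_fe = len(fit.fe_params)
    fe = pd.DataFrame({
        "term": fit.fe_params.index,
        "estimate": fit.fe_params.to_numpy(),
        "se": fit.bse.to_numpy()[:k_fe],
        "z": fit.tvalues.to_numpy()[:k_fe],
        "p": fit.pvalues.to_numpy()[:k_fe],
    })
    ci = fit.conf_int().iloc[:k_fe]
    fe["ci_low"], fe["ci_high"] = ci[0].to_numpy(), ci[1].to_numpy()
    return MixedModelResult(
        fixed_effects=fe,
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        method="mixedlm",
        n_individuals=len(counts),
        n_trials=len(data),
        converged=bool(fit.converged),
    )
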