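"""Trial endpoint statistics and the matched synthetic-control comparison.

Covers: binomial proportion confidence intervals (Wilson score,
Clopper–Pearson, logit-Wald), objective-response tallies, Kaplan–Meier
survival with median follow-up by reverse KM, exact covariate matching of
trial patients to historical controls with balancing weights, and weighted
logistic / Cox comparisons of the matched arms.

Exact matching uses six discretized covariates (age group, sex, LDH,
M stage, BRAF status, PD-L1 status). Within each covariate combination the
controls receive weight (cases in combination)/(controls in combination),
so the weighted control covariate distribution equals the matched-case
distribution exactly and each combination's control mass equals its case
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import qth_survival_times
from scipy import stats
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "MATCHING_COVARIATES",
    "binomial_ci",
    "response_tally",
    "SurvivalCurve",
    "km_estimate",
    "reverse_km_followup",
    "MatchedCohort",
    "exact_match",
    "weighted_logistic",
    "weighted_cox",
]

MATCHING_COVARIATES = ["age_group", "sex", "ldh", "m_stage", "braf", "pdl1"]
RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")
OBJECTIVE = ("CR", "PR")


def binomial_ci(
    x: int, n: int, method: str = "wilson", conf: float = 0.95
) -> tuple[float, float]:
    """Two-sided confidence interval for a binomial proportion x/n.

    ``wilson``: score interval without continuity correction.
    ``clopper_pearson``: exact beta-quantile interval.
    ``logit_wald``: inverse-logit of log(x/(n-x)) +/- z*sqrt(1/x + 1/(n-x)),
    the interval a logistic regression Wald CI produces; undefined at
    x in {0, n}.
    """
    if not (0 <= x <= n) or n < 1:
        raise ValidationError("require 0 <= x <= n and n >= 1")
    alpha = 1.0 - conf
    if method == "wilson":
        lo, hi = proportion_confint(x, n, alpha=alpha, method="wilson")
    elif method == "clopper_pearson":
        lo, hi = proportion_confint(x, n, alpha=alpha, method="beta")
        lo = 0.0 if x == 0 else lo
        hi = 1.0 if x == n else hi
    elif method == "logit_wald":
        if x == 0 or x == n:
            raise DegenerateInputError("logit_wald undefined for x in {0, n}")
        z = stats.norm.ppf(1 - alpha / 2)
        logit_p = np.log(x / (n - x))
        se = np.sqrt(1 / x + 1 / (n - x))
        lo, hi = expit(logit_p - z * se), expit(logit_p + z * se)
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


def response_tally(
    responses: pd.Series | list, method: str = "wilson", conf: float = 0.95
) -> pd.DataFrame:
    """Counts, rates and CIs per response category plus the ORR (CR + PR).

    Missing responses are dropped from the denominator.
    """
    resp = pd.Series(responses).dropna()
    n = len(resp)
    if n == 0:
        raise ValidationError("no recorded responses")
    rows = []
    for level in RESPONSE_LEVELS + ("ORR",):
        x = int(resp.isin(OBJECTIVE).sum()) if level == "ORR" else int((resp == level).sum())
        try:
            lo, hi = binomial_ci(x, n, method=method, conf=conf)
        except DegenerateInputError:
            lo, hi = float("nan"), float("nan")
        rows.append({"category": level, "count": x, "n": n, "rate": x / n,
                     "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


@dataclass
class SurvivalCurve:
    """Product-limit estimate with pointwise CIs and median."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    median: float               # inf when not reached
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        """S(t) with right-continuous step convention."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.timeline, "survival": self.survival,
             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
             "at_risk": self.at_risk}
        )


def km_estimate(times, events, conf: float = 0.95) -> SurvivalCurve:
    """Kaplan–Meier estimate with Greenwood-based log-log pointwise CIs.

    The median is the earliest time with S(t) <= 0.5 (inf when never
    reached); its CI applies the same quantile rule to the pointwise
    confidence bounds (Brookmeyer–Crowley style).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.size != events.size:
        raise ValidationError("times and events must have equal length")
    if (times < 0).any():
        raise ValidationError("negative times")
    kmf = KaplanMeierFitter(alpha=1 - conf)
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    timeline = surv.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    lo_med = float(qth_survival_times(0.5, ci.iloc[:, 1]))  # upper bound crosses last
    hi_med = float(qth_survival_times(0.5, ci.iloc[:, 0]))
    lo_med, hi_med = min(lo_med, hi_med), max(lo_med, hi_med)
    return SurvivalCurve(
        timeline=timeline,
        survival=surv.to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        at_risk=at_risk,
        median=median,
        median_ci=(lo_med, hi_med),
    )


def reverse_km_followup(times, events) -> float:
    """Median follow-up by reverse Kaplan–Meier.

    Event and censoring roles are swapped (censoring becomes the event);
    the median of the resulting curve — earliest time its survival drops to
    0.5 or below — estimates the median follow-up. Returns inf when every
    subject had the event (all reverse-censored: not estimable).
    """
    events = np.asarray(events, dtype=int)
    curve = km_estimate(times, 1 - events)
    return curve.median


@dataclass
class MatchedCohort:
    """Exact-matched trial cases and weighted historical controls."""

    cases: pd.DataFrame
    controls: pd.DataFrame          # includes a 'weight' column
    unmatched_cases: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        """Single analysis table: arm, covariates, outcomes, weight."""
        cases = self.cases.copy()
        cases["weight"] = 1.0
        return pd.concat([cases, self.controls], ignore_index=True)


def exact_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    covariates: list[str] = MATCHING_COVARIATES,
    control_filter=None,
) -> MatchedCohort:
    """Exact matching on a covariate combination with balancing weights.

    Records (case or control) missing any matching covariate are excluded
    and reported. ``control_filter`` is an optional predicate on control
    rows applied before matching (e.g. to drop M1d-stage controls). Controls
    in combination c get weight (cases in c)/(controls in c); cases without
    any same-combination control are listed unmatched.
    """
    missing_cols = [c for c in covariates if c not in cases.columns or c not in controls.columns]
    if missing_cols:
        raise ValidationError(f"missing matching covariate column(s): {missing_cols}")
    if control_filter is not None:
        controls = controls[controls.apply(control_filter, axis=1)]

    complete_cases = cases.dropna(subset=covariates)
    complete_controls = controls.dropna(subset=covariates)
    excluded = pd.concat(
        [cases.loc[cases.index.difference(complete_cases.index)],
         controls.loc[controls.index.difference(complete_controls.index)]]
    )

    key_cases = complete_cases[covariates].apply(tuple, axis=1)
    key_controls = complete_controls[covariates].apply(tuple, axis=1)
    case_counts = key_cases.value_counts()
    control_counts = key_controls.value_counts()

    matchable = key_cases.isin(control_counts.index)
    matched_cases = complete_cases[matchable].copy()
    unmatched = complete_cases[~matchable].copy()
    if matched_cases.empty:
        raise ValidationError("no case could be matched to any control")

    used = key_controls.isin(case_counts.index)
    matched_controls = complete_controls[used].copy()
    keys_used = key_controls[used]
    matched_controls["weight"] = [
        case_counts[k] / control_counts[k] for k in keys_used
    ]
    return MatchedCohort(
        cases=matched_cases.reset_index(drop=True),
        controls=matched_controls.reset_index(drop=True),
        unmatched_cases=unmatched.reset_index(drop=True),
        excluded=excluded.reset_index(drop=True),
    )


def _objective(series: pd.Series) -> pd.Series:
    return series.isin(OBJECTIVE).astype(float)


def weighted_logistic(
    cohort: MatchedCohort | pd.DataFrame,
    outcome: str = "objective_response",
    conf: float = 0.95,
    robust: bool = True,
) -> dict:
    """Weighted logistic regression of response on the arm indicator.

    Cases carry weight 1, controls their matching weights. Returns the
    trial-vs-control odds ratio with CI and p, and per-arm fitted response
    rates with Wald CIs on the logit scale. Standard errors use an HC0
    sandwich by default (``robust=False`` for model-based). Complete
    separation is reported with an infinite-OR sentinel instead of raising.
    """
    df = cohort.to_frame() if isinstance(cohort, MatchedCohort) else cohort.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if outcome == "objective_response":
        if "response" not in df.columns:
            raise ValidationError("cohort lacks a 'response' column")
        df["_y"] = _objective(df["response"])
    else:
        df["_y"] = df[outcome].astype(float)
    df = df.dropna(subset=["_y"])
    df["_arm"] = (df["arm"] == "trial").astype(float)
    for arm in (0.0, 1.0):
        ys = df.loc[df["_arm"] == arm, "_y"]
        if ys.nunique() < 2:
            # separation: report sentinel effects rather than a Wald fit
            rate = float(np.average(ys, weights=df.loc[df["_arm"] == arm, "weight"]))
            return {"or": float("inf"), "or_ci": (float("nan"), float("nan")),
                    "p_value": float("nan"), "separation": True,
                    "rates": {("trial" if arm else "control"): rate}}
    X = sm.add_constant(df["_arm"].to_numpy())
    model = sm.GLM(
        df["_y"].to_numpy(), X, family=sm.families.Binomial(),
        var_weights=df["weight"].to_numpy(),
    )
    res = model.fit(cov_type="HC0") if robust else model.fit()
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    beta, cov = res.params, res.cov_params()
    or_est = float(np.exp(beta[1]))
    se_or = float(np.sqrt(cov[1, 1]))
    out = {
        "or": or_est,
        "or_ci": (float(np.exp(beta[1] - z * se_or)), float(np.exp(beta[1] + z * se_or))),
        "p_value": float(res.pvalues[1]),
        "separation": False,
        "rates": {},
    }
    for arm_name, vec in (("control", np.array([1.0, 0.0])), ("trial", np.array([1.0, 1.0]))):
        eta = float(vec @ beta)
        se = float(np.sqrt(vec @ cov @ vec))
        out["rates"][arm_name] = {
            "rate": float(expit(eta)),
            "ci": (float(expit(eta - z * se)), float(expit(eta + z * se))),
        }
    return out


def weighted_cox(
    cohort: MatchedCohort | pd.DataFrame,
    endpoint: str = "pfs",
    conf: float = 0.95,
    robust: bool = True,
) -> dict:
    """Weighted Cox proportional-hazards comparison of the two arms.

    Fits a partial likelihood with observation weights (Efron tie handling)
    on ``<endpoint>_months`` / ``<endpoint>_event`` columns and returns the
    trial-vs-control hazard ratio with CI and p-value.
    """
    df = cohort.to_frame() if isinstance(cohort, MatchedCohort) else cohort.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    for col in (tcol, ecol):
        if col not in df.columns:
            raise ValidationError(f"cohort lacks column {col!r}")
    df = df.dropna(subset=[tcol, ecol])
    df["_arm"] = (df["arm"] == "trial").astype(float)
    for arm in (0.0, 1.0):
        if df.loc[df["_arm"] == arm, ecol].sum() == 0:
            raise ValidationError("at least one event per arm is required")
    fit_df = df[["_arm", tcol, ecol, "weight"]]
    cph = CoxPHFitter(alpha=1 - conf)
    cph.fit(
        fit_df, duration_col=tcol, event_col=ecol, weights_col="weight",
        robust=robust, show_progress=False,
    )
    summary = cph.summary.loc["_arm"]
    return {
        "hr": float(np.exp(summary["coef"])),
        "hr_ci": (float(np.exp(summary["coef lower 95%"])),
                  float(np.exp(summary["coef upper 95%"]))),
        "p_value": float(summary["p"]),
    }
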