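"""Survival analysis of PV-loop parameters against adverse cardiac events.

Implements the staircase of Cox proportional-hazards models used to ask
whether ventricular energetics add prognostic value over demographics,
clinical history, and conventional volumetrics:

* M1   — age + sex;
* M2   — M1 + hypertension + diabetes + heart-failure etiology;
* M3_V — M2 + ejection fraction + end-diastolic volume index;
* M3_PV — M2 + ventricular efficiency + stroke work.

Percent-valued predictors whose *decrease* marks worse physiology (EF, VE)
are sign-flipped before fitting so the reported hazard ratio reads "per
percentage-point decrease".  Nested models are compared by Harrell's
concordance and the likelihood-ratio test.  Cox fits use the partial
likelihood with Efron tie handling (via lifelines); a Spearman collinearity
screen blocks covariate pairs with |rho| >= 0.8 from entering one model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

__all__ = [
    "CoxModelResult",
    "spearman_screen",
    "code_negative_percent",
    "fit_cox",
    "model_staircase",
    "likelihood_ratio_test",
    "concordance_index",
    "km_curve",
    "tertile_km",
    "CollinearityError",
    "FitError",
    "STAIRCASE_COVARIATES",
]


class CollinearityError(ValueError):
    """A model includes a covariate pair flagged by the collinearity screen."""


class FitError(RuntimeError):
    """The Cox partial-likelihood fit is infeasible or failed."""


DURATION_COL = "time_years"
EVENT_COL = "event"

#: Covariate sets of the nested model staircase.  ``ef_neg_pct`` and
#: ``ve_neg_pct`` are the sign-flipped percent scales.
STAIRCASE_COVARIATES: dict[str, list[str]] = {
    "M1": ["age", "male"],
    "M2": ["age", "male", "hypertension", "diabetes", "nonischemic"],
    "M3_V": ["age", "male", "hypertension", "diabetes", "nonischemic", "ef_neg_pct", "edvi"],
    "M3_PV": [
        "age",
        "male",
        "hypertension",
        "diabetes",
        "nonischemic",
        "ve_neg_pct",
        "stroke_work_j",
    ],
}


def code_negative_percent(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Sign-flip a percent scale so a 1-unit *decrease* is a +1 covariate step.

    Fitting on the coded scale makes ``exp(beta)`` the hazard ratio per
    percentage-point decrease of the raw variable.
    """
    return -values


def add_model_codings(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived covariate codings used by the model staircase."""
    out = table.copy()
    if "etiology" in out.columns:
        out["nonischemic"] = (out["etiology"] == "NIDCM").astype(float)
    if "ef_pct" in out.columns:
        out["ef_neg_pct"] = code_negative_percent(out["ef_pct"])
    if "ve_pct" in out.columns:
        out["ve_neg_pct"] = code_negative_percent(out["ve_pct"])
    for col in ("male", "hypertension", "diabetes", "event"):
        if col in out.columns:
            out[col] = out[col].astype(float) if col != "event" else out[col].astype(bool)
    return out


def spearman_screen(
    table: pd.DataFrame, candidates: list[str], threshold: float = 0.8
) -> tuple[pd.DataFrame, set[frozenset[str]]]:
    """Rank-correlation collinearity screen.

    Returns the Spearman correlation matrix over the candidate covariates
    and the set of unordered pairs with ``|rho| >= threshold`` (such pairs
    must not enter one multivariable model together).  Constant columns have
    undefined rank correlation; they are flagged with every partner and a
    warning is emitted.
    """
    sub = table[candidates].dropna()
    if len(sub) < 3:
        raise FitError("need at least 3 complete rows for the collinearity screen")
    matrix = sub.corr(method="spearman")
    flagged: set[frozenset[str]] = set()
    constant = [c for c in candidates if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant columns have undefined rank correlation: {constant}; "
            "flagging their pairs"
        )
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            rho = matrix.loc[a, b]
            if a in constant or b in constant or (np.isfinite(rho) and abs(rho) >= threshold):
                flagged.add(frozenset((a, b)))
    return matrix, flagged


@dataclass(frozen=True)
class CoxModelResult:
    """A fitted Cox proportional-hazards model."""

    covariates: list[str]
    coefficients: pd.Series  # log-hazard per unit
    hazard_ratios: pd.Series
    ci_lower: pd.Series  # 95% CI on the hazard-ratio scale
    ci_upper: pd.Series
    wald_statistics: pd.Series  # z^2
    p_values: pd.Series
    standard_errors: pd.Series
    log_likelihood: float
    concordance: float
    n_used: int
    n_events: int
    coding_notes: dict[str, str] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "hr": self.hazard_ratios,
                "hr_ci_lower": self.ci_lower,
                "hr_ci_upper": self.ci_upper,
                "wald": self.wald_statistics,
                "p": self.p_values,
                "se": self.standard_errors,
            }
        )


_CODING_NOTES = {
    "ef_neg_pct": "ejection fraction entered as negative percent (HR per-% decrease)",
    "ve_neg_pct": "ventricular efficiency entered as negative percent (HR per-% decrease)",
    "nonischemic": "1 = nonischemic (NIDCM), 0 = ischemic (ICM)",
}


def fit_cox(
    table: pd.DataFrame,
    covariates: list[str],
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
    flagged_pairs: set[frozenset[str]] | None = None,
) -> CoxModelResult:
    """Fit a Cox model by partial-likelihood maximization (Efron ties).

    Rows with missing values in the modelled columns are dropped and the
    per-model sample size reported in ``n_used``.  Raises
    :class:`CollinearityError` if the covariate set contains a pair flagged
    by :func:`spearman_screen`.
    """
    if flagged_pairs:
        for pair in flagged_pairs:
            if pair <= set(covariates):
                raise CollinearityError(
                    f"covariates {sorted(pair)} are rank-correlated above the screen threshold"
                )
    cols = covariates + [duration_col, event_col]
    data = table[cols].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise FitError("cannot fit a Cox model with zero events")

    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise FitError(f"Cox partial-likelihood fit failed: {exc}") from exc

    summ = cph.summary
    z = summ["z"]
    return CoxModelResult(
        covariates=list(covariates),
        coefficients=summ["coef"].copy(),
        hazard_ratios=summ["exp(coef)"].copy(),
        ci_lower=summ["exp(coef) lower 95%"].copy(),
        ci_upper=summ["exp(coef) upper 95%"].copy(),
        wald_statistics=(z**2).rename("wald"),
        p_values=summ["p"].copy(),
        standard_errors=summ["se(coef)"].copy(),
        log_likelihood=float(cph.log_likelihood_),
        concordance=float(cph.concordance_index_),
        n_used=int(len(data)),
        n_events=n_events,
        coding_notes={c: _CODING_NOTES[c] for c in covariates if c in _CODING_NOTES},
    )


def model_staircase(
    table: pd.DataFrame,
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
    screen_threshold: float = 0.8,
) -> dict[str, CoxModelResult]:
    """Fit the nested model staircase M1 -> M2 -> {M3_V, M3_PV}.

    All four models are fit on the common complete-case sample across every
    staircase covariate so that likelihood-ratio tests between nested pairs
    are valid.  The collinearity screen is applied per model.
    """
    coded = add_model_codings(table)
    all_covs = sorted({c for cs in STAIRCASE_COVARIATES.values() for c in cs})
    missing = [c for c in all_covs if c not in coded.columns]
    if missing:
        raise FitError(f"cohort table lacks staircase covariates: {missing}")
    common = coded[all_covs + [duration_col, event_col]].dropna()

    results: dict[str, CoxModelResult] = {}
    for name, covs in STAIRCASE_COVARIATES.items():
        _, flagged = spearman_screen(common, covs, threshold=screen_threshold)
        results[name] = fit_cox(
            common, covs, duration_col, event_col, flagged_pairs=flagged
        )
    return results


def likelihood_ratio_test(
    small: CoxModelResult, big: CoxModelResult
) -> tuple[float, int, float]:
    """Nested-model likelihood-ratio test.

    Returns ``(chi2, df, p)`` with ``chi2 = 2 * (LL_big - LL_small)`` and a
    chi-square upper-tail p-value at ``df`` = difference in covariate count.
    """
    if not set(small.covariates) <= set(big.covariates):
        raise ValueError("models are not nested: small covariates must be a subset")
    if small.n_used != big.n_used:
        raise ValueError("nested models must be fit on the same sample")
    df = len(big.covariates) - len(small.covariates)
    chi2 = 2.0 * (big.log_likelihood - small.log_likelihood)
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def concordance_index(
    risk_scores: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
) -> float:
    """Harrell's C for a risk score against right-censored outcomes.

    The probability, over comparable patient pairs, that the patient with
    the higher risk score fails first; ties in risk count one half.  0.5 is
    chance, 1.0 perfect ranking.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if len(risk) == 0:
        raise ValueError("empty input")
    # lifelines' convention scores concordance of *predicted survival time*,
    # so higher risk enters negated.
    return float(_lifelines_cindex(durations, -risk, events))


def model_concordance(result: CoxModelResult, table: pd.DataFrame,
                      duration_col: str = DURATION_COL,
                      event_col: str = EVENT_COL) -> float:
    """Harrell's C of a fitted model's linear predictor on a given table."""
    data = table[result.covariates + [duration_col, event_col]].dropna()
    risk = data[result.covariates].to_numpy() @ result.coefficients.to_numpy()
    return concordance_index(risk, data[duration_col].to_numpy(), data[event_col].to_numpy())


def km_curve(
    durations: np.ndarray, events: np.ndarray, label: str = "KM"
) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival curve with Greenwood-based CIs.

    Returns a right-continuous nonincreasing step function, ``S(0) = 1``,
    as a DataFrame with columns ``survival``, ``ci_lower``, ``ci_upper``
    indexed by time.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events, label=label)
    ci = kmf.confidence_interval_
    return pd.DataFrame(
        {
            "survival": kmf.survival_function_[label],
            "ci_lower": ci.iloc[:, 0],
            "ci_upper": ci.iloc[:, 1],
        }
    )


def tertile_km(
    table: pd.DataFrame,
    variable: str,
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
    horizon: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier event-free survival by tertiles of a covariate.

    Cut points are the empirical 33.3/66.7 percentiles; ties go to the lower
    tertile.  Each group gets a product-limit curve with Greenwood-based 95%
    confidence bands, returned as a DataFrame with columns ``survival``,
    ``ci_lower``, ``ci_upper`` indexed by time.
    """
    values = table[variable].dropna()
    if values.nunique() < 3:
        raise ValueError(f"{variable!r} has fewer than 3 distinct values; cannot form tertiles")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])

    labels = pd.Series("high", index=table.index, dtype=object)
    labels[table[variable] <= q2] = "middle"
    labels[table[variable] <= q1] = "low"
    labels[table[variable].isna()] = None

    curves: dict[str, pd.DataFrame] = {}
    for group in ("low", "middle", "high"):
        mask = labels == group
        sub = table.loc[mask, [duration_col, event_col]].dropna()
        if len(sub) == 0:
            continue
        frame = km_curve(
            sub[duration_col].to_numpy(), sub[event_col].to_numpy(), label=group
        )
        frame["n_at_risk_start"] = len(sub)
        if horizon is not None:
            frame = frame[frame.index <= horizon]
        curves[group] = frame
    return curves
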