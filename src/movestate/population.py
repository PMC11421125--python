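"""Two-step population inference on individual selection coefficients.

Each habitat coefficient set (one term x one behavioral state, e.g.
beta_dist-to-forest-x-night in the restricted state) becomes the response of
four candidate inverse-variance-weighted regressions — null (y ~ 1), age,
calf fate, and the full calf fate x age interaction — weighted by 1/SE^2.
Candidates are ranked by AICc; models within 2 AICc of the best are averaged
(conditional averaging with renormalized Akaike weights). Movement is
summarized by the selection-updated expected step length
l_mean = (k + beta_ln(l)) / (1/theta - beta_l) and the per-slice difference
l_mean - observed mean step length, modeled with the same four candidates as
ordinary (unweighted) linear models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .issf import HABITAT_TERMS, ISSFFit

__all__ = [
    "estimated_mean_steplen",
    "aicc",
    "CandidateModelSet",
    "fit_ivw_set",
    "run_second_stage",
    "movement_deltas",
    "movement_models",
    "summarize_predictor_inclusion",
    "second_stage_summary",
]

logger = logging.getLogger(__name__)

NOT_INCLUDED = "n.i."

# candidate models: name -> predictor columns beyond the intercept
CANDIDATE_MODELS = {
    "null": [],
    "age": ["age"],
    "calf_fate": ["no_loss"],
    "full": ["no_loss", "age", "no_loss:age"],
}


def estimated_mean_steplen(k: float, theta: float, beta_l: float, beta_lnl: float) -> float:
    """Mean of the selection-updated gamma, (k + beta_ln(l)) / (1/theta - beta_l).

    The movement coefficients of the conditional logistic regression update
    the tentative gamma's shape (via beta_ln(l)) and rate (via beta_l); the
    updated mean is shape/rate. Returns NaN (flagged undefined) when the
    updated rate 1/theta - beta_l or shape k + beta_ln(l) is not positive.
    """
    rate = 1.0 / theta - beta_l
    shape = k + beta_lnl
    if rate <= 0 or shape <= 0:
        logger.warning(
            "estimated_mean_steplen undefined (shape=%.4g, rate=%.4g)", shape, rate
        )
        return float("nan")
    return shape / rate


def aicc(loglik: float, p: int, n: int) -> float:
    """AICc = -2 loglik + 2p + 2p(p+1)/(n - p - 1).

    p counts all estimated parameters (regression coefficients plus one for
    the residual variance in Gaussian models).
    """
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} <= p+1={p + 1}")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def _weighted_gaussian_loglik(resid: np.ndarray, w: np.ndarray) -> float:
    """Gaussian log-likelihood with weights treated as known precisions.

    y_i ~ N(mu_i, sigma^2 / w_i) with sigma^2 profiled at its MLE.
    """
    n = resid.size
    sigma2 = float(np.sum(w * resid**2) / n)
    return float(-0.5 * n * np.log(2 * np.pi * sigma2) + 0.5 * np.sum(np.log(w)) - 0.5 * n)


def average_retained(models: dict, retained: list[str]) -> dict:
    """Conditional (natural) model averaging over the retained set.

    Estimates are averaged with renormalized Akaike weights over the retained
    models that contain each predictor; averaged SEs use the unconditional-
    variance formula sum_m w_m sqrt(se_m^2 + (b_m - b_bar)^2). Predictors in
    no retained model map to "n.i.". With a single retained model this is the
    identity on that model's coefficients and SEs.
    """
    ret_w = {name: models[name]["weight"] for name in retained}
    averaged: dict = {}
    for pred in ["Intercept", "age", "no_loss", "no_loss:age"]:
        containing = [name for name in retained if pred in models[name]["coef"]]
        if not containing:
            averaged[pred] = NOT_INCLUDED
            continue
        wsum = sum(ret_w[name] for name in containing)
        est = sum(ret_w[name] / wsum * models[name]["coef"][pred] for name in containing)
        se = sum(
            ret_w[name]
            / wsum
            * np.sqrt(
                models[name]["se"][pred] ** 2 + (models[name]["coef"][pred] - est) ** 2
            )
            for name in containing
        )
        averaged[pred] = (float(est), float(se))
    return averaged


@dataclass
class CandidateModelSet:
    """The four candidate models for one coefficient set, ranked and averaged."""

    term: str
    state: str
    n_records: int
    models: dict = field(default_factory=dict)  # name -> per-model summary
    retained: list[str] = field(default_factory=list)
    averaged: dict = field(default_factory=dict)  # predictor -> (est, se) | "n.i."
    includes_calf_fate: bool = False
    includes_age: bool = False
    note: str = ""


def _design(df: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    cols = {
        "age": lambda: df["age"].to_numpy(dtype=float),
        "no_loss": lambda: (df["calf_fate"] == "no loss").to_numpy(dtype=float),
        "no_loss:age": lambda: (df["calf_fate"] == "no loss").to_numpy(dtype=float)
        * df["age"].to_numpy(dtype=float),
    }
    for pred in predictors:
        X[pred] = cols[pred]()
    return X


def fit_ivw_set(
    records: pd.DataFrame,
    term: str = "",
    state: str = "",
    weighted: bool = True,
    min_records: int = 8,
) -> CandidateModelSet:
    """Fit, rank, and average the four candidate models for one coefficient set.

    `records` needs columns beta, se (ignored when ``weighted=False``), age,
    calf_fate. Models are weighted least squares with weights 1/se^2
    (ordinary least squares for movement responses), ranked by AICc with the
    weighted-Gaussian likelihood, and models with delta-AICc < 2 (strict) are
    averaged with renormalized Akaike weights. Averaged SEs use the
    unconditional-variance formula. Predictors absent from every retained
    model are reported as "n.i.".
    """
    records = records.dropna(subset=["beta", "age", "calf_fate"]).copy()
    n = len(records)
    if n < min_records:
        raise ValueError(f"too few records ({n} < {min_records}) for {term}/{state}")
    y = records["beta"].to_numpy(dtype=float)
    w = 1.0 / records["se"].to_numpy(dtype=float) ** 2 if weighted else np.ones(n)
    if not np.all(np.isfinite(w) & (w > 0)):
        raise ValueError(f"non-finite weights for {term}/{state}")

    out = CandidateModelSet(term=term, state=state, n_records=n)
    fate_levels = records["calf_fate"].nunique()
    candidates = dict(CANDIDATE_MODELS)
    if fate_levels < 2:
        candidates = {k: v for k, v in candidates.items() if "no_loss" not in v}
        out.note = "single calf-fate level: calf-fate models skipped"
        logger.warning("fit_ivw_set %s/%s: %s", term, state, out.note)

    for name, preds in candidates.items():
        X = _design(records, preds)
        p = X.shape[1] + 1  # + residual variance
        if n <= p + 1:
            continue
        res = sm.WLS(y, X, weights=w).fit()
        ll = _weighted_gaussian_loglik(y - res.fittedvalues, w)
        out.models[name] = {
            "coef": dict(zip(X.columns, res.params)),
            "se": dict(zip(X.columns, res.bse)),
            "loglik": ll,
            "p": p,
            "aicc": aicc(ll, p, n),
        }
    if not out.models:
        raise ValueError(f"no estimable candidate model for {term}/{state}")

    best = min(m["aicc"] for m in out.models.values())
    raw_w = {}
    for name, m in out.models.items():
        m["daicc"] = m["aicc"] - best
        raw_w[name] = np.exp(-0.5 * m["daicc"])
    total = sum(raw_w.values())
    for name, m in out.models.items():
        m["weight"] = raw_w[name] / total

    out.retained = [name for name, m in out.models.items() if m["daicc"] < 2.0]
    out.averaged = average_retained(out.models, out.retained)

    # A predictor "improves model performance" when the best candidate
    # containing it is retained (delta-AICc < 2) and outranks the best
    # candidate without it. Retained-set membership alone is too liberal: a
    # useless extra parameter costs only ~2 AICc, so it stays within the
    # retained band about half the time under the null.
    def improves(pred_col: str) -> bool:
        with_p = [m["aicc"] for n_, m in out.models.items() if pred_col in m["coef"]]
        without = [m["aicc"] for n_, m in out.models.items() if pred_col not in m["coef"]]
        if not with_p or not without:
            return False
        return (min(with_p) - best) < 2.0 and min(with_p) < min(without)

    out.includes_calf_fate = improves("no_loss") or improves("no_loss:age")
    out.includes_age = improves("age") or improves("no_loss:age")
    return out


def run_second_stage(records: pd.DataFrame, min_records: int = 8) -> list[CandidateModelSet]:
    """One candidate-model set per habitat coefficient set per state (24 total).

    The habitat coefficient sets are the 3 covariates x {main, x night,
    x high pressure, x low pressure}; states are restricted and exploratory.
    Term slices too small to model are skipped and counted in the log.
    """
    sets: list[CandidateModelSet] = []
    n_skipped = 0
    for state in ("restricted", "exploratory"):
        for term in HABITAT_TERMS:
            sl = records[(records["term"] == term) & (records["state"] == state)]
            try:
                sets.append(fit_ivw_set(sl, term=term, state=state, min_records=min_records))
            except ValueError as exc:
                n_skipped += 1
                logger.warning("run_second_stage: %s/%s skipped (%s)", term, state, exc)
    if n_skipped:
        logger.warning("run_second_stage: %d coefficient sets skipped", n_skipped)
    return sets


def second_stage_summary(sets: list[CandidateModelSet]) -> pd.DataFrame:
    """Tidy summary: one row per (term, state, predictor) with averaged values."""
    rows = []
    pretty = {
        "Intercept": "Intercept",
        "age": "Age",
        "no_loss": "Calf fate (no loss)",
        "no_loss:age": "Calf fate (no loss) x age",
    }
    for cms in sets:
        for pred, label in pretty.items():
            v = cms.averaged.get(pred, NOT_INCLUDED)
            if v == NOT_INCLUDED:
                est, se = NOT_INCLUDED, NOT_INCLUDED
            else:
                est, se = f"{v[0]:.3f}", f"{v[1]:.3f}"
            rows.append(
                {
                    "term": cms.term,
                    "state": cms.state,
                    "predictor": label,
                    "estimate": est,
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def movement_deltas(fits: list[ISSFFit], cohort: pd.DataFrame) -> pd.DataFrame:
    """Estimated-minus-observed mean step length per individual-year x state.

    l_mean updates the slice's tentative gamma with the fitted movement
    coefficients; slices where the update is undefined (rate or shape not
    positive) are excluded with a log entry.
    """
    cohort_idx = cohort.set_index("iy_id") if "iy_id" in cohort.columns else None
    rows = []
    n_undefined = 0
    for fit in fits:
        if not fit.converged:
            continue
        try:
            beta_l = fit.coef("l")
            beta_lnl = fit.coef("log_l")
        except ValueError:
            continue
        l_mean = estimated_mean_steplen(
            fit.tentative.k, fit.tentative.theta, beta_l, beta_lnl
        )
        if not np.isfinite(l_mean):
            n_undefined += 1
            continue
        row = {
            "iy_id": fit.iy_id,
            "state": fit.state,
            "l_mean": l_mean,
            "observed_mean": fit.observed_mean_steplen,
            "delta": l_mean - fit.observed_mean_steplen,
        }
        if cohort_idx is not None and fit.iy_id in cohort_idx.index:
            row["age"] = cohort_idx.loc[fit.iy_id, "age"]
            row["calf_fate"] = cohort_idx.loc[fit.iy_id, "calf_fate_prev"]
        rows.append(row)
    if n_undefined:
        logger.warning("movement_deltas: %d slices with undefined l_mean", n_undefined)
    return pd.DataFrame(rows)


def movement_models(deltas: pd.DataFrame, min_records: int = 8) -> dict[str, CandidateModelSet]:
    """Per-state candidate models for the movement response (unweighted OLS).

    The response is delta = l_mean - observed mean step length. Selection is
    by lowest AICc; the full retained (delta-AICc < 2) set is kept on the
    returned CandidateModelSet for inspection.
    """
    out = {}
    for state, g in deltas.groupby("state"):
        g = g.rename(columns={"delta": "beta"})
        out[state] = fit_ivw_set(
            g, term="movement_delta", state=state, weighted=False, min_records=min_records
        )
    return out


def summarize_predictor_inclusion(sets: list[CandidateModelSet]) -> dict:
    """Percentage of coefficient sets whose retained models include each predictor."""
    def pct(items, flag):
        if not items:
            return float("nan")
        return 100.0 * sum(1 for s in items if flag(s)) / len(items)

    result = {
        "n_sets": len(sets),
        "calf_fate_pct": pct(sets, lambda s: s.includes_calf_fate),
        "age_pct": pct(sets, lambda s: s.includes_age),
    }
    for state in ("restricted", "exploratory"):
        sub = [s for s in sets if s.state == state]
        result[f"calf_fate_pct_{state}"] = pct(sub, lambda s: s.includes_calf_fate)
        result[f"age_pct_{state}"] = pct(sub, lambda s: s.includes_age)
    return result
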