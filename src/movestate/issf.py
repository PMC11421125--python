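"""Behavioral-state-specific integrated step-selection functions.

For each individual-year and behavioral state, observed step lengths (+1 m,
so zero-length steps do not break the gamma likelihood) and turning angles
are fitted with tentative gamma / von Mises distributions; 25 available
steps per used step are sampled from them; and a conditional logistic
regression compares the used endpoint against the available ones. Habitat
covariates enter as main effects and in one-way interactions with time of
day and hunting pressure; the movement terms l, ln(l + 1), and cos(phi)
are estimated jointly so the tentative distributions can be updated post
hoc (the iSSA construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e
from scipy.stats import gamma as gamma_dist

from .hmm import wrap_angle
from .raster import Raster
from .tracks_io import COVARIATE_NAMES, zscore_by_individual

__all__ = [
    "TentativeDistributions",
    "ISSFFit",
    "fit_tentative",
    "generate_available",
    "build_strata",
    "build_design",
    "fit_clogit",
    "run_issf",
    "DESIGN_TERMS",
    "HABITAT_TERMS",
]

logger = logging.getLogger(__name__)

STATE_NAMES = ("restricted", "exploratory")

HABITAT_TERMS = tuple(
    f"{cov}{suffix}"
    for cov in COVARIATE_NAMES
    for suffix in ("", ":night", ":high", ":low")
)
MOVEMENT_TERMS = ("l", "log_l", "cos_phi")
DESIGN_TERMS = (
    COVARIATE_NAMES
    + tuple(f"{c}:night" for c in COVARIATE_NAMES)
    + tuple(f"{c}:high" for c in COVARIATE_NAMES)
    + tuple(f"{c}:low" for c in COVARIATE_NAMES)
    + MOVEMENT_TERMS
)


@dataclass
class TentativeDistributions:
    """Tentative movement distributions of one individual-year x state."""

    k: float  # gamma shape
    theta: float  # gamma scale, m
    vm_conc: float  # von Mises concentration, mean fixed at 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0 or self.vm_conc < 0:
            raise ValueError("invalid tentative distribution parameters")

    @property
    def mean(self) -> float:
        return self.k * self.theta


@dataclass
class ISSFFit:
    iy_id: str
    state: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_strata: int
    tentative: TentativeDistributions
    observed_mean_steplen: float
    dropped_terms: list[str]

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])


def _solve_vm_conc(r: float) -> float:
    """Concentration whose mean resultant length A1(k) = I1/I0 equals r."""
    if r <= 0:
        return 0.0
    r = min(r, 1 - 1e-10)
    return brentq(lambda k: i1e(k) / i0e(k) - r, 1e-10, 1e8, xtol=1e-10)


def fit_tentative(l, phi, min_steps: int = 30) -> TentativeDistributions:
    """Fit the tentative gamma (to l + 1 m, MLE) and von Mises (mean 0).

    The +1 m offset keeps zero-length steps inside the gamma support. The
    von Mises concentration is the MLE with the mean fixed at 0, i.e. solves
    A1(kappa) = mean(cos(phi)) over the defined turning angles.
    """
    l = np.asarray(l, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if l.size < min_steps:
        raise ValueError(f"too few steps ({l.size} < {min_steps}) for tentative fit")
    if np.std(l) == 0:
        raise ValueError("degenerate (constant) step lengths; unit excluded")
    k, _, theta = gamma_dist.fit(l + 1.0, floc=0)
    if k > 1e4:
        raise ValueError("near-degenerate gamma (shape > 1e4); unit excluded")
    phi_def = phi[np.isfinite(phi)]
    r = float(np.mean(np.cos(phi_def))) if phi_def.size else 0.0
    return TentativeDistributions(k=float(k), theta=float(theta), vm_conc=_solve_vm_conc(r))


def generate_available(
    start_xy,
    prev_bearing: float,
    tentative: TentativeDistributions,
    rasters: dict[str, Raster],
    rng: np.random.Generator,
    n: int = 25,
    max_retries: int = 20,
):
    """Sample n available steps from one start point.

    Lengths are gamma(k, theta) draws minus the 1 m offset (floored at 0);
    headings are von Mises(0, vm_conc) turns added to the previous bearing.
    Endpoints falling outside the raster extent are redrawn up to
    ``max_retries`` times; if any remain outside, returns None (caller drops
    the stratum).
    """
    ref = next(iter(rasters.values()))
    x0, y0 = start_xy
    l = np.empty(n)
    phi = np.empty(n)
    ex = np.full(n, np.nan)
    ey = np.full(n, np.nan)
    todo = np.ones(n, dtype=bool)
    for _ in range(max_retries):
        m = int(todo.sum())
        if m == 0:
            break
        ld = np.maximum(rng.gamma(tentative.k, tentative.theta, size=m) - 1.0, 0.0)
        pd_ = rng.vonmises(0.0, max(tentative.vm_conc, 1e-12), size=m)
        cx = x0 + ld * np.cos(prev_bearing + pd_)
        cy = y0 + ld * np.sin(prev_bearing + pd_)
        ok = ref.contains(cx, cy)
        idx = np.flatnonzero(todo)[ok]
        l[idx] = ld[ok]
        phi[idx] = pd_[ok]
        ex[idx] = cx[ok]
        ey[idx] = cy[ok]
        todo[np.flatnonzero(todo)[ok]] = False
    if todo.any():
        return None
    return l, wrap_angle(phi), ex, ey


def build_strata(
    steps: pd.DataFrame,
    tentative: TentativeDistributions,
    rasters: dict[str, Raster],
    rng: np.random.Generator,
    n_available: int = 25,
) -> pd.DataFrame:
    """Matched used/available table for one individual-year x state slice.

    Strata are formed from used steps with a defined turning angle (the
    previous bearing is needed to orient available steps); others are
    dropped with a log entry. Covariates at all 26 endpoints are extracted
    raw (z-scoring happens afterwards over used + available jointly).
    """
    usable = steps[np.isfinite(steps["phi"])]
    n_dropped = len(steps) - len(usable)
    if n_dropped:
        logger.info("build_strata: %d steps without previous bearing dropped", n_dropped)
    rows = []
    for sid, (_, step) in enumerate(usable.iterrows()):
        prev_bearing = step["bearing"] - step["phi"]
        avail = generate_available(
            (step["start_x"], step["start_y"]),
            prev_bearing,
            tentative,
            rasters,
            rng,
            n=n_available,
        )
        if avail is None:
            logger.warning("build_strata: stratum %d dropped (off-raster endpoints)", sid)
            continue
        l_a, phi_a, ex_a, ey_a = avail
        base = {
            "iy_id": step["iy_id"],
            "stratum_id": sid,
            "t_end": step["t_end"],
            "time_of_day": step["time_of_day"],
            "hunting_pressure": step["hunting_pressure"],
        }
        rows.append(
            dict(
                base,
                case=1,
                l=step["l"],
                phi=step["phi"],
                end_x=step["end_x"],
                end_y=step["end_y"],
            )
        )
        for j in range(n_available):
            rows.append(
                dict(
                    base,
                    case=0,
                    l=l_a[j],
                    phi=phi_a[j],
                    end_x=ex_a[j],
                    end_y=ey_a[j],
                )
            )
    strata = pd.DataFrame(rows)
    if strata.empty:
        return strata
    ref_x = strata["end_x"].to_numpy()
    ref_y = strata["end_y"].to_numpy()
    for name, raster in rasters.items():
        strata[name] = raster.value_at(ref_x, ref_y)
    return strata


def build_design(strata: pd.DataFrame) -> pd.DataFrame:
    """Design matrix of the conditional logistic regression.

    Habitat covariates (already z-scored) enter as main effects and in
    one-way interactions with night and with the high/low hunting-pressure
    levels ('none' and 'day' are the reference levels; main factor effects
    are absorbed by the stratum). Movement terms l, ln(l + 1), cos(phi) are
    never standardized.
    """
    missing = [c for c in COVARIATE_NAMES if c not in strata.columns]
    if missing:
        raise ValueError(f"strata missing covariate(s): {', '.join(missing)}")
    night = (strata["time_of_day"] == "night").to_numpy(dtype=float)
    high = (strata["hunting_pressure"] == "high").to_numpy(dtype=float)
    low = (strata["hunting_pressure"] == "low").to_numpy(dtype=float)
    X = pd.DataFrame(index=strata.index)
    for cov in COVARIATE_NAMES:
        X[cov] = strata[cov].to_numpy(dtype=float)
    for cov in COVARIATE_NAMES:
        X[f"{cov}:night"] = X[cov] * night
    for cov in COVARIATE_NAMES:
        X[f"{cov}:high"] = X[cov] * high
    for cov in COVARIATE_NAMES:
        X[f"{cov}:low"] = X[cov] * low
    X["l"] = strata["l"].to_numpy(dtype=float)
    X["log_l"] = np.log(strata["l"].to_numpy(dtype=float) + 1.0)
    X["cos_phi"] = np.cos(strata["phi"].to_numpy(dtype=float))
    return X


def clogit_loglik(beta, X, case, starts) -> float:
    """Conditional-logistic log-likelihood sum_s [eta_used - log sum_j exp]."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    sizes = np.diff(np.append(starts, len(eta)))
    mx = np.maximum.reduceat(eta, starts)
    lse = np.log(np.add.reduceat(np.exp(eta - np.repeat(mx, sizes)), starts)) + mx
    return float(eta[np.asarray(case) == 1].sum() - lse.sum())


def fit_clogit(
    X: pd.DataFrame,
    case: np.ndarray,
    stratum_ids: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    divergence_bound: float = 15.0,
):
    """Newton-Raphson conditional logistic regression.

    Maximizes the stratified multinomial likelihood with step-halving;
    standard errors come from the inverse observed information. All-zero
    columns are dropped (inestimable within the slice) and reported.
    Coefficients exceeding ``divergence_bound`` in absolute value mark
    separation; the fit is flagged not converged.

    Returns (terms, beta, se, loglik, converged, dropped_terms).
    """
    case = np.asarray(case)
    stratum_ids = np.asarray(stratum_ids)
    order = np.argsort(stratum_ids, kind="mergesort")
    Xs = X.to_numpy(dtype=float)[order]
    cs = case[order]
    sids = stratum_ids[order]
    starts = np.flatnonzero(np.r_[True, sids[1:] != sids[:-1]])
    sizes = np.diff(np.append(starts, len(sids)))

    keep = [i for i in range(Xs.shape[1]) if np.any(Xs[:, i] != 0)]
    dropped = [c for i, c in enumerate(X.columns) if i not in keep]
    terms = [X.columns[i] for i in keep]
    Xk = Xs[:, keep]
    p = Xk.shape[1]
    rep = np.repeat(np.arange(len(starts)), sizes)

    def loglik_probs(beta):
        eta = Xk @ beta
        mx = np.maximum.reduceat(eta, starts)
        e = np.exp(eta - mx[rep])
        denom = np.add.reduceat(e, starts)
        ll = float(eta[cs == 1].sum() - (np.log(denom) + mx).sum())
        return ll, e / denom[rep]

    beta = np.zeros(p)
    ll, probs = loglik_probs(beta)
    converged = False
    for _ in range(max_iter):
        resid = cs - probs
        grad = Xk.T @ resid
        XtWX = Xk.T @ (Xk * probs[:, None])
        M = np.empty((len(starts), p))
        wX = Xk * probs[:, None]
        for j in range(p):
            M[:, j] = np.add.reduceat(wX[:, j], starts)
        info = XtWX - M.T @ M
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            logger.warning("fit_clogit: singular information matrix")
            break
        # step-halving line search
        t = 1.0
        for _ in range(30):
            ll_new, probs_new = loglik_probs(beta + t * step)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        improved = ll_new - ll
        beta = beta + t * step
        ll, probs = ll_new, probs_new
        if np.max(np.abs(beta)) > divergence_bound:
            logger.warning("fit_clogit: divergence (|beta| > %g)", divergence_bound)
            break
        if abs(improved) <= tol * (abs(ll) + 1.0):
            converged = True
            break
    if np.max(np.abs(beta), initial=0.0) > divergence_bound:
        converged = False

    se = np.full(p, np.nan)
    if p:
        resid = cs - probs
        XtWX = Xk.T @ (Xk * probs[:, None])
        wX = Xk * probs[:, None]
        M = np.empty((len(starts), p))
        for j in range(p):
            M[:, j] = np.add.reduceat(wX[:, j], starts)
        info = XtWX - M.T @ M
        try:
            with np.errstate(invalid="ignore"):
                se = np.sqrt(np.diag(np.linalg.inv(info)))
        except np.linalg.LinAlgError:
            converged = False
    return terms, beta, se, ll, converged, dropped


def run_issf(
    steps: pd.DataFrame,
    decoded_states: np.ndarray,
    rasters: dict[str, Raster],
    cohort: pd.DataFrame,
    seed: int,
    n_available: int = 25,
    min_strata: int = 30,
    keep_strata: bool = False,
) -> tuple[list[ISSFFit], pd.DataFrame, dict]:
    """Fit one conditional logistic regression per individual-year x state.

    `steps` must carry the temporal factors (time_of_day, hunting_pressure)
    and raw endpoint covariates are extracted from `rasters` during stratum
    construction; z-scoring is applied per individual-year over used and
    available endpoints jointly. Returns the fits, a tidy table of
    per-term coefficient records annotated with the female's age and
    previous-season calf fate from `cohort`, and an info dict of skip
    counts (plus the full z-scored strata table under "strata" when
    ``keep_strata`` is set).
    """
    steps = steps.copy()
    steps["state"] = np.asarray(
        [STATE_NAMES[s] for s in np.asarray(decoded_states, dtype=int)]
    )
    ss = np.random.SeedSequence(seed)
    skipped = {"too_few_steps": 0, "too_few_strata": 0, "not_converged": 0, "degenerate": 0}

    slices = []
    all_strata = []
    for (iy, state), g in steps.groupby(["iy_id", "state"], sort=True):
        child = np.random.default_rng(ss.spawn(1)[0])
        try:
            tentative = fit_tentative(g["l"].to_numpy(), g["phi"].to_numpy())
        except ValueError as exc:
            logger.info("run_issf: %s/%s skipped (%s)", iy, state, exc)
            if "degenerate" in str(exc):
                skipped["degenerate"] += 1
            else:
                skipped["too_few_steps"] += 1
            continue
        strata = build_strata(g, tentative, rasters, child, n_available=n_available)
        if strata.empty or strata["stratum_id"].nunique() < min_strata:
            skipped["too_few_strata"] += 1
            continue
        strata["state"] = state
        observed_mean = float(g.loc[np.isfinite(g["phi"]), "l"].mean())
        slices.append((iy, state, tentative, observed_mean))
        all_strata.append(strata)

    if not all_strata:
        return [], pd.DataFrame(), skipped
    strata_all = pd.concat(all_strata, ignore_index=True)
    strata_all, _ = zscore_by_individual(strata_all, COVARIATE_NAMES, group="iy_id")
    if keep_strata:
        skipped = dict(skipped, strata=strata_all)

    cohort_idx = cohort.set_index("iy_id") if "iy_id" in cohort.columns else None
    fits: list[ISSFFit] = []
    records = []
    for iy, state, tentative, observed_mean in slices:
        sl = strata_all[(strata_all["iy_id"] == iy) & (strata_all["state"] == state)]
        X = build_design(sl)
        terms, beta, se, ll, conv, droppedcols = fit_clogit(
            X, sl["case"].to_numpy(), sl["stratum_id"].to_numpy()
        )
        fit = ISSFFit(
            iy_id=iy,
            state=state,
            terms=list(terms),
            beta=beta,
            se=se,
            loglik=ll,
            converged=conv,
            n_strata=int(sl["stratum_id"].nunique()),
            tentative=tentative,
            observed_mean_steplen=observed_mean,
            dropped_terms=droppedcols,
        )
        fits.append(fit)
        if not conv:
            skipped["not_converged"] += 1
            continue
        age = calf_fate = None
        if cohort_idx is not None and iy in cohort_idx.index:
            age = cohort_idx.loc[iy, "age"]
            calf_fate = cohort_idx.loc[iy, "calf_fate_prev"]
        for t, b, s in zip(terms, beta, se):
            if not (np.isfinite(b) and np.isfinite(s) and s > 0):
                continue  # inestimable term: no valid inverse-variance weight
            records.append(
                {
                    "iy_id": iy,
                    "state": state,
                    "term": t,
                    "beta": float(b),
                    "se": float(s),
                    "age": age,
                    "calf_fate": calf_fate,
                }
            )
    return fits, pd.DataFrame(records), skipped
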