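"""Cohort-level analyses: calf fate vs age, and in-season calf survival.

The Mann-Whitney U test checks that previous-season calf fate is not
confounded with female age (so both can enter the second-stage models).
In-season calf survival is a binomial GLM with age, litter size before the
season (1 or 2, numeric), and their interaction: the interaction captures
whether older females are better at bringing twins through the season.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

__all__ = ["mann_whitney_u", "fit_survival_glm"]

# exact null enumeration is feasible below this many group assignments
_EXACT_MAX_COMBINATIONS = 200_000


def mann_whitney_u(ages_loss, ages_no_loss) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for the loss group.

    Uses the exact null distribution when both samples are tie-free and the
    number of group assignments C(n1+n2, n1) is small enough to enumerate;
    otherwise the normal approximation with midrank tie correction and
    continuity correction.
    """
    x = np.asarray(ages_loss, dtype=float)
    y = np.asarray(ages_no_loss, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = not has_ties and comb(x.size + y.size, x.size) <= _EXACT_MAX_COMBINATIONS
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def fit_survival_glm(records: pd.DataFrame, min_records: int = 20) -> pd.DataFrame:
    """Binomial GLM: survived_all ~ age * n_calves (logit link, IRLS).

    `records` needs columns age, n_calves (in {1, 2}), survived_all (0/1).
    Returns a coefficient table with Wald SEs and two-sided p-values. Raises
    on too few records, a single outcome level, or complete separation.
    """
    if len(records) < min_records:
        raise ValueError(f"too few records ({len(records)} < {min_records})")
    y = records["survived_all"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("complete separation: only one outcome level present")
    age = records["age"].to_numpy(dtype=float)
    n_calves = records["n_calves"].to_numpy(dtype=float)
    if not np.isin(n_calves, [1.0, 2.0]).all():
        raise ValueError("n_calves must be 1 or 2")
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(records)),
            "age": age,
            "n_calves": n_calves,
            "age_x_calves": age * n_calves,
        }
    )
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    mu = res.fittedvalues
    if np.max(np.abs(res.params)) > 50 or np.all(np.abs(mu - y) < 1e-6):
        raise ValueError("complete separation detected in the survival GLM")
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )
    table.index.name = "term"
    return table
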