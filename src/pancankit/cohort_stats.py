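"""Statistical utilities and cohort summarisation.

Includes the exact tests used for clustered-event/driver association
(Fisher's exact test and Boschloo's uniformly-more-powerful unconditional
variant), the rank-sum comparison of driver classes, linear
burden-versus-age regression with a likelihood-ratio test, a grouped
enrichment scan with Benjamini-Hochberg correction, and demographic
cohort summaries with the half-away-from-zero percentage rounding used
for printed ratios.

Boschloo's test is implemented here directly because the two-binomial
maximisation over the nuisance success probability with Fisher-p
ordering guarantees p_boschloo <= p_fisher on every table; generic
library variants of the two-sided test do not preserve that dominance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .drivers import round_half_away

__all__ = [
    "CohortSummary",
    "fisher_exact",
    "fisher_boschloo",
    "mann_whitney",
    "burden_age_regression",
    "summarize_cohort",
    "enrichment_scan",
]


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValueError("contingency table is all zeros")
    return t.astype(int)


def fisher_exact(table) -> tuple[float, float]:
    """Odds ratio and two-sided p (point-probability rule)."""
    t = _validate_table(table)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


@lru_cache(maxsize=256)
def _fisher_p_grid(n1: int, n2: int) -> np.ndarray:
    """Two-sided Fisher p for every table with row sums (n1, n2).

    Entry [x1, x2] is the conditional hypergeometric two-sided p-value
    (point-probability rule) for the table [[x1, n1-x1], [x2, n2-x2]].
    """
    out = np.ones((n1 + 1, n2 + 1))
    N = n1 + n2
    for k in range(N + 1):
        lo, hi = max(0, k - n2), min(n1, k)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, N, n1, k)
        for x1, p_x1 in zip(support, pmf):
            out[x1, k - x1] = pmf[pmf <= p_x1 * (1 + 1e-9)].sum()
    return np.minimum(out, 1.0)


def fisher_boschloo(table, grid_size: int = 200) -> float:
    """Boschloo's unconditional exact p-value with Fisher-p ordering.

    Row totals are treated as two independent binomials with common
    success probability pi under the null; the p-value is the maximum
    over a ``grid_size`` grid of pi in (0, 1) of the probability of a
    table with Fisher p <= the observed one. Always <= the Fisher p.
    """
    t = _validate_table(table)
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    n1, n2 = int(t[0].sum()), int(t[1].sum())
    if n1 == 0 or n2 == 0:
        return 1.0
    p_grid = _fisher_p_grid(n1, n2)
    p_obs = p_grid[t[0, 0], t[1, 0]]
    mask = p_grid <= p_obs * (1 + 1e-9)
    pis = np.linspace(0, 1, grid_size + 2)[1:-1]
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    pmf1 = stats.binom.pmf(x1[None, :], n1, pis[:, None])  # (grid, n1+1)
    pmf2 = stats.binom.pmf(x2[None, :], n2, pis[:, None])
    probs = np.einsum("gi,gj,ij->g", pmf1, pmf2, mask.astype(float))
    return float(min(probs.max(), p_obs))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-sum U statistic and two-sided p.

    Exact enumeration for samples of at most 8 without ties; otherwise
    the normal approximation with tie correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_lrt: float
    slope_ci: tuple
    n: int


def burden_age_regression(burdens: Sequence[float], ages: Sequence[float],
                          ci_level: float = 0.95) -> RegressionResult:
    """Least-squares burden-per-year slope with a likelihood-ratio test.

    The LRT compares the linear model against intercept-only under
    Gaussian errors: LR = n log(RSS0 / RSS1) ~ chi-square(1).
    """
    y = np.asarray(burdens, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(y) != len(a) or len(y) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(a) == 0:
        raise ValueError("ages are constant; slope is unidentifiable")
    n = len(y)
    X = np.column_stack([np.ones(n), a])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss1 <= 0:
        p = 0.0
    else:
        lr = n * math.log(rss0 / rss1)
        p = float(stats.chi2.sf(lr, df=1))
    # classical t-interval on the slope
    dof = n - 2
    sxx = float(((a - a.mean()) ** 2).sum())
    se = math.sqrt(rss1 / dof / sxx) if dof > 0 and rss1 > 0 else 0.0
    tq = stats.t.ppf(1 - (1 - ci_level) / 2, dof) if dof > 0 else float("inf")
    ci = (beta[1] - tq * se, beta[1] + tq * se)
    return RegressionResult(slope=float(beta[1]), intercept=float(beta[0]),
                            p_lrt=p, slope_ci=ci, n=n)


@dataclass
class CohortSummary:
    n_donors: int
    sex_counts: dict
    sex_percentages: dict
    age_mean: float
    age_range: tuple
    type_counts: dict


def summarize_cohort(metadata: pd.DataFrame) -> CohortSummary:
    """Demographic summary with printed-ratio rounding conventions.

    ``metadata`` needs one row per donor with columns ``sex``, ``age``
    and optionally ``tumour_type``.
    """
    if metadata.empty:
        raise ValueError("empty cohort")
    sex_counts = metadata["sex"].value_counts().to_dict()
    n = len(metadata)
    sex_pct = {k: round_half_away(100 * v / n) for k, v in sex_counts.items()}
    ages = metadata["age"].astype(float)
    types = (metadata["tumour_type"].value_counts().to_dict()
             if "tumour_type" in metadata else {})
    return CohortSummary(
        n_donors=n, sex_counts=sex_counts, sex_percentages=sex_pct,
        age_mean=float(ages.mean()),
        age_range=(float(ages.min()), float(ages.max())),
        type_counts=types)


def enrichment_scan(trait: Sequence[bool], groups: Sequence,
                    grid_size: int = 200) -> pd.DataFrame:
    """Per-group enrichment of a binary trait, Boschloo p + BH q.

    Each group is tested against the rest of the cohort in a 2x2 table
    (carriers/non-carriers inside vs outside the group).
    """
    trait = np.asarray(trait, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for g in labels:
        inside = groups == g
        if inside.sum() == 0:
            warnings.warn(f"group {g!r} has no members; skipped")
            continue
        a = int((trait & inside).sum())
        b = int((~trait & inside).sum())
        c = int((trait & ~inside).sum())
        d = int((~trait & ~inside).sum())
        if a + b + c + d == 0:
            continue
        odds, _ = fisher_exact([[a, b], [c, d]])
        p = fisher_boschloo([[a, b], [c, d]], grid_size=grid_size)
        rows.append({"group": g, "carriers": a, "non_carriers": b,
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no testable groups")
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
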