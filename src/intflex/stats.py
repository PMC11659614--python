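"""Rest–task statistics.

Percent change of a measure from rest to a task state, the correlation of
rest variability with that change, rank-based two-group comparisons with
effect sizes, MAD-based outlier removal, Holm multiple-comparison
correction, and the Clogg test comparing a predictor's coefficient between
two nested regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectResult",
    "CloggResult",
    "percent_change",
    "rest_task_summary",
    "variability_change_correlation",
    "compare_groups",
    "remove_outliers_mad",
    "holm_correct",
    "clogg_compare",
    "clogg_logistic",
]


@dataclass
class EffectResult:
    """A rank-test result: z statistic, two-sided p, effect size, group sizes."""

    z: float
    p: float
    effect_r: float
    n_a: int
    n_b: int
    paired: bool


@dataclass
class CloggResult:
    """Comparison of one predictor's coefficient between nested models."""

    z: float
    p: float
    coef_1: float
    coef_2: float
    se_1: float
    se_2: float


def percent_change(rest_value: float, task_value: float) -> float:
    """((task - rest) / rest) * 100; rest must be positive."""
    rest_value = np.asarray(rest_value, dtype=float)
    if np.any(rest_value <= 0):
        raise ValueError("percent change undefined for non-positive rest value")
    return (np.asarray(task_value, dtype=float) - rest_value) / rest_value * 100.0


def rest_task_summary(
    int_table: pd.DataFrame,
    rest_state: str,
    task_state: str,
    measure: str = "tau_s",
) -> pd.DataFrame:
    """Per-channel rest/task means, rest across-window SD and percent change.

    ``int_table`` is a long-format window x channel table (as produced by
    ``timescales.windowed_int``/``segment_int``); non-converged windows are
    dropped. Channels whose rest mean is not positive, or that lack windows
    in either state, get NaN percent change.
    """
    t = int_table[int_table["converged"]].dropna(subset=[measure])
    rest = t[t["state"] == rest_state].groupby("channel")[measure]
    task = t[t["state"] == task_state].groupby("channel")[measure]
    out = pd.DataFrame(
        {
            "rest_mean": rest.mean(),
            "rest_sd": rest.std(ddof=1),
            "task_mean": task.mean(),
        }
    )
    valid = out["rest_mean"] > 0
    out["pct_change"] = np.nan
    out.loc[valid, "pct_change"] = (
        (out.loc[valid, "task_mean"] - out.loc[valid, "rest_mean"])
        / out.loc[valid, "rest_mean"] * 100.0
    )
    return out


def variability_change_correlation(
    summary: pd.DataFrame,
    var_col: str = "rest_sd",
    change_col: str = "pct_change",
) -> tuple[float, float, int]:
    """Spearman correlation of rest variability with rest->task change.

    Returns ``(rho, p, df)`` with ``df = n - 2``; p from the t
    approximation on df degrees of freedom. Average ranks handle ties.
    """
    d = summary[[var_col, change_col]].dropna()
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 channels with defined values")
    x, y = d[var_col].to_numpy(), d[change_col].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input: Spearman correlation undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    df = n - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p, df


def _signed_rank(a: np.ndarray, b: np.ndarray, effect: str) -> EffectResult:
    d = a - b
    d = d[d != 0]  # drop zero differences (Wilcoxon's convention)
    n = d.size
    if n == 0:
        return EffectResult(0.0, 1.0, 0.0, a.size, b.size, True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    diff = w_pos - mu
    if n >= 10:
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if var > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = float(sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue)
        z = float(np.sign(diff) * sps.norm.isf(min(p, 1.0) / 2.0)) if diff else 0.0
    r_rb = (w_pos - w_neg) / (w_pos + w_neg)
    eff = z / np.sqrt(n) if effect == "z_sqrt_n" else r_rb
    return EffectResult(float(z), p, float(eff), a.size, b.size, True)


def _rank_sum(a: np.ndarray, b: np.ndarray, effect: str) -> EffectResult:
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (nt * (nt - 1.0))
    var = n1 * n2 / 12.0 * (nt + 1.0 - tie_term)
    diff = u1 - mu
    if min(n1, n2) >= 10:
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if var > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
        z = float(np.sign(diff) * sps.norm.isf(min(p, 1.0) / 2.0)) if diff else 0.0
    r_rb = 2.0 * u1 / (n1 * n2) - 1.0  # = P(a > b) - P(b > a)
    eff = z / np.sqrt(min(n1, n2)) if effect == "z_sqrt_n" else r_rb
    return EffectResult(float(z), p, float(eff), n1, n2, False)


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = False,
    effect: str = "rank_biserial",
) -> EffectResult:
    """Wilcoxon signed-rank (paired) or rank-sum (unpaired) comparison.

    z uses the normal approximation with continuity correction at n >= 10
    and exact enumeration below; p is two-sided. The default effect size is
    the rank-biserial correlation, bounded in [-1, 1] (paired: difference of
    positive and negative rank sums over their total; unpaired:
    ``2 U / (n1 n2) - 1``). ``effect='z_sqrt_n'`` selects z over the square
    root of the smaller group size instead.
    """
    if effect not in ("rank_biserial", "z_sqrt_n"):
        raise ValueError(f"unknown effect-size formula {effect!r}")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if min(a.size, b.size) < 5:
        warnings.warn("fewer than 5 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length groups")
        return _signed_rank(a, b, effect)
    return _rank_sum(a, b, effect)


def remove_outliers_mad(
    x: np.ndarray, k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Keep values within ``k`` scaled median absolute deviations of the median.

    The MAD is scaled by 1.4826 (consistent with the SD under normality).
    Returns ``(filtered, mask)``. A zero MAD keeps only exact-median values
    and warns.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("zero MAD: keeping exact-median values only")
        mask = x == med
    else:
        mask = np.abs(x - med) <= k * mad
    return x[mask], mask


def holm_correct(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p values."""
    pvals = np.asarray(pvals, dtype=float).ravel()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


def clogg_compare(
    coef_1: float, se_1: float, coef_2: float, se_2: float
) -> CloggResult:
    """Compare one predictor's coefficient between two nested models.

    Model 1 is the reduced model, model 2 adds covariates on the same data.
    Because the models are nested on identical data, the sampling variance
    of the coefficient difference is the difference of the coefficient
    variances (Clogg, Petkova & Haritou 1995), not their sum:
    ``z = (b1 - b2) / sqrt(se_2^2 - se_1^2)``.
    """
    var_diff = se_2**2 - se_1**2
    if coef_1 == coef_2:
        return CloggResult(0.0, 1.0, coef_1, coef_2, se_1, se_2)
    if var_diff <= 0:
        raise ValueError(
            "non-positive variance of the coefficient difference "
            f"(se_1={se_1:.4g}, se_2={se_2:.4g}); the added covariate did not "
            "increase the predictor's sampling variance — check model nesting"
        )
    z = (coef_1 - coef_2) / np.sqrt(var_diff)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return CloggResult(float(z), p, coef_1, coef_2, se_1, se_2)


def clogg_logistic(
    y: np.ndarray, x: np.ndarray, covariate: np.ndarray
) -> CloggResult:
    """Clogg test for a logistic regression of ``y`` on ``x``.

    Fits ``y ~ x`` and ``y ~ x + covariate`` (both with intercept) by
    maximum likelihood and compares the coefficient of ``x`` between the
    two fits.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    X1 = sm.add_constant(x)
    X2 = sm.add_constant(np.column_stack([x, covariate]))
    fit1 = sm.Logit(y, X1).fit(disp=False)
    fit2 = sm.Logit(y, X2).fit(disp=False)
    return clogg_compare(
        float(fit1.params[1]), float(fit1.bse[1]),
        float(fit2.params[1]), float(fit2.bse[1]),
    )
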