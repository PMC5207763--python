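"""Statistical battery for the life-cycle comparisons.

Exact 2×2 tests and rank tests wrap scipy; the small-sample Wilcoxon path
enumerates rank splits directly so that ties are handled by enumeration
rather than approximation.  The multivariate logistic model of local gene
loss is fit by IRLS (statsmodels) on internally standardized features with
drop-one partial tests, and its fit quality is summarised as the squared
Pearson correlation between fitted probabilities and the binary outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import comb, factorial
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "LossModelFit",
    "fisher_exact_2x2",
    "fold_enrichment",
    "wilcoxon_rank_sum",
    "bootstrap_se_median",
    "fit_local_loss_model",
    "integration_ratio",
    "ordering_pvalue",
    "adjust_pvalues",
]


@dataclass
class StatResult:
    """A statistic with its p-value, effect size and bookkeeping."""

    method: str
    statistic: float
    p_value: float
    effect: float | None = None
    n: tuple[int, ...] = ()
    direction: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    The two-sided p-value sums hypergeometric point probabilities no
    larger than that of the observed table (the R ``fisher.test``
    convention).  The effect is the sample odds ratio ``(a·d)/(b·c)``.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("Fisher 2x2 with a zero margin: p = 1, odds ratio undefined")
        return StatResult("fisher_exact", float("nan"), 1.0, None, (a + b, c + d), None)
    if b * c == 0:
        odds: float | None = float("inf") if a * d > 0 else None
    else:
        odds = (a * d) / (b * c)
    _, pval = scipy.stats.fisher_exact(table, alternative="two-sided")
    direction = None
    if odds is not None and odds != 1.0:
        direction = 1 if odds > 1 else -1
    return StatResult(
        method="fisher_exact",
        statistic=float(odds) if odds is not None else float("nan"),
        p_value=float(min(pval, 1.0)),
        effect=odds,
        n=(a + b, c + d),
        direction=direction,
    )


def fold_enrichment(k1: int, n1: int, k2: int, n2: int) -> float:
    """Ratio of the proportions k1/n1 and k2/n2."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    if k2 == 0:
        logger.warning("fold enrichment against an empty reference: infinite")
        return float("inf")
    return (k1 / n1) / (k2 / n2)


def _exact_rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration of all rank splits.

    Midranks handle ties; the null distribution of U is symmetric about
    n_x·n_y/2 by exchangeability, so the two-sided p-value is the
    probability of a U at least as far from the centre as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    nx, n = len(x), len(pooled)
    offset = nx * (nx + 1) / 2
    centre = nx * (n - nx) / 2
    u_obs = ranks[:nx].sum() - offset
    dev_obs = abs(u_obs - centre)
    count = 0
    total = comb(n, nx)
    for idx in combinations(range(n), nx):
        u = ranks[list(idx)].sum() - offset
        if abs(u - centre) >= dev_obs - 1e-12:
            count += 1
    return float(u_obs), count / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration when n_x + n_y ≤ 12; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must contain at least one value")
    if len(x) + len(y) <= 12:
        u, pval = _exact_rank_sum_pvalue(x, y)
        method = "wilcoxon_exact"
    else:
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, pval = float(res.statistic), float(res.pvalue)
        method = "wilcoxon_asymptotic"
    centre = len(x) * len(y) / 2
    direction = 0 if u == centre else (1 if u > centre else -1)
    return StatResult(
        method=method,
        statistic=u,
        p_value=min(float(pval), 1.0),
        effect=None,
        n=(len(x), len(y)),
        direction=direction,
    )


def bootstrap_se_median(
    values: Sequence[float], n_resamples: int = 100, seed: int = 0
) -> float:
    """Bootstrapped standard error of the median (with-replacement resampling)."""
    vals = np.asarray(list(values), dtype=float)
    if len(vals) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_resamples, len(vals)))
    medians = np.median(vals[idx], axis=1)
    return float(np.std(medians, ddof=1))


@dataclass
class LossModelFit:
    """Multivariate logistic model of local gene loss."""

    params: pd.Series  # input-scale coefficients, incl. "intercept"
    partial_pvalues: pd.Series
    fitted: np.ndarray  # fitted probabilities, in (0, 1)
    r_squared: float
    n: int
    dropped: list[str] = field(default_factory=list)
    partial_test: str = "lr"
    converged: bool = True

    def direction(self) -> pd.Series:
        """Sign pattern of the feature coefficients ('+' / '-')."""
        feats = self.params.drop("intercept")
        return feats.apply(lambda b: "+" if b > 0 else "-")


def _logit_llf(y: np.ndarray, exog: np.ndarray, params: np.ndarray) -> float:
    eta = exog @ params
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logit(y: np.ndarray, exog: np.ndarray, ridge: float = 1e-6) -> tuple[np.ndarray, float, bool]:
    """Fit a logistic regression; fall back to a tiny ridge on separation."""
    model = sm.Logit(y, exog)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if np.isfinite(params).all() and np.abs(params).max() < 1e3:
            return params, _logit_llf(y, exog, params), bool(res.mle_retvals.get("converged", True))
    except Exception:  # PerfectSeparationError, LinAlgError, ...
        pass
    logger.warning("logistic fit unstable (separation?); refitting with ridge λ=%g", ridge)
    glm = sm.GLM(y, exog, family=sm.families.Binomial())
    res = glm.fit_regularized(alpha=ridge, L1_wt=0.0)
    params = np.asarray(res.params, dtype=float)
    return params, _logit_llf(y, exog, params), False


def fit_local_loss_model(
    features: pd.DataFrame,
    outcome: Sequence[bool] | pd.Series,
    partial_test: str = "lr",
) -> LossModelFit:
    """Fit the multivariate logistic model of local gene loss.

    Features are standardized internally (coefficients are reported on the
    input scale).  Per-feature partial p-values compare the full model to
    the drop-one nested model, by likelihood-ratio chi-square by default or
    by an F-statistic on the deviance (``partial_test="f"``).  Collinear or
    constant features are dropped with a warning; rows with missing values
    are excluded.
    """
    if partial_test not in ("lr", "f"):
        raise ValueError("partial_test must be 'lr' or 'f'")
    X = features.astype(float).copy()
    y = pd.Series(np.asarray(outcome, dtype=float), index=X.index)
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[mask], y.loc[mask]
    if y.nunique() < 2:
        raise ValueError("outcome must contain both classes")

    dropped: list[str] = []
    stds = X.std(ddof=0)
    for col in X.columns[stds == 0]:
        dropped.append(col)
        logger.warning("feature %r is constant; dropped from the model", col)
    X = X.drop(columns=dropped)
    # drop columns until full column rank
    while X.shape[1] > 1:
        Z = (X - X.mean()) / X.std(ddof=0)
        if np.linalg.matrix_rank(Z.to_numpy()) == X.shape[1]:
            break
        corr = Z.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        victim = X.columns[int(np.argmax(corr.max(axis=0)))]
        dropped.append(victim)
        logger.warning("feature %r is collinear; dropped from the model", victim)
        X = X.drop(columns=[victim])

    means, stds = X.mean(), X.std(ddof=0)
    Z = (X - means) / stds
    yv = y.to_numpy()
    exog = np.column_stack([np.ones(len(Z)), Z.to_numpy()])
    params_z, llf_full, converged = _fit_logit(yv, exog)

    cols = list(X.columns)
    partial_p = {}
    k = len(cols)
    n = len(yv)
    dev_full = -2 * llf_full
    for j, col in enumerate(cols):
        sub = np.delete(exog, j + 1, axis=1)
        _, llf_red, _ = _fit_logit(yv, sub)
        lr = max(2 * (llf_full - llf_red), 0.0)
        if partial_test == "lr":
            partial_p[col] = float(scipy.stats.chi2.sf(lr, df=1))
        else:
            dev_red = -2 * llf_red
            denom_df = n - (k + 1)
            fstat = (dev_red - dev_full) / (dev_full / denom_df)
            partial_p[col] = float(scipy.stats.f.sf(max(fstat, 0.0), 1, denom_df))

    # back-transform standardized coefficients to the input scale
    coefs = {c: params_z[j + 1] / stds[c] for j, c in enumerate(cols)}
    intercept = params_z[0] - sum(params_z[j + 1] * means[c] / stds[c] for j, c in enumerate(cols))
    params = pd.Series({"intercept": intercept, **coefs})

    eta = exog @ params_z
    fitted = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    r = np.corrcoef(fitted, yv)[0, 1]
    r_squared = float(r**2) if np.isfinite(r) else 0.0

    return LossModelFit(
        params=params,
        partial_pvalues=pd.Series(partial_p),
        fitted=fitted,
        r_squared=r_squared,
        n=n,
        dropped=dropped,
        partial_test=partial_test,
        converged=converged,
    )


def integration_ratio(
    deg_young: Sequence[float], deg_old: Sequence[float]
) -> float:
    """Mean degree of young genes over mean degree of old genes.

    The ratio of the two averages (rather than their difference) normalises
    out the edge density of the network, which varies wildly across network
    types.
    """
    young = np.asarray(list(deg_young), dtype=float)
    old = np.asarray(list(deg_old), dtype=float)
    if len(young) == 0 or len(old) == 0:
        raise ValueError("both groups must be nonempty")
    mo = old.mean()
    if mo <= 0:
        raise ValueError("mean degree of the old group must be positive")
    return float(young.mean() / mo)


def _concordant_pairs(order: Sequence[str], pos: Mapping[str, int]) -> int:
    return sum(
        1
        for i, j in combinations(range(len(order)), 2)
        if pos[order[i]] < pos[order[j]]
    )


def ordering_pvalue(
    observed_order: Sequence[str], reference_order: Sequence[str]
) -> float:
    """Probability of an ordering as concordant as observed, under uniform permutations.

    An exact match has probability 1/k!.  Otherwise the tail counts the
    permutations with at least as many concordant pairs (relative to the
    reference) as the observed ordering.
    """
    obs, ref = list(observed_order), list(reference_order)
    if sorted(obs) != sorted(ref) or len(set(obs)) != len(obs):
        raise ValueError("orders must be permutations of the same set of networks")
    k = len(ref)
    if k <= 1:
        return 1.0
    if obs == ref:
        return 1.0 / factorial(k)
    pos = {name: i for i, name in enumerate(ref)}
    c_obs = _concordant_pairs(obs, pos)
    count = sum(1 for perm in permutations(ref) if _concordant_pairs(perm, pos) >= c_obs)
    return count / factorial(k)


def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing adjustment (off by default in all reports)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvalues), method=method)[1]
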