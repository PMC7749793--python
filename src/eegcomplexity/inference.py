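"""Multiple imputation, confounder selection, pooled regression, importance.

The analysis chain this module implements:

1. **Chained-equations imputation** (:func:`impute`): each incomplete column
   is iteratively regressed on all other columns with a ridge-stabilised
   Bayesian linear model (posterior parameter draws); by default missing
   values are filled by predictive-mean matching (PMM, donor pool k = 5),
   which keeps imputations on the observed support.  Produces ``m``
   completed datasets (default 20).
2. **Stepwise forward selection** (:func:`stepwise_select`) of confounders
   on each imputed dataset, keeping the predictor of interest forced in,
   followed by a strict **majority vote** (:func:`majority_vote`) over the
   m selections.
3. **Rubin's-rules pooling** (:func:`pooled_regression`) of the per-dataset
   OLS fits: pooled estimate Qbar, within-variance Wbar, between-variance B,
   total variance T = Wbar + (1 + 1/m) B, Barnard-Rubin small-sample
   degrees of freedom, two-sided p-values; adjusted R^2 is averaged over
   imputations.
4. **LMG relative importance** (:func:`lmg_importance`): each predictor's
   R^2 contribution averaged over all orders of model entry (exact
   enumeration via the subset decomposition); shares sum to the full-model
   R^2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImputedStack:
    """``m`` completed copies of an analysis dataset."""

    datasets: list[pd.DataFrame]
    seed: int | None = None
    n_iter: int = 5
    method: str = "pmm"

    @property
    def m(self) -> int:
        return len(self.datasets)


def _bayes_ridge_draw(
    x_obs: np.ndarray,
    y_obs: np.ndarray,
    x_mis: np.ndarray,
    rng: np.random.Generator,
    ridge: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior-draw linear prediction for observed and missing rows.

    Ridge-stabilised so wide models (p approaching or exceeding n, as with a
    full longitudinal score panel) remain well-posed.  Returns predictions
    at the drawn parameters for observed rows, for missing rows, and the
    drawn residual sd.
    """
    n, p = x_obs.shape
    xtx = x_obs.T @ x_obs + ridge * np.eye(p)
    xty = x_obs.T @ y_obs
    beta_hat = np.linalg.solve(xtx, xty)
    resid = y_obs - x_obs @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / df
    sigma2_draw = sigma2 * df / rng.chisquare(df)
    cov = np.linalg.inv(xtx) * sigma2_draw
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(p))
    beta_draw = beta_hat + chol @ rng.standard_normal(p)
    return x_obs @ beta_draw, x_mis @ beta_draw, float(np.sqrt(sigma2_draw))


def _impute_once(
    values: np.ndarray,
    miss: np.ndarray,
    rng: np.random.Generator,
    n_iter: int,
    method: str,
    pmm_donors: int,
) -> np.ndarray:
    """One chained-equations pass producing a single completed matrix."""
    n, p = values.shape
    filled = values.copy()
    # initial fill: random draws from each column's observed values
    for j in range(p):
        mj = miss[:, j]
        if mj.any():
            obs = values[~mj, j]
            filled[mj, j] = rng.choice(obs, size=int(mj.sum()), replace=True)

    order = np.argsort(miss.sum(axis=0))  # least missing first
    incomplete = [j for j in order if miss[:, j].any()]
    for _ in range(n_iter):
        for j in incomplete:
            mj = miss[:, j]
            others = np.delete(np.arange(p), j)
            x = filled[:, others]
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = (x - mu) / sd
            x = np.column_stack([np.ones(n), x])
            pred_obs, pred_mis, sigma = _bayes_ridge_draw(
                x[~mj], values[~mj, j], x[mj], rng
            )
            if method == "pmm":
                obs_vals = values[~mj, j]
                # k nearest observed predictions per missing cell
                dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
                k = min(pmm_donors, len(obs_vals))
                donors = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = donors[
                    np.arange(donors.shape[0]),
                    rng.integers(0, k, size=donors.shape[0]),
                ]
                filled[mj, j] = obs_vals[pick]
            elif method == "norm":
                filled[mj, j] = pred_mis + sigma * rng.standard_normal(
                    int(mj.sum())
                )
            else:
                raise ValueError(f"unknown imputation method {method!r}")
    if not np.isfinite(filled).all():
        raise RuntimeError(
            "imputation produced non-finite values; the configuration did "
            "not converge"
        )
    return filled


def impute(
    data: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 5,
    method: str = "pmm",
    pmm_donors: int = 5,
    columns: Sequence[str] | None = None,
) -> ImputedStack:
    """Multiple imputation by chained equations.

    Only numeric columns take part; ``columns`` restricts which columns may
    be *imputed* (all numeric columns still serve as predictors).  Columns
    with >= 50 % missing or entirely missing are rejected.  Deterministic
    given ``seed``; with no missing cells all m datasets equal the input.
    """
    numeric = data.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValueError("need at least two numeric columns to impute")
    target_cols = list(numeric.columns if columns is None else columns)
    values = numeric.to_numpy(dtype=float)
    miss = ~np.isfinite(values)
    col_idx = {c: i for i, c in enumerate(numeric.columns)}
    # columns outside the target set must be complete
    for c in numeric.columns:
        frac = miss[:, col_idx[c]].mean()
        if c not in target_cols and frac > 0:
            raise ValueError(
                f"column {c!r} has missing values but is not in the "
                "imputable set"
            )
        if frac >= 0.5:
            raise ValueError(
                f"column {c!r} is {frac:.0%} missing (>= 50 % not supported)"
            )

    datasets = []
    root = np.random.default_rng(seed & 0x7FFFFFFF)
    for _ in range(m):
        child = np.random.default_rng(root.integers(0, 2**31 - 1))
        if miss.any():
            filled = _impute_once(values, miss, child, n_iter, method, pmm_donors)
        else:
            filled = values.copy()
        out = data.copy()
        out[numeric.columns] = filled
        datasets.append(out)
    return ImputedStack(datasets=datasets, seed=seed, n_iter=n_iter, method=method)


# ---------------------------------------------------------------------------
# Stepwise selection and majority vote
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, x: np.ndarray):
    import statsmodels.api as sm

    return sm.OLS(y, x).fit()


def _last_term_p(y: np.ndarray, x: np.ndarray) -> float:
    """Two-sided p of the last coefficient of OLS(y, x) (partial F, 1 df)."""
    n, p = x.shape
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - p
    if df <= 0:
        return 1.0
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    if se == 0:
        return 1.0
    t = beta[-1] / se
    return float(2 * stats.t.sf(abs(t), df))


def _design(
    df: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    x = df[list(terms)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), x]), ["const", *terms]


def stepwise_select(
    df: pd.DataFrame,
    outcome: str,
    forced: Sequence[str],
    candidates: Sequence[str],
    alpha_enter: float = 0.05,
    cond_max: float = 1e8,
) -> list[str]:
    """Forward selection of confounders with the predictor forced in.

    Starting from the forced terms, repeatedly adds the candidate with the
    smallest partial-F p-value while it is below ``alpha_enter``; forced
    terms are never removed.  Near-collinear candidates (condition number of
    the standardized design above ``cond_max``) are dropped with a warning.
    Returns the selected candidates, in order of entry.
    """
    y = df[outcome].to_numpy(dtype=float)
    current = list(forced)
    selected: list[str] = []
    remaining = list(candidates)
    while remaining:
        best_p, best_c = np.inf, None
        for cand in remaining:
            cols = df[current + [cand]].to_numpy(dtype=float)
            sd = cols.std(axis=0)
            if np.any(sd == 0):
                continue
            if np.linalg.cond((cols - cols.mean(0)) / sd) > cond_max:
                warnings.warn(
                    f"candidate {cand!r} is near-collinear with the current "
                    "model; skipped",
                    stacklevel=2,
                )
                continue
            x, _ = _design(df, current + [cand])
            p = _last_term_p(y, x)  # partial F == squared t for one added term
            if p < best_p:
                best_p, best_c = p, cand
        if best_c is None or best_p >= alpha_enter:
            break
        current.append(best_c)
        selected.append(best_c)
        remaining.remove(best_c)
    return selected


def majority_vote(selections: Sequence[Sequence[str]]) -> list[str]:
    """Confounders selected in a strict majority (> m/2) of datasets."""
    m = len(selections)
    if m < 1:
        raise ValueError("need at least one selection")
    counts: dict[str, int] = {}
    for sel in selections:
        for term in set(sel):
            counts[term] = counts.get(term, 0) + 1
    return sorted(term for term, c in counts.items() if c > m / 2)


# ---------------------------------------------------------------------------
# Rubin's-rules pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledRegression:
    """Rubin-pooled OLS over an imputed stack."""

    predictor: str
    terms: list[str]
    estimates: pd.Series  # Qbar per term
    within_var: pd.Series  # Wbar
    between_var: pd.Series  # B
    total_var: pd.Series  # T = Wbar + (1 + 1/m) B
    df: pd.Series  # Barnard-Rubin adjusted
    p_values: pd.Series
    adj_r2: float  # mean over imputations
    m: int
    selected_confounders: list[str] = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return np.sqrt(self.total_var)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "df": self.df,
                "p": self.p_values,
            }
        )


def pooled_regression(
    stack: ImputedStack,
    outcome: str,
    predictor: str,
    confounders: Sequence[str] = (),
) -> PooledRegression:
    """Fit OLS on every imputed dataset and pool by Rubin's rules.

    With m = 1 the pooled estimates and SEs equal the single OLS fit; with
    identical datasets the between-imputation variance B is zero and the
    pooled SE equals the within-imputation SE.  Degrees of freedom use the
    Barnard-Rubin small-sample adjustment.
    """
    if stack.m < 1:
        raise ValueError("empty imputation stack")
    terms = [predictor, *confounders]
    params, variances, r2s = [], [], []
    for ds in stack.datasets:
        x, names = _design(ds, terms)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("rank-deficient design matrix in an imputation")
        fit = _ols(ds[outcome].to_numpy(dtype=float), x)
        params.append(fit.params)
        variances.append(fit.bse**2)
        r2s.append(fit.rsquared_adj)
    names = ["const", *terms]
    q = pd.DataFrame(params, columns=names)
    w = pd.DataFrame(variances, columns=names)

    m = stack.m
    qbar = q.mean(axis=0)
    wbar = w.mean(axis=0)
    b = q.var(axis=0, ddof=1) if m > 1 else pd.Series(0.0, index=names)
    t = wbar + (1 + 1 / m) * b

    n, k = stack.datasets[0].shape[0], len(names)
    dfcom = n - k
    lam = ((1 + 1 / m) * b / t).replace([np.inf], 1.0).fillna(0.0)
    with np.errstate(divide="ignore"):
        df_old = (m - 1) / lam**2
    df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
    df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    df = df.where(lam > 0, df_obs)  # B = 0 -> observed-data df

    tstat = qbar / np.sqrt(t)
    p = pd.Series(
        2 * stats.t.sf(np.abs(tstat.to_numpy()), df.to_numpy()), index=names
    )
    return PooledRegression(
        predictor=predictor,
        terms=terms,
        estimates=qbar,
        within_var=wbar,
        between_var=b,
        total_var=t,
        df=df,
        p_values=p,
        adj_r2=float(np.mean(r2s)),
        m=m,
        selected_confounders=list(confounders),
    )


def select_and_pool(
    stack: ImputedStack,
    outcome: str,
    predictor: str,
    candidates: Sequence[str],
    alpha_enter: float = 0.05,
) -> PooledRegression:
    """Per-imputation stepwise selection, majority vote, pooled regression."""
    selections = [
        stepwise_select(ds, outcome, [predictor], candidates, alpha_enter)
        for ds in stack.datasets
    ]
    consensus = majority_vote(selections)
    return pooled_regression(stack, outcome, predictor, consensus)


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceShares:
    """LMG decomposition of R^2 over predictors."""

    shares: pd.Series  # per predictor, sums to full-model R^2
    full_r2: float
    residual: float  # 1 - full_r2

    def normalized(self) -> pd.Series:
        """Shares rescaled to sum to one (fraction of explained variance)."""
        return self.shares / self.shares.sum()


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def _lmg_single(df: pd.DataFrame, outcome: str, predictors: Sequence[str]) -> pd.Series:
    from math import factorial

    y = df[outcome].to_numpy(dtype=float)
    p = len(predictors)
    cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in cache:
            if subset:
                x = np.column_stack(
                    [np.ones(len(df)), df[sorted(subset)].to_numpy(dtype=float)]
                )
            else:
                x = np.ones((len(df), 1))
            cache[subset] = _r2(y, x)
        return cache[subset]

    shares = {}
    others_all = list(predictors)
    fact_p = factorial(p)
    for pred in predictors:
        rest = [q for q in others_all if q != pred]
        total = 0.0
        for size in range(p):
            weight = factorial(size) * factorial(p - size - 1) / fact_p
            for combo in itertools.combinations(rest, size):
                s = frozenset(combo)
                total += weight * (r2_of(s | {pred}) - r2_of(s))
        shares[pred] = total
    return pd.Series(shares, dtype=float).reindex(predictors)


def lmg_importance(
    data: pd.DataFrame | ImputedStack,
    outcome: str,
    predictors: Sequence[str],
) -> ImportanceShares:
    """Exact LMG importance (average R^2 increment over all entry orders).

    Enumerates all predictor subsets, so at most 8 predictors are allowed.
    For an :class:`ImputedStack`, shares are averaged over imputations.
    The shares are non-negative for well-posed designs and sum exactly to
    the full-model R^2.
    """
    predictors = list(predictors)
    if len(predictors) == 0:
        raise ValueError("need at least one predictor")
    if len(predictors) > 8:
        raise ValueError(
            "LMG uses exact enumeration; more than 8 predictors is not "
            "supported"
        )
    if isinstance(data, ImputedStack):
        per = [_lmg_single(ds, outcome, predictors) for ds in data.datasets]
        shares = pd.concat(per, axis=1).mean(axis=1)
    else:
        shares = _lmg_single(data, outcome, predictors)
    full_r2 = float(shares.sum())
    return ImportanceShares(
        shares=shares, full_r2=full_r2, residual=1.0 - full_r2
    )
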