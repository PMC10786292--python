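"""Vectorized random-intercept linear mixed-model engine.

Fits y_it = x_it' beta + b_i + e_it with b_i ~ N(0, tau^2), e ~ N(0, s^2),
by REML, simultaneously for many response columns (edges) sharing one fixed
design X and one grouping vector.  The variance ratio theta = tau^2 / s^2 is
profiled: for fixed theta the GLS solution has a closed form built from
per-subject sufficient statistics, so the REML criterion is a cheap 1-D
function optimized per edge by a coarse log-grid plus golden-section
refinement.  This is what makes permutation-based network statistics
(hundreds of edges x thousands of permutations) feasible.

For balanced categorical-time designs (every subject observed exactly once
at every level) the REML solution is closed-form: treatment contrasts equal
differences of level means with variance 2*s^2/n_subjects, where s^2 is the
subject-by-time interaction mean square when the subject variance estimate
is interior, and the pooled OLS residual variance when it is truncated at
zero.  At two levels with an interior estimate this reproduces the paired
t statistic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_GRID = np.concatenate([[0.0], np.logspace(-6.0, 5.0, 34)])
_GOLDEN = 0.6180339887498949
_EPS = 1e-12


@dataclass
class BatchLMEResult:
    """Per-column estimates for each fixed-effect coefficient."""

    beta: np.ndarray       # (E, p)
    se: np.ndarray         # (E, p)
    tstat: np.ndarray      # (E, p)
    pval: np.ndarray       # (E, p)
    sigma2: np.ndarray     # (E,) residual variance
    tau2: np.ndarray       # (E,) subject-intercept variance
    df: float
    ok: np.ndarray         # (E,) fit succeeded / response non-degenerate


class _Suff:
    """Per-subject sufficient statistics for the profiled REML criterion."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        n, self.p = X.shape
        self.n = n
        S = int(groups.max()) + 1
        self.S = S
        self.Y = Y
        self.X = X
        self.groups = groups
        self.ns = np.bincount(groups, minlength=S).astype(float)
        self.Sx = np.zeros((S, self.p))
        np.add.at(self.Sx, groups, X)
        self.Sy = np.zeros((S, Y.shape[1]))
        np.add.at(self.Sy, groups, Y)
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.yty = np.einsum("ne,ne->e", Y, Y)
        self.SxSx = np.einsum("sp,sq->spq", self.Sx, self.Sx)
        self.Sy2 = self.Sy**2

    def solve_shared(self, theta: float):
        """GLS pieces for one theta shared across all columns."""
        c = theta / (1.0 + self.ns * theta)  # (S,)
        A = self.XtX - np.einsum("s,spq->pq", c, self.SxSx)
        B = self.XtY - self.Sx.T @ (c[:, None] * self.Sy)
        q = self.yty - c @ self.Sy2
        beta = np.linalg.solve(A, B)
        rss = np.maximum(q - np.einsum("pe,pe->e", B, beta), 1e-300)
        logdetV = float(np.sum(np.log1p(self.ns * theta)))
        logdetA = float(np.linalg.slogdet(A)[1])
        crit = (self.n - self.p) * np.log(rss) + logdetV + logdetA
        return crit, A, beta, rss

    def crit_per_edge(self, theta: np.ndarray) -> np.ndarray:
        """REML criterion for a per-column theta vector (E,)."""
        c = theta[:, None] / (1.0 + self.ns[None, :] * theta[:, None])  # (E, S)
        A = self.XtX[None] - np.einsum("es,spq->epq", c, self.SxSx)
        B = self.XtY.T - np.einsum("es,sp,se->ep", c, self.Sx, self.Sy)
        q = self.yty - np.einsum("es,se->e", c, self.Sy2)
        beta = np.linalg.solve(A, B[:, :, None])[:, :, 0]
        rss = np.maximum(q - np.einsum("ep,ep->e", B, beta), 1e-300)
        logdetV = np.sum(np.log1p(self.ns[None, :] * theta[:, None]), axis=1)
        logdetA = np.linalg.slogdet(A)[1]
        return (self.n - self.p) * np.log(rss) + logdetV + logdetA

    def finalize(self, theta: np.ndarray, df: float):
        c = theta[:, None] / (1.0 + self.ns[None, :] * theta[:, None])
        A = self.XtX[None] - np.einsum("es,spq->epq", c, self.SxSx)
        B = self.XtY.T - np.einsum("es,sp,se->ep", c, self.Sx, self.Sy)
        q = self.yty - np.einsum("es,se->e", c, self.Sy2)
        Ainv = np.linalg.inv(A)
        beta = np.einsum("epq,eq->ep", Ainv, B)
        rss = np.maximum(q - np.einsum("ep,ep->e", B, beta), 0.0)
        sigma2 = rss / (self.n - self.p)
        var_beta = sigma2[:, None] * np.einsum("epp->ep", Ainv)
        se = np.sqrt(np.maximum(var_beta, 0.0))
        return beta, se, sigma2, theta * sigma2


def batch_lme(
    Y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    df: float | None = None,
    n_golden: int = 28,
) -> BatchLMEResult:
    """REML random-intercept fits for every column of ``Y``.

    Parameters
    ----------
    Y : (n_obs, E) response columns.
    X : (n_obs, p) fixed design, full column rank, first column intercept.
    groups : (n_obs,) integer subject codes.
    df : denominator degrees of freedom for t p-values; defaults to the
        residual convention ``n_obs - p``.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    E = Y.shape[1]
    if df is None:
        df = n - p
    ok = Y.std(axis=0) > 0
    Ywork = Y.copy()
    Ywork[:, ~ok] = np.random.default_rng(0).normal(size=(n, (~ok).sum()))

    suff = _Suff(Ywork, X, groups)
    crits = np.empty((len(_GRID), E))
    for g, th in enumerate(_GRID):
        crits[g] = suff.solve_shared(th)[0]
    best = np.argmin(crits, axis=0)
    lo = np.where(best == 0, 0.0, _GRID[np.maximum(best - 1, 0)])
    hi = np.where(best == len(_GRID) - 1, _GRID[-1] * 10.0, _GRID[np.minimum(best + 1, len(_GRID) - 1)])

    lo_u = np.log(lo + _EPS)
    hi_u = np.log(hi + _EPS)
    for _ in range(n_golden):
        m1 = hi_u - _GOLDEN * (hi_u - lo_u)
        m2 = lo_u + _GOLDEN * (hi_u - lo_u)
        f1 = suff.crit_per_edge(np.maximum(np.exp(m1) - _EPS, 0.0))
        f2 = suff.crit_per_edge(np.maximum(np.exp(m2) - _EPS, 0.0))
        take = f1 < f2
        hi_u = np.where(take, m2, hi_u)
        lo_u = np.where(take, lo_u, m1)
    theta = np.maximum(np.exp((lo_u + hi_u) / 2.0) - _EPS, 0.0)
    # guard: never worse than the exact boundary theta = 0
    at0 = suff.crit_per_edge(np.zeros(E))
    atth = suff.crit_per_edge(theta)
    theta = np.where(at0 < atth, 0.0, theta)

    beta, se, sigma2, tau2 = suff.finalize(theta, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    bad = ~ok | ~np.isfinite(tstat).all(axis=1)
    tstat[bad] = 0.0
    pval[bad] = 1.0
    beta[bad] = 0.0
    return BatchLMEResult(beta, se, tstat, pval, sigma2, tau2, float(df), ~bad)


# -- balanced categorical-time fast path -----------------------------------

def is_balanced(groups: np.ndarray, levels: np.ndarray) -> bool:
    """True if every subject is observed exactly once at every level."""
    uniq = np.unique(levels)
    S = int(groups.max()) + 1
    counts = np.zeros((S, len(uniq)), dtype=int)
    lev_idx = np.searchsorted(uniq, levels)
    np.add.at(counts, (groups, lev_idx), 1)
    return bool(np.all(counts == 1))


def balanced_time_stats(
    Y: np.ndarray, groups: np.ndarray, levels: np.ndarray, df: float | None = None
) -> BatchLMEResult:
    """Closed-form REML treatment contrasts for a balanced within design.

    ``levels`` are the categorical time codes; contrasts are each level vs
    the smallest.  Exact equivalent of :func:`batch_lme` on balanced data.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, E = Y.shape
    uniq = np.unique(levels)
    T = len(uniq)
    S = int(groups.max()) + 1
    if df is None:
        df = n - T
    lev_idx = np.searchsorted(uniq, levels)

    mean_t = np.zeros((T, E))
    np.add.at(mean_t, lev_idx, Y)
    mean_t /= S
    mean_s = np.zeros((S, E))
    np.add.at(mean_s, groups, Y)
    mean_s /= T
    gm = Y.mean(axis=0)

    ss_sub = T * ((mean_s - gm) ** 2).sum(axis=0)
    resid = Y - mean_s[groups] - mean_t[lev_idx] + gm
    ss_err = (resid**2).sum(axis=0)
    ms_sub = ss_sub / (S - 1)
    ms_err = ss_err / ((S - 1) * (T - 1))
    interior = ms_sub > ms_err
    sigma2 = np.where(interior, ms_err, (ss_sub + ss_err) / (n - T))
    tau2 = np.where(interior, (ms_sub - ms_err) / T, 0.0)

    est = (mean_t[1:] - mean_t[0]).T  # (E, T-1)
    se = np.sqrt(2.0 * sigma2 / S)[:, None] * np.ones((1, T - 1))
    ok = Y.std(axis=0) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    tstat[~ok] = 0.0
    pval[~ok] = 1.0
    est = np.where(ok[:, None], est, 0.0)
    # prepend intercept column so the layout matches batch_lme (intercept+contrasts)
    beta = np.concatenate([mean_t[0][:, None], est], axis=1)
    se_full = np.concatenate([np.full((E, 1), np.nan), se], axis=1)
    t_full = np.concatenate([np.full((E, 1), np.nan), tstat], axis=1)
    p_full = np.concatenate([np.full((E, 1), np.nan), pval], axis=1)
    return BatchLMEResult(beta, se_full, t_full, p_full, sigma2, tau2, float(df), ok)


def time_design(levels: np.ndarray) -> np.ndarray:
    """Intercept + treatment dummies (vs the smallest level)."""
    uniq = np.unique(levels)
    X = np.ones((len(levels), len(uniq)))
    for k, lev in enumerate(uniq[1:], start=1):
        X[:, k] = (levels == lev).astype(float)
    return X
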