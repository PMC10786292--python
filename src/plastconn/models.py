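"""Statistical primitives for the longitudinal analysis.

Linear mixed-effects models with a participant random intercept (REML via
statsmodels), timepoint contrasts by releveled refits, classical paired t
tests, and Pearson correlations.  Reported p-values use a t reference
distribution with residual degrees of freedom ``n_obs - rank(X)`` by
default; the convention is configurable because mixed-model software
differs here and t statistics, not p-values, are the primary quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats



class SingularFitError(RuntimeError):
    """Raised when a mixed model cannot be identified (degenerate response)."""


@dataclass(frozen=True)
class ModelSpec:
    """Design of an edge-level or summary-level mixed model.

    ``fixed_effect`` is either ``"time"`` (categorical over measurement
    months, treatment-coded against ``reference_level``) or ``"score"``
    (continuous L2 proficiency).  A participant random intercept is always
    included.
    """

    fixed_effect: str = "time"
    reference_level: int | None = None
    df_method: str = "residual"  # or "normal"

    def __post_init__(self):
        if self.fixed_effect not in ("time", "score"):
            raise ValueError(f"unknown fixed effect {self.fixed_effect!r}")
        if self.df_method not in ("residual", "normal"):
            raise ValueError(f"unknown df method {self.df_method!r}")


@dataclass(frozen=True)
class LMEFit:
    """A fitted random-intercept model."""

    coefficients: pd.DataFrame  # term, estimate, se, t, df, p
    subject_var: float
    resid_var: float
    n_obs: int
    n_participants: int

    def coef(self, term: str) -> pd.Series:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"no coefficient {term!r}")
        return row.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        return self.coefficients.copy()


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _pvalue(t: float, df: float, method: str) -> float:
    if method == "normal":
        return float(2.0 * stats.norm.sf(abs(t)))
    return float(2.0 * stats.t.sf(abs(t), df))


def fit_lme(frame: pd.DataFrame, spec: ModelSpec, value_col: str = "value") -> LMEFit:
    """Fit ``value ~ fixed_effect + (1 | participant)`` by REML.

    ``frame`` is long-format with columns ``participant``, ``value`` and
    either ``timepoint`` or ``score``.  Unbalanced data are allowed;
    participants with a single observation are retained.
    """
    frame = frame.dropna(subset=[value_col]).copy()
    y = frame[value_col].to_numpy(float)
    if len(frame) < 4 or frame["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants and 4 observations")
    if np.ptp(y) == 0:
        raise SingularFitError("response is constant")

    import statsmodels.formula.api as smf

    if spec.fixed_effect == "time":
        ref = spec.reference_level
        if ref is None:
            ref = int(frame["timepoint"].min())
        formula = f"{value_col} ~ C(timepoint, Treatment(reference={ref}))"
        p_rank = frame["timepoint"].nunique()
    else:
        formula = f"{value_col} ~ score"
        p_rank = 2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, frame, groups=frame["participant"])
        try:
            fit = model.fit(reml=True, method="lbfgs")
            if not np.all(np.isfinite(fit.bse_fe)):
                raise ValueError("non-finite SE")
        except Exception:
            fit = model.fit(reml=True, method="powell")
    if not np.isfinite(fit.scale) or fit.scale < 1e-12 * max(np.var(y), 1.0):
        raise SingularFitError("residual variance is (numerically) zero")

    n_obs = len(frame)
    df = n_obs - p_rank
    rows = []
    for name, est, se in zip(fit.fe_params.index, fit.fe_params, fit.bse_fe):
        term = _clean_term(name)
        t = est / se if se > 0 else 0.0
        rows.append((term, float(est), float(se), float(t), df,
                     _pvalue(t, df, spec.df_method)))
    coefs = pd.DataFrame(rows, columns=["term", "estimate", "se", "t", "df", "p"])
    return LMEFit(
        coefficients=coefs,
        subject_var=float(np.asarray(fit.cov_re).ravel()[0]),
        resid_var=float(fit.scale),
        n_obs=n_obs,
        n_participants=int(frame["participant"].nunique()),
    )


def _clean_term(name: str) -> str:
    if name == "Intercept":
        return "intercept"
    if name == "score":
        return "score"
    # e.g. C(timepoint, Treatment(reference=0))[T.3] -> time[3]
    if "[T." in name:
        return "time[" + name.split("[T.")[1].rstrip("]") + "]"
    return name


def contrast(frame: pd.DataFrame, spec: ModelSpec, pair: tuple[int, int],
             value_col: str = "value") -> pd.Series:
    """Adjacent-timepoint contrast by a releveled two-timepoint refit.

    Restricts the data to ``pair``, relevels to the earlier timepoint, refits
    the random-intercept model and returns the later-timepoint coefficient
    row (estimate, se, t, df, p).
    """
    lo, hi = sorted(pair)
    sub = frame.loc[frame["timepoint"].isin([lo, hi])].copy()
    if sub["timepoint"].nunique() < 2:
        raise ValueError(f"pair {pair} not present in data")
    # degenerate screens that the iterative fit cannot represent
    wide = sub.pivot_table(index="participant", columns="timepoint",
                           values=value_col, aggfunc="mean")
    if {lo, hi} <= set(wide.columns):
        d = (wide[hi] - wide[lo]).dropna().to_numpy(float)
        if len(d) >= 2 and float(np.std(d, ddof=1)) == 0.0:
            est = float(np.mean(d))
            t = 0.0 if est == 0.0 else float(np.sign(est) * np.inf)
            p = 1.0 if est == 0.0 else 0.0
            return pd.Series(
                {"term": f"time[{hi}]", "estimate": est, "se": 0.0,
                 "t": t, "df": len(sub) - 2, "p": p}
            )
    fit = fit_lme(sub, ModelSpec("time", reference_level=lo,
                                 df_method=spec.df_method), value_col)
    return fit.coef(f"time[{hi}]")


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t test on matched per-participant values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be matched (equal length)")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        m = float(np.mean(d))
        if m == 0.0:
            return TTestResult(0.0, n - 1, 1.0, n)
        return TTestResult(float(np.sign(m) * np.inf), n - 1, 0.0, n)
    res = stats.ttest_rel(x, y)
    return TTestResult(float(res.statistic), n - 1, float(res.pvalue), n)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def lme_time_contrasts(frame: pd.DataFrame, spec: ModelSpec | None = None,
                       value_col: str = "value") -> pd.DataFrame:
    """Baseline-referenced LME plus all adjacent/total period contrasts.

    Returns tidy rows for 0->3, 3->6 and 0->6 (those present in the data),
    each from a releveled two-timepoint refit.
    """
    spec = spec or ModelSpec("time")
    tps = sorted(frame["timepoint"].unique())
    rows = []
    for lo, hi in [(a, b) for i, a in enumerate(tps) for b in tps[i + 1:]]:
        row = contrast(frame, spec, (lo, hi), value_col)
        rows.append({"contrast": f"{lo}->{hi}", **row.to_dict()})
    return pd.DataFrame(rows)
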