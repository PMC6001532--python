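"""Rubin's-rules combination of per-imputation estimates.

With m point estimates Q_i and their variances U_i, the pooled estimate
is Qbar = mean(Q_i), the within-imputation variance W = mean(U_i), the
between-imputation variance B = var(Q_i), and the total variance
T = W + (1 + 1/m) B.  Intervals and tests use a t reference distribution
with the Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import ImputationRun

__all__ = ["PooledEstimate", "pool", "pooled_fit", "pooled_table"]


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool(
    estimates, variances, complete_df: float, level: float = 0.95
) -> PooledEstimate:
    """Combine m estimates and variances into one pooled estimate.

    *complete_df* is the complete-data degrees of freedom of the analysis
    (n minus the number of fitted parameters), used by the Barnard-Rubin
    adjustment.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    if len(u) != m:
        raise ValueError("estimates and variances must have equal length")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b

    lam = (1.0 + 1.0 / m) * b / t if t > 0 else 0.0
    df_obs = (complete_df + 1.0) / (complete_df + 3.0) * complete_df * (1.0 - lam)
    if b > 0:
        r = (1.0 + 1.0 / m) * b / w
        df_large = (m - 1.0) * (1.0 + 1.0 / r) ** 2
        df = 1.0 / (1.0 / df_large + 1.0 / df_obs)
    else:
        df = df_obs
    se = np.sqrt(t)
    if se > 0:
        crit = stats.t.ppf(0.5 + level / 2.0, df)
        p = 2.0 * stats.t.sf(abs(qbar) / se, df)
        lo, hi = qbar - crit * se, qbar + crit * se
    else:  # degenerate: all estimates identical with zero variance
        p = 0.0 if qbar != 0 else 1.0
        lo = hi = qbar
    return PooledEstimate(
        estimate=qbar,
        within_var=w,
        between_var=b,
        total_var=t,
        df=float(df),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        m=m,
    )


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and their variances (closed form)."""
    n, p = x.shape
    if n <= p:
        raise ValueError("fewer rows than parameters")
    xtx = x.T @ x
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise ValueError("singular design matrix") from None
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    s2 = float(resid @ resid) / (n - p)
    return beta, s2 * np.diag(xtx_inv)


def _design_for(run: ImputationRun, frame: pd.DataFrame, columns: list[str]):
    cols = [np.ones(len(frame))]
    for c in columns:
        if c in frame.columns:
            cols.append(frame[c].to_numpy(float))
        elif run.indicators is not None and c in run.indicators.columns:
            cols.append(run.indicators[c].to_numpy(float))
        else:
            raise ValueError(f"unknown regressor '{c}'")
    return np.column_stack(cols)


def pooled_fit(
    run: ImputationRun,
    outcome: str,
    regressors: list[str],
    level: float = 0.95,
) -> dict[str, PooledEstimate]:
    """Fit ``outcome ~ 1 + regressors`` on every completed dataset and
    pool coefficient-wise.

    Regressors may be substantive variables or missingness-indicator
    columns (``M_<var>``).  Returns one :class:`PooledEstimate` per term,
    keyed by ``"Intercept"`` and the regressor names.
    """
    terms = ["Intercept"] + list(regressors)
    ests = np.empty((run.m, len(terms)))
    vars_ = np.empty_like(ests)
    n = None
    for i, comp in enumerate(run.completed):
        frame = comp.values
        y = frame[outcome].to_numpy(float)
        x = _design_for(run, frame, list(regressors))
        n = len(y)
        try:
            beta, v = _ols(y, x)
        except ValueError as e:
            raise ValueError(f"fit failed in imputation {i + 1}: {e}") from None
        ests[i] = beta
        vars_[i] = v
    complete_df = n - len(terms)
    return {
        t: pool(ests[:, j], vars_[:, j], complete_df, level=level)
        for j, t in enumerate(terms)
    }


def pooled_table(fits: dict[str, PooledEstimate]) -> pd.DataFrame:
    """Arrange pooled estimates as a tidy table for export."""
    rows = [
        {
            "term": t,
            "estimate": e.estimate,
            "se": e.se,
            "df": e.df,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p": e.p_value,
        }
        for t, e in fits.items()
    ]
    return pd.DataFrame(rows)
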