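"""Chained-equations imputation: plain FCS and the not-at-random variant.

Each incomplete variable gets a univariate generalized linear imputation
model.  In the not-at-random mode the model additionally includes the
missingness indicators of the *other* incomplete variables as estimable
predictors, and the variable's *own* indicator carries a user-set offset
(the conditional sensitivity parameter, CSP): the model is fitted on the
rows where the target is observed — where the own indicator is constant
zero, so its coefficient cannot be estimated — and the offset is added to
the linear predictor of the missing rows only.

Imputation is "proper" in Rubin's sense: for the gaussian family the
residual variance is drawn from its scaled inverse-chi-square posterior
and the coefficients from their conditional normal posterior under the
noninformative prior, before each predictive draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .data_model import (
    CompletedDataset,
    IncompleteDataset,
    build_predictor_set,
    indicator_name,
)

__all__ = [
    "NarfcsModelSpec",
    "ImputationRun",
    "draw_linear_model",
    "impute_one_variable",
    "run_chained_equations",
    "narfcs_specs",
    "fcs_specs",
]

_FAMILIES = ("gaussian", "binomial")

#: lower bound on the drawn residual variance, to survive degenerate fits
RESIDUAL_VARIANCE_FLOOR = 1e-10


@dataclass(frozen=True)
class NarfcsModelSpec:
    """Imputation model for one incomplete variable.

    ``predictors`` lists the names of the model terms besides the
    intercept: other substantive variables and, in not-at-random mode,
    the estimable cross-indicators (``M_<other>`` columns).  The target's
    own indicator is never listed — it enters only through ``csp``, the
    offset (in units of the target for gaussian, log-odds for binomial)
    applied when predicting the missing rows.
    """

    target: str
    predictors: tuple[str, ...]
    csp: float = 0.0
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family '{self.family}'")
        if not np.isfinite(self.csp):
            raise ValueError("csp must be finite")
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.target in self.predictors:
            raise ValueError(f"'{self.target}' cannot predict itself")
        if indicator_name(self.target) in self.predictors:
            raise ValueError(
                "the target's own indicator is implicit (the CSP term); "
                "do not list it as a predictor"
            )

    def with_csp(self, csp: float) -> "NarfcsModelSpec":
        return replace(self, csp=float(csp))


@dataclass
class ImputationRun:
    """Result of one chained-equations run: *m* completed datasets.

    ``indicators`` carries the source data's missingness-indicator
    columns, so downstream model fits (for instance the marginal
    sensitivity-parameter regressions) can use them as regressors.
    """

    m: int
    cycles: int
    seed: int
    specs: list[NarfcsModelSpec]
    completed: list[CompletedDataset]
    variable_names: list[str] = field(default_factory=list)
    indicators: pd.DataFrame | None = None


def narfcs_specs(
    data: IncompleteDataset,
    csps: dict[str, float],
    families: dict[str, str] | None = None,
) -> list[NarfcsModelSpec]:
    """Default not-at-random model set: every other variable plus every
    estimable cross-indicator as predictors, one CSP per incomplete
    variable (missing entries of *csps* default to 0)."""
    families = families or {}
    specs = []
    for v in data.incomplete_variables:
        ps = build_predictor_set(v, data)
        specs.append(
            NarfcsModelSpec(
                target=v,
                predictors=tuple(ps.terms),
                csp=float(csps.get(v, 0.0)),
                family=families.get(v, "gaussian"),
            )
        )
    return specs


def fcs_specs(
    data: IncompleteDataset, families: dict[str, str] | None = None
) -> list[NarfcsModelSpec]:
    """Plain missing-at-random model set: other variables only, no
    indicator terms, all offsets zero."""
    families = families or {}
    return [
        NarfcsModelSpec(
            target=v,
            predictors=tuple(w for w in data.variable_names if w != v),
            csp=0.0,
            family=families.get(v, "gaussian"),
        )
        for v in data.incomplete_variables
    ]


def _aliased_columns(design: np.ndarray) -> list[int]:
    r = np.linalg.qr(design, mode="r")
    d = np.abs(np.diag(r))
    tol = d.max() * max(design.shape) * np.finfo(float).eps
    return [int(i) for i in np.flatnonzero(d <= tol)]


def draw_linear_model(
    outcome: np.ndarray, design: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One posterior draw of (coefficients, residual sd) for a linear model.

    Noninformative prior: sigma^2 ~ RSS / chi^2_(n-p), then
    beta ~ N(beta_hat, sigma^2 (X'X)^{-1}).  Returns the coefficient draw
    and the residual *standard deviation* draw.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError(
            f"too few observed rows ({n}) to fit {p} parameters properly"
        )
    xtx = x.T @ x
    try:
        chol = cho_factor(xtx, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        raise ValueError(
            "design matrix is rank deficient; aliased column indices: "
            f"{_aliased_columns(x)}"
        ) from None
    beta_hat = cho_solve(chol, x.T @ y, check_finite=False)
    resid = y - x @ beta_hat
    rss = float(resid @ resid)
    df = n - p
    sigma2 = max(rss / rng.chisquare(df), RESIDUAL_VARIANCE_FLOOR)
    # N(beta_hat, sigma2 * xtx^{-1}) via the Cholesky factor of xtx
    z = rng.standard_normal(p)
    beta = beta_hat + np.sqrt(sigma2) * solve_triangular(
        chol[0].T, z, lower=False, check_finite=False
    )
    return beta, float(np.sqrt(sigma2))


def _draw_logistic_model(
    outcome: np.ndarray, design: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Approximate posterior draw of logistic coefficients (normal
    approximation at the MLE), as in standard chained-equations software."""
    import statsmodels.api as sm

    n, p = design.shape
    if n < p + 2:
        raise ValueError(
            f"too few observed rows ({n}) to fit {p} parameters properly"
        )
    fit = sm.GLM(outcome, design, family=sm.families.Binomial()).fit()
    cov = np.asarray(fit.cov_params())
    beta_hat = np.asarray(fit.params)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    return beta_hat + chol @ rng.standard_normal(p)


class _EngineCore:
    """Precomputed column indices and row masks for one (data, specs) pair.

    Works on a single ndarray whose columns are the substantive variables
    followed by the indicator columns; indicator columns never change, and
    observed rows of each target are fixed, so only the predictor values
    of other incomplete variables vary across cycles.
    """

    def __init__(self, data: IncompleteDataset, specs: list[NarfcsModelSpec]):
        incomplete = set(data.incomplete_variables)
        targets = [s.target for s in specs]
        if set(targets) != incomplete or len(targets) != len(incomplete):
            raise ValueError(
                "specs must cover every incomplete variable exactly once; "
                f"got {sorted(targets)}, need {sorted(incomplete)}"
            )
        self.data = data
        self.specs = specs
        self.var_names = list(data.variable_names)
        self.ind_names = list(data.indicators.columns)
        self.col_index = {
            name: i for i, name in enumerate(self.var_names + self.ind_names)
        }
        vals = data.values.to_numpy(dtype=float)
        inds = data.indicators.to_numpy(dtype=float)
        self.base = np.concatenate([vals, inds], axis=1)
        self.n = self.base.shape[0]

        self.plan = []
        for spec in specs:
            tcol = self.col_index[spec.target]
            missing = np.isnan(vals[:, tcol])
            obs_idx = np.flatnonzero(~missing)
            mis_idx = np.flatnonzero(missing)
            try:
                pred_cols = np.array(
                    [self.col_index[t] for t in spec.predictors], dtype=np.intp
                )
            except KeyError as e:
                raise ValueError(
                    f"unknown predictor {e} in the model for '{spec.target}'"
                ) from None
            self.plan.append((spec, tcol, obs_idx, mis_idx, pred_cols))

    def _update_variable(
        self, work: np.ndarray, item, rng: np.random.Generator
    ) -> None:
        spec, tcol, obs_idx, mis_idx, pred_cols = item
        if len(mis_idx) == 0:
            return
        p = len(pred_cols) + 1
        x_obs = np.empty((len(obs_idx), p))
        x_obs[:, 0] = 1.0
        x_obs[:, 1:] = work[np.ix_(obs_idx, pred_cols)]
        y_obs = work[obs_idx, tcol]
        x_mis = np.empty((len(mis_idx), p))
        x_mis[:, 0] = 1.0
        x_mis[:, 1:] = work[np.ix_(mis_idx, pred_cols)]
        if spec.family == "gaussian":
            beta, sigma = draw_linear_model(y_obs, x_obs, rng)
            mu = x_mis @ beta + spec.csp
            work[mis_idx, tcol] = mu + sigma * rng.standard_normal(len(mis_idx))
        else:
            beta = _draw_logistic_model(y_obs, x_obs, rng)
            prob = expit(x_mis @ beta + spec.csp)
            work[mis_idx, tcol] = (rng.random(len(mis_idx)) < prob).astype(float)

    def run_one(self, cycles: int, rng: np.random.Generator) -> np.ndarray:
        work = self.base.copy()
        # initial fill: sample with replacement from each variable's
        # observed values
        for spec, tcol, obs_idx, mis_idx, _ in self.plan:
            if len(mis_idx):
                work[mis_idx, tcol] = rng.choice(
                    work[obs_idx, tcol], size=len(mis_idx), replace=True
                )
        for cycle in range(cycles):
            for item in self.plan:
                try:
                    self._update_variable(work, item, rng)
                except ValueError as e:
                    raise RuntimeError(
                        f"imputation failed for '{item[0].target}' in cycle "
                        f"{cycle + 1}: {e}"
                    ) from e
        return work[:, : len(self.var_names)]


def impute_one_variable(
    current: pd.DataFrame, spec: NarfcsModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw new values for the target's missing cells given a table in
    which every predictor is currently filled in.

    *current* must contain the target (with its missing cells as NaN or
    currently imputed — the rows to refill are taken from the indicator
    column ``M_<target>``), every predictor column, and the target's own
    indicator column.
    """
    own = indicator_name(spec.target)
    if own not in current.columns:
        raise ValueError(f"current table lacks the indicator column '{own}'")
    mis = current[own].to_numpy() == 1
    obs = ~mis
    cols = list(spec.predictors)
    x_obs = np.column_stack(
        [np.ones(obs.sum())] + [current.loc[obs, c].to_numpy(float) for c in cols]
    )
    x_mis = np.column_stack(
        [np.ones(mis.sum())] + [current.loc[mis, c].to_numpy(float) for c in cols]
    )
    y_obs = current.loc[obs, spec.target].to_numpy(float)
    if spec.family == "gaussian":
        beta, sigma = draw_linear_model(y_obs, x_obs, rng)
        return x_mis @ beta + spec.csp + sigma * rng.standard_normal(mis.sum())
    beta = _draw_logistic_model(y_obs, x_obs, rng)
    prob = expit(x_mis @ beta + spec.csp)
    return (rng.random(mis.sum()) < prob).astype(float)


def run_chained_equations(
    data: IncompleteDataset,
    specs: list[NarfcsModelSpec],
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
) -> ImputationRun:
    """Produce *m* completed datasets by chained-equations imputation.

    Each imputation starts from a random fill (sampling each variable's
    observed values with replacement), then updates the incomplete
    variables in spec order for *cycles* passes.  A master seed spawns one
    independent random sub-stream per imputation, so results are
    reproducible and independent of how the m imputations are scheduled.
    """
    if m < 1 or cycles < 1:
        raise ValueError("m and cycles must both be at least 1")
    core = _EngineCore(data, specs)
    children = np.random.SeedSequence(seed).spawn(m)
    completed = []
    miss_mask = data.values.isna()
    for child in children:
        arr = core.run_one(cycles, np.random.default_rng(child))
        frame = pd.DataFrame(arr, columns=core.var_names)
        completed.append(
            CompletedDataset(values=frame, provenance_mask=miss_mask.copy())
        )
    return ImputationRun(
        m=m,
        cycles=cycles,
        seed=seed,
        specs=list(specs),
        completed=completed,
        variable_names=core.var_names,
        indicators=data.indicators.copy(),
    )
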