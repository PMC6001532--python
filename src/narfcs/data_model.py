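"""Tabular data representation with missingness masks and indicator columns.

An incomplete dataset is a subjects-by-variables numeric table in which
some cells are missing.  For every incomplete variable ``v`` a binary
missingness indicator column ``M_v`` is derived (1 = missing), which the
not-at-random imputation models use both as auxiliary predictors and as
the carrier of the sensitivity-parameter offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncompleteDataset",
    "CompletedDataset",
    "PredictorSet",
    "attach_missingness_indicators",
    "build_predictor_set",
    "indicator_name",
    "read_incomplete_csv",
    "write_completed_csv",
]

#: values treated as missing when reading delimited text
NA_VALUES = ["", "NA"]

#: default condition-number bound above which a cross-indicator is
#: declared inestimable on the target's observed rows
DEFAULT_CONDITION_THRESHOLD = 1e8


def indicator_name(variable: str) -> str:
    """Name of the missingness-indicator column for *variable*."""
    return f"M_{variable}"


@dataclass
class IncompleteDataset:
    """A numeric table with missing cells plus derived indicator columns.

    Attributes
    ----------
    values : pandas.DataFrame
        Subjects x variables, missing entries as NaN.
    variable_names : list of str
        Column order of ``values``.
    complete_mask : dict
        Maps variable name -> True when the column has no missing entries
        (a fully observed covariate).
    indicators : pandas.DataFrame
        One 0/1 integer column per incomplete variable, named ``M_<var>``,
        with 1 exactly where the variable is missing.
    truth : pandas.DataFrame or None
        Optional pre-masking values kept by the synthetic generator for
        oracle checks only; never consulted by the imputation engine.
    """

    values: pd.DataFrame
    variable_names: list[str]
    complete_mask: dict[str, bool]
    indicators: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def incomplete_variables(self) -> list[str]:
        return [v for v in self.variable_names if not self.complete_mask[v]]

    @property
    def complete_variables(self) -> list[str]:
        return [v for v in self.variable_names if self.complete_mask[v]]


@dataclass
class CompletedDataset:
    """A fully filled-in copy of an :class:`IncompleteDataset`.

    ``provenance_mask`` is True exactly where a cell was imputed; observed
    cells are carried over unchanged from the source data.
    """

    values: pd.DataFrame
    provenance_mask: pd.DataFrame


@dataclass
class PredictorSet:
    """Imputation-model terms for one incomplete target variable.

    ``predictors`` lists the other substantive variables and covariates;
    ``cross_indicators`` the other variables' missingness indicators whose
    coefficients are estimable on the target's observed rows;
    ``csp_term`` the target's own indicator, always retained, whose
    coefficient is the (inestimable) conditional sensitivity parameter;
    ``dropped_indicators`` the cross-indicators removed as inestimable.
    """

    target: str
    predictors: list[str]
    cross_indicators: list[str]
    csp_term: str
    dropped_indicators: list[str]

    @property
    def terms(self) -> list[str]:
        """All model terms except the intercept and the CSP term."""
        return self.predictors + self.cross_indicators


def _validate_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        s = df[col]
        if not pd.api.types.is_numeric_dtype(s):
            coerced = pd.to_numeric(s, errors="coerce")
            # values that were present but not numeric become NaN: reject
            bad = coerced.isna() & s.notna()
            if bad.any():
                raise ValueError(
                    f"variable '{col}' contains non-numeric values "
                    "(only continuous and binary 0/1 variables are supported)"
                )
            s = coerced
        out[col] = s.astype(float)
    return pd.DataFrame(out, index=df.index)


def attach_missingness_indicators(data: pd.DataFrame) -> IncompleteDataset:
    """Build an :class:`IncompleteDataset` from a raw table.

    Creates one indicator column per incomplete variable and flags fully
    observed variables as complete.  Raises ``ValueError`` for an empty
    table or for a variable with no observed values at all.
    """
    if len(data) == 0:
        raise ValueError("dataset has zero rows")
    df = _validate_numeric(data.reset_index(drop=True))
    complete_mask: dict[str, bool] = {}
    indicators = {}
    for col in df.columns:
        miss = df[col].isna()
        if miss.all():
            raise ValueError(f"variable '{col}' is entirely missing")
        complete_mask[col] = bool(~miss.any())
        if miss.any():
            indicators[indicator_name(col)] = miss.astype(np.int64)
    return IncompleteDataset(
        values=df,
        variable_names=list(df.columns),
        complete_mask=complete_mask,
        indicators=pd.DataFrame(indicators, index=df.index),
    )


def build_predictor_set(
    target: str,
    data: IncompleteDataset,
    condition_threshold: float = DEFAULT_CONDITION_THRESHOLD,
) -> PredictorSet:
    """Assemble the imputation-model terms for one incomplete variable.

    Every other substantive variable (complete or incomplete) enters as a
    predictor.  Every other incomplete variable's missingness indicator is
    included when its coefficient can be estimated from the rows where the
    target is observed: the indicator must be non-constant there and must
    not push the design matrix's condition number beyond
    *condition_threshold*.  The target's own indicator is always retained
    and tagged as the CSP term (it is constant on the fitting rows, so its
    coefficient is exactly the user-set sensitivity parameter).
    """
    if data.complete_mask[target]:
        raise ValueError(f"'{target}' is fully observed; nothing to impute")
    predictors = [v for v in data.variable_names if v != target]
    obs = ~data.values[target].isna().to_numpy()

    kept: list[str] = []
    dropped: list[str] = []
    # design so far: intercept + substantive predictors on the observed rows
    base_cols = [np.ones(obs.sum())]
    for v in predictors:
        col = data.values[v].to_numpy()[obs]
        base_cols.append(np.where(np.isnan(col), np.nanmean(col), col))
    for other in data.incomplete_variables:
        if other == target:
            continue
        ind = indicator_name(other)
        col = data.indicators[ind].to_numpy()[obs].astype(float)
        if col.min() == col.max():
            dropped.append(ind)
            continue
        trial = np.column_stack(base_cols + [col])
        if np.linalg.cond(trial) > condition_threshold:
            dropped.append(ind)
            continue
        base_cols.append(col)
        kept.append(ind)
    return PredictorSet(
        target=target,
        predictors=predictors,
        cross_indicators=kept,
        csp_term=indicator_name(target),
        dropped_indicators=dropped,
    )


def read_incomplete_csv(path) -> IncompleteDataset:
    """Read a headed CSV where empty fields or ``NA`` denote missing."""
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    return attach_missingness_indicators(df)


def write_completed_csv(completed: list[CompletedDataset], path) -> None:
    """Write the stacked imputations with an ``.imp`` index column."""
    frames = []
    for i, c in enumerate(completed, start=1):
        f = c.values.copy()
        f.insert(0, ".imp", i)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
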