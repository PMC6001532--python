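"""Calibration of conditional sensitivity parameters against marginal ones.

The offsets a not-at-random chained-equations imputation needs (CSPs) are
conditional on all other variables and missingness indicators, which
makes them nearly impossible to elicit from experts.  What experts *can*
state is a marginal sensitivity parameter (MSP): the mean difference
between missing and observed subjects on a variable, marginal on (at
least some of) the others — the own-indicator coefficient of a simple
pattern-mixture regression, the "MSP model".

Calibration searches for the CSP whose imputations, when the MSP model
is fitted to them by pooled regression, reproduce the elicited MSP:

* a grid sweep for elicited *ranges*, which also supports tipping-point
  analysis and an empirical check of the one-at-a-time assumption;
* a joint coarse-to-fine search for elicited *points* on all variables
  at once;
* a one-variable-at-a-time bisection-style search, valid when the
  CSP-MSP relationship of each variable does not depend on the other
  variables' CSPs (as for Gaussian data).

Every sweep reuses one fixed random seed, so the achieved-MSP surface is
a deterministic function of the test vector and searches converge
cleanly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import IncompleteDataset, indicator_name
from .engine import NarfcsModelSpec, run_chained_equations
from .pooling import PooledEstimate, pooled_fit

__all__ = [
    "MspModelSpec",
    "AnalysisSpec",
    "GridRecord",
    "CalibrationResult",
    "OneAtATimeCheck",
    "algorithm1_grid",
    "algorithm2_joint",
    "algorithm3_one_at_a_time",
    "check_one_at_a_time",
    "generalized_curve",
]

DEFAULT_TOLERANCE = 0.001
DEFAULT_TEST_VALUES = 10


@dataclass(frozen=True)
class MspModelSpec:
    """A pattern-mixture regression whose own-indicator coefficient is
    the marginal sensitivity parameter.

    With empty ``conditioning_terms`` this is the fully marginal form
    ``Y_j ~ 1 + M_j``; extra terms give partially conditional MSPs.
    """

    outcome: str
    conditioning_terms: tuple[str, ...] = ()

    @property
    def msp_term(self) -> str:
        return indicator_name(self.outcome)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conditioning_terms", tuple(self.conditioning_terms)
        )
        if self.outcome in self.conditioning_terms:
            raise ValueError("MSP model cannot condition on its own outcome")


@dataclass(frozen=True)
class AnalysisSpec:
    """The substantive analysis: a pooled regression and the term whose
    coefficient is the effect of interest ("Intercept" by default)."""

    outcome: str
    regressors: tuple[str, ...] = ()
    term: str = "Intercept"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regressors", tuple(self.regressors))
        if self.term != "Intercept" and self.term not in self.regressors:
            raise ValueError(f"term '{self.term}' is not among the regressors")


@dataclass
class GridRecord:
    csps: dict[str, float]
    msp_estimates: dict[str, PooledEstimate]
    effect: PooledEstimate | None = None
    failed: str | None = None

    @property
    def msp_values(self) -> dict[str, float]:
        return {k: v.estimate for k, v in self.msp_estimates.items()}


@dataclass
class CalibrationResult:
    grid: list[GridRecord]
    calibrated: list[dict[str, float]] = field(default_factory=list)
    primary: dict[str, float] | None = None
    tolerance: dict[str, float] | None = None
    trace: list[dict] = field(default_factory=list)
    converged: bool = True
    range_covered: dict[str, bool] | None = None
    recommendation: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.grid:
            row = {f"csp_{v}": x for v, x in rec.csps.items()}
            for v, e in rec.msp_estimates.items():
                row[f"msp_{v}"] = e.estimate
            if rec.effect is not None:
                row["effect"] = rec.effect.estimate
                row["ci_low"] = rec.effect.ci_low
                row["ci_high"] = rec.effect.ci_high
                row["p"] = rec.effect.p_value
            row["failed"] = rec.failed
            rows.append(row)
        return pd.DataFrame(rows)


def _evaluate_vector(
    data: IncompleteDataset,
    narfcs_specs: list[NarfcsModelSpec],
    csps: dict[str, float],
    msp_specs: list[MspModelSpec],
    analysis_spec: AnalysisSpec | None,
    m: int,
    cycles: int,
    seed: int,
) -> GridRecord:
    specs = [s.with_csp(csps[s.target]) if s.target in csps else s
             for s in narfcs_specs]
    run = run_chained_equations(data, specs, m=m, cycles=cycles, seed=seed)
    msp_estimates = {}
    for ms in msp_specs:
        fits = pooled_fit(
            run, ms.outcome, list(ms.conditioning_terms) + [ms.msp_term]
        )
        msp_estimates[ms.outcome] = fits[ms.msp_term]
    effect = None
    if analysis_spec is not None:
        fits = pooled_fit(run, analysis_spec.outcome, list(analysis_spec.regressors))
        effect = fits[analysis_spec.term]
    return GridRecord(csps=dict(csps), msp_estimates=msp_estimates, effect=effect)


def sweep(
    data,
    narfcs_specs,
    vectors: list[dict[str, float]],
    msp_specs,
    analysis_spec,
    m,
    cycles,
    seed,
) -> list[GridRecord]:
    """Evaluate a list of CSP test vectors under one fixed seed each."""
    records = []
    for csps in vectors:
        try:
            rec = _evaluate_vector(
                data, narfcs_specs, csps, msp_specs, analysis_spec, m, cycles, seed
            )
        except (ValueError, RuntimeError) as e:
            rec = GridRecord(csps=dict(csps), msp_estimates={}, failed=str(e))
        records.append(rec)
    return records


def _cartesian(csp_test_values: dict[str, list[float]]) -> list[dict[str, float]]:
    names = list(csp_test_values)
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(csp_test_values[v] for v in names))
    ]


def algorithm1_grid(
    data: IncompleteDataset,
    narfcs_specs: list[NarfcsModelSpec],
    msp_specs: list[MspModelSpec],
    csp_test_values: dict[str, list[float]],
    analysis_spec: AnalysisSpec | None = None,
    elicited_ranges: dict[str, tuple[float, float]] | None = None,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
) -> CalibrationResult:
    """Grid sweep over every combination of CSP test values.

    For each test vector the data are imputed under one fixed seed, the
    MSP models are fitted by pooled regression, and (optionally) the
    effect of interest is estimated from the same imputed data.  When
    elicited MSP ranges are given, the result flags per variable whether
    the achieved MSP estimates span the elicited range, with a
    recommendation to widen or recenter the test range when not.
    """
    for v, vals in csp_test_values.items():
        if len(vals) < 1:
            raise ValueError(f"no test values supplied for '{v}'")
    records = sweep(
        data, narfcs_specs, _cartesian(csp_test_values), msp_specs,
        analysis_spec, m, cycles, seed,
    )
    covered = None
    recommendation = None
    if elicited_ranges:
        covered, missing = {}, []
        for v, (lo, hi) in elicited_ranges.items():
            achieved = [
                r.msp_values[v] for r in records if not r.failed and v in r.msp_values
            ]
            ok = bool(achieved) and min(achieved) <= lo and hi <= max(achieved)
            covered[v] = ok
            if not ok:
                missing.append(v)
        if missing:
            recommendation = (
                "achieved MSP ranges do not cover the elicited ranges for "
                f"{missing}; widen or recenter their CSP test ranges and rerun"
            )
    return CalibrationResult(
        grid=records, range_covered=covered, recommendation=recommendation
    )


@dataclass
class OneAtATimeCheck:
    """Empirical screen for the one-at-a-time assumption: the gap between
    a variable's CSP and its achieved MSP should not move when the other
    variables' CSPs move."""

    spreads: dict[str, float]
    threshold: float
    passed: bool


def check_one_at_a_time(
    result: CalibrationResult, threshold: float = 0.1
) -> OneAtATimeCheck:
    """Max cross-setting spread of (CSP - achieved MSP) per variable.

    For each variable and each of its CSP test values, collects the
    deviation across all settings of the other CSPs and reports the
    largest spread.  Requires a grid with at least two settings of the
    other variables for some variable.
    """
    records = [r for r in result.grid if not r.failed]
    if not records:
        raise ValueError("grid contains no successful evaluations")
    variables = list(records[0].csps)
    spreads: dict[str, float] = {}
    for v in variables:
        groups: dict[float, list[float]] = {}
        for r in records:
            if v not in r.msp_values:
                continue
            groups.setdefault(r.csps[v], []).append(r.csps[v] - r.msp_values[v])
        per_group = [max(g) - min(g) for g in groups.values() if len(g) >= 2]
        if per_group:
            spreads[v] = max(per_group)
    if not spreads:
        raise ValueError(
            "grid covers a single setting of the other CSPs for every "
            "variable; a cross-setting comparison needs at least two"
        )
    passed = all(s <= threshold for s in spreads.values())
    return OneAtATimeCheck(spreads=spreads, threshold=threshold, passed=passed)


def _standardized_miss(
    rec: GridRecord, elicited: dict[str, float], tol: dict[str, float]
) -> float:
    return max(
        abs(rec.msp_values[v] - elicited[v]) / tol[v] for v in elicited
    )


def algorithm2_joint(
    data: IncompleteDataset,
    narfcs_specs: list[NarfcsModelSpec],
    msp_specs: list[MspModelSpec],
    elicited_points: dict[str, float],
    tolerances: dict[str, float],
    initial_grids: dict[str, list[float]],
    analysis_spec: AnalysisSpec | None = None,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
    max_rounds: int = 10,
) -> CalibrationResult:
    """Joint coarse-to-fine search for the CSP vector matching all
    elicited MSP points at once.

    Each round sweeps the current Cartesian grid; if some vector's MSP
    estimates all lie within tolerance it is accepted (all qualifying
    vectors are returned, the one with the smallest worst
    tolerance-standardized deviation designated primary).  Otherwise the
    grid contracts around the nearest vector and the sweep repeats, up to
    *max_rounds*; an unconverged search is returned flagged with the
    nearest vector found.
    """
    if any(t <= 0 for t in tolerances.values()):
        raise ValueError("tolerances must be positive")
    grids = {v: sorted(vals) for v, vals in initial_grids.items()}
    trace: list[dict] = []
    all_records: list[GridRecord] = []
    for round_no in range(1, max_rounds + 1):
        res = algorithm1_grid(
            data, narfcs_specs, msp_specs, grids, analysis_spec,
            m=m, cycles=cycles, seed=seed,
        )
        ok = [r for r in res.grid if not r.failed]
        all_records.extend(res.grid)
        trace.append({"round": round_no, "grids": {v: list(g) for v, g in grids.items()}})
        qualifying = [
            r for r in ok
            if all(
                abs(r.msp_values[v] - elicited_points[v]) <= tolerances[v]
                for v in elicited_points
            )
        ]
        if qualifying:
            qualifying.sort(
                key=lambda r: _standardized_miss(r, elicited_points, tolerances)
            )
            return CalibrationResult(
                grid=all_records,
                calibrated=[dict(r.csps) for r in qualifying],
                primary=dict(qualifying[0].csps),
                tolerance=dict(tolerances),
                trace=trace,
                converged=True,
            )
        if not ok:
            raise RuntimeError("every grid point failed to impute")
        best = min(ok, key=lambda r: _standardized_miss(r, elicited_points, tolerances))
        new_grids = {}
        for v, g in grids.items():
            if len(g) == 1:
                new_grids[v] = g
                continue
            i = g.index(best.csps[v])
            lo = g[max(i - 1, 0)]
            hi = g[min(i + 1, len(g) - 1)]
            new_grids[v] = list(np.linspace(lo, hi, len(g)))
        grids = new_grids
    nearest = min(
        (r for r in all_records if not r.failed),
        key=lambda r: _standardized_miss(r, elicited_points, tolerances),
    )
    return CalibrationResult(
        grid=all_records,
        calibrated=[],
        primary=dict(nearest.csps),
        tolerance=dict(tolerances),
        trace=trace,
        converged=False,
        recommendation=(
            "no test vector met the tolerances within the round budget; "
            "nearest vector reported — widen the grids or relax tolerances"
        ),
    )


def algorithm3_one_at_a_time(
    data: IncompleteDataset,
    narfcs_specs: list[NarfcsModelSpec],
    msp_spec: MspModelSpec,
    elicited_value: float,
    initial_range: tuple[float, float],
    fixed_other_csps: dict[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    n_points: int = DEFAULT_TEST_VALUES,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
    max_rounds: int = 10,
) -> CalibrationResult:
    """Calibrate one variable's CSP to a single elicited MSP value.

    Valid under the one-at-a-time assumption.  The other variables' CSPs
    stay fixed (by default at their elicited MSP values supplied in
    *fixed_other_csps*).  Each round evaluates the achieved MSP at
    *n_points* regularly spaced test values under one fixed seed, brackets
    the elicited value between the two nearest achieved MSPs, and re-grids
    inside the bracket until the bracket's achieved MSPs agree to within
    *tolerance*; the test value whose achieved MSP is closest to the
    elicited value is the calibrated CSP.
    """
    target = msp_spec.outcome
    lo, hi = initial_range
    if not lo < hi:
        raise ValueError("initial_range must be a nonempty (low, high) interval")
    fixed = dict(fixed_other_csps or {})
    fixed.pop(target, None)
    cache: dict[float, float] = {}
    trace: list[dict] = []
    all_records: list[GridRecord] = []

    def achieved(value: float) -> float:
        if value not in cache:
            rec = _evaluate_vector(
                data, narfcs_specs, {**fixed, target: value}, [msp_spec],
                None, m, cycles, seed,
            )
            all_records.append(rec)
            cache[value] = rec.msp_values[target]
        return cache[value]

    for round_no in range(1, max_rounds + 1):
        grid = np.linspace(lo, hi, n_points)
        msps = np.array([achieved(v) for v in grid])
        trace.append({"round": round_no, "grid": grid.tolist(), "msp": msps.tolist()})
        below = msps <= elicited_value
        above = msps >= elicited_value
        if round_no == 1 and not (below.any() and above.any()):
            raise ValueError(
                f"elicited MSP {elicited_value} lies outside the achieved "
                f"range [{msps.min():.4g}, {msps.max():.4g}]; widen "
                "initial_range and rerun"
            )
        # bracket: the two test values whose achieved MSPs are nearest the
        # elicited value from either side
        i_lo = int(np.argmin(np.where(below, elicited_value - msps, np.inf)))
        i_hi = int(np.argmin(np.where(above, msps - elicited_value, np.inf)))
        if not (below.any() and above.any()):
            # refined interval overshot (possible under non-monotone noise):
            # fall back to the nearest point
            i_lo = i_hi = int(np.argmin(np.abs(msps - elicited_value)))
        best = int(np.argmin(np.abs(msps - elicited_value)))
        if abs(msps[i_lo] - msps[i_hi]) <= tolerance or i_lo == i_hi:
            return CalibrationResult(
                grid=all_records,
                calibrated=[{target: float(grid[best])}],
                primary={target: float(grid[best])},
                tolerance={target: tolerance},
                trace=trace,
                converged=True,
            )
        lo, hi = sorted((float(grid[i_lo]), float(grid[i_hi])))
    best_rec = min(
        all_records, key=lambda r: abs(r.msp_values[target] - elicited_value)
    )
    return CalibrationResult(
        grid=all_records,
        calibrated=[],
        primary={target: best_rec.csps[target]},
        tolerance={target: tolerance},
        trace=trace,
        converged=False,
        recommendation="bracket did not converge within max_rounds",
    )


def generalized_curve(
    data: IncompleteDataset,
    narfcs_specs: list[NarfcsModelSpec],
    csp_test_values: dict[str, list[float]],
    summary_fn,
    analysis_spec: AnalysisSpec,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration curve of the effect of interest against any summary.

    Same fixed-seed sweep as the grid algorithm, but instead of fitting
    an MSP model, ``summary_fn(completed_values)`` is evaluated on each
    completed dataset and averaged over imputations — useful when an
    interpretable statistic (a marginal mean, say) replaces the MSP.
    Returns a table of (CSP values, summary, effect, CI, p) for plotting.
    """
    rows = []
    for csps in _cartesian(csp_test_values):
        specs = [s.with_csp(csps[s.target]) if s.target in csps else s
                 for s in narfcs_specs]
        run = run_chained_equations(data, specs, m=m, cycles=cycles, seed=seed)
        s_hat = float(np.mean([summary_fn(c.values) for c in run.completed]))
        effect = pooled_fit(
            run, analysis_spec.outcome, list(analysis_spec.regressors)
        )[analysis_spec.term]
        row = {f"csp_{v}": x for v, x in csps.items()}
        row.update(
            summary=s_hat,
            effect=effect.estimate,
            ci_low=effect.ci_low,
            ci_high=effect.ci_high,
            p=effect.p_value,
        )
        rows.append(row)
    return pd.DataFrame(rows)
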