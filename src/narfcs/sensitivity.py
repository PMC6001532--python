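"""Tipping-point analysis and the Monte Carlo evaluation harness.

Tipping-point analysis sweeps the sensitivity-parameter grid, records the
pooled effect of interest and its p-value at every vector, and reports
the smallest-magnitude offset at which the significance conclusion flips.

The simulation harness evaluates three ways of choosing the offsets on
data from the Gaussian pattern-mixture process — the analytically true
CSPs, the (incorrect) insertion of MSPs as if they were CSPs, and CSPs
calibrated one at a time against the true MSPs — scoring each by bias,
empirical standard error and 95% confidence-interval coverage of the two
marginal means, with Monte Carlo errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    AnalysisSpec,
    MspModelSpec,
    algorithm3_one_at_a_time,
    sweep,
    _cartesian,
)
from .engine import NarfcsModelSpec, narfcs_specs, run_chained_equations
from .gaussian_pm import GaussianPmParams, full_conditionals, marginal_means
from .pooling import pooled_fit
from .synthetic import simulate_pm

__all__ = [
    "TippingPointResult",
    "calibrate_for_process",
    "SimulationMetrics",
    "tipping_point",
    "compute_metrics",
    "run_simulation_study",
    "METHODS",
]

METHODS = ("true_csps", "insert_msps", "calibrated")


@dataclass
class TippingPointResult:
    grid: pd.DataFrame
    tipping_points: dict[str, dict]
    alpha: float
    baseline_significant: bool | None
    flags: list[str] = field(default_factory=list)


def tipping_point(
    data,
    specs: list[NarfcsModelSpec],
    analysis_spec: AnalysisSpec,
    csp_grids: dict[str, list[float]],
    alpha: float = 0.05,
    msp_specs: list[MspModelSpec] | None = None,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
) -> TippingPointResult:
    """Sweep the CSP grid and locate where significance flips.

    The baseline cell holds every axis at its smallest-magnitude grid
    value (the nearest-to-zero, MAR-adjacent setting).  Along each axis —
    other axes held at baseline — the tipping point is the first grid
    value, in order of increasing distance from baseline, at which the
    pooled p-value crosses *alpha* relative to the baseline conclusion.
    Tipping CSPs are mapped to achieved MSPs when MSP models are given.
    The full (CSP vector, effect, CI, p) surface is returned for contour
    plotting.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    msp_specs = msp_specs or []
    vectors = _cartesian(csp_grids)
    records = sweep(
        data, specs, vectors, msp_specs, analysis_spec, m, cycles, seed
    )
    rows = []
    for rec in records:
        row = {f"csp_{v}": x for v, x in rec.csps.items()}
        if rec.failed:
            row["failed"] = rec.failed
        else:
            row.update(
                effect=rec.effect.estimate,
                ci_low=rec.effect.ci_low,
                ci_high=rec.effect.ci_high,
                p=rec.effect.p_value,
            )
            for v, e in rec.msp_estimates.items():
                row[f"msp_{v}"] = e.estimate
        rows.append(row)
    grid_df = pd.DataFrame(rows)

    by_vector = {
        tuple(rec.csps[v] for v in csp_grids): rec
        for rec in records
        if not rec.failed
    }
    baseline = {v: min(g, key=abs) for v, g in csp_grids.items()}
    base_rec = by_vector.get(tuple(baseline[v] for v in csp_grids))
    base_sig = None if base_rec is None else bool(base_rec.effect.p_value < alpha)

    flags: list[str] = []
    tips: dict[str, dict] = {}
    for v, g in csp_grids.items():
        if len(g) < 2:
            flags.append(f"axis '{v}' has a single grid value; no tipping detectable")
            continue
        if base_sig is None:
            flags.append("baseline cell failed; tipping undefined")
            break
        ordered = sorted(g, key=lambda x: (abs(x - baseline[v]), abs(x)))
        for val in ordered[1:]:
            key = tuple(val if w == v else baseline[w] for w in csp_grids)
            rec = by_vector.get(key)
            if rec is None:
                continue
            if (rec.effect.p_value < alpha) != base_sig:
                tip = {"csp": val, "p": rec.effect.p_value}
                if v in rec.msp_values:
                    tip["msp"] = rec.msp_values[v]
                tips[v] = tip
                break
    return TippingPointResult(
        grid=grid_df,
        tipping_points=tips,
        alpha=alpha,
        baseline_significant=base_sig,
        flags=flags,
    )


def compute_metrics(
    estimates, ci_lows, ci_highs, truth: float
) -> dict[str, float]:
    """Bias, empirical SE and coverage of one estimator across replicates.

    Monte Carlo errors: bias MCE = empSE/sqrt(R); empSE MCE =
    empSE/sqrt(2(R-1)); coverage MCE = 100*sqrt(p(1-p)/R) at the observed
    coverage proportion p.  With fewer than two replicates the SE-based
    quantities are undefined (NaN) and the row is flagged.
    """
    est = np.asarray(estimates, dtype=float)
    lo = np.asarray(ci_lows, dtype=float)
    hi = np.asarray(ci_highs, dtype=float)
    if not len(est) == len(lo) == len(hi):
        raise ValueError("estimates and CI bounds must have equal length")
    r = len(est)
    if r == 0:
        raise ValueError("no replicates")
    bias = float(est.mean() - truth)
    covered = (lo <= truth) & (truth <= hi)
    coverage = 100.0 * float(covered.mean())
    p_hat = covered.mean()
    out = {
        "true_value": truth,
        "bias": bias,
        "coverage_pct": coverage,
        "mc_error_coverage": 100.0 * float(np.sqrt(p_hat * (1 - p_hat) / r)),
        "n_reps": r,
    }
    if r >= 2:
        emp_se = float(est.std(ddof=1))
        out["empirical_se"] = emp_se
        out["mc_error_bias"] = emp_se / np.sqrt(r)
        out["mc_error_se"] = emp_se / np.sqrt(2.0 * (r - 1))
        out["degenerate"] = False
    else:
        out["empirical_se"] = np.nan
        out["mc_error_bias"] = np.nan
        out["mc_error_se"] = np.nan
        out["degenerate"] = True
    return out


@dataclass
class SimulationMetrics:
    """Per method-and-parameter scores of the simulation study.

    ``table`` has one row per (method, parameter) with the true value,
    bias, empirical SE, coverage and their Monte Carlo errors;
    ``max_mc_error`` is the worst MC error per score column, with the
    coverage entry at the conservative worst case p = 0.5.
    """

    table: pd.DataFrame
    max_mc_error: dict[str, float]
    n_reps: int
    failures: int
    calibrated_csps: dict[str, float] | None = None

    def row(self, method: str, parameter: str) -> pd.Series:
        t = self.table
        sel = t[(t["method"] == method) & (t["parameter"] == parameter)]
        if len(sel) != 1:
            raise KeyError((method, parameter))
        return sel.iloc[0]


def calibrate_for_process(
    params: GaussianPmParams,
    n_calibration: int,
    tolerance: float,
    m: int,
    cycles: int,
    seed_seq: np.random.SeedSequence,
) -> dict[str, float]:
    """One-at-a-time calibration on a large auxiliary dataset drawn from
    the same process, targeting the process's true MSP values."""
    child, engine_seed = seed_seq.spawn(2)
    cal_data = simulate_pm(params, n_calibration, child)
    specs = narfcs_specs(cal_data, {})
    elicited = {"Y1": params.mu11, "Y2": params.mu22}
    sigma = {"Y1": params.sigma1, "Y2": params.sigma2}
    seed_int = int(engine_seed.generate_state(1)[0] % (2**31))
    out = {}
    for v in ("Y1", "Y2"):
        res = algorithm3_one_at_a_time(
            cal_data,
            specs,
            MspModelSpec(outcome=v),
            elicited_value=elicited[v],
            initial_range=(elicited[v] - 2.0 * sigma[v], elicited[v] + 2.0 * sigma[v]),
            fixed_other_csps={w: elicited[w] for w in elicited if w != v},
            tolerance=tolerance,
            m=m,
            cycles=cycles,
            seed=seed_int,
        )
        out[v] = res.primary[v]
    return out


def run_simulation_study(
    params: GaussianPmParams,
    n: int = 1000,
    n_reps: int = 1000,
    methods: tuple[str, ...] = METHODS,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
    n_calibration: int = 100_000,
    calibration_tolerance: float = 0.01,
    calibrate_per_replicate: bool = False,
    calibrated_csps: dict[str, float] | None = None,
) -> SimulationMetrics:
    """Three-arm Monte Carlo evaluation of CSP choice on pattern-mixture data.

    Per replicate and arm: simulate, impute by chained equations with the
    arm's CSPs (both cross-indicators included), fit intercept-only
    models for Y1 and Y2 on the completed data, pool by Rubin's rules,
    and record the estimate and 95% CI.  Arms: ``true_csps`` (analytic
    offsets), ``insert_msps`` (MSPs misused as CSPs), ``calibrated``
    (offsets from the one-at-a-time search; by default calibrated once on
    a large auxiliary dataset and reused, optionally re-calibrated per
    replicate).  Scores are computed against the analytic marginal means.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    cond1, cond2 = full_conditionals(params)
    truths = dict(zip(("Y1", "Y2"), marginal_means(params)))
    csps_by_method: dict[str, dict[str, float] | None] = {
        "true_csps": {"Y1": cond1.csp, "Y2": cond2.csp},
        "insert_msps": {"Y1": params.mu11, "Y2": params.mu22},
        "calibrated": None,
    }
    root = np.random.SeedSequence(seed)
    cal_seq, rep_root = root.spawn(2)
    if calibrated_csps is not None:
        csps_by_method["calibrated"] = dict(calibrated_csps)
    elif "calibrated" in methods and not calibrate_per_replicate:
        calibrated_csps = calibrate_for_process(
            params, n_calibration, calibration_tolerance, m, cycles, cal_seq
        )
        csps_by_method["calibrated"] = calibrated_csps

    results: dict[tuple[str, str], dict[str, list[float]]] = {
        (meth, v): {"est": [], "lo": [], "hi": []}
        for meth in methods
        for v in ("Y1", "Y2")
    }
    failures = 0
    rep_seeds = rep_root.spawn(n_reps)
    for rep, rep_seq in enumerate(rep_seeds):
        data_seq, *arm_seqs = rep_seq.spawn(1 + len(methods))
        data = simulate_pm(params, n, data_seq)
        try:
            base_specs = narfcs_specs(data, {})
            for meth, arm_seq in zip(methods, arm_seqs):
                csps = csps_by_method[meth]
                if csps is None:  # per-replicate calibration
                    csps = calibrate_for_process(
                        params, n_calibration, calibration_tolerance,
                        m, cycles, arm_seq.spawn(1)[0],
                    )
                specs = [s.with_csp(csps[s.target]) for s in base_specs]
                arm_seed = int(arm_seq.generate_state(1)[0] % (2**31))
                run = run_chained_equations(data, specs, m=m, cycles=cycles, seed=arm_seed)
                for v in ("Y1", "Y2"):
                    fit = pooled_fit(run, v, [])["Intercept"]
                    rec = results[(meth, v)]
                    rec["est"].append(fit.estimate)
                    rec["lo"].append(fit.ci_low)
                    rec["hi"].append(fit.ci_high)
        except (ValueError, RuntimeError):
            failures += 1
            continue
    if n_reps and failures / n_reps > 0.01:
        import warnings

        warnings.warn(
            f"{failures} of {n_reps} replicates failed and were excluded",
            stacklevel=2,
        )

    rows = []
    for meth in methods:
        for v in ("Y1", "Y2"):
            rec = results[(meth, v)]
            row = compute_metrics(rec["est"], rec["lo"], rec["hi"], truths[v])
            row.update(method=meth, parameter=f"E({v})")
            rows.append(row)
    table = pd.DataFrame(rows)[
        [
            "method", "parameter", "true_value", "bias", "empirical_se",
            "coverage_pct", "mc_error_bias", "mc_error_se",
            "mc_error_coverage", "n_reps", "degenerate",
        ]
    ]
    r_eff = int(table["n_reps"].min()) if len(table) else 0
    max_mc = {
        "bias": float(table["mc_error_bias"].max()),
        "empirical_se": float(table["mc_error_se"].max()),
        "coverage": 100.0 * float(np.sqrt(0.25 / r_eff)) if r_eff else np.nan,
    }
    return SimulationMetrics(
        table=table,
        max_mc_error=max_mc,
        n_reps=n_reps,
        failures=failures,
        calibrated_csps=calibrated_csps,
    )
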