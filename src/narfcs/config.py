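"""Run configuration and report plumbing for the command-line stages.

Configuration is YAML.  An imputation spec file looks like::

    data: trial.csv          # headed CSV; "" or NA denote missing
    m: 10                    # imputed datasets
    cycles: 10               # chained-equation passes
    seed: 1
    variables:               # one block per incomplete variable
      Y1: {family: gaussian, csp: -2.3, predictors: auto}
      Y2: {csp: -4.2}
    analysis: {outcome: Y1, regressors: [], term: Intercept}
    msp_models:
      Y1: {conditioning_terms: []}
    tolerance: 0.001

``predictors: auto`` (the default) builds the full not-at-random
predictor set: all other variables plus every estimable cross-indicator.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import AnalysisSpec, MspModelSpec
from .data_model import IncompleteDataset, read_incomplete_csv
from .engine import NarfcsModelSpec, narfcs_specs
from .gaussian_pm import GaussianPmParams

__all__ = ["RunConfig", "load_config", "load_pm_params", "write_report"]

_TOP_KEYS = {
    "data", "m", "cycles", "seed", "variables", "analysis", "msp_models",
    "tolerance", "level",
}
_VAR_KEYS = {"family", "csp", "predictors"}

DEFAULTS = {"m": 10, "cycles": 10, "seed": 0, "tolerance": 0.001, "level": 0.95}


@dataclass
class RunConfig:
    data_path: Path
    dataset: IncompleteDataset
    specs: list[NarfcsModelSpec]
    m: int
    cycles: int
    seed: int
    tolerance: float
    level: float
    analysis: AnalysisSpec | None
    msp_models: list[MspModelSpec] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse and validate a run configuration, applying defaults."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    if "data" not in raw:
        raise ValueError(f"{path}: required key 'data' is missing")
    data_path = Path(raw["data"])
    if not data_path.is_absolute():
        data_path = path.parent / data_path
    dataset = read_incomplete_csv(data_path)

    var_blocks = raw.get("variables", {}) or {}
    for v, block in var_blocks.items():
        if v not in dataset.variable_names:
            raise ValueError(f"{path}: unknown variable '{v}'")
        if dataset.complete_mask[v]:
            raise ValueError(
                f"{path}: '{v}' is fully observed; a sensitivity parameter "
                "cannot apply to a complete variable"
            )
        bad = set(block or {}) - _VAR_KEYS
        if bad:
            raise ValueError(f"{path}: unknown keys {sorted(bad)} for variable '{v}'")

    csps = {v: float((var_blocks.get(v) or {}).get("csp", 0.0))
            for v in dataset.incomplete_variables}
    families = {v: (var_blocks.get(v) or {}).get("family", "gaussian")
                for v in dataset.incomplete_variables}
    auto = narfcs_specs(dataset, csps, families)
    specs = []
    for s in auto:
        preds = (var_blocks.get(s.target) or {}).get("predictors", "auto")
        if preds == "auto":
            specs.append(s)
        else:
            specs.append(
                NarfcsModelSpec(
                    target=s.target, predictors=tuple(preds),
                    csp=s.csp, family=s.family,
                )
            )

    analysis = None
    if raw.get("analysis"):
        a = raw["analysis"]
        analysis = AnalysisSpec(
            outcome=a["outcome"],
            regressors=tuple(a.get("regressors", ())),
            term=a.get("term", "Intercept"),
        )
    msp_models = [
        MspModelSpec(outcome=v, conditioning_terms=tuple((b or {}).get("conditioning_terms", ())))
        for v, b in (raw.get("msp_models") or {}).items()
    ]
    merged = {**DEFAULTS, **{k: raw[k] for k in DEFAULTS if k in raw}}
    return RunConfig(
        data_path=data_path,
        dataset=dataset,
        specs=specs,
        m=int(merged["m"]),
        cycles=int(merged["cycles"]),
        seed=int(merged["seed"]),
        tolerance=float(merged["tolerance"]),
        level=float(merged["level"]),
        analysis=analysis,
        msp_models=msp_models,
        raw=raw,
    )


def load_pm_params(path) -> GaussianPmParams:
    """Read Gaussian pattern-mixture parameters from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GaussianPmParams(**raw)


#: column order of the exported metrics table
METRICS_COLUMNS = [
    "method", "parameter", "true_value", "bias", "empirical_se",
    "coverage_pct", "mc_error_bias", "mc_error_se", "mc_error_coverage",
]


def write_report(results: dict, out_dir, seed: int | None = None,
                 spec_hash: str | None = None) -> dict[str, Path]:
    """Write result tables plus a machine-readable run log.

    *results* maps a short name to a DataFrame (written as ``<name>.csv``)
    or to a JSON-serializable object (written into the run log).  The log
    records the master seed, spec hash and library versions needed for a
    bit-exact replay.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log: dict = {
        "seed": seed,
        "spec_hash": spec_hash,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "outputs": {},
    }
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            df = obj
            if set(METRICS_COLUMNS) <= set(df.columns):
                rest = [c for c in df.columns if c not in METRICS_COLUMNS]
                df = df[METRICS_COLUMNS + rest]
            dest = out / f"{name}.csv"
            df.to_csv(dest, index=False)
            written[name] = dest
            log["outputs"][name] = dest.name
        else:
            log["outputs"][name] = obj
    log_path = out / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    written["run_log"] = log_path
    return written
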