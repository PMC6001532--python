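"""Synthetic data from the bivariate Gaussian pattern-mixture process.

Draws independent Bernoulli missingness indicators, then the two outcomes
from the pattern-specific bivariate normal, then masks each Y where its
indicator is 1.  The pre-masking truth is retained on the returned
dataset for oracle checks only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import IncompleteDataset, attach_missingness_indicators
from .gaussian_pm import GaussianPmParams

__all__ = ["simulate_pm", "simulate_study"]


def _draw(params: GaussianPmParams, n: int, rng: np.random.Generator):
    p = params
    m1 = (rng.random(n) < p.pi1).astype(np.int64)
    m2 = (rng.random(n) < p.pi2).astype(np.int64)
    mean1 = p.mu10 + p.mu11 * m1 + p.mu12 * m2
    mean2 = p.mu20 + p.mu21 * m1 + p.mu22 * m2
    # bivariate normal via the Cholesky factor of the common covariance
    z = rng.standard_normal((n, 2))
    y1 = mean1 + p.sigma1 * z[:, 0]
    y2 = mean2 + p.sigma2 * (p.rho * z[:, 0] + (1.0 - p.rho**2) ** 0.5 * z[:, 1])
    return y1, y2, m1, m2


def simulate_pm(
    params: GaussianPmParams, n: int, seed: int | np.random.SeedSequence
) -> IncompleteDataset:
    """Simulate one dataset of *n* subjects and mask by its indicators.

    Degenerate patterns (a variable missing in every row or in none) are
    possible at tiny *n*; indicator construction requires at least one
    observed value per variable, so ``n`` should be large enough for the
    missingness probabilities in play.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    y1, y2, m1, m2 = _draw(params, n, rng)
    truth = pd.DataFrame({"Y1": y1, "Y2": y2, "M1": m1, "M2": m2})
    masked = pd.DataFrame(
        {
            "Y1": np.where(m1 == 1, np.nan, y1),
            "Y2": np.where(m2 == 1, np.nan, y2),
        }
    )
    ds = attach_missingness_indicators(masked)
    ds.truth = truth
    return ds


def simulate_study(
    params: GaussianPmParams, n: int, n_datasets: int, seed: int
) -> list[IncompleteDataset]:
    """Independent replicates via sub-streams spawned from the master seed."""
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    return [simulate_pm(params, n, child) for child in children]
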