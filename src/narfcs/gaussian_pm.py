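"""Bivariate-normal pattern-mixture model: exact conditionals and truths.

The model places a common bivariate-normal covariance over ``(Y1, Y2)``
within each missingness pattern, with pattern-specific mean shifts:

    E(Y1 | M) = mu10 + mu11*M1 + mu12*M2
    E(Y2 | M) = mu20 + mu21*M1 + mu22*M2
    Cov(Y | M) = [[s1^2, rho*s1*s2], [rho*s1*s2, s2^2]]

``mu11`` and ``mu22`` are the *marginal* sensitivity parameters (MSPs):
the mean shift of a variable between missing and observed subjects,
marginal on the other Y.  The *conditional* sensitivity parameters (CSPs)
that a chained-equations not-at-random imputation consumes are the
own-indicator coefficients of the implied full conditionals, which differ
from the MSPs whenever the two variables are correlated.  Every formula
here is written out coefficient by coefficient so each one can be tested
against a simulation-based regression oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GaussianPmParams",
    "ConditionalModel",
    "full_conditionals",
    "marginal_means",
    "dampening_csp",
]


@dataclass(frozen=True)
class GaussianPmParams:
    """Parameters of the two-variable Gaussian pattern-mixture model.

    ``mu10, mu20`` are the fully observed pattern means; ``mu11, mu21``
    the mean shifts when Y1 is missing; ``mu12, mu22`` the shifts when Y2
    is missing.  ``pi1, pi2`` are the independent Bernoulli missingness
    probabilities for Y1 and Y2.
    """

    mu10: float
    mu11: float
    mu12: float
    mu20: float
    mu21: float
    mu22: float
    sigma1: float
    sigma2: float
    rho: float
    pi1: float
    pi2: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        for name in ("pi1", "pi2"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ConditionalModel:
    """One full-conditional regression implied by the pattern mixture.

    The model for Y_j given the other Y and both indicators:

        Y_j | . ~ N(intercept + coef_other_y * Y_k
                    + coef_own_indicator * M_j
                    + coef_other_indicator * M_k,  residual_sd^2)

    ``coef_own_indicator`` is the conditional sensitivity parameter.
    """

    intercept: float
    coef_other_y: float
    coef_own_indicator: float
    coef_other_indicator: float
    residual_sd: float

    @property
    def csp(self) -> float:
        return self.coef_own_indicator


def full_conditionals(
    params: GaussianPmParams,
) -> tuple[ConditionalModel, ConditionalModel]:
    """Exact full conditionals of (Y1 | Y2, M) and (Y2 | Y1, M).

    Standard bivariate-normal conditioning applied within each pattern;
    because the covariance is pattern-invariant, the slope on the other Y
    is the usual ``rho * sigma_j / sigma_k`` and the indicator
    coefficients absorb the pattern-mean shifts.  The own-indicator
    coefficient (the CSP) for Y1 is ``mu11 - rho*(s1/s2)*mu21``.
    """
    p = params
    b12 = p.rho * p.sigma1 / p.sigma2
    b21 = p.rho * p.sigma2 / p.sigma1
    m1 = ConditionalModel(
        intercept=p.mu10 - b12 * p.mu20,
        coef_other_y=b12,
        coef_own_indicator=p.mu11 - b12 * p.mu21,
        coef_other_indicator=p.mu12 - b12 * p.mu22,
        residual_sd=p.sigma1 * (1.0 - p.rho**2) ** 0.5,
    )
    m2 = ConditionalModel(
        intercept=p.mu20 - b21 * p.mu10,
        coef_other_y=b21,
        coef_own_indicator=p.mu22 - b21 * p.mu12,
        coef_other_indicator=p.mu21 - b21 * p.mu11,
        residual_sd=p.sigma2 * (1.0 - p.rho**2) ** 0.5,
    )
    return m1, m2


def marginal_means(params: GaussianPmParams) -> tuple[float, float]:
    """Overall means E(Y1), E(Y2) averaged over the missingness patterns."""
    p = params
    ey1 = p.mu10 + p.mu11 * p.pi1 + p.mu12 * p.pi2
    ey2 = p.mu20 + p.mu21 * p.pi1 + p.mu22 * p.pi2
    return ey1, ey2


def dampening_csp(mu11: float, rho: float) -> float:
    """CSP implied by an MSP under the blood-pressure-style restriction.

    When the other variable carries no pattern shifts (mu12 = mu22 = 0)
    and its conditional model has a zero own-pattern coefficient
    (mu21 = rho*(sigma2/sigma1)*mu11), the CSP collapses to
    ``(1 - rho^2) * mu11``: the conditional shift is a naturally dampened
    version of the marginal one, not an artefact of the chained cycles.
    """
    return (1.0 - rho**2) * mu11
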