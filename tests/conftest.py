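import numpy as np
import pandas as pd
import pytest

from narfcs import GaussianPmParams, attach_missingness_indicators


@pytest.fixture(scope="session")
def pm_params() -> GaussianPmParams:
    """The bivariate pattern-mixture parameter set used throughout the
    simulation-based tests (true MSPs -2 and -3; true CSPs -2.3 and -4.2;
    marginal means 9.65 and 19.55)."""
    return GaussianPmParams(
        mu10=10.0, mu11=-2.0, mu12=1.0,
        mu20=20.0, mu21=1.0, mu22=-3.0,
        sigma1=2.0, sigma2=4.0, rho=0.6,
        pi1=0.3, pi2=0.25,
    )


@pytest.fixture(scope="session")
def rho_zero_params(pm_params) -> GaussianPmParams:
    """Same process with uncorrelated outcomes, where CSP == MSP."""
    from dataclasses import replace

    return replace(pm_params, rho=0.0)


@pytest.fixture()
def single_var_dataset():
    """One incomplete gaussian variable, no covariates: the simplest
    setting for exact offset arithmetic."""
    rng = np.random.default_rng(42)
    y = rng.normal(5.0, 1.0, size=400)
    miss = rng.random(400) < 0.3
    return attach_missingness_indicators(
        pd.DataFrame({"Y": np.where(miss, np.nan, y)})
    )
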