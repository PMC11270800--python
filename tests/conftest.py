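import warnings

import pytest

from armtip import BGLMM, TippingAnalysis, table1_fixture

# light MCMC schedule shared by most fitting tests; heavy enough for the
# ~0.05-level Monte-Carlo agreement these tests assert
LIGHT = dict(chains=2, adaptation=2_000, iterations=20_000, burn_in=5_000,
             thin=2)


@pytest.fixture(scope="session")
def t1():
    """The frozen five-study example dataset."""
    return table1_fixture()


@pytest.fixture(scope="session")
def light_fit(t1):
    """Free-correlation equal-SD fit of the five-study data, light schedule."""
    return BGLMM(variance_structure="equal", seed=42, **LIGHT).fit(t1)


@pytest.fixture(scope="session")
def full_fit(t1):
    """Free-correlation equal-SD fit with the headline MCMC schedule
    (3 chains x 100,000 iterations, 10,000 adaptation/burn-in, thin 2)."""
    return BGLMM(variance_structure="equal", seed=1).fit(t1)


@pytest.fixture(scope="session")
def small_tipping(t1, light_fit):
    """Tipping analysis of the five-study data over a coarse high-rho grid.

    The grid {0.5, ..., 0.9} brackets the value where the OR interval
    conclusion flips from covering to excluding the null.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return TippingAnalysis(
            rho_min=0.4, rho_max=1.0, step=0.1, seed=7, chains=2,
            adaptation=1_000, iterations=8_000, burn_in=2_000,
        ).fit(t1, original=light_fit)
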