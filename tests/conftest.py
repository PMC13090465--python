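import numpy as np
import pytest

from scalenorm import irt
from scalenorm.simulate import make_fixture_cohort, random_item_params, simulate_responses


@pytest.fixture(scope="session")
def five_item_params():
    """Fixed well-conditioned 5-item K=3 design used across calibration tests."""
    rng = np.random.default_rng(12345)
    return random_item_params(rng, [f"i{j}" for j in range(5)], 3)


@pytest.fixture(scope="session")
def null_cohort(five_item_params):
    """One n=2000 cohort drawn from the 5-item design (the null model holds)."""
    theta = np.random.default_rng(1000).standard_normal(2000)
    return simulate_responses(theta, five_item_params, 7000), theta


@pytest.fixture(scope="session")
def null_calibration(null_cohort, five_item_params):
    m, _ = null_cohort
    return m, irt.fit_grm(m, [p.item_id for p in five_item_params])


@pytest.fixture(scope="session")
def psc17_cohort():
    return make_fixture_cohort("psc17-like")


def make_calibration(params):
    """Calibration wrapper around known parameters (no fitting)."""
    return irt.Calibration(
        params=list(params),
        model="grm",
        grid=irt.default_grid(),
        log_marginal_likelihood=0.0,
        n_iterations=0,
        converged=True,
    )
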