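import numpy as np
import pytest

from mvmr import (
    SummaryDataset,
    compute_joint_summaries,
    simulate_identification_design,
)


@pytest.fixture(scope="session")
def both_identified_data():
    """Strongly identified two-exposure design (shared confounder), n=50k."""
    return simulate_identification_design("both_identified", n=50_000, L=100, seed=101)


@pytest.fixture(scope="session")
def both_identified_summary(both_identified_data):
    return compute_joint_summaries(both_identified_data)


@pytest.fixture()
def toy_summary():
    """Small two-exposure summary table with a known outcome relation.

    gamma = 2*pi1 + 3*pi2 exactly, tiny but positive variances, zero
    cross-exposure covariance.
    """
    rng = np.random.default_rng(7)
    L = 12
    pi = np.column_stack([rng.uniform(0.2, 0.8, L), rng.uniform(0.2, 0.8, L)])
    return SummaryDataset(
        pi_hat=pi,
        gamma_hat=2.0 * pi[:, 0] + 3.0 * pi[:, 1],
        var_pi=np.full((L, 2), 0.01),
        var_gamma=np.full(L, 0.04),
        cov_pi=np.zeros((L, 1)),
    )
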