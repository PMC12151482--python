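import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from burstpop import BurstFeedbackParams, burst_frequency_for_mean


@pytest.fixture(scope="session")
def feedback_mean100() -> BurstFeedbackParams:
    """Feedback configuration with the single-cell mean pinned at 100.

    lam = burst_frequency_for_mean(100, k=1/100, beta=10, gamma=1) = 100/21.
    """
    return BurstFeedbackParams(lam=100.0 / 21.0, beta=10.0, gamma=1.0, k=0.01)


@pytest.fixture(scope="session")
def unregulated_params() -> BurstFeedbackParams:
    return BurstFeedbackParams(lam=10.0, beta=10.0, gamma=1.0, k=0.0)


def three_se(a: np.ndarray, b: np.ndarray | None = None) -> float:
    """3x the (combined) standard error of the mean(s) of the sample(s)."""
    se2 = a.var(ddof=1) / a.size
    if b is not None:
        se2 += b.var(ddof=1) / b.size
    return 3.0 * np.sqrt(se2)
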