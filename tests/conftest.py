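import numpy as np
import pytest

from medboot import BootstrapDistribution, MediationSample


@pytest.fixture
def noiseless_sample() -> MediationSample:
    """Exact linear system with a full-rank design.

    m = 2x + e with e orthogonal to both the intercept and x, so the
    simple slope of m on x is exactly 2; y = 3m exactly, so the partial
    slopes of y on (x, m) are exactly (0, 3) and the indirect effect is 6.
    """
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([1.0, -2.0, 0.0, 2.0, -1.0])
    m = 2.0 * x + e
    y = 3.0 * m
    return MediationSample(x=x, m=m, y=y)


def make_dist(estimates, source_ab_hat=0.0) -> BootstrapDistribution:
    """Build a BootstrapDistribution directly from raw estimates."""
    est = np.sort(np.asarray(estimates, dtype=float))
    return BootstrapDistribution(
        estimates=est, B=len(est), n_degenerate=0, source_ab_hat=source_ab_hat
    )


@pytest.fixture
def symmetric_dist() -> BootstrapDistribution:
    """Symmetric integer distribution -5..5, centered (and median) at 0."""
    return make_dist(np.arange(-5, 6, dtype=float), source_ab_hat=0.0)
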