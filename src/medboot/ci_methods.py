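"""Bootstrap confidence intervals for the indirect effect.

Five methods are implemented, all operating on the same sorted bootstrap
distribution:

``P`` (percentile)
    Limits at the alpha/2 and 1-alpha/2 empirical percentiles.
``BC`` (bias-corrected)
    The percentile positions are shifted before the normal-CDF mapping by
    twice the median-bias constant z_adj = Phi^-1(proportion of bootstrap
    estimates below the sample estimate): the limits sit at
    Phi(2*z_adj + z_{alpha/2}) and Phi(2*z_adj + z_{1-alpha/2}).
``rBC`` (reduced bias-corrected)
    Same mapping with z_adj added once instead of twice, correcting only
    the bootstrap-level median bias.
``stBC`` (significance-tested bias-corrected)
    A two-sided binomial test of whether the sample estimate sits at the
    bootstrap distribution's median gates the correction: significant ->
    the BC interval, otherwise the percentile interval.
``WBC`` (Winsorized bias-corrected)
    The BC mapping with the bias reference replaced by the gamma-Winsorized
    mean of the bootstrap distribution (gamma = 0.30 per tail by default).

When z_adj = 0 all five methods coincide exactly, and at gamma = 0.5 the
Winsorized method collapses to the percentile interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import binomtest

from .bootstrap import BootstrapDistribution, empirical_percentile

__all__ = [
    "CIRequest",
    "ConfidenceInterval",
    "METHODS",
    "bias_z",
    "pbci",
    "bcbci",
    "rbcbci",
    "stbcbci",
    "wbcbci",
    "winsorized_mean",
    "gate_thresholds",
    "all_intervals",
]

logger = logging.getLogger(__name__)

#: Method labels in the conventional reporting order.
METHODS = ("P", "BC", "rBC", "WBC", "stBC")


@dataclass(frozen=True)
class CIRequest:
    """Settings shared by the interval constructors.

    Parameters
    ----------
    level
        Confidence level 1 - alpha, default 0.95.
    alpha_test
        Significance level of the stBC gate's binomial test (independent
        of ``level``), default 0.05.
    gamma
        Winsorization fraction per tail for the WBC reference mean,
        default 0.30.
    exact_gate
        Use an exact binomial test for the stBC gate instead of the
        normal approximation.  The normal approximation (without
        continuity correction) is the default and corresponds to gate
        proportions 0.4862 / 0.5138 at B = 5000, alpha_test = 0.05.
    """

    level: float = 0.95
    alpha_test: float = 0.05
    gamma: float = 0.30
    exact_gate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not (0.0 < self.alpha_test < 1.0):
            raise ValueError(f"alpha_test must be in (0, 1), got {self.alpha_test}")
        if not (0.0 <= self.gamma <= 0.5):
            raise ValueError(f"gamma must be in [0, 0.5], got {self.gamma}")


@dataclass(frozen=True)
class ConfidenceInterval:
    """One bootstrap confidence interval plus its diagnostics.

    ``lower_percentile`` and ``upper_percentile`` are the (possibly
    bias-shifted) probabilities at which the limits were extracted from
    the bootstrap distribution; ``z_adj_hat`` is the bias constant used
    (absent for the percentile method); ``branch`` records which interval
    the significance-tested method returned.
    """

    method: str
    level: float
    lower: float
    upper: float
    lower_percentile: float
    upper_percentile: float
    z_adj_hat: float | None = None
    branch: str | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower limit exceeds upper limit")
        if not (0.0 < self.lower_percentile < self.upper_percentile < 1.0):
            raise ValueError("percentile positions must satisfy 0 < lo < up < 1")


def _count_below(dist: BootstrapDistribution, reference: float) -> int:
    """Number of bootstrap estimates strictly below ``reference``."""
    return int(np.searchsorted(dist.estimates, reference, side="left"))


def bias_z(dist: BootstrapDistribution, reference: float) -> float:
    """Median-bias constant: Phi^-1 of the proportion of estimates below ``reference``.

    The count is clamped to [1, B-1] so the inverse-normal transform stays
    finite when the reference falls outside the whole distribution; the
    resulting interval then degenerates toward the extreme order
    statistics.
    """
    c = _count_below(dist, reference)
    clamped = min(max(c, 1), dist.B - 1)
    if clamped != c:
        logger.warning(
            "bias reference %g lies %s the whole bootstrap distribution; "
            "count clamped to %d/%d",
            reference,
            "below" if c < clamped else "above",
            clamped,
            dist.B,
        )
    return float(ndtri(clamped / dist.B))


def _percentile_interval(
    dist: BootstrapDistribution, p_lo: float, p_up: float
) -> tuple[float, float]:
    return empirical_percentile(dist, p_lo), empirical_percentile(dist, p_up)


def pbci(dist: BootstrapDistribution, req: CIRequest = CIRequest()) -> ConfidenceInterval:
    """Percentile bootstrap confidence interval."""
    alpha = 1.0 - req.level
    p_lo, p_up = alpha / 2.0, 1.0 - alpha / 2.0
    lo, up = _percentile_interval(dist, p_lo, p_up)
    return ConfidenceInterval(
        method="P",
        level=req.level,
        lower=lo,
        upper=up,
        lower_percentile=p_lo,
        upper_percentile=p_up,
    )


def _shifted_interval(
    dist: BootstrapDistribution,
    z_adj: float,
    req: CIRequest,
    shift_factor: float,
    method: str,
) -> ConfidenceInterval:
    alpha = 1.0 - req.level
    z_lo = ndtri(alpha / 2.0)
    z_up = ndtri(1.0 - alpha / 2.0)
    p_lo = float(ndtr(shift_factor * z_adj + z_lo))
    p_up = float(ndtr(shift_factor * z_adj + z_up))
    lo, up = _percentile_interval(dist, p_lo, p_up)
    return ConfidenceInterval(
        method=method,
        level=req.level,
        lower=lo,
        upper=up,
        lower_percentile=p_lo,
        upper_percentile=p_up,
        z_adj_hat=float(z_adj),
    )


def bcbci(
    dist: BootstrapDistribution,
    ab_hat: float | None = None,
    req: CIRequest = CIRequest(),
) -> ConfidenceInterval:
    """Bias-corrected bootstrap CI (double z_adj shift).

    ``ab_hat`` defaults to the original-sample estimate recorded on the
    distribution.
    """
    if ab_hat is None:
        ab_hat = dist.source_ab_hat
    z = bias_z(dist, ab_hat)
    return _shifted_interval(dist, z, req, shift_factor=2.0, method="BC")


def rbcbci(
    dist: BootstrapDistribution,
    ab_hat: float | None = None,
    req: CIRequest = CIRequest(),
) -> ConfidenceInterval:
    """Reduced bias-corrected bootstrap CI (single z_adj shift)."""
    if ab_hat is None:
        ab_hat = dist.source_ab_hat
    z = bias_z(dist, ab_hat)
    return _shifted_interval(dist, z, req, shift_factor=1.0, method="rBC")


def gate_thresholds(
    B: int, alpha_test: float = 0.05, exact: bool = False
) -> tuple[float, float]:
    """Non-rejection boundary proportions of the stBC median-bias gate.

    Returns the smallest and largest achievable proportions (multiples of
    1/B) for which the two-sided test of H0: G*(ab_hat) = 0.5 is NOT
    significant; the gate applies the bias correction for proportions
    strictly outside this range.  With the default normal-approximation
    test at B = 5000 and alpha_test = 0.05 these are 0.4862 and 0.5138.
    """
    if exact:
        counts = np.arange(0, B + 1)
        keep = np.array(
            [binomtest(int(c), B, 0.5).pvalue > alpha_test for c in counts]
        )
        kept = counts[keep]
        return float(kept.min() / B), float(kept.max() / B)
    delta = float(ndtri(1.0 - alpha_test / 2.0)) * math.sqrt(0.25 / B)
    lower = math.ceil((0.5 - delta) * B - 1e-9) / B
    upper = math.floor((0.5 + delta) * B + 1e-9) / B
    return lower, upper


def _gate_rejects(count: int, B: int, req: CIRequest) -> bool:
    if req.exact_gate:
        return binomtest(count, B, 0.5).pvalue <= req.alpha_test
    delta = float(ndtri(1.0 - req.alpha_test / 2.0)) * math.sqrt(0.25 / B)
    return abs(count / B - 0.5) > delta


def stbcbci(
    dist: BootstrapDistribution,
    ab_hat: float | None = None,
    req: CIRequest = CIRequest(),
) -> ConfidenceInterval:
    """Significance-tested bias-corrected bootstrap CI.

    The proportion of bootstrap estimates below ``ab_hat`` is tested
    against 0.5; a significant result returns the BC interval
    (``branch='bias_corrected'``), otherwise the percentile interval
    (``branch='percentile'``).  The returned limits are always
    bit-identical to one of those two intervals.
    """
    if ab_hat is None:
        ab_hat = dist.source_ab_hat
    count = _count_below(dist, ab_hat)
    if _gate_rejects(count, dist.B, req):
        base = bcbci(dist, ab_hat, req)
        branch = "bias_corrected"
    else:
        base = pbci(dist, req)
        branch = "percentile"
    return replace(base, method="stBC", branch=branch)


def winsorized_mean(values, gamma: float) -> float:
    """Mean of ``values`` after Winsorizing a fraction ``gamma`` per tail.

    With sorted values and g = floor(gamma * len(values)), the g smallest
    values are replaced by the (g+1)th and the g largest by the (len-g)th
    before averaging.  gamma = 0 gives the arithmetic mean; gamma = 0.5
    averages the two middle order statistics.
    """
    if not (0.0 <= gamma <= 0.5):
        raise ValueError(f"gamma must be in [0, 0.5], got {gamma}")
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("values must be non-empty")
    nb = v.size
    g = math.floor(gamma * nb)
    if g > 0:
        # capture both replacement values first: at gamma = 0.5 the two
        # tail slices touch and the second read would see the first write
        lo_val = v[g]
        hi_val = v[nb - g - 1]
        v[:g] = lo_val
        v[nb - g :] = hi_val
    return float(v.mean())


def wbcbci(
    dist: BootstrapDistribution, req: CIRequest = CIRequest()
) -> ConfidenceInterval:
    """Winsorized bias-corrected bootstrap CI.

    Identical to :func:`bcbci` except the bias reference is the
    gamma-Winsorized mean of the bootstrap distribution rather than the
    sample estimate.
    """
    ref = winsorized_mean(dist.estimates, req.gamma)
    z = bias_z(dist, ref)
    return _shifted_interval(dist, z, req, shift_factor=2.0, method="WBC")


def all_intervals(
    dist: BootstrapDistribution,
    ab_hat: float | None = None,
    req: CIRequest = CIRequest(),
) -> dict[str, ConfidenceInterval]:
    """All five intervals on one shared bootstrap distribution, keyed by method."""
    if ab_hat is None:
        ab_hat = dist.source_ab_hat
    return {
        "P": pbci(dist, req),
        "BC": bcbci(dist, ab_hat, req),
        "rBC": rbcbci(dist, ab_hat, req),
        "WBC": wbcbci(dist, req),
        "stBC": stbcbci(dist, ab_hat, req),
    }
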