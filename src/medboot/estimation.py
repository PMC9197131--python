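"""OLS estimation of the mediation paths and the product indirect effect.

The a-path is the slope from the regression of M on X (with intercept);
the b-path and direct effect c' are the partial slopes from the regression
of Y on X and M (with intercept).  The indirect effect is estimated by the
product a_hat * b_hat.

The solver is the closed-form normal-equations solution written in terms
of centered sums of squares and cross-products.  This is exactly the
textbook OLS solution, and the same moment algebra is reused in vectorized
form by the bootstrap engine, so single-sample fits and bootstrap
replicates are guaranteed to agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PathEstimates", "DegenerateDesignError", "fit_simple_mediation"]

# Relative tolerance for declaring a design degenerate: the (x, m) design
# is treated as collinear when 1 - r^2 falls below this value.
_RANK_TOL = 1e-12


class DegenerateDesignError(ValueError):
    """Raised when x has zero variance or (x, m) are collinear."""


@dataclass(frozen=True)
class PathEstimates:
    """OLS path estimates for one mediation dataset.

    ``ab_hat`` is always exactly ``a_hat * b_hat``.
    """

    a_hat: float
    b_hat: float
    c_prime_hat: float
    ab_hat: float


def _centered_moments(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxm = float(xc @ mc)
    smm = float(mc @ mc)
    sxy = float(xc @ yc)
    smy = float(mc @ yc)
    return sxx, sxm, smm, sxy, smy


def fit_simple_mediation(sample) -> PathEstimates:
    """Fit both mediation regressions by OLS and return the path estimates.

    Raises
    ------
    DegenerateDesignError
        If x is constant or (x, m) are (numerically) collinear, so that
        one of the regressions has no unique solution.
    """
    x = np.asarray(sample.x, dtype=float)
    m = np.asarray(sample.m, dtype=float)
    y = np.asarray(sample.y, dtype=float)
    sxx, sxm, smm, sxy, smy = _centered_moments(x, m, y)
    if sxx <= 0.0:
        raise DegenerateDesignError("x has zero variance")
    if smm <= 0.0:
        raise DegenerateDesignError("m has zero variance")
    # det = sxx*smm*(1 - r^2) >= 0; collinear x, m drive it to zero.
    det = sxx * smm - sxm * sxm
    if det <= _RANK_TOL * sxx * smm:
        raise DegenerateDesignError("x and m are collinear")
    a_hat = sxm / sxx
    b_hat = (sxx * smy - sxm * sxy) / det
    c_prime_hat = (smm * sxy - sxm * smy) / det
    return PathEstimates(
        a_hat=a_hat,
        b_hat=b_hat,
        c_prime_hat=c_prime_hat,
        ab_hat=a_hat * b_hat,
    )
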