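"""Case-resampling bootstrap of the indirect effect.

Each bootstrap replicate draws n row indices uniformly with replacement
and keeps the (x, m, y) triples together, so the joint structure of the
data is preserved.  The indirect effect a_hat* x b_hat* is recomputed in
each resample and the B values are returned sorted ascending — the
"observed bootstrap sampling distribution" that every confidence-interval
method in :mod:`medboot.ci_methods` consumes.

The inner loop is fully vectorized across resamples using the same
centered-moment OLS algebra as :mod:`medboot.estimation`.  Resamples with
a degenerate design (a constant x or collinear x and m — possible at very
small n) are redrawn with fresh indices so the distribution always holds
exactly B estimates; the number of redraws is reported on the result.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .estimation import _RANK_TOL, fit_simple_mediation

__all__ = ["BootstrapDistribution", "draw_bootstrap_distribution", "empirical_percentile"]

logger = logging.getLogger(__name__)

# Rounds of redrawing degenerate resamples before giving up.  A sample on
# which every resample is degenerate (e.g. m an exact linear function of x)
# can never produce a bootstrap distribution of the indirect effect.
_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class BootstrapDistribution:
    """Sorted bootstrap estimates of the indirect effect.

    Attributes
    ----------
    estimates
        The B bootstrap indirect-effect estimates, sorted ascending.
    B
        Number of bootstrap replicates.
    n_degenerate
        Count of resamples that were redrawn because their design was
        degenerate (zero x variance or collinear x, m).
    source_ab_hat
        The original-sample indirect-effect estimate the distribution was
        drawn around.
    """

    estimates: np.ndarray
    B: int
    n_degenerate: int
    source_ab_hat: float

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        object.__setattr__(self, "estimates", est)
        if len(est) != self.B:
            raise ValueError(f"expected {self.B} estimates, got {len(est)}")
        if not np.all(np.isfinite(est)):
            raise ValueError("non-finite bootstrap estimate")
        if np.any(np.diff(est) < 0):
            raise ValueError("estimates must be sorted ascending")


def _resample_ab(x: np.ndarray, m: np.ndarray, y: np.ndarray, idx: np.ndarray):
    """Indirect-effect estimates for a block of resamples.

    ``idx`` has shape (k, n); returns (ab, degenerate_mask), both length k.
    """
    xs = x[idx]
    ms = m[idx]
    ys = y[idx]
    n = idx.shape[1]
    xc = xs - xs.mean(axis=1, keepdims=True)
    mc = ms - ms.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    det = sxx * smm - sxm * sxm
    degenerate = (sxx <= 0.0) | (smm <= 0.0) | (det <= _RANK_TOL * sxx * smm)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
        ab = a * b
    ab = np.where(degenerate, np.nan, ab)
    return ab, degenerate


def draw_bootstrap_distribution(
    sample, B: int = 5000, seed: object = None
) -> BootstrapDistribution:
    """Draw the observed bootstrap sampling distribution of the indirect effect.

    Parameters
    ----------
    sample
        A :class:`~medboot.datagen.MediationSample`.
    B
        Number of bootstrap replicates (default 5000).
    seed
        Anything accepted by :func:`numpy.random.default_rng`; fixing it
        makes the distribution fully reproducible.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    source = fit_simple_mediation(sample)  # also validates the original design
    x = np.asarray(sample.x, dtype=float)
    m = np.asarray(sample.m, dtype=float)
    y = np.asarray(sample.y, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(B, n))
    ab, degenerate = _resample_ab(x, m, y, idx)
    n_degenerate = int(degenerate.sum())
    rounds = 0
    while degenerate.any():
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise RuntimeError(
                "could not draw a non-degenerate resample after "
                f"{_MAX_REDRAW_ROUNDS} redraw rounds; the sample itself may "
                "have (near-)collinear x and m"
            )
        bad = np.flatnonzero(degenerate)
        idx_bad = rng.integers(0, n, size=(len(bad), n))
        ab_bad, degen_bad = _resample_ab(x, m, y, idx_bad)
        ab[bad] = ab_bad
        new_degenerate = np.zeros_like(degenerate)
        new_degenerate[bad] = degen_bad
        n_degenerate += int(degen_bad.sum())
        degenerate = new_degenerate
    if n_degenerate > 0.01 * B:
        warnings.warn(
            f"{n_degenerate} degenerate resamples redrawn out of {B} "
            "bootstrap replicates; results may be unstable at this n",
            RuntimeWarning,
            stacklevel=2,
        )
    ab.sort()
    return BootstrapDistribution(
        estimates=ab, B=B, n_degenerate=n_degenerate, source_ab_hat=source.ab_hat
    )


def empirical_percentile(dist: BootstrapDistribution, p: float) -> float:
    """Order statistic of the bootstrap distribution at probability ``p``.

    Returns the 1-based order statistic at index ceil(p*B), clamped to
    [1, B].  No interpolation is performed, so every returned limit is an
    element of ``dist.estimates`` and bias-shifted percentiles map cleanly
    onto order statistics (the 125th/4875th values for a 95% interval at
    B = 5000).
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    # Small slack guards against 0.025 * 5000 evaluating to 125.0000...01.
    k = math.ceil(p * dist.B - 1e-9)
    k = min(max(k, 1), dist.B)
    return float(dist.estimates[k - 1])
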