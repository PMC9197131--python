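"""Outcome measures for the Monte Carlo study.

Per-iteration confidence intervals are reduced to the study's measures:
rejection rate (type I error when the true indirect effect is zero, power
otherwise), coverage, balance (the share of missing intervals that fall
above the true effect), mean width, sample mean bias and bootstrap mean
bias, a Bradley robustness flag for null conditions, and an exact binomial
test of whether balance differs from 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .ci_methods import ConfidenceInterval

__all__ = [
    "IterationRecord",
    "ConditionResult",
    "rejection_indicator",
    "summarize_condition",
    "BRADLEY_LOWER",
    "BRADLEY_UPPER",
]

# Bradley's liberal robustness criterion at alpha = 0.05: an empirical
# type I error rate in [0.5*alpha, 1.5*alpha] counts as robust.
BRADLEY_LOWER = 0.025
BRADLEY_UPPER = 0.075


@dataclass(frozen=True)
class IterationRecord:
    """One simulation iteration: sample estimate, bootstrap mean, intervals.

    All intervals are computed from the same bootstrap distribution
    (paired design), keyed by method label.
    """

    ab_hat: float
    bootstrap_mean: float
    intervals: dict[str, ConfidenceInterval]
    true_ab: float


@dataclass(frozen=True)
class ConditionResult:
    """Aggregate outcomes for one method in one simulation condition."""

    method: str
    a_path: float
    b_path: float
    n: int
    level: float
    iterations: int
    rejections: int
    above: int
    below: int
    coverage: float
    balance: float | None
    mean_width: float
    sample_mean_bias: float
    bootstrap_mean_bias: float
    bradley_flag: str | None
    balance_significant: bool
    stbc_gate_rate: float | None = None

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.iterations


def rejection_indicator(ci: ConfidenceInterval) -> int:
    """1 if the interval excludes zero, else 0.

    A limit exactly equal to zero counts as including zero (closed
    interval) — immaterial for continuous data but documented behavior.
    """
    return 1 if (ci.lower > 0.0 or ci.upper < 0.0) else 0


def summarize_condition(
    records: list[IterationRecord],
    method: str,
    true_ab: float,
    level: float,
    *,
    a_path: float = float("nan"),
    b_path: float = float("nan"),
    n: int = 0,
    stbc_gate_rate: float | None = None,
) -> ConditionResult:
    """Aggregate one method's intervals across the iterations of a condition."""
    if not records:
        raise ValueError("at least one iteration record is required")
    iters = len(records)
    cis = [r.intervals[method] for r in records]
    rejections = sum(rejection_indicator(ci) for ci in cis)
    above = sum(1 for ci in cis if ci.lower > true_ab)
    below = sum(1 for ci in cis if ci.upper < true_ab)
    coverage = 1.0 - (above + below) / iters
    missed = above + below
    balance = above / missed if missed > 0 else None
    mean_width = float(np.mean([ci.upper - ci.lower for ci in cis]))
    sample_mean_bias = float(np.mean([r.ab_hat for r in records])) - true_ab
    bootstrap_mean_bias = float(
        np.mean([r.bootstrap_mean - r.ab_hat for r in records])
    )
    if true_ab == 0.0:
        rate = rejections / iters
        if rate > BRADLEY_UPPER:
            bradley = "liberal"
        elif rate < BRADLEY_LOWER:
            bradley = "conservative"
        else:
            bradley = "robust"
    else:
        bradley = None
    if missed > 0:
        balance_significant = binomtest(above, missed, 0.5).pvalue < 0.05
    else:
        balance_significant = False
    return ConditionResult(
        method=method,
        a_path=a_path,
        b_path=b_path,
        n=n,
        level=level,
        iterations=iters,
        rejections=rejections,
        above=above,
        below=below,
        coverage=coverage,
        balance=balance,
        mean_width=mean_width,
        sample_mean_bias=sample_mean_bias,
        bootstrap_mean_bias=bootstrap_mean_bias,
        bradley_flag=bradley,
        balance_significant=balance_significant,
        stbc_gate_rate=stbc_gate_rate,
    )
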