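"""Simulated and user-supplied data for the simple mediation model.

The simple mediation model is the two-equation linear system

    M = d2 + a*X + e2
    Y = d3 + c'*X + b*M + e3

with independent, homoscedastic normal errors.  The generator here draws X
from a standard normal distribution and builds M and Y from the equations
above; intercepts default to zero, the direct path c' defaults to zero, and
the error standard deviation defaults to one, which is the configuration
used throughout the Monte Carlo study this package implements.

Real data enters through :func:`load_sample`, which reads a CSV with
columns named X, M and Y (case-insensitive; extra columns are ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd

__all__ = ["GeneratorSpec", "MediationSample", "generate_sample", "load_sample"]

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


@dataclass(frozen=True)
class GeneratorSpec:
    """Population configuration for one simulated mediation dataset.

    Parameters
    ----------
    a_path, b_path
        Population slopes of X -> M and M -> Y (controlling X).  Their
        product ``a_path * b_path`` is the true indirect effect.
    n
        Sample size; at least 3 rows are required to fit a regression with
        two predictors and an intercept.
    c_prime
        Population direct effect of X on Y controlling M.  Defaults to 0.
    intercepts
        Intercepts (d1, d2, d3) of the three mediation equations; only d2
        and d3 enter data generation.  Default all zero.
    error_sd
        Standard deviation of the (normal) error terms, shared by both
        equations.  Default 1 (standard-normal errors).
    seed
        Anything accepted by :func:`numpy.random.default_rng`.  The same
        seed reproduces the same sample bit for bit.
    """

    a_path: float
    b_path: float
    n: int
    c_prime: float = 0.0
    intercepts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    error_sd: float = 1.0
    seed: object = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 3:
            raise ValueError(f"n must be an integer >= 3, got {self.n!r}")
        if not (self.error_sd > 0):
            raise ValueError(f"error_sd must be > 0, got {self.error_sd!r}")
        if len(self.intercepts) != 3:
            raise ValueError("intercepts must be a (d1, d2, d3) triple")


@dataclass(frozen=True)
class MediationSample:
    """One (X, M, Y) dataset, simulated or loaded from disk.

    ``spec`` is the generating :class:`GeneratorSpec` when the sample was
    simulated and ``None`` for user-loaded data.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    spec: GeneratorSpec | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        m = np.asarray(self.m, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "y", y)
        if not (x.ndim == m.ndim == y.ndim == 1):
            raise ValueError("x, m, y must be one-dimensional vectors")
        if not (len(x) == len(m) == len(y)):
            raise ValueError(
                f"x, m, y must have equal length, got {len(x)}, {len(m)}, {len(y)}"
            )
        if len(x) < 3:
            raise ValueError(f"need at least 3 rows, got {len(x)}")
        for name, v in (("x", x), ("m", m), ("y", y)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite value in column {name}")

    @property
    def n(self) -> int:
        return len(self.x)


def generate_sample(spec: GeneratorSpec) -> MediationSample:
    """Draw one mediation dataset from the population described by ``spec``.

    X is iid standard normal; M and Y follow the mediation equations with
    iid N(0, error_sd^2) errors.  Identical specs (including the seed)
    yield identical samples.
    """
    rng = np.random.default_rng(spec.seed)
    d1, d2, d3 = spec.intercepts
    x = rng.standard_normal(spec.n)
    e2 = rng.standard_normal(spec.n) * spec.error_sd
    e3 = rng.standard_normal(spec.n) * spec.error_sd
    m = d2 + spec.a_path * x + e2
    y = d3 + spec.c_prime * x + spec.b_path * m + e3
    return MediationSample(x=x, m=m, y=y, spec=spec)


def load_sample(path: "str | PathLike[str]") -> MediationSample:
    """Read a mediation dataset from a CSV file with columns X, M, Y.

    Column matching is case-insensitive and extra columns are ignored.
    Raises ``ValueError`` naming the offending column or row on missing
    columns, non-numeric cells, or fewer than 3 data rows.
    """
    df = pd.read_csv(path)
    lookup = {str(c).strip().lower(): c for c in df.columns}
    cols: dict[str, np.ndarray] = {}
    for name in ("X", "M", "Y"):
        key = name.lower()
        if key not in lookup:
            raise ValueError(f"column {name!r} not found in {path}")
        raw = df[lookup[key]]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & ~raw.isna()
        if bad.any() or numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise ValueError(
                f"non-numeric or missing value in column {name!r} at data row {row}"
            )
        cols[name] = numeric.to_numpy(dtype=float)
    if len(df) < 3:
        raise ValueError(f"need at least 3 data rows, got {len(df)}")
    return MediationSample(x=cols["X"], m=cols["M"], y=cols["Y"], spec=None)
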