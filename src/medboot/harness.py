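"""Monte Carlo harness for the bootstrap CI comparison study.

Orchestrates the full factorial simulation: for every combination of
a-path size, b-path size, and sample size, datasets are generated, the
paths estimated by OLS, one bootstrap distribution drawn per dataset, and
all five confidence-interval methods computed from that shared
distribution (paired design).  Per-condition aggregates come from
:mod:`medboot.metrics`.

The default grid is the study's: path sizes {0, 0.14, 0.39, 0.59}, sample
sizes {25, 50, 75, 100, 500}, 1000 iterations per condition, B = 5000
bootstrap replicates, 95% intervals.  A supplementary mode re-runs the
nonzero-effect conditions comparing each bias-corrected method against a
percentile interval whose confidence level is lowered to match that
method's maximum observed null rejection rate.

Seeding: every condition derives its own ``SeedSequence`` from the master
seed and the condition coordinates, and each iteration spawns separate
child seeds for data generation and for the bootstrap, so any single
iteration can be replayed in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import draw_bootstrap_distribution
from .ci_methods import METHODS, CIRequest, all_intervals, pbci
from .datagen import GeneratorSpec, generate_sample
from .estimation import fit_simple_mediation
from .metrics import ConditionResult, IterationRecord, summarize_condition

__all__ = [
    "StudyConfig",
    "PAPER_COMPARISON_LEVELS",
    "run_condition",
    "run_grid",
    "run_matched_power",
    "derive_comparison_levels",
    "results_to_frame",
    "write_results",
    "load_config",
]

logger = logging.getLogger(__name__)

#: Matched-power comparison levels published for the primary study's
#: maximum null rejection rates (BC/stBC 0.088 -> 91.2%, rBC 0.077 ->
#: 92.3%, WBC 0.073 -> 92.7%).
PAPER_COMPARISON_LEVELS = {"BC": 0.912, "stBC": 0.912, "rBC": 0.923, "WBC": 0.927}

_BC_FAMILY = ("BC", "rBC", "WBC", "stBC")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one Monte Carlo study."""

    a_levels: tuple[float, ...] = (0.0, 0.14, 0.39, 0.59)
    b_levels: tuple[float, ...] = (0.0, 0.14, 0.39, 0.59)
    n_levels: tuple[int, ...] = (25, 50, 75, 100, 500)
    levels: tuple[float, ...] = (0.95,)
    iterations: int = 1000
    B: int = 5000
    master_seed: int = 0
    methods: tuple[str, ...] = METHODS
    alpha_test: float = 0.05
    gamma: float = 0.30
    exact_gate: bool = False
    comparison_levels: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("a_levels", "b_levels", "n_levels", "levels", "methods"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _condition_seed(master_seed: int, a: float, b: float, n: int) -> np.random.SeedSequence:
    """Seed sequence tied to the condition coordinates, not grid order."""
    return np.random.SeedSequence(
        [int(master_seed), int(round(a * 1000)), int(round(b * 1000)), int(n)]
    )


def _iterate_condition(a: float, b: float, n: int, cfg: StudyConfig):
    """Run the iterations of one condition, yielding per-level records.

    Returns (records, gate_rate) where ``records`` maps confidence level
    to the list of :class:`IterationRecord` and ``gate_rate`` is the
    fraction of iterations in which the stBC gate chose the
    bias-corrected branch.
    """
    true_ab = a * b
    cond_ss = _condition_seed(cfg.master_seed, a, b, n)
    children = cond_ss.spawn(cfg.iterations)
    records: dict[float, list[IterationRecord]] = {lv: [] for lv in cfg.levels}
    gate_hits = 0
    for i, child in enumerate(children):
        data_ss, boot_ss = child.spawn(2)
        try:
            sample = generate_sample(
                GeneratorSpec(a_path=a, b_path=b, n=n, seed=data_ss)
            )
            est = fit_simple_mediation(sample)
            dist = draw_bootstrap_distribution(sample, B=cfg.B, seed=boot_ss)
        except Exception:
            logger.error(
                "iteration %d of condition (a=%g, b=%g, n=%d) failed; "
                "replay with SeedSequence entropy %r",
                i,
                a,
                b,
                n,
                cond_ss.entropy,
            )
            raise
        boot_mean = float(dist.estimates.mean())
        for lv in cfg.levels:
            req = CIRequest(
                level=lv,
                alpha_test=cfg.alpha_test,
                gamma=cfg.gamma,
                exact_gate=cfg.exact_gate,
            )
            intervals = all_intervals(dist, est.ab_hat, req)
            records[lv].append(
                IterationRecord(
                    ab_hat=est.ab_hat,
                    bootstrap_mean=boot_mean,
                    intervals=intervals,
                    true_ab=true_ab,
                )
            )
        if records[cfg.levels[0]][-1].intervals["stBC"].branch == "bias_corrected":
            gate_hits += 1
    return records, gate_hits / cfg.iterations


def run_condition(
    a: float, b: float, n: int, cfg: StudyConfig
) -> list[ConditionResult]:
    """Simulate one (a, b, n) condition; one result per method x level."""
    true_ab = a * b
    records, gate_rate = _iterate_condition(a, b, n, cfg)
    results = []
    for lv in cfg.levels:
        for method in cfg.methods:
            results.append(
                summarize_condition(
                    records[lv],
                    method,
                    true_ab,
                    lv,
                    a_path=a,
                    b_path=b,
                    n=n,
                    stbc_gate_rate=gate_rate if method == "stBC" else None,
                )
            )
    return results


def results_to_frame(results: list[ConditionResult]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in results])
    frame["rejection_rate"] = frame["rejections"] / frame["iterations"]
    frame["true_ab"] = frame["a_path"] * frame["b_path"]
    return frame


def run_grid(cfg: StudyConfig) -> pd.DataFrame:
    """Run every (a, b, n) combination in the config's factorial grid.

    Deterministic under ``cfg.master_seed``; returns one long-format row
    per condition x method x level.
    """
    results: list[ConditionResult] = []
    n_conditions = len(cfg.a_levels) * len(cfg.b_levels) * len(cfg.n_levels)
    done = 0
    for a in cfg.a_levels:
        for b in cfg.b_levels:
            for n in cfg.n_levels:
                results.extend(run_condition(a, b, n, cfg))
                done += 1
                logger.info(
                    "condition %d/%d done (a=%g, b=%g, n=%d)",
                    done,
                    n_conditions,
                    a,
                    b,
                    n,
                )
    return results_to_frame(results)


def derive_comparison_levels(
    frame: pd.DataFrame, base_level: float = 0.95
) -> dict[str, float]:
    """Matched-power PBCI levels from a grid's maximum null rejection rates.

    For each bias-corrected method the comparison level is 1 minus its
    maximum rejection rate over the null (true_ab = 0) conditions at
    ``base_level``.
    """
    null = frame[(frame["true_ab"] == 0) & (frame["level"] == base_level)]
    if null.empty:
        raise ValueError("frame contains no null conditions at the base level")
    out = {}
    for method in _BC_FAMILY:
        rates = null.loc[null["method"] == method, "rejection_rate"]
        if rates.empty:
            continue
        out[method] = 1.0 - float(rates.max())
    return out


def run_matched_power(cfg: StudyConfig) -> pd.DataFrame:
    """Power of each bias-corrected method vs its type-I-error-matched PBCI.

    Requires ``cfg.comparison_levels`` (method label -> PBCI level), e.g.
    :data:`PAPER_COMPARISON_LEVELS` or the output of
    :func:`derive_comparison_levels`.  Only conditions with a nonzero true
    indirect effect are run; within each iteration the method interval and
    its matched percentile interval share the bootstrap distribution.
    """
    if not cfg.comparison_levels:
        raise ValueError("comparison_levels are required for matched-power runs")
    unknown = set(cfg.comparison_levels) - set(_BC_FAMILY)
    if unknown:
        raise ValueError(f"comparison_levels for non-BC methods: {sorted(unknown)}")
    base_level = cfg.levels[0]
    base_req = CIRequest(
        level=base_level,
        alpha_test=cfg.alpha_test,
        gamma=cfg.gamma,
        exact_gate=cfg.exact_gate,
    )
    comp_reqs = {
        method: CIRequest(level=lv, alpha_test=cfg.alpha_test, gamma=cfg.gamma)
        for method, lv in cfg.comparison_levels.items()
    }
    rows = []
    for a in cfg.a_levels:
        for b in cfg.b_levels:
            if a == 0 or b == 0:
                continue
            for n in cfg.n_levels:
                cond_ss = _condition_seed(cfg.master_seed, a, b, n)
                children = cond_ss.spawn(cfg.iterations)
                method_rej = {m: 0 for m in cfg.comparison_levels}
                matched_rej = {m: 0 for m in cfg.comparison_levels}
                for child in children:
                    data_ss, boot_ss = child.spawn(2)
                    sample = generate_sample(
                        GeneratorSpec(a_path=a, b_path=b, n=n, seed=data_ss)
                    )
                    est = fit_simple_mediation(sample)
                    dist = draw_bootstrap_distribution(sample, B=cfg.B, seed=boot_ss)
                    intervals = all_intervals(dist, est.ab_hat, base_req)
                    for method in cfg.comparison_levels:
                        ci = intervals[method]
                        if ci.lower > 0 or ci.upper < 0:
                            method_rej[method] += 1
                        matched = pbci(dist, comp_reqs[method])
                        if matched.lower > 0 or matched.upper < 0:
                            matched_rej[method] += 1
                for method, comp_level in cfg.comparison_levels.items():
                    rows.append(
                        {
                            "a_path": a,
                            "b_path": b,
                            "n": n,
                            "method": method,
                            "level": base_level,
                            "comparison_level": comp_level,
                            "power_method": method_rej[method] / cfg.iterations,
                            "power_matched_pbci": matched_rej[method] / cfg.iterations,
                        }
                    )
    return pd.DataFrame(rows)


def _pivot_rates(frame: pd.DataFrame, value: str) -> pd.DataFrame:
    wide = frame.pivot_table(
        index=["a_path", "b_path", "n", "level"],
        columns="method",
        values=value,
        aggfunc="first",
    ).reset_index()
    cols = ["a_path", "b_path", "n", "level"] + [
        m for m in METHODS if m in wide.columns
    ]
    return wide[cols]


def write_results(frame: pd.DataFrame, outdir: "str | Path") -> dict[str, Path]:
    """Write the study's result tables under ``outdir``.

    Emits a long-format ``results.csv`` with every aggregate field, wide
    rejection-rate tables split into ``null_conditions.csv`` (true
    indirect effect zero; rates are type I errors) and
    ``power_conditions.csv`` (nonzero effects; rates are power), plus
    ``balance.csv`` and ``bias.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    long_path = outdir / "results.csv"
    frame.to_csv(long_path, index=False)
    paths["results"] = long_path
    null = frame[frame["true_ab"] == 0]
    power = frame[frame["true_ab"] != 0]
    if not null.empty:
        p = outdir / "null_conditions.csv"
        _pivot_rates(null, "rejection_rate").to_csv(p, index=False)
        paths["null_conditions"] = p
    if not power.empty:
        p = outdir / "power_conditions.csv"
        _pivot_rates(power, "rejection_rate").to_csv(p, index=False)
        paths["power_conditions"] = p
    p = outdir / "balance.csv"
    _pivot_rates(frame, "balance").to_csv(p, index=False)
    paths["balance"] = p
    bias = (
        frame.groupby(["a_path", "b_path", "n"], as_index=False)[
            ["sample_mean_bias", "bootstrap_mean_bias"]
        ].first()
    )
    p = outdir / "bias.csv"
    bias.to_csv(p, index=False)
    paths["bias"] = p
    return paths


def write_manifest(cfg: StudyConfig, outdir: "str | Path") -> Path:
    """Write a JSON manifest recording the config and library versions."""
    import scipy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(cfg),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=list))
    return path


def load_config(path: "str | Path") -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file mirroring its fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    kwargs = {}
    tuple_fields = {"a_levels", "b_levels", "n_levels", "levels", "methods"}
    for key, value in raw.items():
        if key in tuple_fields:
            value = tuple(value)
        kwargs[key] = value
    return StudyConfig(**kwargs)
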