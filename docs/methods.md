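# Methods

## Model and estimands

The package works with the simple mediation model

    M = d2 + a·X + e2
    Y = d3 + c′·X + b·M + e3

with independent homoscedastic normal errors.  The target of inference
is the indirect effect *ab*, estimated by the product âb̂ of the OLS
slope of M on X and the partial OLS slope of Y on M controlling X.
âb̂ is exactly mean-unbiased under this model (E[b̂ | X, M] = b and â
depends only on (X, M), so E[âb̂] = ab), but its sampling distribution
is skewed at nonzero *ab*; median bias, not mean bias, is what the
bias-corrected bootstrap targets.

OLS is solved in closed form from centered sums of squares and
cross-products (the normal equations).  This is numerically equivalent
to a generic least-squares solver on these tiny, well-conditioned
designs (unit tests require 1e-10 agreement with `numpy.linalg.lstsq`)
and lets the bootstrap evaluate all B resamples as vectorized moment
arithmetic, which is what makes full-scale runs (1000 iterations ×
B = 5000) take seconds per condition rather than hours.

## Bootstrap engine

Case resampling: each replicate draws n row indices uniformly with
replacement and keeps (x, m, y) triples together.  The B indirect-effect
estimates are sorted ascending; every confidence limit is an element of
that sorted vector.

Percentile extraction uses the 1-based order statistic at ⌈p·B⌉,
clamped to [1, B], with no interpolation — at B = 5000 a 95% percentile
interval uses the 125th and 4875th ordered estimates, and bias-shifted
percentile positions map onto order statistics the same way.  A small
numerical guard (p·B − 1e-9) prevents binary floating point from
pushing an exact integer index such as 0.025 × 5000 up by one.

Degenerate resamples — a resampled x with zero variance, or resampled
(x, m) that are collinear (detected as 1 − r² ≤ 1e-12) — cannot yield an
indirect-effect estimate.  They are redrawn with fresh indices so the
distribution always holds exactly B values; the count is reported as
`n_degenerate` and a warning is emitted when more than 1% of B had to be
redrawn.  This matters only at very small n (at n = 4 roughly a third of
resamples have ≤ 2 distinct rows); at the study's n ≥ 25 it is
essentially never triggered.  A source sample whose own design is
degenerate raises an error instead.

## Confidence interval methods

All five methods consume one shared bootstrap distribution per dataset.

- **P** — limits at the α/2 and 1−α/2 empirical percentiles.
- **BC** — the median-bias constant ẑ_adj = Φ⁻¹(c/B), with c the number
  of bootstrap estimates *strictly* below âb̂, shifts both percentile
  positions: Φ(2ẑ_adj + z_{α/2}) and Φ(2ẑ_adj + z_{1−α/2}).  The count
  is clamped to [1, B−1] so the transform stays finite when âb̂ falls
  outside the whole distribution (the interval then degenerates toward
  the extreme order statistics and a warning is logged).  Ties between
  âb̂* and âb̂ are not counted — the strict inequality of the defining
  formula; ties have probability ~0 for continuous data.
- **rBC** — identical mapping with ẑ_adj added once instead of twice,
  correcting only the bootstrap-level median bias.
- **stBC** — a two-sided test of H0: the proportion of bootstrap
  estimates below âb̂ equals 0.5 gates the correction.  The default test
  is the normal approximation without continuity correction (reject when
  |c/B − 0.5| > z_{1−α_test/2}·√(0.25/B)), which at B = 5000 and
  α_test = 0.05 yields the achievable-proportion cutoffs 0.4862 and
  0.5138; an exact binomial gate is available behind `exact_gate` and
  agrees at these settings.  α_test is independent of the interval's
  confidence level.  The returned interval is always bit-identical to
  the BC or the P interval, with the branch recorded.
- **WBC** — BC with the bias reference replaced by the γ-Winsorized mean
  of the bootstrap distribution (γ = 0.30 per tail by default).
  Winsorization replaces the g = ⌊γB⌋ smallest values with the (g+1)th
  and the g largest with the (B−g)th before averaging; at γ = 0.5 the
  reference becomes the average of the two middle order statistics,
  ẑ_adj is 0, and the interval collapses to the percentile interval.
  The double-ẑ mapping is retained for WBC (the variant substitutes only
  the reference in the bias estimate, not the limit equations).

Whenever ẑ_adj = 0 all methods coincide exactly; for ẑ_adj > 0 the
percentile positions order as P ≤ rBC ≤ BC, mirrored for negative bias.

## Simulation design

The generator draws X i.i.d. standard normal and builds M and Y from the
equations above with standard-normal errors, zero intercepts, and
c′ = 0; X is redrawn every iteration.  Defaults mirror the comparison
study: path sizes {0, 0.14, 0.39, 0.59} (the conventional null / small /
medium / large levels — the small level is occasionally quoted as 0.16,
but all tabulated results use 0.14, so 0.14 is the default and 0.16
remains reachable via config), sample sizes {25, 50, 75, 100, 500},
1000 iterations per condition, B = 5000, 95% intervals (90% and 80%
selectable).

Seeding: each condition owns a `SeedSequence` derived from the master
seed and the condition coordinates (so results are independent of grid
enumeration order), and every iteration spawns separate child seeds for
data generation and for the bootstrap.  Any single iteration can be
replayed in isolation; identical configs are bit-reproducible.

Per iteration, all five intervals are computed from the single bootstrap
distribution (paired design).  This matches how such comparisons are
run, sharpens between-method contrasts, and is required for the stBC
interval to be bit-identical to that iteration's BC or P interval in
the outputs.

Measured outcomes per condition × method: rejection rate (type I error
when ab = 0, power otherwise; an interval "rejects" when both limits are
on the same side of zero, a limit exactly at zero counting as inclusion),
coverage, counts of intervals entirely above/below the true effect,
balance = above/(above+below) (reported as absent when no interval
misses the truth — not 0 and not 0.5), mean width, sample mean bias
(mean âb̂ − ab), and bootstrap mean bias (mean over iterations of the
bootstrap-distribution mean minus âb̂).  Null-condition rates get a
robustness flag against the liberal criterion [0.025, 0.075]; balance is
tested against 0.5 with an exact binomial test at α = 0.05 (exclusion
counts are often tiny, where the normal approximation is poor).

The matched-power mode compares each bias-corrected method's power
against a percentile interval whose confidence level is lowered to that
method's maximum null rejection rate — either derived from a grid run
via `derive_comparison_levels` or the published preset
(BC/stBC 91.2%, rBC 92.3%, WBC 92.7%).  Method and matched interval are
computed from the same distributions within each iteration.

## What the generator does and does not emulate

It reproduces the idealized study conditions exactly: correctly
specified model, continuous normal data, no missing values, no
confounding, homoscedastic errors.  Passing tests therefore demonstrate
correctness of the estimators, interval constructions, and aggregation
under those conditions — not robustness of the methods to assumption
violations (non-normality, outliers, missingness), which the harness
does not simulate.

## Problem sizes and tolerances

The test suite verifies the headline rates at full per-condition scale
(1000 iterations × B = 5000) for five conditions, using 3-binomial-SE
tolerances appropriate to 1000-iteration proportions; the method-ordering
continuum is checked on a reduced 3 × 3 × {25, 75} grid at 300
iterations × B = 1000, requiring the P ≤ WBC ≤ rBC ≤ stBC ≤ BC ordering
in at least 90% of adjacent comparisons.  Full 80-condition grid
summaries (e.g. the stBC gate's average rejection frequency and the
complete matched-power tables) are produced by `run_grid` /
`run_matched_power` but are not part of the default suite; the
machinery is exercised at reduced scale instead.

## Known limitations

- Single mediator, OLS only; no SEM estimation, standard errors, or
  BCa (acceleration) intervals.
- No residual, wild, or iterated bootstrap.
- The degenerate-resample redraw policy is a documented implementation
  choice; alternatives (dropping, NaN-propagation) would change nothing
  at realistic n but differ at n ≲ 5.
- Reported percentile positions are the Φ-mapped probabilities actually
  used; because extraction is by order statistic, realized coverage is
  granular in 1/B.
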