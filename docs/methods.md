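# Methods

This note records the models implemented in `tpphen`, the numerical choices
behind them, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Rate-summation framework

All three models share the accumulation loop: walk a temperature
time-series with a fixed step (default 24 h), obtain a development rate
(stage fraction per day) for the current life stage at the step's
temperature, add `rate × step_days` to the stage fraction, and complete the
stage at the first step where the cumulative fraction reaches 1. The next
stage starts at the following step and the overshoot beyond 1 is discarded,
matching the daily granularity at which rearing observations are made.
Seasonal timing (diapause, oviposition date) is out of scope: day 0 is
oviposition and all emergence days are relative to it.

Numerical detail: completion is tested against `1 − 1e-9` rather than 1.
Accumulating tens of float steps makes a rate that divides the step exactly
(0.1/day over 10 days) land at 0.9999999999999999; without the slack the
stage would complete a day late. The slack is far below any biologically
meaningful rate difference.

An individual that has not completed all stages when the series or the
`max_days` horizon (default 365 d, a guard against near-zero rates) ends is
*censored*, reported as a count next to each stage's emergence-day sample,
never silently dropped.

## Model 1 — mean thermal performance curve

The Lactin-1 form `r(T) = exp(ρT) − exp(ρ t_max − (t_max − T)/Δ)` is fitted
by least squares to per-temperature mean rates (≥ 4 distinct temperatures
required), with a 36-point multi-start grid over (ρ, t_max, Δ) to avoid
local minima; the lowest residual sum of squares wins. The curve is clamped
at zero (development cannot regress) and is exactly zero at `t_max`. Every
individual develops at the same deterministic rate, so Model 1 predicts one
emergence day per stage.

## Model 2A — thermal performance probability

At each rearing temperature and stage, observed rates are modelled as a
two-component Gaussian mixture (weights λ₁+λ₂ = 1). The EM fit uses:

* tolerance 1e-8 on the log-likelihood, at most 1000 iterations;
* restart 0 initialized by a hard split at the sample median, further
  restarts (10 by default) by random assignment from the seed — the best
  log-likelihood wins, so the result is label-order invariant;
* a variance floor of 1e-6 × sample range against singular components;
* components relabelled so μ₁ ≤ μ₂: component 1 *is* the slow component by
  definition (lower development rate).

Samples smaller than 4, non-positive rates and zero-variance samples are
rejected. Surface fitting over a whole dataset can optionally collapse a
zero-variance cell (every individual took the same number of days, common
at daily resolution for short stages) to a near-degenerate mixture instead
of failing, so that one cell does not block the downstream stages.

Between anchor temperatures every mixture parameter p is interpolated
linearly, `p(T_x) = p_{T1} + (p_{T2} − p_{T1})(1 − (T2 − T_x)/(T2 − T1))`;
weights are re-normalized afterwards so rounding cannot push λ₁+λ₂ off 1.
The standard deviation σ (not the variance) is the interpolated parameter.
Outside the anchor range parameters clamp to the nearest anchor — a
deliberately conservative default; extending the surface to the thermal
limits with a fitted TPC through the component means is possible but not
the default because it extrapolates beyond the data. A single-anchor
surface is allowed for constant-temperature work.

During simulation each individual redraws its rate from the interpolated
mixture at every time step; negative draws truncate to 0.

## Model 2B — TPP with pace-of-life strategies

The population is split at birth into `floor(slow·n)` slow and
`floor(fast·n)` fast individuals (remainder intermediate), shuffled once,
strategies fixed for life. Slow/fast individuals draw each step from
component 1/2 only; intermediates from the full mixture. With composition
(0, 0) the model reduces bit-for-bit to Model 2A under the same seed.

### Strategy classification

Within one rearing temperature, each scored stage (egg + six larval
instars, 7 stages) is median-split over all individuals observed at that
stage. Ties at the median go to the *lower* category — a deterministic
choice that matters because daily checks quantize durations and ties are
common. An individual in the same category for ≥ 5 of 7 stages is fast or
slow; individuals missing any scored stage are excluded. The rule depends
only on ranks, hence is invariant under monotone transforms of the rates.

Two structural properties of this rule worth knowing (both derived in the
test suite):

* an individual whose per-stage side is an independent coin flip still
  reaches 5-of-7 consistency with probability 2·P(Bin(7, ½) ≥ 5) ≈ 0.45, so
  genuinely unstructured individuals inflate the slow/fast classes — the
  classifier's output is the true composition convolved with this chance
  kernel, not the composition itself;
* the ties-to-lower rule biases toward "slow" when durations are heavily
  quantized (short stages at warm temperatures), since the median then
  coincides with a modal value. A tie-splitting sensitivity analysis is
  straightforward by re-running `categorize_stagewise` on jittered rates.

## Evaluation

Model 1 is scored by RMSE (days) between its scalar per-stage emergence day
and the observed individuals. Models 2A/2B are scored by the Dhat1 overlap:
Gaussian KDEs of the predicted and observed emergence-day samples with
normal-reference (Silverman) plug-in bandwidths, evaluated on a shared
512-point linear grid padded by 3 bandwidths, pointwise minimum integrated
by the trapezoid rule, clipped into [0, 1]. Samples with fewer than 2
points or zero spread yield an NA marker (a unique observed value cannot
support an overlap). The estimator is symmetric and shift-invariant; its
grid and bandwidth are fixed for bit-reproducibility.

Cross-validation: per repeat, each temperature's individuals are split
70/30 (the split unit is the *individual*, so evaluation phenologies stay
coherent; the per-observation alternative would scatter one individual's
stages across both sides). All responses and the strategy composition are
fitted on the calibration side; models are simulated along each
temperature's series (constant at the rearing mean unless measured series
are supplied); observed per-stage emergence is the cumulative sum of the
individual's stage durations. Per (temperature, stage) cell the best
overlap across repeats is kept, cells are won by the higher best overlap,
and the report carries both win fractions over decided cells and a full
partition of cells into m2a/m2b/tie/na.

## Synthetic-data generator

The generator emulates the structure of an individually-followed rearing
study: ~5 temperatures (13–30 °C) spanning the favourable range, nine
stages, one row per individual × stage, durations rounded to the daily
check resolution. The truth behind each dataset is explicit: per-individual
strategies with exact composition counts, and per-(temperature, stage)
mixtures whose mid rate follows a degree-day-style linear response above a
6 °C threshold, with stage baselines (egg 5 d … pupa 12 d at 20 °C) chosen
to resemble a multivoltine noctuid moth. Components sit at 0.75× and 1.25×
the mid rate with a within-component spread of 10% of the mid rate
(components 5σ apart). The 10% spread is deliberate: real rearing data show
roughly that coefficient of variation, and a much tighter spread would
collapse rounded durations onto one or two discrete values, making the
median split degenerate. Egg mortality can be injected per temperature
(dead eggs keep their E row but no later stages), which is what the
egg-survival filter (retain temperatures with ≥ 50% egg survival) keys on.

What the generator does **not** emulate: within-individual persistence for
intermediates (each stage's rate is an independent mixture draw), rate
correlations between stages, temperature fluctuation within a rearing unit,
measurement error other than rounding, and mortality after the egg stage.
Passing round-trip tests therefore shows the pipeline is self-consistent
under the stated stochastic model — not that real populations satisfy that
model.

## Virtual-species experiment

A virtual species applies one mixture (defaults: μ = 0.05/0.10 per day,
σ = 0.01, λ = ½/½, single 20 °C anchor — constant-temperature runs never
leave the anchor) identically to 4 or 8 life stages. For each slow × fast
composition on a 0–50% by 10% grid, Model 2B runs 30 times with 100
individuals; the cell records the mean variance of the last stage's
emergence days. Cells are normalized by the maximum mean variance across
all grids in the experiment, so the 4- and 8-stage grids share one scale
with a global maximum of exactly 1. Per-(cell, run) child seeds derive from
one root seed, making cells independent of evaluation order.

## Reproducibility

Every stochastic entry point takes an integer seed; derived streams use
`numpy.random.SeedSequence` spawning, so identical inputs give bit-identical
outputs. Problem sizes in the tests and the acceptance script (e.g. 60–120
individuals per temperature, 1–3 cross-validation repeats, 80–100 simulated
individuals) are desk-scale choices that keep every quantity's Monte-Carlo
error comfortably below the assertion tolerances while the full pipeline
runs in minutes.

## Known limitations

* K is fixed at 2 mixture components; no Bayesian or K > 2 variants.
* Linear parameter interpolation assumes anchors are dense and well spread
  over the thermal range; clamping makes out-of-range predictions constant.
* The classifier's chance floor (above) means reported slow/fast
  proportions are upper bounds on the structured fraction.
* Constant-temperature evaluation series ignore the mild fluctuation real
  rearing units show; measured series can be supplied but are not required.
* No behavioural thermoregulation, microclimate choice, or field
  validation under natural fluctuating temperatures.
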