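# tpphen

Individual-based phenology prediction for ectotherms, built around **thermal
performance probability (TPP)** surfaces and **pace-of-life (POL)**
slow/fast strategies.

## The problem

The timing of life-cycle events in ectotherms — when eggs hatch, larvae
moult, pupae emerge — is driven by temperature through the development rate.
The classical tool is the thermal performance curve (TPC): a single mean
rate *r(T)* per life stage, accumulated over a temperature time-series until
the stage fraction reaches 1 (rate summation). A mean curve, however,
predicts one identical emergence day for every individual, while real
populations — even siblings reared side by side — spread their emergence
over days to weeks. Part of that spread is persistent: some individuals are
consistently *fast* across life stages and some consistently *slow*, the
pace-of-life syndrome.

`tpphen` implements three nested models of increasing realism and the tools
to fit, simulate and compare them:

* **Model 1 (TPC)** — Lactin-1 mean curve,
  `r(T) = exp(ρT) − exp(ρ t_max − (t_max − T)/Δ)`, clamped at 0.
* **Model 2A (TPP)** — at every rearing temperature the observed rates are
  described by a two-component Gaussian mixture
  `f(x) = Σ_k λ_k N(μ_k, σ_k²)` (K = 2), fitted by expectation–maximization;
  the six parameters are interpolated linearly between anchor temperatures
  to form a continuous probability surface. Each individual redraws its rate
  from the mixture at every time step.
* **Model 2B (TPP + POL)** — individuals are slow, fast or intermediate for
  life; slow and fast individuals draw only from the first (lower-rate) or
  second mixture component, intermediates from the full mixture.

Strategies are estimated from individually-followed rearing data by a
median split per stage: an individual in the same half of the population
for at least 5 of 7 scored stages (egg + six larval instars) is classified
slow or fast. Probabilistic predictions are scored against observed
emergence-day distributions with the small-sample overlap estimator Dhat1
(`∫ min(f̂, ĝ)` between kernel density estimates); the deterministic Model 1
is scored by RMSE.

The package is aimed at thermal ecologists and phenology modellers: it
consumes per-individual stage-duration tables from rearing experiments
(CSV), and it ships a fully parameterized synthetic-data generator so every
pipeline stage can be exercised — and round-trip tested — without live
insects.

## Worked example

```bash
python examples/03_simulate_phenology.py
```

```
M2A (slow=0%, fast=0%): last stage emerges on day 55.5 +- 2.5 (range 49-61)
M2B (slow=30%, fast=30%): last stage emerges on day 59.8 +- 15.9 (range 40-86)
```

A four-stage virtual species develops at a constant 20 °C with slow and fast
mixture components at 0.05 and 0.10 stage/day. Under Model 2A the daily
redraws average out across a stage, so all 200 individuals emerge within a
~12-day window. Under Model 2B with 30% slow and 30% fast individuals the
persistent strategies survive accumulation: slow individuals need ~20 days
per stage and fast ones ~10, so the population's final emergence spreads
over ~46 days — the pace-of-life signal a mean-curve model cannot produce.

The other examples cover fitting (`01`), classification (`02`),
cross-validated model comparison (`04`) and the phenological-variance grid
(`05`). The same functionality is available from the shell via the `tpphen`
CLI (`tpphen generate|fit|classify|simulate|evaluate|explore`).

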