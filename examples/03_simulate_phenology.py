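"""Predict population phenology under the three accumulation models.

A four-stage virtual species develops at a constant 20 °C.  Model 1 (mean
curve) gives one emergence day per stage; Model 2A draws a fresh rate from
the population mixture at every step; Model 2B fixes slow/fast strategies at
birth (30% slow, 30% fast here).  The printed spread (standard deviation of
emergence days across individuals) shows why the models differ: redrawing
every day averages individual differences away, persistent strategies keep
them.
"""

import numpy as np

from tpphen import (
    SimulationConfig,
    TemperatureSeries,
    default_virtual_species,
    simulate_population,
    stage_distribution,
)

species = default_virtual_species(n_stages=4)
series = TemperatureSeries.constant(20.0, days=200)

for model, comp in (("M2A", (0.0, 0.0)), ("M2B", (0.3, 0.3))):
    pred = simulate_population(
        SimulationConfig(model=model, n_individuals=200, n_stages=4,
                         strategy_composition=comp, seed=1),
        [species.surface] * 4, series,
    )
    days, _ = stage_distribution(pred, 3)
    print(f"{model} (slow={comp[0]:.0%}, fast={comp[1]:.0%}): "
          f"last stage emerges on day {days.mean():.1f} "
          f"+- {days.std():.1f} (range {days.min():.0f}-{days.max():.0f})")
print("Slow individuals develop at ~0.05 stage/day (20 d per stage), fast at "
      "~0.10 (10 d); Model 2B's wider spread is the pace-of-life signal.")
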