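"""Synthetic rearing-data generation with known pace-of-life ground truth.

The generator emulates the structure of an individual-based rearing study:
cohorts at ~5 temperatures spanning the favourable thermal range, nine life
stages (E, L1--L6, P, A), and per-individual stage durations recorded at daily
resolution.  Each individual carries a true slow/fast/intermediate strategy;
its realized development rate for every stage is drawn from the stage's
two-component mixture restricted to the matching component (full mixture for
intermediates), then converted to a duration and rounded to the observation
resolution.

Default mixture truth: every stage has a baseline duration at 20 °C, rates
scale linearly with temperature above a 6 °C lower threshold (a degree-day
style response), the slow/fast component means sit at 0.75x / 1.25x the
stage's mid rate, component spread is 10% of the mid rate (components 5
sigma apart, i.e. clearly bimodal yet with realistic within-component
variability), and weights are (0.5, 0.5).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import OBS_COLUMNS, STAGES, RearingDataset
from .thermal import GaussianMixturePair, TPPSurface, sample_rate

__all__ = ["GeneratorTruth", "default_truth", "generate_rearing_dataset"]

#: Baseline stage durations (days) at the 20 °C reference temperature.
BASE_DURATIONS_20C: dict[str, float] = {
    "E": 5.0, "L1": 3.0, "L2": 3.0, "L3": 4.0, "L4": 4.0,
    "L5": 5.0, "L6": 6.0, "P": 12.0, "A": 10.0,
}
DEFAULT_TEMPS: tuple[float, ...] = (13.0, 18.0, 20.0, 25.0, 30.0)
_T_BASE = 6.0  # lower developmental threshold, °C
_T_REF = 20.0


@dataclasses.dataclass
class GeneratorTruth:
    """Ground truth behind a synthetic dataset.

    ``strategies`` maps individual id -> true strategy; ``mixtures`` maps
    ``(temperature, stage)`` to the true rate mixture.  Kept alongside the
    generated observations so that round-trip tests (fit, classify, predict)
    can compare against the truth.
    """

    strategies: dict[str, str]
    mixtures: dict[tuple[float, str], GaussianMixturePair]
    seed: int

    def surface(self, stage: str) -> TPPSurface:
        anchors = {t: m for (t, s), m in self.mixtures.items() if s == stage}
        return TPPSurface(stage=stage, anchors=anchors)

    def composition(self) -> tuple[float, float, float]:
        labels = list(self.strategies.values())
        n = len(labels)
        return (
            labels.count("slow") / n,
            labels.count("fast") / n,
            labels.count("intermediate") / n,
        )


def _mid_rate(stage: str, temp: float) -> float:
    scale = max((temp - _T_BASE) / (_T_REF - _T_BASE), 0.05)
    return scale / BASE_DURATIONS_20C[stage]


def default_truth(
    n_per_temp: int = 120,
    composition: tuple[float, float] = (0.2, 0.2),
    temps: Sequence[float] = DEFAULT_TEMPS,
    stages: Sequence[str] = STAGES,
    seed: int = 0,
    slow_factor: float = 0.75,
    fast_factor: float = 1.25,
    rel_sigma: float = 0.10,
    weights: tuple[float, float] = (0.5, 0.5),
) -> GeneratorTruth:
    """Build a ground truth with exact strategy counts per temperature.

    ``composition`` gives the (slow, fast) fractions; counts are
    ``floor(frac * n)`` with the remainder intermediate, shuffled per
    temperature.  Mixture components at each (temperature, stage) sit at
    ``slow_factor`` / ``fast_factor`` times the stage's mid rate with standard
    deviation ``rel_sigma`` times the mid rate.
    """
    slow_frac, fast_frac = composition
    if slow_frac < 0 or fast_frac < 0 or slow_frac + fast_frac > 1:
        raise ValueError("composition fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    strategies: dict[str, str] = {}
    n_slow = int(np.floor(slow_frac * n_per_temp))
    n_fast = int(np.floor(fast_frac * n_per_temp))
    for temp in temps:
        labels = np.array(
            ["slow"] * n_slow
            + ["fast"] * n_fast
            + ["intermediate"] * (n_per_temp - n_slow - n_fast),
            dtype=object,
        )
        rng.shuffle(labels)
        for i, lab in enumerate(labels):
            strategies[f"T{temp:g}_i{i:04d}"] = str(lab)
    mixtures: dict[tuple[float, str], GaussianMixturePair] = {}
    for temp in temps:
        for stage in stages:
            mid = _mid_rate(stage, float(temp))
            mixtures[(float(temp), stage)] = GaussianMixturePair(
                lambda1=weights[0],
                lambda2=weights[1],
                mu1=slow_factor * mid,
                mu2=fast_factor * mid,
                sigma1=rel_sigma * mid,
                sigma2=rel_sigma * mid,
            )
    return GeneratorTruth(strategies=strategies, mixtures=mixtures, seed=seed)


def _positive_rate(
    mix: GaussianMixturePair, strategy: str, rng: np.random.Generator
) -> float:
    # negative draws truncate to 0, which has no finite duration; redraw
    for _ in range(100):
        r = sample_rate(mix, strategy, rng)
        if r > 0:
            return r
    return max(mix.mu1, 1e-6)


def generate_rearing_dataset(
    truth: GeneratorTruth,
    temps: Sequence[float] | None = None,
    n_per_temp: int | None = None,
    duration_resolution: float = 1.0,
    egg_survival: Mapping[float, float] | None = None,
    stages: Sequence[str] = STAGES,
) -> RearingDataset:
    """Generate an observation table from a ground truth.

    For every individual x stage a rate is drawn from the stage's mixture
    under the individual's true strategy, converted to a duration
    ``1 / rate``, rounded to ``duration_resolution`` (default: daily checks)
    and floored at one resolution unit.  With ``egg_survival`` given, a
    ``1 - survival`` fraction of each cohort dies in the egg: those
    individuals keep their E row but no later stages, which is what the
    egg-survival filter keys on.

    Deterministic given the truth's seed.
    """
    if duration_resolution <= 0:
        raise ValueError("duration_resolution must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    truth_temps = sorted({t for t, _ in truth.mixtures})
    temps = [float(t) for t in (temps if temps is not None else truth_temps)]
    rows: list[dict] = []
    for temp in temps:
        unit = f"U{temp:g}"
        ids = sorted(i for i in truth.strategies if i.startswith(f"T{temp:g}_"))
        if n_per_temp is not None:
            ids = ids[:n_per_temp]
        if len(ids) < 2:
            raise ValueError(f"need >= 2 individuals at {temp} °C, got {len(ids)}")
        survival = 1.0 if egg_survival is None else float(egg_survival.get(temp, 1.0))
        dead = rng.random(len(ids)) >= survival
        for k, ind in enumerate(ids):
            strategy = truth.strategies[ind]
            for stage in stages:
                mix = truth.mixtures[(temp, stage)]
                rate = _positive_rate(mix, strategy, rng)
                duration = max(
                    round((1.0 / rate) / duration_resolution) * duration_resolution,
                    duration_resolution,
                )
                rows.append(
                    dict(
                        individual_id=ind,
                        rearing_unit=unit,
                        mean_temp=temp,
                        stage=stage,
                        duration_days=duration,
                    )
                )
                if dead[k] and stage == "E":
                    break
    frame = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return RearingDataset(frame, {t: None for t in temps})
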