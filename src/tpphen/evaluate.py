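"""Goodness-of-fit between predicted and observed phenology distributions.

Model 1 produces a single emergence day per stage and is scored by the root
mean squared error against the observed individuals.  Models 2A/2B produce a
*distribution* of emergence days and are scored by the Dhat1 overlap
coefficient -- an estimate of ``integral min(f, g)`` between kernel density
estimates of the predicted and observed samples, suited to the small samples
(< 50) typical of per-stage evaluation sets.  Overlap 1 means a perfect
prediction of the whole distribution, 0 means none.

`cross_validated_comparison` ties everything together: repeated 70/30
calibration/evaluation splits at the individual level, model fitting on the
calibration side, simulation along each temperature's series, and per
(temperature, stage) scoring, with the best overlap per cell across repeats.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .datasets import (
    MODEL_STAGES,
    SCORED_STAGES,
    RearingDataset,
    TemperatureSeries,
    split_calibration_evaluation,
)
from .engine import PhenologyPrediction, SimulationConfig, simulate_population, stage_distribution
from .pol import assign_strategies, categorize_stagewise, strategy_proportions
from .thermal import LactinTPC, TPPSurface, fit_lactin1, fit_tpp_surface

__all__ = [
    "OverlapScore",
    "ComparisonReport",
    "rmse",
    "dhat1_overlap",
    "observed_phenology",
    "cross_validated_comparison",
    "tally_winners",
]


@dataclasses.dataclass(frozen=True)
class OverlapScore:
    """Dhat1 overlap between two emergence-day samples, in [0, 1]."""

    value: float
    n_pred: int
    n_obs: int
    estimator: str = "Dhat1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")


def rmse(predicted: float, observed) -> float | None:
    """Root mean squared error of a scalar prediction against observations.

    Returns ``None`` when the observed sample is empty.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        return None
    return float(np.sqrt(np.mean((obs - float(predicted)) ** 2)))


def dhat1_overlap(
    sample_a, sample_b, grid_size: int = 512, pad_bandwidths: float = 3.0
) -> OverlapScore | None:
    """Dhat1 overlap coefficient between two samples.

    Both samples get a Gaussian kernel density estimate with a
    normal-reference (Silverman) plug-in bandwidth; the pointwise minimum of
    the two densities is integrated by the trapezoid rule on a shared linear
    grid spanning both ranges padded by ``pad_bandwidths`` bandwidths, and the
    result is clipped into [0, 1].  Symmetric in its arguments and invariant
    under a common shift.

    Returns ``None`` (not-available marker) when either sample has fewer than
    2 points or zero spread -- e.g. when the evaluation data reduce to a
    unique value.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    bw_a = float(np.sqrt(kde_a.covariance[0, 0]))
    bw_b = float(np.sqrt(kde_b.covariance[0, 0]))
    lo = min(a.min() - pad_bandwidths * bw_a, b.min() - pad_bandwidths * bw_b)
    hi = max(a.max() + pad_bandwidths * bw_a, b.max() + pad_bandwidths * bw_b)
    grid = np.linspace(lo, hi, grid_size)
    overlap = np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid)
    return OverlapScore(
        value=float(np.clip(overlap, 0.0, 1.0)), n_pred=a.size, n_obs=b.size
    )


def observed_phenology(
    dataset: RearingDataset, temperature: float, stages: Sequence[str] = MODEL_STAGES
) -> pd.DataFrame:
    """Observed cumulative emergence day per individual per stage.

    Observation and prediction share the same time axis: oviposition is day 0
    and the emergence day of stage ``s`` is the sum of the individual's stage
    durations up to and including ``s``.  A stage is ``NaN`` whenever any
    earlier stage duration is missing.
    """
    stages = list(stages)
    f = dataset.frame
    sub = f[f["mean_temp"] == float(temperature)]
    wide = sub.pivot(index="individual_id", columns="stage", values="duration_days")
    wide = wide.reindex(columns=stages)
    return wide.cumsum(axis=1, skipna=False)


def _derived_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence([root, *key]).generate_state(1)[0] % 2**31)


@dataclasses.dataclass
class ComparisonReport:
    """Cross-validated model comparison.

    ``rows`` is the tidy per-repeat score table
    (``temp_c, stage, model, metric, value, n_pred, n_obs, repeat``).
    ``best_overlap`` holds the best overlap per (temperature, stage, model)
    across repeats (the headline evaluation convention); ``mean_overlap_by_temp``
    the repeat-averaged mean overlap per temperature and model.  ``wins`` are
    fractions over decided (non-NA, non-tie) cells; ``cell_fractions``
    partitions *all* cells into m2a/m2b/tie/na and sums to 1.
    """

    rows: pd.DataFrame
    best_overlap: pd.DataFrame
    rmse_table: pd.DataFrame
    wins: dict[str, float]
    cell_fractions: dict[str, float]
    mean_overlap: dict[str, float]
    mean_overlap_by_temp: pd.DataFrame


def tally_winners(best_overlap: pd.DataFrame) -> tuple[dict[str, float], dict[str, float]]:
    """Count per-cell winners from a best-overlap table.

    ``best_overlap`` must have columns ``temp_c, stage, M2A, M2B`` where the
    model columns hold the best overlap (NaN = not available).  Returns
    ``(wins, cell_fractions)``: ``wins`` are fractions of decided cells won by
    each model; ``cell_fractions`` cover all cells (m2a + m2b + tie + na = 1).
    """
    n_cells = len(best_overlap)
    if n_cells == 0:
        raise ValueError("empty score table")
    a = best_overlap["M2A"].to_numpy(dtype=float)
    b = best_overlap["M2B"].to_numpy(dtype=float)
    na = np.isnan(a) | np.isnan(b)
    tie = ~na & (a == b)
    m2a = ~na & (a > b)
    m2b = ~na & (b > a)
    decided = int(m2a.sum() + m2b.sum())
    wins = {
        "M2A": float(m2a.sum() / decided) if decided else float("nan"),
        "M2B": float(m2b.sum() / decided) if decided else float("nan"),
    }
    cell_fractions = {
        "m2a": float(m2a.sum() / n_cells),
        "m2b": float(m2b.sum() / n_cells),
        "tie": float(tie.sum() / n_cells),
        "na": float(na.sum() / n_cells),
    }
    return wins, cell_fractions


def cross_validated_comparison(
    dataset: RearingDataset,
    n_repeats: int = 1,
    seed: int = 0,
    *,
    stages: Sequence[str] = MODEL_STAGES,
    scored_stages: Sequence[str] = SCORED_STAGES,
    k_min: int = 5,
    frac: float = 0.7,
    n_individuals: int = 100,
    max_days: float = 365.0,
    series_by_temp: Mapping[float, TemperatureSeries] | None = None,
    em_restarts: int = 5,
) -> ComparisonReport:
    """Repeated 70/30 cross-validation of Models 1, 2A and 2B.

    For each repeat the dataset is split per temperature at the individual
    level; Lactin-1 curves, TPP surfaces and strategy proportions are fitted
    on the calibration side; each model is simulated along every
    temperature's series (a constant series at the rearing temperature unless
    ``series_by_temp`` provides measured ones); and every
    (temperature, stage) cell is scored by RMSE (M1) or Dhat1 overlap
    (M2A/M2B) against the evaluation individuals.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    stages = list(stages)
    temps = list(dataset.temperatures)
    rows: list[dict] = []

    for rep in range(n_repeats):
        cal, ev = split_calibration_evaluation(
            dataset, frac=frac, seed=_derived_seed(seed, rep, 0)
        )

        # thermal responses from the calibration side
        tpcs: dict[str, LactinTPC | None] = {}
        surfaces: dict[str, TPPSurface | None] = {}
        for stage in stages:
            sub = cal.frame[cal.frame["stage"] == stage]
            try:
                tpcs[stage] = fit_lactin1(
                    sub["mean_temp"].to_numpy(), sub["rate"].to_numpy()
                )
            except (ValueError, RuntimeError):
                tpcs[stage] = None
            try:
                surfaces[stage] = fit_tpp_surface(
                    cal,
                    stage,
                    seed=_derived_seed(seed, rep, 1),
                    restarts=em_restarts,
                    on_degenerate="collapse",
                )
            except ValueError:
                surfaces[stage] = None

        # longest stage prefix with a usable probabilistic response
        prefix = 0
        while prefix < len(stages) and surfaces[stages[prefix]] is not None:
            prefix += 1
        tpc_prefix = 0
        while tpc_prefix < len(stages) and tpcs[stages[tpc_prefix]] is not None:
            tpc_prefix += 1

        for ti, temp in enumerate(temps):
            series = (
                series_by_temp[temp]
                if series_by_temp is not None and temp in series_by_temp
                else TemperatureSeries.constant(temp, max_days)
            )
            try:
                table = categorize_stagewise(cal, temp, scored_stages)
                assignment = assign_strategies(table, k_min=k_min)
                slow, fast, _ = strategy_proportions(assignment)
            except ValueError:
                slow, fast = 0.0, 0.0

            observed = observed_phenology(ev, temp, stages)

            preds: dict[str, PhenologyPrediction | None] = {}
            if tpc_prefix:
                preds["M1"] = simulate_population(
                    SimulationConfig(
                        model="M1",
                        n_individuals=1,
                        n_stages=tpc_prefix,
                        seed=_derived_seed(seed, rep, 2, ti),
                        max_days=max_days,
                    ),
                    [tpcs[s] for s in stages[:tpc_prefix]],
                    series,
                )
            else:
                preds["M1"] = None
            for model, comp in (("M2A", (0.0, 0.0)), ("M2B", (slow, fast))):
                if prefix:
                    preds[model] = simulate_population(
                        SimulationConfig(
                            model=model,
                            n_individuals=n_individuals,
                            n_stages=prefix,
                            strategy_composition=comp,
                            seed=_derived_seed(seed, rep, 3, ti),
                            max_days=max_days,
                        ),
                        [surfaces[s] for s in stages[:prefix]],
                        series,
                    )
                else:
                    preds[model] = None

            for si, stage in enumerate(stages):
                obs = (
                    observed[stage].dropna().to_numpy()
                    if stage in observed.columns
                    else np.array([])
                )
                # Model 1: scalar predicted day, RMSE
                value = None
                n_pred = 0
                if preds["M1"] is not None and si < tpc_prefix:
                    day = preds["M1"].emergence[0, si]
                    if not np.isnan(day):
                        value = rmse(day, obs)
                        n_pred = 1
                rows.append(
                    dict(
                        temp_c=temp, stage=stage, model="M1", metric="rmse",
                        value=np.nan if value is None else value,
                        n_pred=n_pred, n_obs=obs.size, repeat=rep,
                    )
                )
                # Models 2A/2B: Dhat1 overlap
                for model in ("M2A", "M2B"):
                    score = None
                    n_pred = 0
                    if preds[model] is not None and si < prefix:
                        sample, _ = stage_distribution(preds[model], si)
                        n_pred = sample.size
                        score = dhat1_overlap(sample, obs)
                    rows.append(
                        dict(
                            temp_c=temp, stage=stage, model=model, metric="dhat1",
                            value=np.nan if score is None else score.value,
                            n_pred=n_pred, n_obs=obs.size, repeat=rep,
                        )
                    )

    frame = pd.DataFrame(rows)
    ov = frame[frame["metric"] == "dhat1"]
    best = (
        ov.pivot_table(
            index=["temp_c", "stage"], columns="model", values="value", aggfunc="max"
        )
        .reindex(columns=["M2A", "M2B"])
        .reset_index()
    )
    best.columns.name = None
    wins, cell_fractions = tally_winners(best)
    mean_overlap = {
        m: float(ov.loc[ov["model"] == m, "value"].mean()) for m in ("M2A", "M2B")
    }
    mean_by_temp = (
        ov.pivot_table(index="temp_c", columns="model", values="value", aggfunc="mean")
        .reset_index()
    )
    mean_by_temp.columns.name = None
    rmse_rows = frame[frame["metric"] == "rmse"]
    rmse_table = (
        rmse_rows.pivot_table(index=["temp_c", "stage"], values="value", aggfunc="mean")
        .rename(columns={"value": "rmse"})
        .reset_index()
    )
    return ComparisonReport(
        rows=frame,
        best_overlap=best,
        rmse_table=rmse_table,
        wins=wins,
        cell_fractions=cell_fractions,
        mean_overlap=mean_overlap,
        mean_overlap_by_temp=mean_by_temp,
    )
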