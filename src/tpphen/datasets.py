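"""Data containers and file I/O for individually followed rearing experiments.

The experimental design mirrors classical insect rearing studies: cohorts of
eggs are kept at a small number of roughly constant temperatures, every
individual sits in its own container, and a daily check records when it moults
into the next life stage.  The stage alphabet is fixed to nine stages typical
of noctuid moths: egg (``E``), six larval instars (``L1``--``L6``), pupa
(``P``) and adult (``A``).

A development *rate* is the fraction of a life stage completed per day,
``1 / duration``.  Rate summation over a temperature time-series is what the
phenology engine consumes downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Ordered life-stage alphabet.
STAGES: tuple[str, ...] = ("E", "L1", "L2", "L3", "L4", "L5", "L6", "P", "A")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
#: Stages scored for pace-of-life consistency: egg through the last larval instar.
SCORED_STAGES: tuple[str, ...] = STAGES[:7]
#: Stages carried through simulation/evaluation by default (adult excluded).
MODEL_STAGES: tuple[str, ...] = STAGES[:8]

OBS_COLUMNS = ["individual_id", "rearing_unit", "mean_temp", "stage", "duration_days"]


class FormatError(ValueError):
    """An input file does not match the expected schema."""


@dataclasses.dataclass(frozen=True)
class StageObservation:
    """One individual's time spent in one life stage at its rearing temperature."""

    individual_id: str
    rearing_unit: str
    mean_temp: float
    stage: str
    duration: float

    def __post_init__(self) -> None:
        if self.stage not in STAGE_INDEX:
            raise ValueError(f"unknown stage label {self.stage!r}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Stage fraction completed per day (1/duration)."""
        return 1.0 / self.duration


class RearingDataset:
    """Per-individual stage durations at each rearing temperature.

    Parameters
    ----------
    frame:
        Table with columns ``individual_id, rearing_unit, mean_temp, stage,
        duration_days``; a ``rate`` column is derived.  Each
        ``(individual_id, stage)`` pair appears at most once and an individual
        is reared at a single temperature.
    temperatures:
        Optional mapping of rearing temperature (°C) to the measured standard
        deviation of that unit's temperature (``None`` when unknown).
        Defaults to the distinct temperatures present in ``frame``.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        temperatures: Mapping[float, float | None] | None = None,
    ) -> None:
        missing = [c for c in OBS_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, OBS_COLUMNS].copy()
        frame["individual_id"] = frame["individual_id"].astype(str)
        frame["rearing_unit"] = frame["rearing_unit"].astype(str)
        frame["stage"] = frame["stage"].astype(str)
        frame["mean_temp"] = frame["mean_temp"].astype(float)
        frame["duration_days"] = frame["duration_days"].astype(float)

        bad = ~frame["stage"].isin(STAGES)
        if bad.any():
            labels = sorted(frame.loc[bad, "stage"].unique())
            raise ValueError(f"unknown stage label(s): {labels}")
        bad = ~(frame["duration_days"] > 0)
        if bad.any():
            ids = sorted(frame.loc[bad, "individual_id"].unique())
            raise ValueError(f"non-positive duration for individual(s): {ids}")
        dup = frame.duplicated(["individual_id", "stage"])
        if dup.any():
            pairs = frame.loc[dup, ["individual_id", "stage"]].values.tolist()
            raise ValueError(f"duplicate (individual, stage) record(s): {pairs}")
        multi = frame.groupby("individual_id")["mean_temp"].nunique()
        if (multi > 1).any():
            ids = sorted(multi.index[multi > 1])
            raise ValueError(f"individual(s) recorded at several temperatures: {ids}")

        frame["rate"] = 1.0 / frame["duration_days"]
        frame = (
            frame.assign(_ord=frame["stage"].map(STAGE_INDEX))
            .sort_values(["mean_temp", "individual_id", "_ord"], kind="stable")
            .drop(columns="_ord")
            .reset_index(drop=True)
        )

        present = sorted(float(t) for t in frame["mean_temp"].unique())
        if temperatures is None:
            temperatures = {t: None for t in present}
        else:
            temperatures = {float(t): sd for t, sd in temperatures.items()}
            missing_t = [t for t in present if t not in temperatures]
            if missing_t:
                raise ValueError(
                    f"observations at temperature(s) {missing_t} absent from "
                    "the temperature list"
                )
        self.frame = frame
        self.temperatures: dict[float, float | None] = dict(sorted(temperatures.items()))

    # -- introspection -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RearingDataset({len(self)} observations, "
            f"{len(self.individuals())} individuals, "
            f"{len(self.temperatures)} temperatures)"
        )

    @property
    def observations(self) -> Iterator[StageObservation]:
        for row in self.frame.itertuples(index=False):
            yield StageObservation(
                individual_id=row.individual_id,
                rearing_unit=row.rearing_unit,
                mean_temp=row.mean_temp,
                stage=row.stage,
                duration=row.duration_days,
            )

    def individuals(self, temperature: float | None = None) -> list[str]:
        """Distinct individual ids, optionally at one rearing temperature."""
        f = self.frame
        if temperature is not None:
            f = f[f["mean_temp"] == float(temperature)]
        return sorted(f["individual_id"].unique())

    def rates(self, temperature: float, stage: str) -> np.ndarray:
        """Observed development rates (1/day) for one temperature x stage cell."""
        f = self.frame
        sel = (f["mean_temp"] == float(temperature)) & (f["stage"] == stage)
        return f.loc[sel, "rate"].to_numpy()

    def durations(self, temperature: float, stage: str) -> np.ndarray:
        f = self.frame
        sel = (f["mean_temp"] == float(temperature)) & (f["stage"] == stage)
        return f.loc[sel, "duration_days"].to_numpy()

    # -- derived datasets --------------------------------------------------

    def subset_temperatures(self, temps: Sequence[float]) -> "RearingDataset":
        temps = [float(t) for t in temps]
        frame = self.frame[self.frame["mean_temp"].isin(temps)]
        kept = {t: self.temperatures.get(t) for t in temps}
        return RearingDataset(frame, kept)

    def subset_individuals(self, ids: Sequence[str]) -> "RearingDataset":
        frame = self.frame[self.frame["individual_id"].isin(set(ids))]
        present = set(frame["mean_temp"].unique())
        kept = {t: sd for t, sd in self.temperatures.items() if t in present}
        return RearingDataset(frame, kept)

    def equals(self, other: "RearingDataset") -> bool:
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b) and self.temperatures == other.temperatures


@dataclasses.dataclass(frozen=True)
class TemperatureSeries:
    """Temperature time-series with a fixed step (default one value per day)."""

    values: np.ndarray
    step_hours: float = 24.0

    def __post_init__(self) -> None:
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if values.size < 1:
            raise ValueError("temperature series must contain at least one value")
        if not self.step_hours > 0:
            raise ValueError("step must be > 0 hours")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def step_days(self) -> float:
        return self.step_hours / 24.0

    @classmethod
    def constant(cls, temp: float, days: float, step_hours: float = 24.0) -> "TemperatureSeries":
        """A constant-temperature series spanning ``days`` days."""
        n = int(np.ceil(days / (step_hours / 24.0)))
        return cls(np.full(max(n, 1), float(temp)), step_hours)


# -- file I/O ----------------------------------------------------------------


def read_observations(path: str | Path) -> RearingDataset:
    """Read a rearing-observation CSV.

    The file must carry the header ``individual_id,rearing_unit,mean_temp,
    stage,duration_days`` (comma-separated, UTF-8, dot decimals).  Malformed
    rows are rejected with errors naming the offending file row (header = row
    1).
    """
    df = pd.read_csv(
        path, dtype={"individual_id": str, "rearing_unit": str, "stage": str}
    )
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")

    def _bad_rows(mask: pd.Series) -> list[int]:
        # +2: one for the header line, one for 0-based indexing
        return [int(i) + 2 for i in df.index[mask]]

    for col in ("mean_temp", "duration_days"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = _bad_rows(bad | df[col].isna())
            raise ValueError(f"{path}: non-numeric or missing {col} in row(s) {rows}")
        df[col] = vals
    bad = ~(df["duration_days"] > 0)
    if bad.any():
        raise ValueError(f"{path}: duration_days <= 0 in row(s) {_bad_rows(bad)}")
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        raise ValueError(f"{path}: unknown stage label in row(s) {_bad_rows(bad)}")
    return RearingDataset(df)


def write_observations(dataset: RearingDataset, path: str | Path) -> None:
    """Write a dataset back to the observation CSV schema (deterministic order)."""
    dataset.frame.loc[:, OBS_COLUMNS].to_csv(path, index=False)


def read_temperature_series(path: str | Path) -> TemperatureSeries:
    """Read a temperature-series CSV with header ``hour,temp_c`` and constant step."""
    df = pd.read_csv(path)
    for col in ("hour", "temp_c"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    hours = df["hour"].astype(float).to_numpy()
    if len(hours) > 1:
        steps = np.diff(hours)
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"{path}: time step is not constant")
        step = float(steps[0])
    else:
        step = 24.0
    return TemperatureSeries(df["temp_c"].astype(float).to_numpy(), step)


def write_temperature_series(series: TemperatureSeries, path: str | Path) -> None:
    hours = np.arange(len(series)) * series.step_hours
    pd.DataFrame({"hour": hours, "temp_c": series.values}).to_csv(path, index=False)


# -- dataset filters ---------------------------------------------------------


def filter_by_egg_survival(
    dataset: RearingDataset, min_survival: float = 0.5
) -> RearingDataset:
    """Keep only temperatures whose egg cohort survived well enough.

    An individual *started* if it has an egg (E) record, and *completed* the
    egg stage if it has any later-stage record.  Temperatures where the
    completed/started fraction falls below ``min_survival`` are dropped, as are
    temperatures with no egg cohort at all.  Idempotent.
    """
    if not 0 < min_survival <= 1:
        raise ValueError("min_survival must be in (0, 1]")
    if dataset.frame.empty:
        raise ValueError("cannot filter an empty dataset")
    keep: list[float] = []
    f = dataset.frame
    for t in dataset.temperatures:
        sub = f[f["mean_temp"] == t]
        started = set(sub.loc[sub["stage"] == "E", "individual_id"])
        if not started:
            continue
        completed = set(sub.loc[sub["stage"] != "E", "individual_id"]) & started
        if len(completed) / len(started) >= min_survival:
            keep.append(t)
    return dataset.subset_temperatures(keep)


def split_calibration_evaluation(
    dataset: RearingDataset, frac: float = 0.7, seed: int = 0
) -> tuple[RearingDataset, RearingDataset]:
    """Split individuals into calibration/evaluation sets, per temperature.

    The split unit is the individual: an individual's full stage record goes to
    one side, so the evaluation side carries coherent phenologies.  Per
    temperature ``round(frac * n)`` individuals go to calibration.
    Deterministic for a fixed ``seed``.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cal_ids: list[str] = []
    eval_ids: list[str] = []
    for t in dataset.temperatures:
        ids = dataset.individuals(t)
        if len(ids) < 2:
            raise ValueError(
                f"temperature {t} has {len(ids)} individual(s); need >= 2 to split"
            )
        order = rng.permutation(len(ids))
        n_cal = int(np.floor(frac * len(ids) + 0.5))
        shuffled = [ids[i] for i in order]
        cal_ids.extend(shuffled[:n_cal])
        eval_ids.extend(shuffled[n_cal:])
    return dataset.subset_individuals(cal_ids), dataset.subset_individuals(eval_ids)
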