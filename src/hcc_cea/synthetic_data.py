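"""Synthetic inputs for every stage of the analysis.

Three generators mirror the statistical structure of the real inputs: a
right-censored survival sampler (stand-in for trial arms), a digitized-style
Kaplan-Meier curve with numbers at risk (stand-in for curves read off a
published figure), and a Gompertz life table (synthetic stand-in for the US
all-cause mortality table; the real table is a drop-in replacement via the
same ``age,qx`` text format).
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .survival import ParametricSurvival
from .km_reconstruct import KMCurve, km_estimate

__all__ = [
    "SimulatedCohort",
    "LifeTable",
    "simulate_survival",
    "make_km_curve",
    "make_life_table",
    "default_life_table",
]


@dataclass(frozen=True)
class SimulatedCohort:
    """Event-or-censoring times (months) with event indicators."""

    times: np.ndarray
    events: np.ndarray
    seed: int
    truth: ParametricSurvival

    def __post_init__(self) -> None:
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have the same length")
        if np.any(self.times <= 0):
            raise ValueError("times must be strictly positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0/1")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        out = io.StringIO()
        out.write("time,event\n")
        for t, e in zip(self.times, self.events):
            out.write(f"{t:.6f},{int(e)}\n")
        Path(path).write_text(out.getvalue())


@dataclass(frozen=True)
class LifeTable:
    """Annual mortality probability qx by integer age, ascending."""

    ages: np.ndarray
    annual_mortality: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        q = self.annual_mortality
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("annual mortality must lie in [0, 1]")

    def qx(self, age: float) -> float:
        """Annual death probability at (integer part of) ``age``."""
        a = int(np.floor(age))
        if a < self.ages[0] or a > self.ages[-1]:
            raise ValueError(f"age {a} outside life-table range "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(self.annual_mortality[np.searchsorted(self.ages, a)])

    def annual_hazard(self, age: float) -> float:
        """Continuous-time all-cause hazard per year at ``age``."""
        q = self.qx(age)
        return float("inf") if q >= 1.0 else -np.log1p(-q)

    def cumulative_hazard_months(self, start_age: float, t_months: float) -> float:
        """Integrated background hazard over [0, t] months from ``start_age``.

        The hazard is piecewise constant on integer-age years.
        """
        if t_months <= 0:
            return 0.0
        H = 0.0
        t_years = t_months / 12.0
        age = start_age
        remaining = t_years
        while remaining > 1e-12:
            step = min(remaining, np.floor(age + 1.0) - age) or 1.0
            H += self.annual_hazard(age) * step
            age += step
            remaining -= step
        return H

    def to_csv(self, path: str | Path) -> None:
        lines = ["age,qx"] + [
            f"{int(a)},{q:.12g}" for a, q in zip(self.ages, self.annual_mortality)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        rows = [
            line.split(",") for line in Path(path).read_text().strip().splitlines()[1:]
        ]
        ages = np.array([int(r[0]) for r in rows])
        qx = np.array([float(r[1]) for r in rows])
        return cls(ages=ages, annual_mortality=qx)


def simulate_survival(
    dist: ParametricSurvival,
    n: int,
    censor_rate: float = 0.0,
    max_follow_up: float = np.inf,
    seed: int = 0,
) -> SimulatedCohort:
    """Draw ``n`` subjects from ``dist`` with independent exponential censoring.

    Each subject's observed time is ``min(event time, censor time,
    max_follow_up)`` and the event indicator is 1 iff the event time is the
    minimum.  Censoring is exponential with per-month rate ``censor_rate``
    (non-informative), the simplest structure compatible with the
    reconstruction stage.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    if max_follow_up <= 0:
        raise ValueError("max_follow_up must be positive")
    rng = np.random.default_rng(seed)
    event_times = dist.rvs(n, rng)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    censor_times = np.minimum(censor_times, max_follow_up)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    # guard against degenerate zero times from underflow
    times = np.maximum(times, 1e-9)
    return SimulatedCohort(times=times, events=events, seed=seed, truth=dist)


def make_km_curve(
    cohort: SimulatedCohort,
    coordinate_grid: Sequence[float],
    risk_table_times: Sequence[float],
    jitter: float = 0.0,
    seed: int = 0,
) -> KMCurve:
    """Kaplan-Meier estimate of ``cohort`` on a grid, as a digitized curve.

    ``jitter`` applies multiplicative log-normal noise to the survival values
    (emulating digitization error), after which the curve is clamped to
    [0, 1] and forced monotone non-increasing so it remains a valid KM shape.
    Numbers at risk are exact counts of subjects still under observation.
    """
    grid = np.asarray(coordinate_grid, dtype=float)
    rtimes = np.asarray(risk_table_times, dtype=float)
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if np.any(np.diff(grid) <= 0) or np.any(np.diff(rtimes) <= 0):
        raise ValueError("grids must be strictly ascending")
    if grid[0] != 0 or rtimes[0] != 0:
        raise ValueError("grids must start at 0")
    surv = km_estimate(cohort.times, cohort.events, grid)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(jitter * rng.standard_normal(len(grid)))
        surv = surv * noise
        surv[grid == 0] = 1.0
        surv = np.clip(surv, 0.0, 1.0)
        surv = np.minimum.accumulate(surv)
    at_risk = np.array([(cohort.times >= t).sum() for t in rtimes])
    return KMCurve(
        coords=np.column_stack([grid, surv]),
        risk_table=np.column_stack([rtimes, at_risk]),
        n0=len(cohort),
    )


def make_life_table(
    base_rate: float,
    doubling_time: float,
    age_min: int = 18,
    age_max: int = 110,
) -> LifeTable:
    """Gompertz-style life table: mortality doubles every ``doubling_time`` years.

    ``base_rate`` is the annual death probability at ``age_min``; values are
    capped at 1.0.
    """
    if not 0 < base_rate < 1:
        raise ValueError("base_rate must lie in (0, 1)")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    ages = np.arange(age_min, age_max + 1)
    qx = np.minimum(base_rate * 2.0 ** ((ages - age_min) / doubling_time), 1.0)
    return LifeTable(ages=ages, annual_mortality=qx)


def default_life_table() -> LifeTable:
    """Synthetic US-like background mortality.

    Gompertz table with q(18) = 3.5e-4 doubling every 9 years, which gives
    q(65) = 0.0131 and q(75) = 0.0284, close to the published US all-cause
    annual probabilities at those ages.
    """
    return make_life_table(base_rate=3.5e-4, doubling_time=9.0)
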