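"""Comparison layer: ICER/NMB, deterministic and probabilistic sensitivity
analyses, acceptability curves and price-threshold search.

All analyses re-run the same cohort engine; the probabilistic analysis
exploits its array broadcasting to evaluate every Monte-Carlo draw in a
single vectorized pass per arm (chunked to bound memory).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_model import CEOutcome, ModelSettings, run_cohort
from .parameters import ARM_ATEZO_BEV, PARAMETERS, build_strategies
from .scenarios import ScenarioSpec, apply_duration_cap
from .synthetic_data import LifeTable, default_life_table

__all__ = [
    "CEComparison",
    "PSAResult",
    "compare",
    "evaluate_arms",
    "one_way_dsa",
    "psa",
    "price_threshold",
    "two_way_dsa",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of two arms (first minus second)."""

    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    icer: float | str                 # USD/QALY, or a dominance label
    icer_per_life_year: float | str
    nmb: dict[float, float] = field(default_factory=dict)  # WTP -> USD

    @property
    def icer_value(self) -> float:
        """Numeric ICER (inf when dominated, -inf when dominant)."""
        if isinstance(self.icer, str):
            return -np.inf if self.icer == DOMINANT else np.inf
        return self.icer


def _ratio(dc: float, de: float) -> float | str:
    if de > 0:
        return DOMINANT if dc <= 0 else dc / de
    if de == 0:
        return "equal" if dc == 0 else (DOMINATED if dc > 0 else DOMINANT)
    return DOMINATED if dc >= 0 else dc / de  # less effect & cheaper: a true ratio


def compare(
    a: CEOutcome, b: CEOutcome, wtps: Sequence[float] = (100_000.0, 150_000.0)
) -> CEComparison:
    """Incremental cost, effect, ICER and net monetary benefit of a vs b.

    ``nmb = wtp * delta_qalys - delta_cost``; when the incremental effect is
    positive, a positive NMB is equivalent to ICER below the WTP.
    Dominance labels replace the ratio when its sign is meaningless.
    """
    dc = a.total_cost - b.total_cost
    dq = a.qalys - b.qalys
    dl = a.life_years - b.life_years
    return CEComparison(
        delta_cost=float(dc),
        delta_qalys=float(dq),
        delta_life_years=float(dl),
        icer=_ratio(float(dc), float(dq)),
        icer_per_life_year=_ratio(float(dc), float(dl)),
        nmb={float(w): float(w * dq - dc) for w in wtps},
    )


def evaluate_arms(
    values: Mapping[str, float | np.ndarray] | None = None,
    scenario: ScenarioSpec | None = None,
    settings: ModelSettings | None = None,
    life_table: LifeTable | None = None,
    societal: bool = False,
    duration_cap: float | None = None,
    price_multiplier: float | np.ndarray = 1.0,
) -> tuple[CEOutcome, CEOutcome, CEComparison]:
    """Evaluate both arms under one parameter set and compare them.

    The scenario applies to the atezo-bev arm's overall survival only; the
    duration cap and price multiplier likewise target the atezo-bev arm
    (the transforms the published scenario analyses vary).
    """
    settings = settings or ModelSettings()
    life_table = life_table or default_life_table()
    ab, sor = build_strategies(values, societal=societal)
    if duration_cap is not None:
        ab = apply_duration_cap(ab, duration_cap)
    if not np.all(np.asarray(price_multiplier) == 1.0):
        ab = replace(ab, price_multiplier=price_multiplier)
    _, out_ab = run_cohort(ab, settings, life_table, scenario=scenario,
                           collect_trace=False)
    _, out_sor = run_cohort(sor, settings, life_table, collect_trace=False)
    if np.ndim(out_ab.total_cost) == 0:
        cmp_ = compare(out_ab, out_sor, settings.wtp_thresholds)
    else:
        cmp_ = None  # vectorized callers aggregate themselves
    return out_ab, out_sor, cmp_


def one_way_dsa(
    param_names: Sequence[str] | None = None,
    scenario: ScenarioSpec | None = None,
    settings: ModelSettings | None = None,
    life_table: LifeTable | None = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado rows).

    Each parameter is set to its range endpoints with everything else at
    base; rows are sorted by descending ICER spread.  Columns: parameter,
    low/high input values, ICER at each endpoint, spread.
    """
    names = list(param_names or PARAMETERS)
    _, _, base_cmp = evaluate_arms(scenario=scenario, settings=settings,
                                   life_table=life_table)
    rows = []
    for name in names:
        p = PARAMETERS[name]
        icers = {}
        for side, val in (("low", p.low), ("high", p.high)):
            try:
                _, _, c = evaluate_arms({name: val}, scenario=scenario,
                                        settings=settings, life_table=life_table)
                icers[side] = c.icer_value
            except (ValueError, RuntimeError):
                icers[side] = np.nan
        spread = abs(icers["high"] - icers["low"])
        rows.append(
            dict(parameter=name, low_value=p.low, high_value=p.high,
                 icer_low=icers["low"], icer_high=icers["high"],
                 spread=spread, base_icer=base_cmp.icer_value)
        )
    df = pd.DataFrame(rows).sort_values("spread", ascending=False,
                                        kind="stable").reset_index(drop=True)
    return df


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo propagation of parameter uncertainty."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    cost: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.delta_cost)

    def acceptability(self, wtp: float) -> float:
        """Fraction of draws with positive incremental net monetary benefit."""
        return float(np.mean(wtp * self.delta_qalys - self.delta_cost > 0))

    def ceac(self, wtps: Sequence[float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": list(wtps),
             "acceptability": [self.acceptability(w) for w in wtps]}
        )

    def icer_point(self) -> float:
        return float(np.mean(self.delta_cost) / np.mean(self.delta_qalys))

    def icer_credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval of the per-draw cost/effect ratio.

        Restricted to draws with positive incremental effect (the ratio has
        no ordering interpretation elsewhere).
        """
        mask = self.delta_qalys > 0
        ratios = self.delta_cost[mask] / self.delta_qalys[mask]
        lo, hi = np.quantile(ratios, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)


def psa(
    n_iter: int = 100_000,
    seed: int = 0,
    scenario: ScenarioSpec | None = None,
    settings: ModelSettings | None = None,
    life_table: LifeTable | None = None,
    societal: bool = False,
    chunk: int = 20_000,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Every registry parameter is drawn independently from its distribution
    (normal hazard ratios truncated at 1e-6, binomial proportions with the
    trial denominators, triangular costs and utilities); shared parameters
    use common draws across arms.  The fitted Weibull parameters are held
    fixed (no sampling distribution is published for them).  Reproducible
    bit-for-bit given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    draws = {name: p.sample(n_iter, rng) for name, p in PARAMETERS.items()}

    dcost = np.empty(n_iter)
    dq = np.empty(n_iter)
    cost_ab = np.empty(n_iter)
    cost_s = np.empty(n_iter)
    q_ab = np.empty(n_iter)
    q_s = np.empty(n_iter)
    for start in range(0, n_iter, chunk):
        sl = slice(start, min(start + chunk, n_iter))
        vals = {k: v[sl] for k, v in draws.items()}
        out_ab, out_s, _ = evaluate_arms(
            vals, scenario=scenario, settings=settings, life_table=life_table,
            societal=societal,
        )
        cost_ab[sl], cost_s[sl] = out_ab.total_cost, out_s.total_cost
        q_ab[sl], q_s[sl] = out_ab.qalys, out_s.qalys
        dcost[sl] = out_ab.total_cost - out_s.total_cost
        dq[sl] = out_ab.qalys - out_s.qalys
    return PSAResult(
        delta_cost=dcost, delta_qalys=dq,
        cost={ARM_ATEZO_BEV: cost_ab, "sorafenib": cost_s},
        qalys={ARM_ATEZO_BEV: q_ab, "sorafenib": q_s},
        seed=seed,
    )


def price_threshold(
    wtp: float,
    scenario: ScenarioSpec | None = None,
    settings: ModelSettings | None = None,
    life_table: LifeTable | None = None,
    resolution: float = 0.001,
    values: Mapping[str, float] | None = None,
) -> float:
    """Smallest price-reduction fraction meeting a WTP threshold.

    Bisection on a common multiplier applied to both atezolizumab and
    bevacizumab unit costs, to ``resolution`` (default 0.1%).  Returns 0.0
    if the base-case ICER already meets the threshold; raises if even a
    100% reduction cannot.
    """

    def icer_at(reduction: float) -> float:
        _, _, c = evaluate_arms(values, scenario=scenario, settings=settings,
                                life_table=life_table,
                                price_multiplier=1.0 - reduction)
        return c.icer_value

    if icer_at(0.0) <= wtp:
        return 0.0
    if icer_at(1.0) > wtp:
        raise ValueError(f"no price reduction in [0, 1] reaches WTP {wtp:g}")
    lo, hi = 0.0, 1.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if icer_at(mid) <= wtp:
            hi = mid
        else:
            lo = mid
    return hi


def two_way_dsa(
    x_name: str,
    x_grid: Sequence[float],
    y_name: str,
    y_grid: Sequence[float],
    scenario: ScenarioSpec | None = None,
    settings: ModelSettings | None = None,
    life_table: LifeTable | None = None,
) -> pd.DataFrame:
    """Full-factorial ICER surface over two axes.

    Axes may be registry parameters, or the special names
    ``price_reduction`` (common atezo-bev price multiplier ``1 - x``),
    ``survival_3yr`` (atezo-bev 3-year survival anchor, implemented as a
    calibrated post-switch hazard) and ``duration_cap`` / ``bev_dose``.
    """

    def run_point(axis: str, val: float, kw: dict) -> dict:
        if axis == "price_reduction":
            kw["price_multiplier"] = 1.0 - val
        elif axis == "survival_3yr":
            kw["scenario"] = ScenarioSpec(mode="pessimistic", anchor_3yr=val)
        elif axis == "duration_cap":
            kw["duration_cap"] = val
        elif axis in PARAMETERS:
            kw.setdefault("values", {})[axis] = val
        else:
            raise KeyError(f"unknown axis {axis!r}")
        return kw

    rows = []
    for x in x_grid:
        for y in y_grid:
            kw: dict = dict(scenario=scenario, settings=settings,
                            life_table=life_table)
            kw = run_point(x_name, x, kw)
            kw = run_point(y_name, y, kw)
            try:
                _, _, c = evaluate_arms(**kw)
                rows.append({x_name: x, y_name: y, "icer": c.icer_value,
                             "delta_cost": c.delta_cost,
                             "delta_qalys": c.delta_qalys})
            except (ValueError, RuntimeError):
                # e.g. an unattainable survival anchor: flag, don't abort
                rows.append({x_name: x, y_name: y, "icer": np.nan,
                             "delta_cost": np.nan, "delta_qalys": np.nan})
    return pd.DataFrame(rows)
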