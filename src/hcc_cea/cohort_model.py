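"""Three-state Markov cohort engine with full cost and utility accounting.

States are progression-free on first-line therapy (PF), progressed (PD)
and dead.  Cycles are 21 days; the horizon defaults to 5 years; costs and
health outcomes are discounted at 3% per year at cycle midpoints, with a
half-cycle correction (state membership counted as the mean of start- and
end-of-cycle occupancy).

Transition construction follows the standard two-curve reading: the
overall-survival curve governs death from either alive state, the
progression-free-survival curve governs exit from PF, and the progression
probability is their difference (floored at zero).  Background mortality is
combined with the disease hazard on the hazard scale.

Cost accrual
------------
Drug and administration costs accrue over *time on treatment*, modelled per
drug component as a Weibull stopping curve with the arm's PFS shape and
median equal to the trial's median treatment duration, bounded above by PF
occupancy (no first-line drug after progression) and thinned once by the
AE-discontinuation rate.  Imaging and supportive ("other") care accrue in
both alive states; post-progression therapy accrues per PD cycle; one-off
end-of-life cost is paid on the transition to death; adverse-event
management cost and QALY decrements are charged once at model entry.

Every numeric field of :class:`StrategySpec` may be a numpy array; the
engine broadcasts, which is how probabilistic sensitivity analysis
evaluates 1e5 parameter draws in a single pass.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .scenarios import LongTermOS, ScenarioSpec, longterm_hazard
from .survival import ParametricSurvival, cycle_transition_prob
from .synthetic_data import LifeTable

__all__ = [
    "ModelSettings",
    "DrugComponent",
    "AdverseEvent",
    "StrategySpec",
    "MarkovTrace",
    "CEOutcome",
    "build_transitions",
    "run_cohort",
    "ae_burden",
    "bev_cost",
]

DAYS_PER_MONTH = 365.25 / 12.0

#: anchor for bevacizumab dosing: Table-1 unit cost is quoted at 70 kg, 15 mg/kg
BEV_REFERENCE_WEIGHT = 70.0
BEV_REFERENCE_DOSE = 15.0
BEV_UNIT_COST = 117.60


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings (cycle structure, discounting, thresholds)."""

    cycle_days: float = 21.0
    horizon_years: float = 5.0
    discount_rate: float = 0.03
    start_age: float = 65.0
    wtp_thresholds: tuple[float, ...] = (100_000.0, 150_000.0)
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount rate must lie in [0, 1)")

    @property
    def n_cycles(self) -> int:
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_days))

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25


@dataclass(frozen=True)
class DrugComponent:
    """One drug in a regimen: per-cycle price and stopping-time median.

    ``duration_median`` (months) anchors the Weibull time-on-treatment
    curve; ``None`` means treatment continues for as long as the patient is
    progression-free.
    """

    name: str
    cost_per_cycle: float | np.ndarray
    duration_median: float | None = None


@dataclass(frozen=True)
class AdverseEvent:
    """Grade 3-4 adverse event: incidence, management cost, utility decrement."""

    name: str
    incidence: float | np.ndarray
    management_cost: float | np.ndarray
    disutility: float | np.ndarray


@dataclass(frozen=True)
class StrategySpec:
    """One treatment arm: effectiveness models plus every cost/utility input."""

    name: str
    os_model: ParametricSurvival
    pfs_model: ParametricSurvival
    drug_components: tuple[DrugComponent, ...]
    administration_cost: float | np.ndarray = 0.0
    administration_duration_median: float | None = None
    imaging_cost_6wk: float | np.ndarray = 0.0
    other_care_weekly: float | np.ndarray = 0.0
    post_progression_cost: float | np.ndarray = 0.0   # per cycle
    eol_cost: float | np.ndarray = 0.0                # one-off at death
    ae_profile: tuple[AdverseEvent, ...] = ()
    discontinuation_rate: float | np.ndarray = 0.0
    utility_first_line: float | np.ndarray = 0.78
    utility_progressed: float | np.ndarray = 0.68
    duration_cap: float | None = None                 # months
    societal: bool = False
    caregiver_cost_cycle: float | np.ndarray = 0.0
    patient_time_cost_cycle: float | np.ndarray = 0.0
    travel_cost_cycle: float | np.ndarray = 0.0
    price_multiplier: float | np.ndarray = 1.0        # scales drug components only


@dataclass(frozen=True)
class CEOutcome:
    """Discounted totals for one arm (plus undiscounted companions)."""

    total_cost: float | np.ndarray
    life_years: float | np.ndarray
    qalys: float | np.ndarray
    total_cost_undiscounted: float | np.ndarray = 0.0
    life_years_undiscounted: float | np.ndarray = 0.0
    qalys_undiscounted: float | np.ndarray = 0.0


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle state occupancy and accruals for a scalar run."""

    time_months: np.ndarray          # cycle start times, length K
    occupancy: np.ndarray            # (K + 1, 3): PF, PD, dead at cycle starts
    cost: np.ndarray                 # discounted per-cycle cost
    cost_undiscounted: np.ndarray
    qaly: np.ndarray                 # discounted per-cycle QALY
    qaly_undiscounted: np.ndarray
    life_years: np.ndarray           # discounted per-cycle life-years
    life_years_undiscounted: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write("cycle,time_months,pf,progressed,dead,cost,cost_undisc,"
                  "qaly,qaly_undisc,ly,ly_undisc\n")
        for k in range(len(self.time_months)):
            o = self.occupancy[k]
            buf.write(
                f"{k},{self.time_months[k]:.6f},{o[0]:.10f},{o[1]:.10f},"
                f"{o[2]:.10f},{self.cost[k]:.6f},{self.cost_undiscounted[k]:.6f},"
                f"{self.qaly[k]:.10f},{self.qaly_undiscounted[k]:.10f},"
                f"{self.life_years[k]:.10f},{self.life_years_undiscounted[k]:.10f}\n"
            )
        Path(path).write_text(buf.getvalue())


def bev_cost(weight: float, dose: float, unit_cost: float = BEV_UNIT_COST):
    """Bevacizumab cost per 3-week cycle, linear in weight and dose.

    The unit cost is anchored at 70 kg and 15 mg/kg.
    """
    if np.any(np.asarray(weight) <= 0):
        raise ValueError("weight must be positive")
    if np.any(np.asarray(dose) < 0):
        raise ValueError("dose must be non-negative")
    return unit_cost * (weight / BEV_REFERENCE_WEIGHT) * (dose / BEV_REFERENCE_DOSE)


def ae_burden(strategy: StrategySpec):
    """One-off adverse-event cost and QALY decrement at model entry.

    ``cost = sum incidence * management_cost``;
    ``decrement = sum incidence * disutility``.
    """
    cost = 0.0
    dec = 0.0
    for ae in strategy.ae_profile:
        cost = cost + ae.incidence * ae.management_cost
        dec = dec + ae.incidence * ae.disutility
    return cost, dec


def _tot_logsf(t: float, median: float | None, pfs_model: ParametricSurvival):
    """log survival of the time-on-treatment stopping curve at t months."""
    if median is None:
        return 0.0
    if pfs_model.family == "weibull":
        _, gam = pfs_model.params
    else:
        gam = 1.0
    return -(math.log(2) / median**gam) * t**gam


def _os_curve(
    strategy: StrategySpec,
    settings: ModelSettings,
    life_table: LifeTable,
    scenario: ScenarioSpec | None,
) -> LongTermOS:
    scen = scenario or ScenarioSpec(mode="extrapolate")
    return longterm_hazard(strategy.os_model, scen, life_table, settings.start_age)


def _cycle_probs(
    strategy: StrategySpec,
    settings: ModelSettings,
    os_curve: LongTermOS,
    k: int,
):
    """(death, progression) probabilities for cycle ``k``."""
    dm = settings.cycle_months
    t0, t1 = k * dm, (k + 1) * dm
    p_death = os_curve.cycle_death_prob(t0, t1)
    p_exit = cycle_transition_prob(strategy.pfs_model, t0, dm)
    p_prog = np.maximum(0.0, p_exit - p_death)
    return p_death, p_prog


def build_transitions(
    strategy: StrategySpec,
    settings: ModelSettings,
    life_table: LifeTable,
    scenario: ScenarioSpec | None = None,
) -> np.ndarray:
    """Per-cycle 3x3 transition matrices (scalar parameters only).

    State order is (PF, progressed, dead); dead is absorbing and every row
    sums to one exactly.
    """
    os_curve = _os_curve(strategy, settings, life_table, scenario)
    K = settings.n_cycles
    out = np.zeros((K, 3, 3))
    for k in range(K):
        p_death, p_prog = _cycle_probs(strategy, settings, os_curve, k)
        p_death, p_prog = float(p_death), float(p_prog)
        out[k, 0] = (1.0 - p_death - p_prog, p_prog, p_death)
        out[k, 1] = (0.0, 1.0 - p_death, p_death)
        out[k, 2] = (0.0, 0.0, 1.0)
    return out


def run_cohort(
    strategy: StrategySpec,
    settings: ModelSettings,
    life_table: LifeTable,
    scenario: ScenarioSpec | None = None,
    transitions: np.ndarray | None = None,
    collect_trace: bool | None = None,
) -> tuple[MarkovTrace | None, CEOutcome]:
    """Run the cohort through the Markov model and accrue costs and QALYs.

    The cohort starts fully progression-free.  With scalar parameters a
    :class:`MarkovTrace` is returned alongside the totals; with array
    parameters (probabilistic draws) the trace is skipped and the outcome
    fields are arrays.

    If ``transitions`` is supplied (from :func:`build_transitions`) the
    occupancy recursion consumes it; otherwise probabilities are computed
    from the survival models directly — the two paths are equivalent.
    """
    scen = scenario or ScenarioSpec(mode="extrapolate")
    os_curve = _os_curve(strategy, settings, life_table, scen)
    K = settings.n_cycles
    dm, dy = settings.cycle_months, settings.cycle_years
    r = settings.discount_rate

    # broadcast shape across all array-valued inputs
    probe = np.broadcast(
        np.asarray(strategy.os_model.params[0]),
        np.asarray(strategy.utility_first_line),
        np.asarray(strategy.post_progression_cost),
        np.asarray(strategy.price_multiplier),
        *[np.asarray(c.cost_per_cycle) for c in strategy.drug_components],
    )
    shape = probe.shape
    vector = shape != ()
    if collect_trace is None:
        collect_trace = not vector

    zeros = np.zeros(shape) if vector else 0.0
    pf = zeros + 1.0
    pd_ = zeros + 0.0
    dead = zeros + 0.0

    ae_cost, ae_dec = ae_burden(strategy)
    cost = zeros + ae_cost
    cost_ud = zeros + ae_cost
    qaly = zeros - ae_dec
    qaly_ud = zeros - ae_dec
    ly = zeros + 0.0
    ly_ud = zeros + 0.0

    if collect_trace:
        tr_occ = np.zeros((K + 1, 3))
        tr_occ[0] = (1.0, 0.0, 0.0)
        tr_cost = np.zeros(K)
        tr_cost_ud = np.zeros(K)
        tr_qaly = np.zeros(K)
        tr_qaly_ud = np.zeros(K)
        tr_ly = np.zeros(K)
        tr_ly_ud = np.zeros(K)

    imaging_cycle = strategy.imaging_cost_6wk / 2.0
    care_cycle = strategy.other_care_weekly * 3.0
    thin = 1.0 - strategy.discontinuation_rate

    for k in range(K):
        t0, tm = k * dm, (k + 0.5) * dm
        t1 = t0 + dm
        if transitions is not None:
            p_death = transitions[k, 0, 2]
            p_prog = transitions[k, 0, 1]
        else:
            p_death, p_prog = _cycle_probs(strategy, settings, os_curve, k)
        pf2 = pf * (1.0 - p_death - p_prog)
        pd2 = pd_ * (1.0 - p_death) + pf * p_prog
        dead2 = dead + (pf + pd_) * p_death
        deaths = dead2 - dead

        if settings.half_cycle_correction:
            m_pf, m_pd = 0.5 * (pf + pf2), 0.5 * (pd_ + pd2)
        else:
            m_pf, m_pd = pf, pd_
        alive = m_pf + m_pd
        disc = (1.0 + r) ** (-(tm / 12.0))

        ly_c = alive * dy
        qaly_c = (strategy.utility_first_line * m_pf
                  + strategy.utility_progressed * m_pd) * dy

        # --- cost accrual -------------------------------------------------
        c = zeros + 0.0
        in_cap = strategy.duration_cap is None or tm < strategy.duration_cap
        on_primary = zeros + 0.0
        if in_cap:
            drug = zeros + 0.0
            for comp in strategy.drug_components:
                on = np.minimum(
                    math.exp(_tot_logsf(tm, comp.duration_median, strategy.pfs_model)),
                    m_pf,
                )
                drug = drug + comp.cost_per_cycle * strategy.price_multiplier * on
            if strategy.drug_components:
                on_primary = np.minimum(
                    math.exp(_tot_logsf(
                        tm, strategy.drug_components[0].duration_median,
                        strategy.pfs_model)),
                    m_pf,
                ) * thin
            adm = strategy.administration_cost * np.minimum(
                math.exp(_tot_logsf(
                    tm, strategy.administration_duration_median, strategy.pfs_model)),
                m_pf,
            )
            c = c + (drug + adm) * thin
        c = c + alive * (imaging_cycle + care_cycle)
        post = strategy.post_progression_cost
        if scen.mode == "optimistic" and tm >= scen.switch_time:
            post = 0.0  # cured survivors no longer receive systemic therapy
        c = c + m_pd * post
        c = c + deaths * strategy.eol_cost
        if strategy.societal:
            c = c + alive * strategy.caregiver_cost_cycle
            c = c + on_primary * (strategy.patient_time_cost_cycle
                                  + strategy.travel_cost_cycle)

        cost = cost + c * disc
        cost_ud = cost_ud + c
        qaly = qaly + qaly_c * disc
        qaly_ud = qaly_ud + qaly_c
        ly = ly + ly_c * disc
        ly_ud = ly_ud + ly_c

        if collect_trace:
            tr_occ[k + 1] = (float(pf2), float(pd2), float(dead2))
            tr_cost[k] = float(c * disc)
            tr_cost_ud[k] = float(c)
            tr_qaly[k] = float(qaly_c * disc)
            tr_qaly_ud[k] = float(qaly_c)
            tr_ly[k] = float(ly_c * disc)
            tr_ly_ud[k] = float(ly_c)

        pf, pd_, dead = pf2, pd2, dead2

    if np.any(np.asarray(cost_ud) < 0):
        raise RuntimeError("negative cost accrual - inconsistent strategy inputs")

    outcome = CEOutcome(
        total_cost=cost, life_years=ly, qalys=qaly,
        total_cost_undiscounted=cost_ud,
        life_years_undiscounted=ly_ud,
        qalys_undiscounted=qaly_ud,
    )
    if not collect_trace:
        return None, outcome
    trace = MarkovTrace(
        time_months=np.arange(K) * dm,
        occupancy=tr_occ,
        cost=tr_cost, cost_undiscounted=tr_cost_ud,
        qaly=tr_qaly, qaly_undiscounted=tr_qaly_ud,
        life_years=tr_ly, life_years_undiscounted=tr_ly_ud,
    )
    return trace, outcome
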