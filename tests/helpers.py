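"""Shared test utilities: an individual-level microsimulation oracle.

The microsimulation replays the cohort engine's per-cycle transition
probabilities subject by subject, so its expected life-years and QALYs
equal the cohort model's by construction; agreement within Monte-Carlo
error validates the occupancy recursion and half-cycle accrual.
"""
import numpy as np

from hcc_cea import ae_burden, build_transitions


def microsim_ly_qaly(strategy, settings, life_table, n, seed, scenario=None):
    """Mean discounted life-years and QALYs over ``n`` simulated subjects."""
    T = build_transitions(strategy, settings, life_table, scenario=scenario)
    rng = np.random.default_rng(seed)
    state = np.zeros(n, dtype=np.int8)  # 0 PF, 1 progressed, 2 dead
    ly = 0.0
    qaly = 0.0
    u_pf = float(strategy.utility_first_line)
    u_pd = float(strategy.utility_progressed)
    cycle_months = settings.cycle_months
    for k in range(settings.n_cycles):
        p_death, p_prog = T[k, 0, 2], T[k, 0, 1]
        u = rng.uniform(size=n)
        new = state.copy()
        pf = state == 0
        pd_ = state == 1
        new[pf & (u < p_death)] = 2
        new[pf & (u >= p_death) & (u < p_death + p_prog)] = 1
        new[pd_ & (u < p_death)] = 2
        disc = (1 + settings.discount_rate) ** (-(k + 0.5) * cycle_months / 12)
        w0 = np.where(state == 0, u_pf, np.where(state == 1, u_pd, 0.0))
        w1 = np.where(new == 0, u_pf, np.where(new == 1, u_pd, 0.0))
        alive = ((state < 2).astype(float) + (new < 2)) / 2
        ly += alive.mean() * settings.cycle_years * disc
        qaly += ((w0 + w1) / 2).mean() * settings.cycle_years * disc
        state = new
    _, ae_dec = ae_burden(strategy)
    return ly, qaly - ae_dec
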