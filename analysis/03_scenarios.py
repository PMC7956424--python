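#!/usr/bin/env python
"""Scenario analyses: long-term survival, treatment duration caps,
bevacizumab dosage, societal perspective and time horizons.

Writes results/scenarios.csv with the ICER of every scenario.
"""
from pathlib import Path

import pandas as pd

from hcc_cea import ModelSettings, ScenarioSpec, evaluate_arms

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []


def add(label, **kwargs):
    _, _, c = evaluate_arms(**kwargs)
    rows.append(dict(scenario=label, icer=round(c.icer_value, 0),
                     delta_cost=round(c.delta_cost, 0),
                     delta_qalys=round(c.delta_qalys, 4)))


add("base case")
add("long-term optimistic (cure at 17 m)",
    scenario=ScenarioSpec(mode="optimistic"))
add("long-term pessimistic (anchor 27.8%)",
    scenario=ScenarioSpec(mode="pessimistic", anchor_3yr=0.278))
add("long-term pessimistic (anchor 23.8%)",
    scenario=ScenarioSpec(mode="pessimistic", anchor_3yr=0.238))
for cap in (24, 18, 12, 6):
    add(f"atezo-bev duration capped at {cap} months", duration_cap=float(cap))
for dose in (12.5, 10.0, 7.5, 5.0):
    add(f"bevacizumab {dose} mg/kg", values={"bev_dose": dose})
add("societal perspective", societal=True)
for hy in (10, 40):
    label = "lifetime" if hy == 40 else f"{hy}-year"
    add(f"{label} horizon", settings=ModelSettings(horizon_years=hy))

df = pd.DataFrame(rows)
df.to_csv(OUT / "scenarios.csv", index=False)
print(df.to_string(index=False))
print(
    "\nOnly the cure assumption brings the combination below the 150k "
    "USD/QALY threshold at full price; capping therapy at 12 months or "
    "less approaches it.  With the packaged bevacizumab unit cost "
    "(117.60 USD/cycle at 70 kg) the dosage scenarios barely move the "
    "ICER.  Under the published hazard-ratio-scaled Weibull, the "
    "registry-anchored 'pessimistic' survival (27.8% at 3 years) actually "
    "lies above the extrapolated 3-year survival (~20%), so that scenario "
    "improves rather than worsens the ICER - see the methods note."
)
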