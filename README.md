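# hcc_cea — cost-effectiveness of atezolizumab–bevacizumab vs sorafenib in HCC

First-line atezolizumab plus bevacizumab (atezo–bev) improves survival over
sorafenib in unresectable hepatocellular carcinoma (IMbrave 150), but at a
drug cost an order of magnitude above the benefit most payers will fund.
This package implements the full economic evaluation of that trade-off for
health-economics researchers: a three-state Markov cohort model
(progression-free → progressed → dead) on 3-week cycles over 5 years, driven
by Weibull survival models, with complete cost and utility accounting,
long-term survival scenarios, deterministic and probabilistic sensitivity
analysis, and price-threshold search — plus the preprocessing such analyses
rest on (pseudo individual-patient-data reconstruction from digitized
Kaplan–Meier curves, censored maximum-likelihood fitting with AIC
selection).

## Model core

Survival follows S(t) = exp(−λ·t^γ) with t in months: sorafenib OS
(λ=0.027, γ=1.286) and PFS (λ=0.093, γ=1.312), the atezo–bev arm via
proportional hazards (HR 0.58 OS, 0.59 PFS, λ → HR·λ).  Per cycle of length
Δ, the death probability from either alive state is

    p_death = 1 − exp(−[H_disease(t, t+Δ) + H_background(age)])

with background mortality from a life table added on the hazard scale, and
progression = max(0, p_PFS-exit − p_death).  Discounted accruals use
half-cycle-corrected occupancy:

    QALY_k = (0.78·PF_k + 0.68·PD_k) · Δyears · 1.03^(−t_mid)

Drug cost accrues over time on treatment (a Weibull stopping curve with the
arm's PFS shape and the trial's median treatment duration, bounded by PF
occupancy); imaging and supportive care accrue while alive; blended
post-progression therapy per progressed cycle; one-off end-of-life cost at
death.  Strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY and net monetary benefit NMB = WTP·ΔQALY − ΔCost at
willingness-to-pay thresholds of 100k and 150k USD/QALY.  See
`docs/methods.md` for every assumption and the known divergences from the
originally reported numbers.

## Worked example

```python
from hcc_cea import ScenarioSpec, evaluate_arms, price_threshold, psa

out_ab, out_sor, cmp_ = evaluate_arms()          # base case
print(f"atezo-bev: {out_ab.qalys:.3f} QALYs, {out_ab.total_cost:,.0f} USD")
print(f"sorafenib: {out_sor.qalys:.3f} QALYs, {out_sor.total_cost:,.0f} USD")
print(f"ICER: {cmp_.icer:,.0f} USD/QALY")

_, _, cure = evaluate_arms(scenario=ScenarioSpec(mode="optimistic"))
print(f"cure scenario ICER: {cure.icer:,.0f} USD/QALY")

print(f"price cut for 150k/QALY: {price_threshold(150_000):.1%}")
print(f"acceptability at 150k: {psa(100_000, seed=1).acceptability(150_000):.1%}")
```

prints

```
atezo-bev: 1.278 QALYs, 245,681 USD
sorafenib: 0.862 QALYs, 162,692 USD
ICER: 199,392 USD/QALY
cure scenario ICER: 45,895 USD/QALY
price cut for 150k/QALY: 19.3%
acceptability at 150k: 12.0%
```

Read: at its list price the combination buys 0.42 extra QALYs for an extra
83k USD — about 199k USD per QALY, above both common US thresholds — but if
patients alive at 17 months are effectively cured, the same comparison costs
only ~46k USD per QALY; a ~20% price cut meets the 150k threshold even
without the cure assumption.

The numbered drivers under `analysis/` run the complete study and write
tables to `results/`: `01_survival_reconstruction.py` (synthetic
digitization → pseudo-IPD → AIC selection), `02_base_case.py`,
`03_scenarios.py` (long-term survival, duration caps, bev dose, societal,
horizons), `04_sensitivity.py` (tornado + two-way surface), `05_psa.py`
(CEACs), `06_price_thresholds.py`.  Config-driven runs go through
`hcc_cea.load_config` / `run_pipeline` (YAML, schema-validated, byte-stable
outputs).

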