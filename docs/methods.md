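# Methods

`hcc_cea` implements a cohort-level cost-utility model comparing first-line
atezolizumab plus bevacizumab (atezo–bev) against sorafenib in unresectable
hepatocellular carcinoma (HCC), from the US payer perspective (2020 USD),
together with the preprocessing (Kaplan–Meier digitization → pseudo-IPD →
parametric fitting) and the uncertainty machinery (one-way/two-way
deterministic sensitivity analysis, probabilistic sensitivity analysis,
price-threshold search) that such evaluations rest on.

## Model structure

A three-state Markov cohort model: **progression-free on first-line therapy
(PF)**, **progressed (PD)** and **dead**.  Cycles are 21 days
(0.6899 months); the base-case horizon is 5 years (86 cycles); costs and
health outcomes are discounted at 3% per year, evaluated at cycle midpoints;
state membership is counted as the mean of start- and end-of-cycle occupancy
(half-cycle correction, toggleable).

Transitions use the standard two-curve construction:

- the arm's overall-survival (OS) law supplies the per-cycle death hazard
  from *both* alive states (OS is an arm-level quantity; with only OS and
  PFS curves available no state-specific death hazard is identifiable);
- the progression-free-survival (PFS) law supplies the per-cycle PF-exit
  probability; progression = max(0, PF-exit − death);
- background (other-cause) mortality is added to the disease hazard on the
  hazard scale, using the age at the cycle midpoint for a cohort starting at
  age 65 (the starting age is configuration; 65 is a typical trial-population
  age and the model is insensitive to it because disease hazards dominate).

## Survival inputs

Survival laws use S(t) = exp(−λ·t^γ) (Weibull, rate/shape) with time in
months.  The sorafenib arm uses the fitted trial curves λ=0.027, γ=1.286
(OS) and λ=0.093, γ=1.312 (PFS); these reproduce the printed sorafenib
medians (derived 12.47 vs reported 13.2 months OS; 4.62 vs 4.3 months PFS).
The atezo–bev arm applies the trial hazard ratios (0.58 OS, 0.59 PFS) to the
sorafenib hazards (λ → HR·λ), which reproduces the reported atezo–bev median
PFS (derived 6.91 vs reported 6.8 months).  Direct refitting of digitized
atezo–bev curves is supported through the reconstruction/fitting modules but
is not the default, because no fitted atezo–bev parameters were published.

The fitting module maximizes the right-censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t) on the log-parameter scale
(L-BFGS-B, three starts, 1e-10 relative tolerance on the objective) for four
families — Weibull, exponential, log-logistic, log-normal — and ranks them
by AIC = 2k − 2ℓ, ties broken by parsimony then name.  Parameter recovery is
verified at n = 5,000 with ~20% exponential censoring (within 5% for every
family at the fixed test seed; note the rate parameter's sampling standard
error at this design is itself ≈5%, so this bound is tight).

## Pseudo-IPD reconstruction

`reconstruct_ipd` implements the interval-wise iterative allocation that has
become standard for rebuilding patient records from a digitized KM plot with
a numbers-at-risk table.  Within each inter-risk-table interval the number
of censorings is found by bisection (the implied number at risk at the
interval end is monotone in it, and ties are resolved toward the smallest
censoring count, i.e. events as early as possible); events are placed at
coordinate times so the running product-limit estimate tracks the digitized
survival; censoring times are spread uniformly.  Beyond the last risk-table
time no censoring is assumed; survivors are administratively censored at the
final coordinate, so the output has exactly n0 records.  If the total event
count is known, administrative censorings at the final coordinate are traded
against events there to match it.  Round-trip fidelity (curve → IPD → KM) is
≤0.02 sup-norm for n ≥ 200 noiseless curves, typically ≤0.005.

## Time on treatment and cost accrual

Drug and administration costs accrue over *time on treatment*, not over the
whole PF stay.  Each drug component carries a stopping curve: a Weibull with
the arm's PFS shape parameter and median equal to the trial's reported
median treatment duration (atezolizumab 7.4, bevacizumab 6.9, sorafenib 2.8
months), bounded above by PF occupancy and thinned once by the
adverse-event discontinuation rate (0.07 / 0.10).  This single rule captures
both arms' observed behaviour: for atezo–bev the duration median exceeds the
PFS median, so the progression bound binds and accrual effectively follows
PF occupancy (treatment to progression, as in the trial); for sorafenib the
reported duration (2.8 months) is far *below* its PFS median (4.3 months) —
toxicity-driven stopping — so the stopping curve binds.  Accruing sorafenib
cost over the full PF stay instead would overstate its drug cost by ~40% and
understate the incremental cost of atezo–bev by ~30%, and is inconsistent
with the reported incremental cost and with the reported duration-cap
scenario results, whose ICER deltas match an accrual tail that follows PFS
occupancy.

Other accrual, per cycle and occupancy-weighted: CT imaging (1543 USD per
6 weeks → 771.50/cycle) and supportive care (174.50 USD/week → 523.50/cycle)
in both alive states; post-progression therapy as a blended per-cycle cost
(4612.66 atezo–bev arm, 4825.93 sorafenib arm — subsequent-therapy uptake is
taken as already baked into these blended figures); one-off end-of-life cost
(7360.16) on the transition to death; administration cost (435.04/cycle)
for the infusion arm only (sorafenib is oral).  Bevacizumab cost scales
linearly in body weight and dose from the 70 kg / 15 mg/kg anchor
(117.60 USD/cycle).  Grade 3–4 adverse-event management costs and utility
decrements (incidence-weighted sums) are charged once at model entry.
QALYs weight PF occupancy by 0.78 and PD occupancy by 0.68.

The societal perspective adds caregiver cost (382.21/cycle) in alive states
and patient-time plus travel costs (896.20 + 329.50) per on-treatment cycle.
Duration caps zero drug and administration accrual beyond the cap, leaving
effectiveness untouched.

## Long-term survival scenarios

Trial follow-up covers ~17 months; the atezo–bev OS hazard beyond that point
is exposed as three scenarios, all continuous in S(t) at the switch and
applied to the atezo–bev arm's OS only:

- **extrapolate** (base case): the fitted Weibull hazard continues;
- **optimistic** (cure): survivors at 17 months face background mortality
  only, and post-progression therapy costs cease at the switch (a cured
  cohort no longer receives systemic therapy — without this the scenario's
  total cost would rise with the longer survival, whereas the reported
  optimistic total cost *falls* relative to base);
- **pessimistic**: a constant excess hazard after the switch, calibrated so
  that modelled 3-year survival (including background mortality) equals a
  registry anchor (SEER-based; 0.278 default, 0.238 selectable).  The
  calibration equation is log-linear in the excess hazard, so the root is
  closed-form; tests verify S(36 m) = anchor to 1e-6.

**Known inconsistency, reported rather than patched:** under the published
inputs (sorafenib Weibull OS × HR 0.58) the extrapolated atezo–bev 3-year
survival is 19.9%, *below* both registry anchors.  The "pessimistic"
calibration therefore lowers the post-17-month hazard and the scenario comes
out slightly *more* favourable than base (ICER ≈ 186k vs 199k USD/QALY),
instead of the sharply less favourable result reported (385,857).  The
reported scenario analysis presupposes an unpublished fitted atezo–bev curve
with 3-year survival 37.7%; that curve cannot be reconciled with the
published Weibull + hazard-ratio inputs (any Weibull through S(36 m) = 0.377
implies ≥2.2 discounted life-years, contradicting the reported 2.02, and
inflates the incremental QALYs ~70% beyond the reported 0.44).  We keep the
published inputs, report the computed scenario results, and leave the
corresponding acceptance checks red.  The same applies to the
optimistic-vs-base QALY ordering (holds) and pessimistic-vs-base ordering
(inverted at the default anchor; the mechanism's ordering guarantee — tested
— applies whenever the anchor lies below the extrapolated 3-year survival).

## Sensitivity analyses

- **One-way DSA:** every registry parameter to its range endpoints
  (published CIs, otherwise ±20%), everything else at base; rows sorted by
  ICER spread.  In this model the first-line utility, the atezolizumab
  price, the post-progression costs and the OS hazard ratio dominate.
- **Two-way DSA:** full-factorial ICER surface; special axes for the common
  price multiplier, the 3-year-survival anchor, the duration cap and the
  bevacizumab dose.  Unattainable anchor points are flagged (NaN), not
  fatal.
- **PSA:** 100,000 independent draws — normal hazard ratios (sd from the
  95% CI width, truncated at 1e-6), binomial proportions with the trial arm
  sizes (336 / 165) as denominators, triangular costs and utilities
  (min/mode/max).  The fitted Weibull parameters are held fixed (no sampling
  distribution was published for them).  Both arms share draws of shared
  parameters.  The engine broadcasts parameter arrays through the cohort
  recursion, so a full PSA takes seconds; results are bit-reproducible given
  the seed.  The acceptability at a willingness-to-pay threshold is the
  fraction of draws with positive incremental net monetary benefit
  (NMB = WTP·ΔQALY − Δcost).
- **Price threshold:** bisection to 0.1% on a common multiplier applied to
  both atezolizumab and bevacizumab unit costs; the headline figure is the
  smallest whole-percent reduction meeting the threshold.

**A second reported-number caveat:** the reported base-case PSA
acceptability (45.6% at 150k USD/QALY) is not internally consistent with the
reported ICER credible interval (163,932–191,054): an ICER distribution that
narrow implies an acceptability near 0 at 150k, while 45.6% requires an NMB
spread an order of magnitude wider.  Our PSA yields ≈12% at 150k with an
ICER credible interval of ≈123k–342k; the corresponding acceptance check is
left red.  Under the cure scenario our acceptability at 150k is ≈100%,
consistent with the reported 92.7% within its tolerance.

## Synthetic data

The generators exist so every stage is testable without downloads:
right-censored samples from any supported law (independent exponential
censoring plus administrative follow-up cutoff — non-informative, the
simplest structure the reconstruction assumes); digitized-style KM curves
(grid evaluation, optional multiplicative log-normal jitter with
monotonicity repair, exact numbers at risk); and a Gompertz life table
(annual mortality doubling every `doubling_time` years).  The default
background-mortality table is the synthetic Gompertz output with
q(18) = 3.5e-4 doubling every 9 years — q(65) ≈ 0.013, q(75) ≈ 0.028,
close to US all-cause values — and a real life table is a drop-in
replacement via the `age,qx` CSV format.  What the generators do *not*
emulate: informative censoring, accrual patterns, digitization bias that is
correlated over time, and cohort heterogeneity; passing round-trip tests
therefore validates the algorithms, not the fidelity of any particular
published figure's digitization.

## Numerical choices

- Cycle length is exactly 21/365.25 years everywhere (discounting, QALY
  conversion, background-hazard integration).
- Hazard-scale combination of disease and background mortality; probability
  conversions via `expm1`/`log1p` for stability.
- Progression probability floored at zero when the death probability
  exceeds the PF-exit probability (does not occur at base-case inputs).
- Reconstruction bisection is bounded by the interval's at-risk deficit;
  rounding is half-up for determinism.
- The microsimulation used as a test oracle replays the same per-cycle
  transition probabilities subject-by-subject (200,000 subjects agree with
  the cohort engine within 0.5%, far above Monte-Carlo noise).

## Problem sizes

Default analysis sizes: 86-cycle deterministic runs (instant), 100,000-draw
PSA per scenario (~1–2 s, vectorized), parameter-recovery fits at n = 5,000,
reconstruction round trips at n = 200–500, microsimulation oracle at
n = 200,000.  These sizes make every reported quantity's Monte-Carlo error
negligible relative to its acceptance tolerance.

## Limitations

- No tunnel states: time-on-treatment is an occupancy-level accrual rule,
  not an explicit state, so drug cost and PF membership are coupled only
  through the stopping-curve bound.
- The atezo–bev OS curve is hazard-ratio-scaled rather than independently
  fitted; proportional hazards over the whole horizon is an assumption, and
  it is the root of the scenario-anchor inconsistency above.
- Post-progression therapy is a blended per-cycle cost, not an explicit
  subsequent-treatment mix; the bevacizumab unit cost of 117.60 USD/cycle
  makes dose-reduction scenarios nearly cost-neutral in this implementation.
- Parameters are drawn independently in the PSA (no correlation structure
  was published).
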