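"""Baseline model parameters: values, plausible ranges and distributions.

Every tunable input of the analysis lives in one registry so the
deterministic run, the one-way sensitivity analysis and the probabilistic
sensitivity analysis all draw on the same source.  Costs are 2020 USD.
Ranges are the published confidence limits where available, otherwise
+/-20% around the base value.  Distribution kinds: ``normal`` (hazard
ratios; sd from the 95% CI width), ``binomial`` (event proportions, with
the trial arm sizes as denominators), ``triangular`` (costs and utilities,
min/mode/max), ``fixed`` (not sampled).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort_model import (
    AdverseEvent,
    DrugComponent,
    ModelSettings,
    StrategySpec,
    bev_cost,
)
from .survival import ParametricSurvival, apply_hazard_ratio

__all__ = [
    "Param",
    "PARAMETERS",
    "ARM_ATEZO_BEV",
    "ARM_SORAFENIB",
    "TRIAL_N",
    "base_values",
    "build_strategies",
    "default_settings",
]

ARM_ATEZO_BEV = "atezo-bev"
ARM_SORAFENIB = "sorafenib"

#: trial arm sizes (denominators for binomial draws)
TRIAL_N = {ARM_ATEZO_BEV: 336, ARM_SORAFENIB: 165}

#: fitted sorafenib survival models, S(t) = exp(-lam * t**gam), t in months
WEIBULL_OS_SORAFENIB = (0.027, 1.286)
WEIBULL_PFS_SORAFENIB = (0.093, 1.312)

#: median time on treatment, months
DURATION_MEDIANS = {"atezolizumab": 7.4, "bevacizumab": 6.9, "sorafenib": 2.8}


@dataclass(frozen=True)
class Param:
    """One registry entry."""

    name: str
    base: float
    low: float
    high: float
    dist: str               # normal | binomial | triangular | fixed
    n_denom: int | None = None
    is_cost: bool = False

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "fixed" or self.high == self.low == self.base:
            return np.full(size, self.base)
        if self.dist == "normal":
            sd = (self.high - self.low) / (2 * 1.959964)
            return np.maximum(rng.normal(self.base, sd, size), 1e-6)
        if self.dist == "binomial":
            n = self.n_denom or 100
            return rng.binomial(n, self.base, size) / n
        if self.dist == "triangular":
            return rng.triangular(self.low, self.base, self.high, size)
        raise ValueError(f"unknown distribution {self.dist!r}")


def _p(name, base, low=None, high=None, dist="triangular", n=None, cost=False):
    if low is None:
        low, high = 0.8 * base, 1.2 * base
    return Param(name, base, low, high, dist, n, cost)


_N_AB, _N_S = TRIAL_N[ARM_ATEZO_BEV], TRIAL_N[ARM_SORAFENIB]

PARAMETERS: dict[str, Param] = {
    p.name: p
    for p in [
        # clinical effectiveness
        _p("hr_os", 0.58, 0.42, 0.79, "normal"),
        _p("hr_pfs", 0.59, 0.47, 0.76, "normal"),
        # treatment discontinuation due to AEs
        _p("disc_rate_atezo_bev", 0.07, 0.056, 0.084, "binomial", _N_AB),
        _p("disc_rate_sorafenib", 0.10, 0.08, 0.12, "binomial", _N_S),
        # grade 3-4 AE incidences
        _p("ae_diarrhea_atezo_bev", 0.018, 0.014, 0.022, "binomial", _N_AB),
        _p("ae_hfs_atezo_bev", 0.0, 0.0, 0.0, "binomial", _N_AB),
        _p("ae_hypertension_atezo_bev", 0.152, 0.122, 0.182, "binomial", _N_AB),
        _p("ae_bilirubin_atezo_bev", 0.024, 0.019, 0.029, "binomial", _N_AB),
        _p("ae_diarrhea_sorafenib", 0.051, 0.041, 0.061, "binomial", _N_S),
        _p("ae_hfs_sorafenib", 0.083, 0.066, 0.1, "binomial", _N_S),
        _p("ae_hypertension_sorafenib", 0.122, 0.098, 0.146, "binomial", _N_S),
        _p("ae_bilirubin_sorafenib", 0.064, 0.051, 0.077, "binomial", _N_S),
        _p("patient_weight", 70.0, 40.0, 200.0),
        # drug and care costs, USD
        _p("cost_atezolizumab", 9419.16, 7535.33, 11302.99, cost=True),
        _p("cost_bevacizumab_unit", 117.60, 94.08, 141.12, cost=True),
        _p("cost_sorafenib", 14609.28, 11687.42, 17531.14, cost=True),
        _p("cost_administration", 435.04, 348.03, 522.05, cost=True),
        _p("cost_imaging_6wk", 1543.0, 1235.0, 1852.0, cost=True),
        _p("cost_other_care_weekly", 174.5, 139.6, 209.4, cost=True),
        _p("cost_eol", 7360.16, 6208.85, 9313.77, cost=True),
        _p("cost_postprog_atezo_bev", 4612.66, 3690.13, 5535.20, cost=True),
        _p("cost_postprog_sorafenib", 4825.93, 3860.74, 5791.11, cost=True),
        # societal costs
        _p("cost_caregiver_cycle", 382.21, 305.77, 458.65, cost=True),
        _p("cost_patient_time", 896.2, 716.96, 1075.44, cost=True),
        _p("cost_travel", 329.5, 263.6, 395.4, cost=True),
        # AE management costs
        _p("ae_cost_diarrhea", 88.38, 70.70, 106.05, cost=True),
        _p("ae_cost_hfs", 145.65, 116.51, 174.78, cost=True),
        _p("ae_cost_hypertension", 64.01, 51.21, 76.81, cost=True),
        _p("ae_cost_bilirubin", 0.0, 0.0, 0.0, "fixed", cost=True),
        # utilities and disutilities (magnitudes)
        _p("utility_pf_atezo_bev", 0.78, 0.624, 0.936),
        _p("utility_pf_sorafenib", 0.78, 0.624, 0.936),
        _p("utility_progressed", 0.68, 0.54, 0.82),
        _p("disutil_diarrhea", 0.103, 0.082, 0.123),
        _p("disutil_hfs", 0.116, 0.093, 0.139),
        _p("disutil_hypertension", 0.0, 0.0, 0.0, "fixed"),
        _p("disutil_bilirubin", 0.0, 0.0, 0.0, "fixed"),
        _p("bev_dose", 15.0, 15.0, 15.0, "fixed"),
    ]
}


def base_values() -> dict[str, float]:
    """Base-case value of every registry parameter."""
    return {name: p.base for name, p in PARAMETERS.items()}


def default_settings(**overrides) -> ModelSettings:
    return ModelSettings(**overrides)


def build_strategies(
    values: Mapping[str, float | np.ndarray] | None = None,
    societal: bool = False,
) -> tuple[StrategySpec, StrategySpec]:
    """Build the two treatment arms from a parameter mapping.

    ``values`` may override any registry entry with a scalar or an array of
    draws (arrays broadcast through the cohort engine).  Returns
    ``(atezo_bev, sorafenib)``.
    """
    v = base_values()
    if values:
        unknown = set(values) - set(v)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        v.update(values)

    os_sor = ParametricSurvival("weibull", WEIBULL_OS_SORAFENIB)
    pfs_sor = ParametricSurvival("weibull", WEIBULL_PFS_SORAFENIB)
    os_ab = apply_hazard_ratio(os_sor, v["hr_os"])
    pfs_ab = apply_hazard_ratio(pfs_sor, v["hr_pfs"])

    atezo_bev = StrategySpec(
        name=ARM_ATEZO_BEV,
        os_model=os_ab,
        pfs_model=pfs_ab,
        drug_components=(
            DrugComponent("atezolizumab", v["cost_atezolizumab"],
                          DURATION_MEDIANS["atezolizumab"]),
            DrugComponent(
                "bevacizumab",
                bev_cost(v["patient_weight"], v["bev_dose"],
                         v["cost_bevacizumab_unit"]),
                DURATION_MEDIANS["bevacizumab"],
            ),
        ),
        administration_cost=v["cost_administration"],
        administration_duration_median=DURATION_MEDIANS["atezolizumab"],
        imaging_cost_6wk=v["cost_imaging_6wk"],
        other_care_weekly=v["cost_other_care_weekly"],
        post_progression_cost=v["cost_postprog_atezo_bev"],
        eol_cost=v["cost_eol"],
        ae_profile=(
            AdverseEvent("diarrhea", v["ae_diarrhea_atezo_bev"],
                         v["ae_cost_diarrhea"], v["disutil_diarrhea"]),
            AdverseEvent("hand-foot syndrome", v["ae_hfs_atezo_bev"],
                         v["ae_cost_hfs"], v["disutil_hfs"]),
            AdverseEvent("hypertension", v["ae_hypertension_atezo_bev"],
                         v["ae_cost_hypertension"], v["disutil_hypertension"]),
            AdverseEvent("bilirubin increase", v["ae_bilirubin_atezo_bev"],
                         v["ae_cost_bilirubin"], v["disutil_bilirubin"]),
        ),
        discontinuation_rate=v["disc_rate_atezo_bev"],
        utility_first_line=v["utility_pf_atezo_bev"],
        utility_progressed=v["utility_progressed"],
        societal=societal,
        caregiver_cost_cycle=v["cost_caregiver_cycle"],
        patient_time_cost_cycle=v["cost_patient_time"],
        travel_cost_cycle=v["cost_travel"],
    )
    sorafenib = StrategySpec(
        name=ARM_SORAFENIB,
        os_model=os_sor,
        pfs_model=pfs_sor,
        drug_components=(
            DrugComponent("sorafenib", v["cost_sorafenib"],
                          DURATION_MEDIANS["sorafenib"]),
        ),
        administration_cost=0.0,  # oral therapy: no infusion visits
        administration_duration_median=None,
        imaging_cost_6wk=v["cost_imaging_6wk"],
        other_care_weekly=v["cost_other_care_weekly"],
        post_progression_cost=v["cost_postprog_sorafenib"],
        eol_cost=v["cost_eol"],
        ae_profile=(
            AdverseEvent("diarrhea", v["ae_diarrhea_sorafenib"],
                         v["ae_cost_diarrhea"], v["disutil_diarrhea"]),
            AdverseEvent("hand-foot syndrome", v["ae_hfs_sorafenib"],
                         v["ae_cost_hfs"], v["disutil_hfs"]),
            AdverseEvent("hypertension", v["ae_hypertension_sorafenib"],
                         v["ae_cost_hypertension"], v["disutil_hypertension"]),
            AdverseEvent("bilirubin increase", v["ae_bilirubin_sorafenib"],
                         v["ae_cost_bilirubin"], v["disutil_bilirubin"]),
        ),
        discontinuation_rate=v["disc_rate_sorafenib"],
        utility_first_line=v["utility_pf_sorafenib"],
        utility_progressed=v["utility_progressed"],
        societal=societal,
        caregiver_cost_cycle=v["cost_caregiver_cycle"],
        patient_time_cost_cycle=v["cost_patient_time"],
        travel_cost_cycle=v["cost_travel"],
    )
    return atezo_bev, sorafenib
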