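"""Cost accumulation: trial dosing rules and per-cycle cost components.

Reading of "per cycle" for supportive-care, disease and second-line costs is
per *model* cycle (1 week), the reading consistent with the published
totals.  Drug regimens run on 3-week treatment cycles and are spread evenly
over their weeks (1/3 of a treatment-cycle cost per model week), weighted by
the probability of still being progression-free:

* serplulimab 4.5 mg/kg every 3 weeks, continued until progression;
* etoposide + carboplatin for the first four 3-week cycles (12 weeks) only;
* one administration unit per infusion day (serplulimab: 1/treatment cycle;
  chemotherapy: 3 etoposide days, carboplatin sharing day 1).

Adverse-event management is a one-off at entry (undiscounted); terminal care
attaches to the death mass in the cycle it occurs, at that cycle's discount
factor.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig, Arm, SERP
from .engine import Trace

__all__ = ["dose_serplulimab", "dose_carboplatin", "dose_etoposide",
           "arm_costs", "COST_COMPONENTS"]

COST_COMPONENTS = ("serplulimab_drug", "chemo_drug", "administration",
                   "second_line", "supportive_pfs", "supportive_pd",
                   "ae_management", "terminal_care")


def dose_serplulimab(weight_kg: float, mg_per_kg: float = 4.5) -> float:
    """Serplulimab dose per 3-week cycle, mg (weight-based)."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return mg_per_kg * weight_kg


def dose_carboplatin(ccr_ml_min: float, auc: float = 5.0,
                     cap_mg: float = 750.0) -> float:
    """Carboplatin dose per cycle by the Calvert formula, capped.

    dose = AUC x (CrCl + 25), up to the trial cap of 750 mg.
    """
    if ccr_ml_min < 0:
        raise ValueError("creatinine clearance must be non-negative")
    if auc < 0:
        raise ValueError("target AUC must be non-negative")
    return min(auc * (ccr_ml_min + 25.0), cap_mg)


def dose_etoposide(bsa_m2: float, mg_per_m2: float = 100.0,
                   days: int = 3) -> float:
    """Etoposide dose per 3-week cycle, mg (100 mg/m^2 on days 1-3)."""
    if bsa_m2 <= 0:
        raise ValueError("body surface area must be positive")
    return mg_per_m2 * bsa_m2 * days


def arm_costs(trace: Trace, config: ModelConfig) -> dict:
    """Discounted cost components (USD) for one arm, plus their total."""
    arm: Arm = trace.arm
    c = config.costs
    d = config.dosing
    body = config.body

    seg_w = trace.seg_weeks()
    pfs_w = trace.seg_pfs * seg_w * trace.discount   # discounted PFS weeks/cycle
    pd_w = trace.seg_pd * seg_w * trace.discount

    components = dict.fromkeys(COST_COMPONENTS, 0.0)

    # serplulimab acquisition + administration, until progression (serp arm)
    if arm == SERP:
        per_cycle = dose_serplulimab(body.weight_kg, d.serplulimab_mg_per_kg) \
            * c.serplulimab_per_mg
        weekly = per_cycle / d.regimen_cycle_weeks
        components["serplulimab_drug"] = weekly * float(np.sum(pfs_w))
        components["administration"] += (c.administration_per_unit
                                         / d.regimen_cycle_weeks
                                         * float(np.sum(pfs_w)))

    # platinum-etoposide over the first `chemo_cycles` regimen cycles, both arms
    chemo_weeks = d.chemo_cycles * d.regimen_cycle_weeks
    n_seg = int(round(chemo_weeks / config.cycle_weeks))
    eto = dose_etoposide(body.bsa_m2, d.etoposide_mg_per_m2, d.etoposide_days)
    carbo = dose_carboplatin(body.ccr_ml_min, d.carboplatin_auc,
                             d.carboplatin_cap_mg)
    chemo_per_cycle = eto * c.etoposide_per_mg + carbo * c.carboplatin_per_mg
    admin_days = d.etoposide_days          # carboplatin shares day 1
    early_pfs_w = float(np.sum(pfs_w[:n_seg]))
    components["chemo_drug"] = chemo_per_cycle / d.regimen_cycle_weeks * early_pfs_w
    components["administration"] += (admin_days * c.administration_per_unit
                                     / d.regimen_cycle_weeks * early_pfs_w)

    # disease management, second-line therapy, one-offs
    components["supportive_pfs"] = c.supportive_per_cycle["pfs"] * float(np.sum(pfs_w))
    components["supportive_pd"] = c.supportive_per_cycle["pd"] * float(np.sum(pd_w))
    components["second_line"] = c.second_line_per_cycle[arm] * float(np.sum(pd_w))
    components["ae_management"] = c.ae_management[arm]
    components["terminal_care"] = c.terminal_care_per_patient * float(
        np.sum(trace.deaths * trace.discount))

    components["total"] = sum(components[k] for k in COST_COMPONENTS)
    # reporting split used by the published cost table
    components["drug"] = (components["serplulimab_drug"] + components["chemo_drug"]
                          + components["administration"] + components["second_line"])
    components["nondrug"] = components["total"] - components["drug"]
    return components
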