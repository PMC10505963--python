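"""Subgroup re-analysis by substituting subgroup-specific OS hazard ratios.

The ASTRUM-005 subgroup report gives an unstratified OS hazard ratio (and
95% CI) per subgroup.  Each subgroup's economics are recomputed by holding
the treatment arm at its fitted curves and rebuilding the comparator OS as
S_trt^(1/HR) -- the same proportional-hazards mechanism as the base case and
the HR rows of the sensitivity analysis.  PFS (and all costs and utilities)
stay at base, since only OS hazard ratios were reported per subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .economics import CEAResult
from .model import run_cea
from .sensitivity import set_parameter, ParamSpec, run_psa

__all__ = ["SubgroupSpec", "ASTRUM_005_SUBGROUPS", "subgroup_cea",
           "subgroup_table"]


@dataclass(frozen=True)
class SubgroupSpec:
    label: str
    os_hr: float
    hr_ci: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.hr_ci
        if not (self.os_hr > 0 and lo <= self.os_hr <= hi):
            raise ValueError(f"{self.label}: need 0 < low <= HR <= high")


#: Unstratified OS hazard ratios per ASTRUM-005 subgroup.
ASTRUM_005_SUBGROUPS = [
    SubgroupSpec("Age <65 years", 0.62, (0.45, 0.86)),
    SubgroupSpec("Age >=65 years", 0.60, (0.40, 0.89)),
    SubgroupSpec("Male", 0.64, (0.48, 0.84)),
    SubgroupSpec("Female", 0.57, (0.30, 1.06)),
    SubgroupSpec("Asian", 0.58, (0.43, 0.79)),
    SubgroupSpec("Non-Asian", 0.70, (0.43, 1.13)),
    SubgroupSpec("ECOG PS 0", 0.44, (0.23, 0.84)),
    SubgroupSpec("ECOG PS 1", 0.65, (0.49, 0.86)),
    SubgroupSpec("Never smoked", 0.75, (0.42, 1.33)),
    SubgroupSpec("Current smoker", 0.61, (0.36, 1.02)),
    SubgroupSpec("Former smoker", 0.59, (0.42, 0.83)),
    SubgroupSpec("No brain metastases", 0.62, (0.47, 0.82)),
    SubgroupSpec("Brain metastases", 0.61, (0.33, 1.13)),
    SubgroupSpec("PD-L1 TPS <1%", 0.58, (0.44, 0.76)),
    SubgroupSpec("PD-L1 TPS >=1%", 0.92, (0.44, 1.89)),
    SubgroupSpec("PD-L1 not evaluable/available", 0.42, (0.10, 1.72)),
]


def subgroup_cea(config: ModelConfig, spec: SubgroupSpec) -> CEAResult:
    """Base-case economics with the subgroup's OS hazard ratio substituted."""
    return run_cea(set_parameter(config, "hr.os", spec.os_hr))


def subgroup_table(config: ModelConfig, specs=ASTRUM_005_SUBGROUPS,
                   psa_iter: int = 0, seed: int = 0) -> pd.DataFrame:
    """Per-subgroup incremental outcomes (and optional PSA acceptability).

    With ``psa_iter > 0`` a probabilistic analysis is re-run per subgroup
    with the OS HR drawn lognormally from the subgroup CI (all other inputs
    drawn from their base-case distributions), reporting the probability of
    cost-effectiveness at each configured threshold.
    """
    from .sensitivity import default_param_specs

    rows = []
    for k, spec in enumerate(specs):
        cea = subgroup_cea(config, spec)
        row = {"subgroup": spec.label, "os_hr": spec.os_hr,
               "hr_low": spec.hr_ci[0], "hr_high": spec.hr_ci[1],
               "delta_cost": cea.delta_cost, "delta_qalys": cea.delta_qalys,
               "icer_per_qaly": cea.icer_per_qaly}
        for wtp in config.wtp_thresholds:
            row[f"inhb@{wtp:g}"] = cea.inhb(wtp)
        if psa_iter > 0:
            base_specs = [s for s in default_param_specs(config)
                          if s.name != "hr.os"]
            lo, hi = spec.hr_ci
            base_specs.append(ParamSpec("hr.os", "HR for OS (subgroup)",
                                        spec.os_hr, lo, hi, "lognormal"))
            psa = run_psa(config, base_specs, n_iter=psa_iter,
                          seed=seed + k)
            for wtp in config.wtp_thresholds:
                row[f"p_ce@{wtp:g}"] = psa.prob_cost_effective(wtp)
        rows.append(row)
    return pd.DataFrame(rows)
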