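"""Model / Results front-end for the partitioned-survival CEA.

`PartitionedSurvivalCEA` is constructed from a :class:`ModelConfig` (or a
YAML config path); ``fit()`` evaluates both arms and returns
:class:`CEAResults`, which carries per-arm traces, totals and incremental
outcomes and renders a summary table shaped like the published base-case
table.  Sensitivity analyses (tornado, threshold search, probabilistic) and
subgroup re-analysis are methods on the model returning their own result
objects.

Example
-------
>>> from psmcea import PartitionedSurvivalCEA
>>> res = PartitionedSurvivalCEA().fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelConfig, base_case_config, SERP, CHEMO, ARMS
from .costing import arm_costs, COST_COMPONENTS
from .economics import CEAResult
from .engine import run_trace, arm_effectiveness

__all__ = ["PartitionedSurvivalCEA", "CEAResults", "run_cea"]


def run_cea(config: ModelConfig) -> CEAResult:
    """Evaluate both arms under ``config`` and return incremental outcomes.

    This is the light-weight core used by the sensitivity machinery; the
    Model/Results wrapper below adds traces and report tables on top.
    """
    arms = {}
    for arm in ARMS:
        trace = run_trace(arm, config)
        eff = arm_effectiveness(trace, config)
        costs = arm_costs(trace, config)
        arms[arm] = {**eff, "cost": costs["total"],
                     "cost_drug": costs["drug"], "cost_nondrug": costs["nondrug"]}
    return CEAResult(arms=arms, treatment=SERP, comparator=CHEMO,
                     wtp_thresholds=tuple(config.wtp_thresholds))


class PartitionedSurvivalCEA:
    """Three-state (PFS / progressed / dead) partitioned-survival CEA model."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = (config or base_case_config()).validate(strict=False)

    @classmethod
    def from_yaml(cls, path) -> "PartitionedSurvivalCEA":
        from .config import load_config
        return cls(load_config(path))

    def fit(self) -> "CEAResults":
        """Run both arms over the horizon; deterministic."""
        cfg = self.config
        traces = {arm: run_trace(arm, cfg) for arm in ARMS}
        effectiveness = {a: arm_effectiveness(t, cfg) for a, t in traces.items()}
        costs = {a: arm_costs(t, cfg) for a, t in traces.items()}
        arms = {a: {**effectiveness[a], "cost": costs[a]["total"],
                    "cost_drug": costs[a]["drug"],
                    "cost_nondrug": costs[a]["nondrug"]} for a in ARMS}
        cea = CEAResult(arms=arms, treatment=SERP, comparator=CHEMO,
                        wtp_thresholds=tuple(cfg.wtp_thresholds))
        return CEAResults(self, traces, costs, cea)

    # -- analyses beyond the base case --------------------------------------

    def one_way(self, specs=None) -> pd.DataFrame:
        from .sensitivity import one_way, default_param_specs
        return one_way(self.config, specs or default_param_specs(self.config))

    def threshold_search(self, parameter: str, wtp: float,
                         bracket=None) -> float:
        from .sensitivity import threshold_search
        return threshold_search(self.config, parameter, wtp, bracket)

    def psa(self, n_iter: int = 10_000, seed: int = 0, specs=None,
            lambda_grid=None):
        from .sensitivity import run_psa, default_param_specs
        return run_psa(self.config, specs or default_param_specs(self.config),
                       n_iter=n_iter, seed=seed, lambda_grid=lambda_grid)

    def subgroups(self, specs=None, psa_iter: int = 0, seed: int = 0
                  ) -> pd.DataFrame:
        from .subgroups import subgroup_table, ASTRUM_005_SUBGROUPS
        return subgroup_table(self.config, specs or ASTRUM_005_SUBGROUPS,
                              psa_iter=psa_iter, seed=seed)


class CEAResults:
    """Fitted base-case results: traces, cost components, incrementals."""

    def __init__(self, model, traces, costs, cea: CEAResult):
        self.model = model
        self.config = model.config
        self.traces = traces
        self.costs = costs
        self.cea = cea

    # passthroughs for the quantities users ask for most
    @property
    def delta_cost(self): return self.cea.delta_cost
    @property
    def delta_qalys(self): return self.cea.delta_qalys
    @property
    def delta_life_years(self): return self.cea.delta_life_years
    @property
    def icer_per_qaly(self): return self.cea.icer_per_qaly
    @property
    def icer_per_life_year(self): return self.cea.icer_per_life_year
    def inhb(self, wtp): return self.cea.inhb(wtp)
    def inmb(self, wtp): return self.cea.inmb(wtp)

    def cumulative_mortality(self, arm) -> float:
        return float(self.traces[arm].occ_dead[-1])

    def summary(self) -> pd.DataFrame:
        """Base-case summary shaped like the published cost/outcome table.

        Life-years are undiscounted, QALYs and costs discounted (the
        published convention).
        """
        a = self.cea.arms
        rows = {
            "Cost, drug ($)": [a[SERP]["cost_drug"], a[CHEMO]["cost_drug"]],
            "Cost, nondrug ($)": [a[SERP]["cost_nondrug"], a[CHEMO]["cost_nondrug"]],
            "Cost, overall ($)": [a[SERP]["cost"], a[CHEMO]["cost"]],
            "Life-years, progression-free": [a[SERP]["pfs_life_years"],
                                             a[CHEMO]["pfs_life_years"]],
            "Life-years, overall": [a[SERP]["life_years"], a[CHEMO]["life_years"]],
            "QALYs": [a[SERP]["qalys"], a[CHEMO]["qalys"]],
        }
        df = pd.DataFrame(rows, index=["serplulimab+chemo", "chemotherapy"]).T
        df["incremental"] = df["serplulimab+chemo"] - df["chemotherapy"]
        extra = {"ICER per life-year ($)": self.icer_per_life_year,
                 "ICER per QALY ($)": self.icer_per_qaly}
        for wtp in self.config.wtp_thresholds:
            extra[f"INHB at ${wtp:,.0f}/QALY"] = self.inhb(wtp)
            extra[f"INMB at ${wtp:,.0f}/QALY ($)"] = self.inmb(wtp)
        for k, v in extra.items():
            df.loc[k] = [np.nan, np.nan, v]
        return df

    def cost_breakdown(self) -> pd.DataFrame:
        """Discounted cost components per arm (USD)."""
        df = pd.DataFrame({a: {k: self.costs[a][k] for k in
                               (*COST_COMPONENTS, "drug", "nondrug", "total")}
                           for a in ARMS})
        df["incremental"] = df[SERP] - df[CHEMO]
        return df

    def to_dict(self) -> dict:
        return self.cea.to_dict()
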