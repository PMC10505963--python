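"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the ICER with each input at the ends of its
range (the published 95% CI where one exists, otherwise +/-20% of the base
value) holding everything else fixed.  Threshold search bisects a
continuous input to the value where the ICER equals a willingness-to-pay
threshold.  The probabilistic analysis draws all inputs independently --
gamma for costs, beta for utilities/disutilities, normal for body metrics,
lognormal for hazard ratios -- with hyper-parameters moment-matched to
(base, low, high) using SE = (high - low)/3.92, re-runs both arms per
iteration, and summarises acceptability as CEAC(λ) = P(INMB(λ) > 0).

Treatment-effect uncertainty enters through the OS and PFS hazard ratios:
drawing/varying an HR rebuilds the comparator curve as S_trt^(1/HR) (the
same proportional-hazards mechanism the subgroup analysis uses); the fitted
treatment-arm curve parameters themselves are not varied.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .config import (ModelConfig, SERP, CHEMO, TRIAL_OS_HR, TRIAL_OS_HR_CI,
                     TRIAL_PFS_HR, TRIAL_PFS_HR_CI)
from .survival import ProportionalHazards
from .model import run_cea

__all__ = ["ParamSpec", "default_param_specs", "set_parameter", "one_way",
           "threshold_search", "run_psa", "PSAResult", "NoThresholdError",
           "DEFAULT_LAMBDA_GRID"]

log = logging.getLogger(__name__)

#: λ grid for acceptability curves: 0..150,000 USD/QALY in $100 steps.
DEFAULT_LAMBDA_GRID = np.arange(0.0, 150_000.0 + 1, 100.0)


@dataclass(frozen=True)
class ParamSpec:
    """One model input: base value, range, and PSA distribution.

    ``in_psa=False`` marks inputs that take part in the one-way analysis
    over their range but are held fixed in the probabilistic analysis: the
    published Monte-Carlo draws cover cost, hazard-ratio and
    preference-value variables only, with body metrics treated as fixed
    population characteristics (the reading that reproduces the published
    acceptability probabilities).
    """

    name: str          # dotted path, e.g. "costs.serplulimab_per_mg" or "hr.os"
    label: str
    base: float
    low: float
    high: float
    dist: str          # gamma | beta | normal | lognormal | none
    in_psa: bool = True

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.dist == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta parameter outside [0, 1]")

    @property
    def se(self) -> float:
        return (self.high - self.low) / 3.92


def _pm20(x: float) -> tuple[float, float]:
    return 0.8 * x, 1.2 * x


def default_param_specs(config: ModelConfig | None = None) -> list[ParamSpec]:
    """Every published input row with a distribution (95% CIs as printed)."""
    cfg = config or ModelConfig()
    c, u, b = cfg.costs, cfg.utilities, cfg.body
    return [
        ParamSpec("costs.serplulimab_per_mg", "Serplulimab cost per mg",
                  c.serplulimab_per_mg, 6.65, 9.98, "gamma"),
        ParamSpec("costs.etoposide_per_mg", "Etoposide cost per mg",
                  c.etoposide_per_mg, 0.17, 0.26, "gamma"),
        ParamSpec("costs.carboplatin_per_mg", "Carboplatin cost per mg",
                  c.carboplatin_per_mg, 0.15, 0.23, "gamma"),
        ParamSpec(f"costs.second_line_per_cycle.{SERP}",
                  "Second-line cost per cycle (serplulimab arm)",
                  c.second_line_per_cycle[SERP], 26.63, 39.94, "gamma"),
        ParamSpec(f"costs.second_line_per_cycle.{CHEMO}",
                  "Second-line cost per cycle (chemo arm)",
                  c.second_line_per_cycle[CHEMO], 45.75, 68.63, "gamma"),
        ParamSpec("costs.terminal_care_per_patient", "Terminal care cost",
                  c.terminal_care_per_patient, 2077.0, 3116.0, "gamma"),
        ParamSpec("costs.supportive_per_cycle.pfs", "PFS disease cost per cycle",
                  c.supportive_per_cycle["pfs"], 148.0, 222.0, "gamma"),
        ParamSpec("costs.supportive_per_cycle.pd", "PD disease cost per cycle",
                  c.supportive_per_cycle["pd"], 441.0, 662.0, "gamma"),
        ParamSpec(f"costs.ae_management.{SERP}", "AE cost (serplulimab arm)",
                  c.ae_management[SERP], 1250.0, 1874.0, "gamma"),
        ParamSpec(f"costs.ae_management.{CHEMO}", "AE cost (chemo arm)",
                  c.ae_management[CHEMO], 1358.0, 2036.0, "gamma"),
        ParamSpec("costs.administration_per_unit", "Administration cost per unit",
                  c.administration_per_unit, 15.288, 22.932, "gamma"),
        ParamSpec("utilities.pfs", "Utility of PFS", u.pfs, 0.538, 0.808, "beta"),
        ParamSpec("utilities.pd", "Utility of PD", u.pd, 0.378, 0.568, "beta"),
        ParamSpec(f"utilities.ae_disutility.{SERP}",
                  "AE disutility (serplulimab arm)",
                  u.ae_disutility[SERP], 0.040, 0.060, "beta"),
        ParamSpec(f"utilities.ae_disutility.{CHEMO}",
                  "AE disutility (chemo arm)",
                  u.ae_disutility[CHEMO], 0.042, 0.064, "beta"),
        ParamSpec("body.bsa_m2", "Body surface area (m^2)",
                  b.bsa_m2, 1.44, 2.16, "normal", in_psa=False),
        ParamSpec("body.weight_kg", "Body weight (kg)",
                  b.weight_kg, 50.0, 90.0, "normal", in_psa=False),
        ParamSpec("body.ccr_ml_min", "Creatinine clearance (mL/min)",
                  b.ccr_ml_min, 80.0, 100.0, "normal", in_psa=False),
        ParamSpec("hr.os", "HR for OS (serplulimab+chemo vs chemo)",
                  TRIAL_OS_HR, *TRIAL_OS_HR_CI, "lognormal"),
        ParamSpec("hr.pfs", "HR for PFS (serplulimab+chemo vs chemo)",
                  TRIAL_PFS_HR, *TRIAL_PFS_HR_CI, "lognormal"),
    ]


def set_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """A deep copy of ``config`` with the named input set to ``value``.

    Names are dotted attribute/key paths; the special ``hr.os`` / ``hr.pfs``
    names rebuild the comparator curve as S_trt^(1/HR).
    """
    return _set_param_inplace(copy.deepcopy(config), name, value)


def _set_param_inplace(cfg: ModelConfig, name: str, value: float) -> ModelConfig:
    if name == "hr.os":
        cfg.os_model[CHEMO] = ProportionalHazards(cfg.os_model[SERP], 1.0 / value)
        return cfg
    if name == "hr.pfs":
        cfg.pfs_model[CHEMO] = ProportionalHazards(cfg.pfs_model[SERP], 1.0 / value)
        return cfg
    parts = name.split(".")
    obj = cfg
    for p in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[p]
        elif hasattr(obj, p):
            obj = getattr(obj, p)
        else:
            raise KeyError(f"parameter {name!r} is not wired into the model "
                           f"(no attribute {p!r})")
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise KeyError(f"parameter {name!r} is not wired into the model")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise KeyError(f"parameter {name!r} is not wired into the model")
        setattr(obj, last, value)
    return cfg


def _icer_value(cea) -> float:
    v = cea.icer_per_qaly
    return v if isinstance(v, float) else math.nan


def one_way(config: ModelConfig, specs: list[ParamSpec]) -> pd.DataFrame:
    """Tornado table: ICER at each input's low/high, sorted by range width."""
    base = run_cea(config)
    base_icer = _icer_value(base)
    rows = []
    for spec in specs:
        lo = _icer_value(run_cea(set_parameter(config, spec.name, spec.low)))
        hi = _icer_value(run_cea(set_parameter(config, spec.name, spec.high)))
        rows.append({"parameter": spec.name, "label": spec.label,
                     "base_icer": base_icer, "low_value": spec.low,
                     "high_value": spec.high, "icer_at_low": lo,
                     "icer_at_high": hi,
                     "range": abs(hi - lo)})
    df = pd.DataFrame(rows).sort_values("range", ascending=False,
                                        kind="stable").reset_index(drop=True)
    return df


class NoThresholdError(ValueError):
    """The ICER never crosses the target WTP on the given bracket."""


_DEFAULT_BRACKETS = {
    "costs.serplulimab_per_mg": (1e-6, 8.32),
    "body.weight_kg": (1.0, 65.0),
}


def threshold_search(config: ModelConfig, parameter: str, wtp: float,
                     bracket: tuple[float, float] | None = None) -> float:
    """Input value at which the ICER equals ``wtp`` (bisection, rtol 1e-6)."""
    if bracket is None:
        try:
            bracket = _DEFAULT_BRACKETS[parameter]
        except KeyError:
            raise ValueError(f"no default bracket for {parameter!r}; pass one")
    lo, hi = bracket

    def gap(v: float) -> float:
        return _icer_value(run_cea(set_parameter(config, parameter, v))) - wtp

    g_lo, g_hi = gap(lo), gap(hi)
    if not np.isfinite(g_lo) or not np.isfinite(g_hi) or g_lo * g_hi > 0:
        raise NoThresholdError(
            f"ICER - {wtp:g} does not change sign on [{lo:g}, {hi:g}] "
            f"(gap {g_lo:g} .. {g_hi:g})")
    return float(brentq(gap, lo, hi, rtol=1e-6))


# -- probabilistic sensitivity analysis -------------------------------------

def _sampler(spec: ParamSpec, rng: np.random.Generator):
    """Moment-matched sampler for one parameter; returns draws array maker."""
    m, se = spec.base, spec.se
    if se == 0.0 or spec.dist == "none":
        return lambda n: np.full(n, m)
    var = se * se
    if spec.dist == "gamma":
        shape = m * m / var
        return lambda n: rng.gamma(shape, var / m, size=n)
    if spec.dist == "beta":
        if var >= m * (1.0 - m):
            # infeasible beta moments: logit-normal fallback
            log.warning("%s: beta moment-matching infeasible, using "
                        "logit-normal", spec.name)
            mu = math.log(m / (1.0 - m))
            sd = se / (m * (1.0 - m))  # delta method on the logit scale
            return lambda n: 1.0 / (1.0 + np.exp(-rng.normal(mu, sd, size=n)))
        nu = m * (1.0 - m) / var - 1.0
        a, b = m * nu, (1.0 - m) * nu
        return lambda n: rng.beta(a, b, size=n)
    if spec.dist == "normal":
        return lambda n: rng.normal(m, se, size=n)
    if spec.dist == "lognormal":
        sdlog = (math.log(spec.high) - math.log(spec.low)) / 3.92
        return lambda n: rng.lognormal(math.log(m), sdlog, size=n)
    raise ValueError(f"unknown distribution {spec.dist!r}")


class PSAResult:
    """Monte-Carlo draws and their incremental outcomes."""

    def __init__(self, draws: pd.DataFrame, wtp_thresholds, lambda_grid,
                 seed: int):
        self.draws = draws
        self.wtp_thresholds = tuple(wtp_thresholds)
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)
        self.seed = seed

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations with positive INMB at ``wtp``."""
        inmb = self.draws["delta_qalys"] * wtp - self.draws["delta_cost"]
        return float(np.mean(inmb > 0.0))

    def ceac(self) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve on the λ grid."""
        dq = self.draws["delta_qalys"].to_numpy()
        dc = self.draws["delta_cost"].to_numpy()
        prob = [float(np.mean(dq * lam - dc > 0.0)) for lam in self.lambda_grid]
        return pd.DataFrame({"lambda": self.lambda_grid, "probability": prob})

    def summary(self) -> pd.DataFrame:
        rows = {"iterations": len(self.draws),
                "mean delta cost ($)": self.draws["delta_cost"].mean(),
                "mean delta QALYs": self.draws["delta_qalys"].mean()}
        for wtp in self.wtp_thresholds:
            rows[f"P(cost-effective) at ${wtp:,.0f}/QALY"] = \
                self.prob_cost_effective(wtp)
        return pd.Series(rows).to_frame("value")

    def plot_ceac(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        curve = self.ceac()
        ax.plot(curve["lambda"], curve["probability"])
        ax.set_xlabel("Willingness to pay ($/QALY)")
        ax.set_ylabel("P(serplulimab+chemo cost-effective)")
        ax.set_ylim(-0.02, 1.02)
        return ax


def run_psa(config: ModelConfig, specs: list[ParamSpec], n_iter: int = 10_000,
            seed: int = 0, lambda_grid=None) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    All parameters are drawn independently; each iteration re-runs both
    arms.  Reproducible for a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    specs = [s for s in specs if s.in_psa]
    rng = np.random.default_rng(seed)
    draws = {spec.name: _sampler(spec, rng)(n_iter) for spec in specs}
    # supports: strictly positive quantities must stay positive
    for spec in specs:
        if spec.dist == "normal":
            np.clip(draws[spec.name], 1e-6, None, out=draws[spec.name])

    records = []
    for i in range(n_iter):
        cfg = copy.deepcopy(config)
        for spec in specs:
            _set_param_inplace(cfg, spec.name, float(draws[spec.name][i]))
        cea = run_cea(cfg)
        records.append((cea.delta_cost, cea.delta_qalys))
    out = pd.DataFrame({spec.name: draws[spec.name] for spec in specs})
    out.insert(0, "iteration", np.arange(n_iter))
    out["delta_cost"] = [r[0] for r in records]
    out["delta_qalys"] = [r[1] for r in records]
    for wtp in config.wtp_thresholds:
        out[f"inmb@{wtp:g}"] = out["delta_qalys"] * wtp - out["delta_cost"]
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid
    return PSAResult(out, config.wtp_thresholds, grid, seed)
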