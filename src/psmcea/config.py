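"""Model configuration: survival curves, costs, utilities, dosing, horizon.

Defaults reproduce the published base case for first-line serplulimab plus
carboplatin-etoposide versus carboplatin-etoposide alone in extensive-stage
small cell lung cancer (ASTRUM-005 population; Chinese healthcare
perspective; 2021 USD).

The treatment arm uses the published log-logistic fits to the digitized
trial curves.  The comparator arm is derived from them by proportional
hazards with the trial hazard ratios (OS HR 0.63, PFS HR 0.48 for
serplulimab+chemo vs chemo; here applied as S_chemo = S_trt^(1/HR)): this is
the construction that reproduces the published per-arm life-years, costs,
and the subgroup table, whereas the separately printed comparator
parametric fits do not.  Those printed fits remain available via
:func:`printed_chemo_models` for fitting demonstrations and alternative
scenarios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .survival import ParametricSurvival, ProportionalHazards

__all__ = [
    "Arm", "DosingRules", "CostInputs", "Utilities", "BodyMetrics",
    "ModelConfig", "base_case_config", "printed_chemo_models",
    "load_config", "save_config", "ConfigError",
]

SERP = "serplulimab_chemo"
CHEMO = "chemotherapy"
ARMS = (SERP, CHEMO)
Arm = str

#: ASTRUM-005 treatment-effect hazard ratios (treatment vs chemotherapy).
TRIAL_OS_HR = 0.63
TRIAL_OS_HR_CI = (0.49, 0.82)
TRIAL_PFS_HR = 0.48
TRIAL_PFS_HR_CI = (0.38, 0.59)


class ConfigError(ValueError):
    """Raised when a configuration violates a documented invariant."""


@dataclass
class DosingRules:
    """Trial dosing constants.

    Serplulimab 4.5 mg/kg every 3 weeks until progression; etoposide
    100 mg/m^2 on days 1-3 and carboplatin dosed by the Calvert formula
    (target AUC x (CrCl + 25), capped at 750 mg) on day 1 of each 3-week
    cycle, for four cycles.
    """

    serplulimab_mg_per_kg: float = 4.5
    etoposide_mg_per_m2: float = 100.0
    etoposide_days: int = 3
    carboplatin_auc: float = 5.0       # trial protocol target AUC (not printed)
    carboplatin_cap_mg: float = 750.0
    chemo_cycles: int = 4
    regimen_cycle_weeks: float = 3.0


@dataclass
class CostInputs:
    """Unit costs, 2021 USD."""

    serplulimab_per_mg: float = 8.32
    etoposide_per_mg: float = 0.22
    carboplatin_per_mg: float = 0.19
    second_line_per_cycle: dict = field(
        default_factory=lambda: {SERP: 33.28, CHEMO: 57.19})
    terminal_care_per_patient: float = 2596.0
    supportive_per_cycle: dict = field(
        default_factory=lambda: {"pfs": 185.0, "pd": 552.0})
    ae_management: dict = field(
        default_factory=lambda: {SERP: 1562.0, CHEMO: 1697.0})
    administration_per_unit: float = 19.11

    def validate(self) -> None:
        flat = [self.serplulimab_per_mg, self.etoposide_per_mg,
                self.carboplatin_per_mg, self.terminal_care_per_patient,
                self.administration_per_unit,
                *self.second_line_per_cycle.values(),
                *self.supportive_per_cycle.values(),
                *self.ae_management.values()]
        if any(c < 0 for c in flat):
            raise ConfigError("unit costs must be non-negative")


@dataclass
class Utilities:
    pfs: float = 0.673
    pd: float = 0.473
    #: Published one-off QALY decrements for grade >=3 adverse events.
    ae_disutility: dict = field(
        default_factory=lambda: {SERP: 0.050, CHEMO: 0.053})
    #: Whether the decrement is subtracted from QALYs at model entry.
    #: The published totals are only self-consistent with the disutility
    #: *not* applied (see methods note), so the default is False; the
    #: values above stay available for scenario analysis.
    apply_ae_disutility: bool = False

    def validate(self, strict: bool = True) -> None:
        for name, u in (("pfs", self.pfs), ("pd", self.pd)):
            if not 0.0 <= u <= 1.0:
                raise ConfigError(f"utilities.{name}={u} outside [0, 1]")
        if strict and self.pfs < self.pd:
            raise ConfigError("utilities.pfs must be >= utilities.pd")
        for arm, d in self.ae_disutility.items():
            if d < 0:
                raise ConfigError(f"ae_disutility[{arm}] must be >= 0")


@dataclass
class BodyMetrics:
    bsa_m2: float = 1.80
    weight_kg: float = 65.0
    ccr_ml_min: float = 90.0

    def validate(self) -> None:
        if self.bsa_m2 <= 0 or self.weight_kg <= 0 or self.ccr_ml_min < 0:
            raise ConfigError("body metrics must be positive (CCR >= 0)")


@dataclass
class ModelConfig:
    """Complete base-case input set for the partitioned survival model."""

    os_model: dict = None
    pfs_model: dict = None
    horizon_weeks: int = 520
    cycle_weeks: float = 1.0
    annual_discount: float = 0.05
    discount_mode: str = "annual"      # "annual" (year buckets) | "continuous"
    utilities: Utilities = field(default_factory=Utilities)
    costs: CostInputs = field(default_factory=CostInputs)
    dosing: DosingRules = field(default_factory=DosingRules)
    body: BodyMetrics = field(default_factory=BodyMetrics)
    wtp_thresholds: tuple = (37669.0, 86569.0)

    def __post_init__(self):
        if self.os_model is None or self.pfs_model is None:
            trt_os = ParametricSurvival("loglogistic", (1.7870, 0.0124))
            trt_pfs = ParametricSurvival("loglogistic", (2.0490, 0.0294))
            if self.os_model is None:
                self.os_model = {SERP: trt_os,
                                 CHEMO: ProportionalHazards(trt_os, 1.0 / TRIAL_OS_HR)}
            if self.pfs_model is None:
                self.pfs_model = {SERP: trt_pfs,
                                  CHEMO: ProportionalHazards(trt_pfs, 1.0 / TRIAL_PFS_HR)}

    def validate(self, strict: bool = True) -> "ModelConfig":
        if self.horizon_weeks < 1:
            raise ConfigError("horizon_weeks must be >= 1")
        if not 0.0 <= self.annual_discount < 1.0:
            raise ConfigError("annual_discount must be in [0, 1)")
        if self.cycle_weeks <= 0:
            raise ConfigError("cycle_weeks must be positive")
        for d in (self.os_model, self.pfs_model):
            missing = [a for a in ARMS if a not in d]
            if missing:
                raise ConfigError(f"survival model missing for arm(s) {missing}")
        self.utilities.validate(strict=strict)
        self.costs.validate()
        self.body.validate()
        if any(w <= 0 for w in self.wtp_thresholds):
            raise ConfigError("WTP thresholds must be positive")
        return self

    def replace(self, **kwargs) -> "ModelConfig":
        """A copy with the given top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def deepcopy(self) -> "ModelConfig":
        import copy
        return copy.deepcopy(self)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def curve(m):
            if isinstance(m, ProportionalHazards):
                return {"proportional_hazards": {"hr": float(m.hr),
                                                 "base": curve(m.base)}}
            return {"family": m.family.value,
                    "params": {n: float(v) for n, v in
                               zip(m.family.param_names, m.params)}}
        return {
            "os_model": {a: curve(m) for a, m in self.os_model.items()},
            "pfs_model": {a: curve(m) for a, m in self.pfs_model.items()},
            "horizon_weeks": self.horizon_weeks,
            "cycle_weeks": self.cycle_weeks,
            "annual_discount": self.annual_discount,
            "discount_mode": self.discount_mode,
            "utilities": {"pfs": self.utilities.pfs, "pd": self.utilities.pd,
                          "ae_disutility": dict(self.utilities.ae_disutility)},
            "costs": dataclasses.asdict(self.costs),
            "dosing": dataclasses.asdict(self.dosing),
            "body": dataclasses.asdict(self.body),
            "wtp_thresholds": list(self.wtp_thresholds),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def base_case_config() -> ModelConfig:
    """The published base case (all defaults), validated."""
    return ModelConfig().validate()


def printed_chemo_models() -> dict:
    """The separately published comparator-arm parametric fits.

    Lognormal OS (mu=4.1481, sigma=1.0719 in log-weeks) and log-logistic PFS
    (shape=2.5671, rate=0.0448 per week).  These are what a refit of the
    comparator curves yields, but they are *not* the curves behind the
    published totals; see the methods note.
    """
    return {"os": ParametricSurvival("lognormal", (4.1481, 1.0719)),
            "pfs": ParametricSurvival("loglogistic", (2.5671, 0.0448))}


# -- plain-text (YAML) config files -----------------------------------------

_TOP_KEYS = {"os_model", "pfs_model", "horizon_weeks", "cycle_weeks",
             "annual_discount", "discount_mode", "utilities", "costs",
             "dosing", "body", "wtp_thresholds"}


def _parse_curve(spec: dict):
    if "proportional_hazards" in spec:
        ph = spec["proportional_hazards"]
        return ProportionalHazards(_parse_curve(ph["base"]), float(ph["hr"]))
    fam = spec["family"]
    params = spec["params"]
    if isinstance(params, dict):
        from .survival import Family
        params = [params[n] for n in Family(fam).param_names]
    return ParametricSurvival(fam, params)


def load_config(path) -> ModelConfig:
    """Load a ModelConfig from YAML; omitted fields keep base-case defaults.

    Unknown keys are rejected (typo guard).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = ModelConfig()
    for key in ("horizon_weeks", "cycle_weeks", "annual_discount",
                "discount_mode"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "wtp_thresholds" in raw:
        cfg.wtp_thresholds = tuple(float(x) for x in raw["wtp_thresholds"])
    for attr, cls in (("utilities", Utilities), ("costs", CostInputs),
                      ("dosing", DosingRules), ("body", BodyMetrics)):
        if attr in raw:
            section = raw[attr]
            base = dataclasses.asdict(getattr(cfg, attr))
            bad = set(section) - set(base)
            if bad:
                raise ConfigError(f"unknown {attr} key(s): {sorted(bad)}")
            base.update(section)
            setattr(cfg, attr, cls(**base))
    for attr in ("os_model", "pfs_model"):
        if attr in raw:
            cur = dict(getattr(cfg, attr))
            for arm, spec in raw[attr].items():
                if arm not in ARMS:
                    raise ConfigError(f"unknown arm {arm!r} in {attr}")
                cur[arm] = _parse_curve(spec)
            setattr(cfg, attr, cur)
    return cfg.validate()


def save_config(config: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
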