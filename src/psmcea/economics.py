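"""Incremental outcomes: ICER, net health benefit, net monetary benefit.

At willingness-to-pay λ (USD/QALY):

    INHB(λ) = ΔE - ΔC/λ      (QALYs)
    INMB(λ) = ΔE·λ - ΔC      (USD)

so INMB(λ) = λ·INHB(λ) identically.  All incremental quantities are carried
at full floating precision; rounding happens only when reports are written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["icer", "inhb", "inmb", "DOMINANT", "DOMINATED", "CEAResult"]

DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and less effective


def icer(delta_cost: float, delta_effect: float):
    """ΔC/ΔE, with dominance cases labelled instead of a bare negative ratio.

    Returns a float when both increments have the same sign, the string
    ``"dominant"``/``"dominated"`` otherwise, and raises for ΔE = 0.
    """
    if delta_effect == 0.0:
        raise ZeroDivisionError("ICER undefined: zero incremental effect")
    if delta_cost < 0.0 and delta_effect > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_effect < 0.0:
        return DOMINATED
    return delta_cost / delta_effect


def _check_lambda(wtp: float) -> None:
    if not (wtp > 0 and math.isfinite(wtp)):
        raise ValueError(f"WTP threshold must be positive and finite, got {wtp}")


def inhb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net health benefit, QALYs."""
    _check_lambda(wtp)
    return delta_qaly - delta_cost / wtp


def inmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit, USD."""
    _check_lambda(wtp)
    return delta_qaly * wtp - delta_cost


@dataclass
class CEAResult:
    """Per-arm totals plus incremental outcomes of a two-arm comparison."""

    arms: dict                       # arm -> {cost components, effectiveness}
    treatment: str
    comparator: str
    wtp_thresholds: tuple

    delta_cost: float = field(init=False)
    delta_qalys: float = field(init=False)
    delta_life_years: float = field(init=False)
    delta_disc_life_years: float = field(init=False)

    def __post_init__(self):
        t, c = self.arms[self.treatment], self.arms[self.comparator]
        self.delta_cost = t["cost"] - c["cost"]
        self.delta_qalys = t["qalys"] - c["qalys"]
        self.delta_life_years = t["life_years"] - c["life_years"]
        self.delta_disc_life_years = t["disc_life_years"] - c["disc_life_years"]

    @property
    def icer_per_qaly(self):
        return icer(self.delta_cost, self.delta_qalys)

    @property
    def icer_per_life_year(self):
        """ICER per (undiscounted) life-year, the published convention."""
        return icer(self.delta_cost, self.delta_life_years)

    def inhb(self, wtp: float) -> float:
        return inhb(self.delta_cost, self.delta_qalys, wtp)

    def inmb(self, wtp: float) -> float:
        return inmb(self.delta_cost, self.delta_qalys, wtp)

    def to_dict(self) -> dict:
        out = {
            "arms": {a: {k: v for k, v in d.items()} for a, d in self.arms.items()},
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "delta_life_years": self.delta_life_years,
            "delta_disc_life_years": self.delta_disc_life_years,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_life_year": self.icer_per_life_year,
        }
        for wtp in self.wtp_thresholds:
            out[f"inhb@{wtp:g}"] = self.inhb(wtp)
            out[f"inmb@{wtp:g}"] = self.inmb(wtp)
        return out
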