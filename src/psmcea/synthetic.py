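"""Synthetic trial fixtures: simulated cohorts and digitized-KM emulations.

The published analysis starts from curves digitized off trial figures,
which are not deposited anywhere; this module generates stand-ins with
known truth so the reconstruction and fitting stages can be exercised
offline.  A cohort is simulated from a chosen parametric model with
administrative censoring at a follow-up cutoff plus independent exponential
random censoring; its KM curve is then sampled on a digitization-like grid
(optionally with small survival-axis jitter mimicking plot-digitizer noise)
together with a numbers-at-risk table.

What this emulates -- and what it does not: real digitized curves carry
correlated, locally systematic digitization error and risk-table rounding;
the jitter here is independent per point.  Green roundtrip tests establish
algorithmic correctness, not robustness to every real-figure artefact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import DigitizedKM, PseudoIPD, km_estimator
from .survival import ParametricSurvival

__all__ = ["SimulationSpec", "simulate_ipd", "emit_digitized_km"]


@dataclass(frozen=True)
class SimulationSpec:
    """A simulated cohort: true model, size, censoring scheme, seed."""

    true_model: ParametricSurvival
    n: int
    admin_cutoff_weeks: float = 104.0   # 2-year follow-up
    random_censor_rate: float = 0.0     # exponential censoring hazard, per week
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.admin_cutoff_weeks <= 0:
            raise ValueError("administrative cutoff must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")


def simulate_ipd(spec: SimulationSpec) -> PseudoIPD:
    """Draw a right-censored cohort from the spec's true model."""
    rng = np.random.default_rng(spec.seed)
    t_event = spec.true_model.rvs(spec.n, rng)
    censor = np.full(spec.n, float(spec.admin_cutoff_weeks))
    if spec.random_censor_rate > 0:
        censor = np.minimum(censor,
                            rng.exponential(1.0 / spec.random_censor_rate,
                                            size=spec.n))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return PseudoIPD(time, event)


def emit_digitized_km(ipd: PseudoIPD, risk_table_times,
                      grid: np.ndarray | None = None,
                      jitter: float = 0.002,
                      seed: int = 0) -> DigitizedKM:
    """Emulate digitizing the cohort's KM plot.

    The KM step function is sampled at ``grid`` (default: weekly points up
    to the last observed time), jittered on the survival axis by uniform
    noise of half-width ``jitter`` (plot-digitizer noise scale), and paired
    with the true numbers at risk at ``risk_table_times``.
    """
    kt, ks = km_estimator(ipd)
    t_max = float(np.max(ipd.time))
    if grid is None:
        grid = np.arange(0.0, t_max + 1.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(kt, grid, side="right") - 1
    surv = np.where(idx >= 0, ks[np.clip(idx, 0, None)], 1.0)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        surv = np.clip(surv + rng.uniform(-jitter, jitter, size=len(surv)),
                       0.0, 1.0)
        surv[grid == 0.0] = 1.0
    risk_table_times = np.asarray(risk_table_times, dtype=float)
    n_at_risk = np.array([int(np.sum(ipd.time >= rt)) for rt in
                          risk_table_times])
    return DigitizedKM(grid, surv, risk_table_times, n_at_risk,
                       total_events=int(ipd.event.sum()))
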