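"""Three-state partitioned survival engine.

State occupancy at each weekly cycle boundary is read directly off the OS
and PFS curves: alive-progression-free = min(PFS, OS), alive-progressed =
max(OS - PFS, 0), dead = 1 - OS.  The min/max clamp repairs curve crossing
in the extrapolated tail (PFS nominally above OS), which is logged, never
fatal.  Life-year and QALY increments integrate occupancy between adjacent
boundaries by the trapezoid rule -- with 1-week cycles this is equivalent to
a half-cycle correction -- and are discounted with per-interval factors
evaluated at interval midpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, Arm
from .survival import WEEKS_PER_YEAR, discount_factors

__all__ = ["Trace", "run_trace", "arm_effectiveness"]

log = logging.getLogger(__name__)


@dataclass
class Trace:
    """Per-cycle state-occupancy and accumulation ledger for one arm.

    Boundary arrays (``times``, ``occ_*``) have ``n_cycles + 1`` entries;
    interval arrays (``deaths``, ``discount``, segment occupancies) have
    ``n_cycles`` entries, one per cycle.
    """

    arm: Arm
    times: np.ndarray          # cycle boundaries, weeks
    occ_pfs: np.ndarray        # boundary occupancy, progression-free
    occ_pd: np.ndarray         # boundary occupancy, progressed
    occ_dead: np.ndarray       # boundary occupancy, dead
    deaths: np.ndarray         # probability mass dying within each cycle
    discount: np.ndarray       # per-interval discount factor (midpoint)
    seg_pfs: np.ndarray        # trapezoid mean PFS occupancy per interval
    seg_pd: np.ndarray
    seg_alive: np.ndarray
    n_clamped: int             # cycles where PFS exceeded OS and was clamped

    @property
    def n_cycles(self) -> int:
        return len(self.deaths)

    def seg_weeks(self) -> np.ndarray:
        return np.diff(self.times)

    # discounted / undiscounted occupancy-time, in years
    def life_years(self, discounted: bool = True) -> float:
        w = self.discount if discounted else 1.0
        return float(np.sum(self.seg_alive * self.seg_weeks() * w) / WEEKS_PER_YEAR)

    def pfs_life_years(self, discounted: bool = True) -> float:
        w = self.discount if discounted else 1.0
        return float(np.sum(self.seg_pfs * self.seg_weeks() * w) / WEEKS_PER_YEAR)

    def pd_life_years(self, discounted: bool = True) -> float:
        w = self.discount if discounted else 1.0
        return float(np.sum(self.seg_pd * self.seg_weeks() * w) / WEEKS_PER_YEAR)

    def to_frame(self) -> pd.DataFrame:
        """Boundary-level ledger as a DataFrame (CSV-exportable)."""
        n = self.n_cycles
        pad = lambda x: np.concatenate([[np.nan], x])
        return pd.DataFrame({
            "cycle": np.arange(n + 1),
            "time_weeks": self.times,
            "occ_pfs": self.occ_pfs,
            "occ_pd": self.occ_pd,
            "occ_dead": self.occ_dead,
            "deaths_this_cycle": pad(self.deaths),
            "discount_factor": pad(self.discount),
            "ly_weeks": pad(self.seg_alive * self.seg_weeks()),
            "disc_ly_weeks": pad(self.seg_alive * self.seg_weeks() * self.discount),
        })


def run_trace(arm: Arm, config: ModelConfig) -> Trace:
    """Run the weekly-cycle occupancy trace for one arm."""
    os_curve = config.os_model[arm]
    pfs_curve = config.pfs_model[arm]
    t = np.arange(0.0, config.horizon_weeks + 0.5 * config.cycle_weeks,
                  config.cycle_weeks)
    s_os = os_curve.survival(t)
    s_pfs = pfs_curve.survival(t)

    crossed = s_pfs > s_os + 1e-15
    n_clamped = int(np.count_nonzero(crossed))
    if n_clamped:
        log.warning("%s: PFS exceeded OS at %d/%d cycle boundaries; "
                    "clamped to OS", arm, n_clamped, len(t))
    occ_pfs = np.minimum(s_pfs, s_os)
    occ_pd = np.maximum(s_os - s_pfs, 0.0)
    occ_dead = 1.0 - s_os

    mid = 0.5 * (t[:-1] + t[1:])
    df = discount_factors(mid, config.annual_discount, config.discount_mode)
    seg = lambda x: 0.5 * (x[:-1] + x[1:])
    return Trace(arm=arm, times=t, occ_pfs=occ_pfs, occ_pd=occ_pd,
                 occ_dead=occ_dead, deaths=-np.diff(s_os), discount=df,
                 seg_pfs=seg(occ_pfs), seg_pd=seg(occ_pd),
                 seg_alive=seg(s_os), n_clamped=n_clamped)


def arm_effectiveness(trace: Trace, config: ModelConfig,
                      discounted: bool = True) -> dict:
    """Life-years and QALYs for one arm.

    QALYs weight progression-free and progressed occupancy-time by their
    utilities; when ``utilities.apply_ae_disutility`` is set, the arm's
    one-off adverse-event disutility is additionally subtracted
    (undiscounted, at model entry).  Life-years are reported both
    discounted and undiscounted; the published convention reports them
    undiscounted while QALYs and costs are discounted.
    """
    u = config.utilities
    qaly = (u.pfs * trace.pfs_life_years(discounted)
            + u.pd * trace.pd_life_years(discounted))
    if u.apply_ae_disutility:
        qaly -= u.ae_disutility[trace.arm]
    return {
        "life_years": trace.life_years(discounted=False),
        "disc_life_years": trace.life_years(discounted=True),
        "pfs_life_years": trace.pfs_life_years(discounted=False),
        "disc_pfs_life_years": trace.pfs_life_years(discounted=True),
        "qalys": qaly,
    }
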