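"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Implements the standard reconstruction algorithm for published KM plots
(Guyot-style): digitized (time, survival) coordinates plus the
numbers-at-risk table are inverted into per-patient (time, event) records
such that the product-limit estimate of the reconstruction tracks the
digitized curve.  Censoring within each risk-table interval is assumed
uniform across the digitized time points; events are placed before
censorings at tied times (the usual KM convention).  The procedure is
deterministic.

Digitization jitter can make adjacent survival values increase slightly;
inputs are monotone-repaired by a running minimum before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DigitizedKM", "PseudoIPD", "reconstruct_ipd", "km_estimator",
           "ReconstructionError"]


class ReconstructionError(ValueError):
    """Raised when the risk table cannot be reconciled with the curve."""


@dataclass
class DigitizedKM:
    """Digitized KM coordinates plus the numbers-at-risk table."""

    times: np.ndarray          # weeks, increasing
    survival: np.ndarray       # probabilities, (0, 1]
    risk_times: np.ndarray     # weeks at which n-at-risk was printed
    n_at_risk: np.ndarray      # non-negative integers, non-increasing
    total_events: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("digitized times must be non-decreasing")
        if np.any((self.survival <= 0) & (self.survival != 0)) or \
                np.any(self.survival > 1):
            raise ValueError("survival values must lie in [0, 1]")
        if len(self.risk_times) != len(self.n_at_risk):
            raise ValueError("risk table lengths differ")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ReconstructionError("numbers at risk must be non-increasing")
        if self.n_at_risk[0] <= 0:
            raise ValueError("initial number at risk must be positive")

    def monotone(self) -> "DigitizedKM":
        """Copy with survival repaired to be non-increasing (running min)."""
        return DigitizedKM(self.times, np.minimum.accumulate(self.survival),
                           self.risk_times, self.n_at_risk, self.total_events)

    # CSV dialect: curve as (time_weeks, survival); risk table as
    # (time_weeks, n_at_risk)
    def to_csv(self, curve_path, risk_path) -> None:
        pd.DataFrame({"time_weeks": self.times,
                      "survival": self.survival}).to_csv(curve_path, index=False)
        pd.DataFrame({"time_weeks": self.risk_times,
                      "n_at_risk": self.n_at_risk}).to_csv(risk_path, index=False)

    @classmethod
    def from_csv(cls, curve_path, risk_path,
                 total_events: int | None = None) -> "DigitizedKM":
        curve = pd.read_csv(curve_path)
        risk = pd.read_csv(risk_path)
        return cls(curve["time_weeks"].to_numpy(),
                   curve["survival"].to_numpy(),
                   risk["time_weeks"].to_numpy(),
                   risk["n_at_risk"].to_numpy(), total_events)


@dataclass
class PseudoIPD:
    """Reconstructed patient-level records: time (weeks) and event flag."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.time) != len(self.event) or len(self.time) == 0:
            raise ValueError("need equal-length, non-empty time/event vectors")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0/1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_weeks": self.time, "event": self.event})


def km_estimator(ipd: PseudoIPD) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit (Kaplan-Meier) estimate as step-function coordinates.

    Returns ``(times, survival)`` where ``survival[k]`` is S(t) just after
    ``times[k]``; backed by lifelines' KaplanMeierFitter.
    """
    from lifelines import KaplanMeierFitter
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, event_observed=ipd.event)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def km_survival_at(ipd: PseudoIPD, times) -> np.ndarray:
    """KM estimate evaluated (right-continuously) at arbitrary times."""
    kt, ks = km_estimator(ipd)
    idx = np.searchsorted(kt, np.asarray(times, dtype=float), side="right") - 1
    return np.where(idx >= 0, ks[np.clip(idx, 0, None)], 1.0)


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Invert a digitized KM curve + risk table into pseudo-IPD.

    For each risk-table interval the number censored is found iteratively so
    the implied number at risk at the start of the next interval matches the
    published figure; censoring times are spread evenly across the
    interval, and event counts at each digitized time follow from the
    survival drops relative to the running product-limit estimate.
    """
    km = km.monotone()
    t = km.times
    s = km.survival
    if len(t) == 0:
        raise ValueError("no digitized coordinates")
    if t[0] > 0 or s[0] < 1.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])

    risk_t = km.risk_times
    n_risk = km.n_at_risk
    n_int = len(risk_t)
    # click-index bounds of each risk interval
    lower = np.searchsorted(t, risk_t, side="left")
    upper = np.empty(n_int, dtype=int)
    upper[:-1] = np.searchsorted(t, risk_t[1:], side="left") - 1
    upper[-1] = len(t) - 1

    K = len(t)
    d = np.zeros(K, dtype=int)                  # events at click k
    cen_times_all: list[np.ndarray] = []

    def walk(j: int, n_entry: int, km_entry: float, cen_times: np.ndarray):
        """Step through interval j's clicks, consuming censor times in order.

        Returns (n_exit, km_exit, events-per-click, n censors consumed).
        """
        n_cur = n_entry
        km_cur = km_entry
        dj = np.zeros(K, dtype=int)
        ptr = 0
        for k in range(lower[j], upper[j] + 1):
            if n_cur <= 0:
                break
            # events at this click from the survival drop vs the running KM
            dk = int(round(n_cur * (1.0 - s[k] / km_cur))) if km_cur > 0 else 0
            dk = min(max(dk, 0), n_cur)
            if dk > 0:
                km_cur *= 1.0 - dk / n_cur
            dj[k] = dk
            n_cur -= dk
            # censorings up to the next click (events precede ties)
            t_hi = t[k + 1] if k + 1 < K else np.inf
            while ptr < len(cen_times) and cen_times[ptr] < t_hi and n_cur > 0:
                ptr += 1
                n_cur -= 1
        return n_cur, km_cur, dj, ptr

    n_entry = int(n_risk[0])
    km_entry = 1.0
    for j in range(n_int):
        t_start = risk_t[j]
        t_end = risk_t[j + 1] if j + 1 < n_int else (t[-1] if t[-1] > t_start
                                                     else t_start + 1.0)
        if j + 1 < n_int:
            target = int(n_risk[j + 1])
            if target > n_entry:
                raise ReconstructionError(
                    f"interval {j}: n at risk rises from {n_entry} to {target}")
            s_next = s[min(lower[j + 1], K - 1)]
            expected_no_cen = n_entry * (s_next / km_entry) if km_entry > 0 else 0
            guess = min(max(int(round(expected_no_cen)) - target, 0), n_entry)
        else:
            target = None
            guess = 0

        def censor_grid(g: int) -> np.ndarray:
            if g <= 0:
                return np.zeros(0)
            return t_start + (np.arange(g) + 0.5) / g * (t_end - t_start)

        best = None
        seen: set[int] = set()
        while True:
            cen = censor_grid(guess)
            n_exit, km_exit, dj, used = walk(j, n_entry, km_entry, cen)
            if target is None:
                best = (0, guess, cen[:used], n_exit, km_exit, dj)
                break
            diff = n_exit - target
            if best is None or abs(diff) < best[0]:
                best = (abs(diff), guess, cen[:used], n_exit, km_exit, dj)
            if diff == 0 or guess in seen:
                break
            seen.add(guess)
            nxt = guess + (1 if diff > 0 else -1)
            if not 0 <= nxt <= n_entry:
                break
            guess = nxt

        _, guess, cen_used, n_exit, km_exit, dj = best
        if target is not None and n_exit != target:
            extra = n_exit - target
            if extra > 0:
                # surplus absorbed as extra end-of-interval censorings
                # (published risk tables are themselves rounded)
                cen_used = np.concatenate([cen_used,
                                           np.full(extra, t_end - 1e-9)])
                n_exit = target
            elif extra >= -max(2, round(0.05 * n_entry)):
                # small deficit from event rounding: carry the recomputed
                # risk set forward (only censoring is fitted to the table)
                pass
            else:
                raise ReconstructionError(
                    f"interval {j}: implied events exceed patients at risk "
                    f"({n_exit} left, {target} published)")
        d += dj
        cen_times_all.append(cen_used)
        n_entry, km_entry = n_exit, km_exit

    # patients still at risk after the last click: administratively censored
    tail = n_entry
    if km.total_events is not None:
        gap = km.total_events - int(d.sum())
        if 0 < gap <= tail:
            d[-1] += gap
            tail -= gap

    times, events = [], []
    for k in range(K):
        if d[k]:
            times.extend([t[k]] * d[k])
            events.extend([1] * d[k])
    for cen in cen_times_all:
        times.extend(cen.tolist())
        events.extend([0] * len(cen))
    if tail:
        times.extend([t[-1]] * tail)
        events.extend([0] * tail)
    order = np.argsort(times, kind="stable")
    return PseudoIPD(np.asarray(times)[order], np.asarray(events)[order])
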