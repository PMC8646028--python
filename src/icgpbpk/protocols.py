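"""ICG administration schedules: timed boluses, infusion segments, priming doses.

A bolus is modeled as a constant-rate input over the injection duration
(default 5 s), not an instantaneous state jump, keeping the ODE system
event-free within dosing segments. Rates of overlapping events add; the
integral of the input-rate function equals the resolved total dose exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .pbpk_core import MR_ICG, BodyParameters

__all__ = ["DoseEvent", "DosingProtocol", "standard_bolus", "infusion"]


@dataclass(frozen=True)
class DoseEvent:
    """One administration event.

    ``kind='bolus'`` uses ``amount`` [mg] (or mg/kg if ``per_kg``) delivered
    over ``duration`` minutes; ``kind='infusion'`` uses ``rate`` [mg/min] for
    ``duration`` minutes.
    """

    kind: str                     # 'bolus' | 'infusion'
    amount: float | None = None   # mg (or mg/kg), bolus only
    rate: float | None = None     # mg/min, infusion only
    start: float = 0.0            # min
    duration: float | None = None  # min; bolus defaults to ti_icg/60
    per_kg: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "infusion"):
            raise ValueError(f"unknown dose-event kind: {self.kind!r}")
        if self.kind == "bolus":
            if self.amount is None or self.amount < 0:
                raise ValueError("bolus requires a non-negative amount")
        else:
            if self.rate is None or self.rate < 0:
                raise ValueError("infusion requires a non-negative rate")
            if self.duration is None or self.duration <= 0:
                raise ValueError("infusion requires a positive duration")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.start < 0:
            raise ValueError("start must be non-negative")


@dataclass(frozen=True)
class DosingProtocol:
    """Ordered list of dose events plus resolution state."""

    events: tuple[DoseEvent, ...]
    resolved: bool = False

    def __init__(self, events: Sequence[DoseEvent], resolved: bool = False):
        object.__setattr__(self, "events", tuple(events))
        object.__setattr__(self, "resolved", resolved)

    def resolve(self, body: BodyParameters) -> "DosingProtocol":
        """Resolve per-kg doses against body weight and default bolus
        durations against the injection time; returns an absolute-mg protocol."""
        if body.BW <= 0:
            raise ValueError("body weight must be positive to resolve per-kg doses")
        out = []
        for ev in self.events:
            if ev.kind == "bolus":
                amount = ev.amount * body.BW if ev.per_kg else ev.amount
                duration = ev.duration if ev.duration is not None else body.ti_icg / 60.0
                out.append(
                    replace(ev, amount=amount, per_kg=False, duration=duration)
                )
            else:
                if ev.per_kg:
                    out.append(replace(ev, rate=ev.rate * body.BW, per_kg=False))
                else:
                    out.append(ev)
        return DosingProtocol(out, resolved=True)

    def _require_resolved(self) -> None:
        if not self.resolved:
            raise ValueError("protocol must be resolved against BodyParameters first")

    def total_dose_mg(self) -> float:
        """Total administered mass [mg]."""
        self._require_resolved()
        total = 0.0
        for ev in self.events:
            total += ev.amount if ev.kind == "bolus" else ev.rate * ev.duration
        return total

    def total_dose_mmole(self) -> float:
        return self.total_dose_mg() / MR_ICG

    def breakpoints(self) -> np.ndarray:
        """Sorted unique event start/stop times [min]; the integrator restarts
        at these discontinuities."""
        self._require_resolved()
        pts = {0.0}
        for ev in self.events:
            pts.add(ev.start)
            pts.add(ev.start + ev.duration)
        return np.array(sorted(pts))

    def input_rate_mg(self, t: float) -> float:
        """Input rate [mg/min] at time t; half-open windows [start, start+d)."""
        self._require_resolved()
        rate = 0.0
        for ev in self.events:
            if ev.start <= t < ev.start + ev.duration:
                rate += ev.amount / ev.duration if ev.kind == "bolus" else ev.rate
        return rate

    def input_rate(self, t: float) -> float:
        """Input rate [mmole/min] at time t."""
        return self.input_rate_mg(t) / MR_ICG

    def input_rate_fn(self) -> Callable[[float], float]:
        self._require_resolved()
        return self.input_rate


def standard_bolus(
    dose_per_kg: float = 0.5, start: float = 0.0, duration: float | None = None
) -> DosingProtocol:
    """The standard clinical protocol: a per-kg ICG bolus (default 0.5 mg/kg)."""
    return DosingProtocol(
        [DoseEvent(kind="bolus", amount=dose_per_kg, per_kg=True, start=start,
                   duration=duration)]
    )


def infusion(
    rate_mg_min: float,
    duration_min: float,
    start: float = 0.0,
    priming_dose_mg: float | None = None,
) -> DosingProtocol:
    """A constant infusion [mg/min], optionally preceded by a priming bolus."""
    events = []
    if priming_dose_mg is not None:
        events.append(DoseEvent(kind="bolus", amount=priming_dose_mg, start=start))
    events.append(
        DoseEvent(kind="infusion", rate=rate_mg_min, start=start, duration=duration_min)
    )
    return DosingProtocol(events)
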