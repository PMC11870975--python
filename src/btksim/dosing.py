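"""Oral dosing regimens as sequences of dose events.

A dose event carries the administration time, the amount (stored in ug so the
free-concentration formula is dimensionally exact with volumes in L), and the
fed/antacid covariate flags that modify bioavailability and the duration of
the zero-order absorption phase.  Absorption is realized as a zero-order
input of ``f1 * amount / d_zero`` into the depot compartment over
``[t + tlag, t + tlag + d_zero]``, followed by first-order transfer (ka) to
the central compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import PKParameters

__all__ = ["DoseEvent", "qd_regimen", "cycle_regimen", "infusion_window"]

MG_TO_UG = 1000.0


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: time (h), amount (ug), covariate flags."""

    time: float
    amount_ug: float
    fed: bool = True
    antacid: bool = False

    def __post_init__(self) -> None:
        if self.amount_ug < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount_ug}")

    @property
    def amount_mg(self) -> float:
        return self.amount_ug / MG_TO_UG


def qd_regimen(
    dose_mg: float,
    days: int,
    *,
    fed: bool = True,
    antacid: bool = False,
    start: float = 0.0,
) -> list[DoseEvent]:
    """Once-daily dosing of ``dose_mg`` for ``days`` consecutive days."""
    if days < 1:
        raise ValueError("days must be >= 1")
    return [
        DoseEvent(start + 24.0 * i, dose_mg * MG_TO_UG, fed=fed, antacid=antacid)
        for i in range(days)
    ]


def cycle_regimen(
    cycles: list[tuple[float, int]],
    *,
    fed: bool = True,
    antacid: bool = False,
) -> list[DoseEvent]:
    """Contiguous multi-cycle QD dosing, e.g. ``[(420, 28), (280, 28), (140, 28)]``.

    Cycle k starts the day after cycle k-1 ends; there are no gaps.
    """
    events: list[DoseEvent] = []
    start = 0.0
    for dose_mg, length_days in cycles:
        events.extend(qd_regimen(dose_mg, length_days, fed=fed, antacid=antacid, start=start))
        start += 24.0 * length_days
    return events


def infusion_window(event: DoseEvent, pk: PKParameters) -> tuple[float, float, float]:
    """Zero-order depot input implied by a dose event.

    Returns ``(t_start, t_end, rate_ug_per_h)`` where the input runs over
    ``[t + tlag, t + tlag + d_zero]`` at rate ``f1 * amount / d_zero``, with
    ``f1`` and ``d_zero`` resolved from the event's fed/antacid flags.
    """
    d = pk.d_zero(fed=event.fed, antacid=event.antacid)
    f1 = pk.f1(fed=event.fed)
    t0 = event.time + pk.tlag
    return t0, t0 + d, f1 * event.amount_ug / d
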