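"""Treatment schedules: fractionated irradiation plus Mdm2-inhibitor dosing.

A protocol is a sequence of identical cycles (the interval between
consecutive irradiations, 12/18/24/36 h).  Cells are irradiated at the
beginning of each cycle; the inhibitor is given orally at fixed offsets
after each irradiation (once per 12/18-h cycle, up to twice per 24/36-h
cycle) or as a continuous drip.  Irradiation intensity is stored in Gy per
day — the reporting unit of every critical dose — and converted to the
per-event dose (Gy/day x cycle_h/24) only when the event list is built.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

VALID_CYCLES = (12, 18, 24, 36)
#: Maximum inhibitor administrations per cycle, by cycle length.
MAX_ADMIN = {12: 1, 18: 1, 24: 2, 36: 2}

DeliveryMode = Literal["oral", "drip", "none"]


class ProtocolError(ValueError):
    """A schedule violating the protocol invariants."""


@dataclass(frozen=True)
class Protocol:
    """A validated treatment schedule.

    ``inh_dose`` is in IC50 units per administration for oral delivery and
    per day for drip delivery.  ``ir_dose_per_day`` may be None in templates
    whose critical dose is to be determined by bisection.
    """

    cycle_h: int
    n_cycles: int
    ir_dose_per_day: float | None
    inhibitor_offsets_h: tuple[float, ...] = ()
    inh_dose: float = 0.0
    mode: DeliveryMode = "none"
    name: str = ""

    def __post_init__(self):
        if self.cycle_h not in VALID_CYCLES:
            raise ProtocolError(f"cycle length must be one of {VALID_CYCLES}")
        if not (isinstance(self.n_cycles, int) and self.n_cycles > 0):
            raise ProtocolError("n_cycles must be a positive integer")
        if self.ir_dose_per_day is not None and self.ir_dose_per_day < 0:
            raise ProtocolError("irradiation dose must be non-negative")
        if self.inh_dose < 0:
            raise ProtocolError("inhibitor dose must be non-negative")
        if self.mode == "oral":
            if not self.inhibitor_offsets_h:
                raise ProtocolError("oral delivery requires at least one offset")
            if len(self.inhibitor_offsets_h) > MAX_ADMIN[self.cycle_h]:
                raise ProtocolError(
                    f"{self.cycle_h}-h cycles allow at most "
                    f"{MAX_ADMIN[self.cycle_h]} administration(s) per cycle"
                )
            for off in self.inhibitor_offsets_h:
                if not (0 <= off < self.cycle_h):
                    raise ProtocolError("offsets must lie in [0, cycle_h)")
            if len(set(self.inhibitor_offsets_h)) != len(self.inhibitor_offsets_h):
                raise ProtocolError("duplicate inhibitor offsets")
        elif self.mode in ("drip", "none"):
            if self.inhibitor_offsets_h:
                raise ProtocolError(f"{self.mode} delivery takes no offsets")
            if self.mode == "none" and self.inh_dose != 0:
                raise ProtocolError("monotherapy must have zero inhibitor dose")
        else:
            raise ProtocolError(f"unknown delivery mode '{self.mode}'")

    @property
    def duration_h(self) -> float:
        return float(self.cycle_h * self.n_cycles)

    @property
    def ir_dose_per_event(self) -> float:
        """Gy delivered at each irradiation (dose/day scaled by cycle length)."""
        if self.ir_dose_per_day is None:
            raise ProtocolError("irradiation dose not set")
        return self.ir_dose_per_day * self.cycle_h / 24.0

    @property
    def inh_dose_per_day(self) -> float:
        if self.mode == "oral":
            return self.inh_dose * len(self.inhibitor_offsets_h) * 24.0 / self.cycle_h
        if self.mode == "drip":
            return self.inh_dose
        return 0.0

    def with_ir_dose(self, dose_per_day: float) -> "Protocol":
        return replace(self, ir_dose_per_day=dose_per_day)

    def with_inh_dose(self, dose: float) -> "Protocol":
        if self.mode == "none" and dose != 0:
            raise ProtocolError("cannot dose a monotherapy protocol")
        return replace(self, inh_dose=dose)


def make_protocol(
    cycle_h: int,
    n_cycles: int,
    ir_dose_per_day: float | None,
    offsets: tuple[float, ...] = (),
    inh_dose: float = 0.0,
    mode: DeliveryMode = "none",
    name: str = "",
) -> Protocol:
    """Validate and build a protocol (thin functional constructor)."""
    return Protocol(cycle_h, n_cycles, ir_dose_per_day,
                    tuple(offsets), inh_dose, mode, name)


@dataclass(frozen=True)
class Event:
    time_h: float
    kind: Literal["irradiate", "dose_inhibitor", "infusion_on"]
    magnitude: float  # Gy (irradiate), IC50 (dose), IC50/day (infusion)


@dataclass(frozen=True)
class EventSchedule:
    events: tuple[Event, ...]

    def __post_init__(self):
        times = [e.time_h for e in self.events]
        if times != sorted(times):
            raise ProtocolError("events must be time-ordered")

    def of_kind(self, kind: str) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.kind == kind)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def event_schedule(protocol: Protocol) -> EventSchedule:
    """Expand a protocol into its deterministic, time-ordered event list."""
    events: list[Event] = []
    for k in range(protocol.n_cycles):
        t0 = k * protocol.cycle_h
        events.append(Event(float(t0), "irradiate", protocol.ir_dose_per_event))
        if protocol.mode == "oral":
            for off in protocol.inhibitor_offsets_h:
                events.append(Event(float(t0 + off), "dose_inhibitor",
                                    protocol.inh_dose))
    if protocol.mode == "drip":
        events.append(Event(0.0, "infusion_on", protocol.inh_dose))
    events.sort(key=lambda e: (e.time_h, e.kind))
    return EventSchedule(tuple(events))


# ---------------------------------------------------------------------------
# Protocol catalog: the ten 6-day oral combination templates plus drip.
# Daily inhibitor dose is 20 IC50 throughout.  Three timing variants are
# fixed as printed (24h/(6,18), 36h/(6,30), 36h/(0,24)); the offsets of the
# remaining seven are reconstructions (evenly spaced placements), exposed as
# configuration precisely because only a figure records them graphically.
# ---------------------------------------------------------------------------

#: (cycle_h, offsets) per catalog name; doses filled in by _catalog_dose.
_CATALOG_ORAL: dict[str, tuple[int, tuple[float, ...]]] = {
    "12h_0": (12, (0.0,)),
    "12h_6": (12, (6.0,)),
    "18h_0": (18, (0.0,)),
    "18h_9": (18, (9.0,)),
    "24h_0_12": (24, (0.0, 12.0)),
    "24h_6_18": (24, (6.0, 18.0)),      # fixed as printed
    "24h_0_6": (24, (0.0, 6.0)),
    "36h_0_24": (36, (0.0, 24.0)),      # fixed as printed
    "36h_6_30": (36, (6.0, 30.0)),      # fixed as printed
    "36h_0_18": (36, (0.0, 18.0)),
}

#: Catalog names whose offsets are printed in the text (not reconstructed).
PRINTED_OFFSETS = ("24h_6_18", "36h_0_24", "36h_6_30")

DAILY_INH_DOSE = 20.0  # IC50 per day in the catalog setting


def _catalog_dose(cycle_h: int, n_offsets: int) -> float:
    """Per-administration dose giving exactly 20 IC50 per day."""
    return DAILY_INH_DOSE * cycle_h / 24.0 / n_offsets


def _cycles_for_days(cycle_h: int, days: float) -> int:
    n = days * 24.0 / cycle_h
    if abs(n - round(n)) > 1e-9:
        raise ProtocolError(f"{days}-day horizon is not a whole number of "
                            f"{cycle_h}-h cycles")
    return int(round(n))


def protocol_catalog(days: float = 6.0, inh_dose: float | None = None
                     ) -> dict[str, Protocol]:
    """The named protocol templates (10 oral + 1 drip), without an
    irradiation dose set.

    ``inh_dose`` overrides the per-administration dose (oral) for every
    template; by default each template delivers 20 IC50 per day.
    """
    catalog: dict[str, Protocol] = {}
    for name, (cycle_h, offsets) in _CATALOG_ORAL.items():
        dose = _catalog_dose(cycle_h, len(offsets)) if inh_dose is None else inh_dose
        catalog[name] = Protocol(
            cycle_h, _cycles_for_days(cycle_h, days), None,
            offsets, dose, "oral", name=name,
        )
    catalog["drip"] = Protocol(
        24, _cycles_for_days(24, days), None, (),
        DAILY_INH_DOSE if inh_dose is None else inh_dose, "drip", name="drip",
    )
    return catalog


def get_protocol(name: str, days: float = 6.0, inh_dose: float | None = None
                 ) -> Protocol:
    """Look a template up by name; raises a lookup error for unknown names."""
    catalog = protocol_catalog(days=days, inh_dose=inh_dose)
    try:
        return catalog[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol '{name}'; known: {', '.join(catalog)}"
        ) from None
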