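"""One-compartment pharmacokinetics of the Mdm2 inhibitor.

Oral administration fills a gut depot that liberates drug to blood at rate
d_r1 (nominally 1/h) while blood drug is eliminated at d_r2 (0.25/h); a
single dose therefore follows the two-exponential Bateman curve, peaking
about two hours after intake.  Drip delivery is a constant zero-order
infusion with the same first-order elimination, approaching its plateau
with relaxation time 1/d_r2 = 4 h.  Doses are expressed in IC50 units, in
which the equilibrium inhibitor-bound Mdm2 fraction is
F = INH_B / (1 + INH_B).

During simulations the depot/blood states are integrated jointly with the
reaction network; the closed forms here serve the protocol-design surface
and as the independent oracle for that integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "DosingEvent",
    "PKState",
    "blood_level",
    "peak_time",
    "bound_fraction",
    "relaxation_time_h",
    "time_to_within",
]


@dataclass(frozen=True)
class PKParameters:
    """Liberation (d_r1) and elimination (d_r2) rate coefficients, per hour."""

    d_r1: float = 1.0
    d_r2: float = 0.25
    mode: Literal["oral", "drip"] = "oral"

    def __post_init__(self):
        if self.mode == "oral" and not (self.d_r1 > self.d_r2 > 0):
            raise ValueError("oral PK requires d_r1 > d_r2 > 0 (a peak must exist)")
        if self.mode == "drip" and self.d_r2 <= 0:
            raise ValueError("elimination rate must be positive")


@dataclass(frozen=True)
class DosingEvent:
    """A single administration: oral bolus (IC50 units) or, for drip, the
    daily dose whose infusion starts at ``time_h``."""

    time_h: float
    dose: float

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.time_h < 0:
            raise ValueError("dosing time must be non-negative")


@dataclass(frozen=True)
class PKState:
    depot: float
    inh_b: float

    @property
    def bound_fraction(self) -> float:
        return bound_fraction(self.inh_b)


def _single_oral(dose: float, d_r1: float, d_r2: float, dt: np.ndarray) -> np.ndarray:
    """Bateman response to one oral dose, evaluated at times dt >= 0."""
    out = np.zeros_like(dt, dtype=float)
    m = dt >= 0
    out[m] = dose * d_r1 / (d_r1 - d_r2) * (
        np.exp(-d_r2 * dt[m]) - np.exp(-d_r1 * dt[m])
    )
    return out


def blood_level(
    events: Iterable[DosingEvent],
    params: PKParameters,
    t: float | Sequence[float] | np.ndarray,
) -> float | np.ndarray:
    """Blood inhibitor level INH_B(t), IC50 units.

    Oral: superposition of per-dose Bateman responses (the PK is linear in
    dose).  Drip: first-order approach to the plateau (daily dose / 24) / d_r2
    from each infusion start.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    level = np.zeros_like(t_arr)
    for ev in events:
        if ev.dose < 0:
            raise ValueError("negative dose")
        dt = t_arr - ev.time_h
        if params.mode == "oral":
            level += _single_oral(ev.dose, params.d_r1, params.d_r2, dt)
        else:
            rate = ev.dose / 24.0  # IC50 per hour
            m = dt >= 0
            level[m] += rate / params.d_r2 * (1.0 - np.exp(-params.d_r2 * dt[m]))
    return level if np.ndim(t) else float(level[0])


def peak_time(params: PKParameters) -> float:
    """Time to the blood-level maximum after a single oral dose:
    ln(d_r1/d_r2) / (d_r1 - d_r2) hours."""
    if params.mode != "oral":
        raise ValueError("peak time is defined for oral delivery only")
    return math.log(params.d_r1 / params.d_r2) / (params.d_r1 - params.d_r2)


def bound_fraction(inh_b: float | np.ndarray) -> float | np.ndarray:
    """Equilibrium fraction of inhibitor-bound Mdm2, F = INH_B/(1+INH_B)."""
    x = np.asarray(inh_b, dtype=float)
    if np.any(x < 0):
        raise ValueError("INH_B must be non-negative")
    f = x / (1.0 + x)
    return f if np.ndim(inh_b) else float(f)


def relaxation_time_h(params: PKParameters) -> float:
    """Elimination relaxation time 1/d_r2 (hours); the timescale on which a
    drip approaches its plateau."""
    return 1.0 / params.d_r2


def time_to_within(params: PKParameters, fraction: float = 0.05) -> float:
    """Hours for a drip to come within ``fraction`` of its plateau."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return -math.log(fraction) / params.d_r2
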