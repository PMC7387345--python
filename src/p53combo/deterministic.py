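"""Deterministic (ODE) engine: protocol simulation, apoptosis detection,
critical-dose bisection and oscillation analysis.

Integration uses fixed-step RK4 (default 30 s; the model's fastest rate
constants are ~1e-2/s so the step is well inside the stability region) and
restarts at every protocol event: irradiation adds DNA lesions impulsively,
oral dosing adds to the gut depot, drip delivery switches on a zero-order
infusion.  Apoptosis commitment is the first crossing of the caspase
threshold and is treated as absorbing: samples after commitment are flagged
but the state keeps evolving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from . import _kernels
from .network import (
    CAS_COMMIT,
    CompiledNetwork,
    ReactionNetwork,
    SECONDS_PER_HOUR,
)
from .protocols import Event, EventSchedule, Protocol, event_schedule

__all__ = [
    "Trajectory",
    "IrCritResult",
    "simulate",
    "apoptosis_time",
    "find_ir_crit",
    "oscillation_period",
    "NonMonotoneDoseResponse",
]

_EV_CODES = {"irradiate": _kernels.EV_IRRADIATE,
             "dose_inhibitor": _kernels.EV_DOSE,
             "infusion_on": _kernels.EV_INFUSION}


class IntegrationError(RuntimeError):
    """Integration failure carrying the last good state."""

    def __init__(self, message, t_h=None, state=None):
        super().__init__(message)
        self.t_h = t_h
        self.state = state


class NonMonotoneDoseResponse(UserWarning):
    """The apoptotic/non-apoptotic predicate changed sign more than once
    within the bisection bracket."""


@dataclass
class Trajectory:
    """A sampled state path with event markers and commitment annotation."""

    times_h: np.ndarray                 # (n_t,)
    states: np.ndarray                  # (n_t, n_species)
    species_names: tuple[str, ...]
    events: EventSchedule
    apoptosis_time_h: float | None

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]

    @property
    def committed(self) -> np.ndarray:
        """Per-sample flag: sample lies at/after apoptosis commitment (the
        'faded line' convention)."""
        if self.apoptosis_time_h is None:
            return np.zeros_like(self.times_h, dtype=bool)
        return self.times_h >= self.apoptosis_time_h - 1e-9

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.species_names))
        df.insert(0, "time_h", self.times_h)
        df["apoptosis"] = self.committed.astype(int)
        return df


@dataclass(frozen=True)
class IrCritResult:
    """Critical irradiation dose (Gy/day) from bisection."""

    ir_crit: float                       # inf when even the bracket top fails
    bracket: tuple[float, float]
    tolerance: float
    protocol: str
    phenotype: str
    crossings: tuple[float, ...] = ()    # extra sign changes, if any

    @property
    def resistant(self) -> bool:
        return not np.isfinite(self.ir_crit)


def _compiled(network: ReactionNetwork | CompiledNetwork) -> CompiledNetwork:
    return network.compile() if isinstance(network, ReactionNetwork) else network


def _sparse_stoich(c: CompiledNetwork):
    ptr = [0]
    sp: list[int] = []
    dl: list[float] = []
    for j in range(c.n_reactions):
        nz = np.nonzero(c.stoich[j])[0]
        sp.extend(nz.tolist())
        dl.extend(c.stoich[j, nz].astype(float).tolist())
        ptr.append(len(sp))
    return (np.asarray(ptr, dtype=np.int64), np.asarray(sp, dtype=np.int64),
            np.asarray(dl, dtype=np.float64))


def _event_arrays(schedule: EventSchedule):
    t = np.array([e.time_h * SECONDS_PER_HOUR for e in schedule], dtype=float)
    kind = np.array([_EV_CODES[e.kind] for e in schedule], dtype=np.int64)
    mag = np.array([e.magnitude for e in schedule], dtype=float)
    return t, kind, mag


def simulate(
    network: ReactionNetwork,
    protocol: Protocol,
    horizon_h: float | None = None,
    *,
    dt_s: float = 30.0,
    sample_every_h: float = 0.1,
    y0: np.ndarray | None = None,
    equilibrate_h: float = 200.0,
) -> Trajectory:
    """Integrate the ODE approximation of the network under a protocol.

    The phenotype must already be applied to ``network``.  The system is
    first relaxed to its resting state for ``equilibrate_h`` hours without
    treatment (skipped when ``y0`` is given), then the protocol events are
    applied with integration restarting at each discontinuity.
    """
    if horizon_h is None:
        horizon_h = protocol.duration_h
    if horizon_h < protocol.duration_h - 1e-9:
        raise ValueError("horizon shorter than the protocol duration")
    c = _compiled(network)
    st_ptr, st_sp, st_dl = _sparse_stoich(c)
    args = (c.k.copy(), c.ma_idx, c.reg_idx, c.reg_kind, c.reg_K, c.reg_n,
            st_ptr, st_sp, st_dl)

    if y0 is None:
        y = resting_state(network, equilibrate_h=equilibrate_h, dt_s=dt_s)
    else:
        y = np.asarray(y0, dtype=float).copy()

    schedule = event_schedule(protocol)
    k = args[0]
    dsb = c.index["DSB"]
    depot = c.index["INH_depot"]
    dsb_per_gy = network.params["dsb_per_gy"]
    inf_rxn = next(
        j for j, r in enumerate(network.reactions) if r.name == "pk_infusion"
    )

    n_t = int(np.floor(horizon_h / sample_every_h + 1e-9)) + 1
    sample_t = np.arange(n_t) * sample_every_h * SECONDS_PER_HOUR
    out = np.empty((n_t, c.n_species))

    # segment boundaries: event times + horizon
    ev_t, ev_kind, ev_mag = _event_arrays(schedule)
    bounds = np.unique(np.concatenate([[0.0], ev_t,
                                       [horizon_h * SECONDS_PER_HOUR]]))
    bounds = bounds[bounds <= horizon_h * SECONDS_PER_HOUR + 1e-9]
    row = 0
    t_prev = 0.0
    for b in range(len(bounds)):
        t_seg = bounds[b]
        # integrate up to the boundary, sampling strictly before it
        j = int(np.searchsorted(sample_t, t_seg - 1e-9))
        if t_seg > t_prev:
            row += _kernels.ode_segment(y, t_prev, t_seg, dt_s, *args,
                                        sample_t[row:j], out, row)
        # apply events at this boundary before any sample at the same time
        for i in np.nonzero(np.abs(ev_t - t_seg) <= 1e-9)[0]:
            if ev_kind[i] == _kernels.EV_IRRADIATE:
                y[dsb] += ev_mag[i] * dsb_per_gy
            elif ev_kind[i] == _kernels.EV_DOSE:
                y[depot] += ev_mag[i]
            else:
                k[inf_rxn] = ev_mag[i] / 86400.0
        j2 = int(np.searchsorted(sample_t, t_seg + 1e-9))
        while row < j2:
            out[row] = y
            row += 1
        t_prev = t_seg
    if row != n_t:
        raise IntegrationError(f"sampled {row} of {n_t} points",
                               t_h=t_prev / SECONDS_PER_HOUR, state=y)
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite state encountered",
                               t_h=horizon_h, state=y)

    times_h = sample_t / SECONDS_PER_HOUR
    traj = Trajectory(times_h, out, c.species_names, schedule, None)
    traj.apoptosis_time_h = _commit_time(traj)
    return traj


def resting_state(network: ReactionNetwork, equilibrate_h: float = 200.0,
                  dt_s: float = 30.0) -> np.ndarray:
    """Pre-treatment fixed point: relax from the initial amounts with no
    irradiation and no inhibitor."""
    cache = network.__dict__.setdefault("_resting_cache", {})
    key = (equilibrate_h, dt_s)
    cached = cache.get(key)
    if cached is not None:
        return cached.copy()
    c = _compiled(network)
    st_ptr, st_sp, st_dl = _sparse_stoich(c)
    y = c.y0.copy()
    sample = np.empty((0,))
    _kernels.ode_segment(y, 0.0, equilibrate_h * SECONDS_PER_HOUR, dt_s,
                         c.k.copy(), c.ma_idx, c.reg_idx, c.reg_kind, c.reg_K,
                         c.reg_n, st_ptr, st_sp, st_dl, sample,
                         np.empty((0, c.n_species)), 0)
    cache[key] = y.copy()
    return y


def _commit_time(traj: Trajectory) -> float | None:
    cas = traj.species("Caspase")
    above = cas >= CAS_COMMIT
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(traj.times_h[0])
    # linear interpolation to the crossing
    t0, t1 = traj.times_h[i - 1], traj.times_h[i]
    c0, c1 = cas[i - 1], cas[i]
    frac = (CAS_COMMIT - c0) / (c1 - c0) if c1 != c0 else 1.0
    return float(t0 + frac * (t1 - t0))


def apoptosis_time(trajectory: Trajectory) -> float | None:
    """First crossing of the caspase commitment threshold (hours), or None."""
    return trajectory.apoptosis_time_h


def find_ir_crit(
    network: ReactionNetwork,
    protocol_template: Protocol,
    *,
    horizon_h: float | None = None,
    bracket: tuple[float, float] = (0.0, 10.0),
    tolerance: float = 0.01,
    prescan: int = 8,
    dt_s: float = 30.0,
    warm_bracket: tuple[float, float] | None = None,
) -> IrCritResult:
    """Bisect the minimal irradiation dose per day inducing apoptosis.

    The bracket is first scanned at ``prescan`` coarse points to detect a
    non-monotone dose response, which triggers a warning rather than a
    silent bisection.  Radiation-resistant cells (no apoptosis even at the
    bracket top) yield ``ir_crit = inf``.  ``warm_bracket`` skips the
    prescan when a tighter bracket is already known (e.g. the neighbouring
    point of a dose grid).
    """
    rest = resting_state(network, dt_s=dt_s)

    def apoptotic(dose: float) -> bool:
        traj = simulate(network, protocol_template.with_ir_dose(dose),
                        horizon_h, dt_s=dt_s, sample_every_h=0.25, y0=rest)
        return traj.apoptosis_time_h is not None

    lo, hi = bracket
    crossings: list[float] = []
    if warm_bracket is not None and warm_bracket[0] < warm_bracket[1]:
        wlo, whi = warm_bracket
        wlo, whi = max(lo, wlo), min(hi, whi)
        if not apoptotic(whi) or (wlo > lo and apoptotic(wlo)):
            warm_bracket = None  # stale bracket; fall back to the prescan
        else:
            lo, hi = wlo, whi
    if warm_bracket is None:
        doses = np.linspace(lo, hi, prescan + 1)
        flags = [apoptotic(d) for d in doses]
        first = next((i for i, f in enumerate(flags) if f), None)
        if first is None:
            return IrCritResult(np.inf, (lo, hi), tolerance,
                                protocol_template.name, "")
        # sign changes after the first apoptotic point indicate non-monotonicity
        for i in range(first + 1, len(flags)):
            if flags[i] != flags[i - 1]:
                crossings.append(float(doses[i]))
        if crossings:
            warnings.warn(
                f"non-monotone dose response; extra crossings near {crossings}",
                NonMonotoneDoseResponse,
            )
        if first == 0:
            return IrCritResult(float(doses[0]), (lo, float(doses[0])),
                                tolerance, protocol_template.name, "",
                                tuple(crossings))
        lo, hi = float(doses[first - 1]), float(doses[first])

    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if apoptotic(mid):
            hi = mid
        else:
            lo = mid
    return IrCritResult(hi, (lo, hi), tolerance, protocol_template.name, "",
                        tuple(crossings))


def oscillation_period(
    trajectory: Trajectory,
    species: str,
    window_h: tuple[float, float] | None = None,
    min_peaks: int = 3,
) -> float | None:
    """Median inter-peak interval (hours) of a species inside a window;
    None for flat signals or fewer than ``min_peaks`` maxima."""
    t = trajectory.times_h
    x = trajectory.species(species)
    if window_h is not None:
        m = (t >= window_h[0]) & (t <= window_h[1])
        t, x = t[m], x[m]
    if len(x) < 3:
        return None
    span = float(x.max() - x.min())
    if span <= 0 or span < 1e-6 * max(1.0, abs(float(x.max()))):
        return None
    peaks, _ = find_peaks(x, prominence=0.1 * span)
    if len(peaks) < min_peaks:
        return None
    return float(np.median(np.diff(t[peaks])))
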