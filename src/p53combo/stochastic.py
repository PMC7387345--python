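"""Stochastic (Gillespie) engine with the high-copy scaling acceleration.

The model is simulated as a time-continuous Markov process.  Two execution
modes share one kernel:

* ``exact`` — every molecular species is discrete and every reaction fires
  as an individual Gillespie event (the reference path).  Only the
  extracellular drug pools (gut depot, blood level) evolve deterministically:
  they describe macroscopic amounts with no intrinsic noise.
* ``scaled`` — species flagged ``scalable`` in the network definition
  (abundant mRNA/protein pools) are advanced deterministically between
  exact-SSA events of the low-copy channels (promoter states, DNA lesions),
  with propensities refreshed at least every ``cap_s`` seconds.  This is the
  acceleration used for all production runs; a distributional fixture test
  pins it against the exact path.

Irradiation draws a Poisson number of double-strand breaks with mean
dose x dsb_per_gy (intrinsic noise of lesion induction); a run terminates
as soon as the caspase commitment threshold is crossed (the apoptotic state
is absorbing).  Identical (network, protocol, seed) triples give identical
runs; per-cell streams are derived from a root seed by a counter-based hash
so that growing ``n_cells`` never reshuffles earlier cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as _beta

from . import _kernels
from .deterministic import _compiled, _event_arrays, _sparse_stoich, resting_state
from .network import CAS_COMMIT, ReactionNetwork, SECONDS_PER_HOUR
from .protocols import Protocol, event_schedule

__all__ = ["SsaRun", "ApoptoticFraction", "ssa_run", "apoptotic_fraction",
           "spawn_seed"]


_U64 = (1 << 64) - 1


def spawn_seed(seed0: int, index: int) -> int:
    """Counter-based per-cell seed (splitmix64 finaliser, 31-bit output)."""
    z = (seed0 * 0x9E3779B97F4A7C15 + index * 0xBF58476D1CE4E5B9) & _U64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _U64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _U64
    z ^= z >> 31
    return int(z & 0x7FFFFFFF)


@dataclass
class SsaRun:
    """One seeded stochastic run."""

    seed: int
    committed: bool
    commit_time_h: float | None
    times_h: np.ndarray | None = None
    states: np.ndarray | None = None
    species_names: tuple[str, ...] = ()

    def species(self, name: str) -> np.ndarray:
        if self.states is None:
            raise ValueError("run was executed without trajectory sampling")
        return self.states[:, self.species_names.index(name)]


@dataclass(frozen=True)
class ApoptoticFraction:
    """Apoptotic-cell fraction with an exact (Clopper-Pearson) 95% CI."""

    n_cells: int
    n_apoptotic: int
    commit_times_h: tuple[float, ...]
    horizon_h: float

    @property
    def fraction(self) -> float:
        return self.n_apoptotic / self.n_cells

    @property
    def ci95(self) -> tuple[float, float]:
        k, n = self.n_apoptotic, self.n_cells
        lo = 0.0 if k == 0 else float(_beta.ppf(0.025, k, n - k + 1))
        hi = 1.0 if k == n else float(_beta.ppf(0.975, k + 1, n - k))
        return lo, hi

    def fraction_at(self, t_h: float) -> float:
        """Fraction committed within the first ``t_h`` hours (non-decreasing
        in the horizon by construction)."""
        return sum(ct <= t_h for ct in self.commit_times_h) / self.n_cells

    def per_day_counts(self) -> list[int]:
        n_days = int(np.ceil(self.horizon_h / 24.0))
        counts = [0] * n_days
        for ct in self.commit_times_h:
            counts[min(int(ct // 24.0), n_days - 1)] += 1
        return counts


def _prepare(network: ReactionNetwork, protocol: Protocol, mode: str):
    c = _compiled(network)
    st_ptr, st_sp, st_dl = _sparse_stoich(c)
    roles = {s.name: s.role for s in network.species}
    drug = np.array([roles[n] == "drug-pool" for n in c.species_names])
    if mode == "exact":
        discrete_sp = ~drug
    elif mode == "scaled":
        discrete_sp = ~(c.scalable | drug)
    else:
        raise ValueError(f"unknown SSA mode '{mode}'")
    touches_discrete = (c.stoich[:, discrete_sp] != 0).any(axis=1)
    disc_rxn = np.nonzero(touches_discrete)[0].astype(np.int64)
    fast_rxn = np.nonzero(~touches_discrete)[0].astype(np.int64)
    ev_t, ev_kind, ev_mag = _event_arrays(event_schedule(protocol))
    inf_rxn = next(j for j, r in enumerate(network.reactions)
                   if r.name == "pk_infusion")
    return c, (st_ptr, st_sp, st_dl), discrete_sp, disc_rxn, fast_rxn, \
        (ev_t, ev_kind, ev_mag), inf_rxn


def _initial_state(network: ReactionNetwork, c, discrete_sp) -> np.ndarray:
    y = resting_state(network)
    y0 = y.copy()
    y0[discrete_sp] = np.round(y[discrete_sp])
    return y0


def ssa_run(
    network: ReactionNetwork,
    protocol: Protocol,
    horizon_h: float | None = None,
    seed: int = 0,
    *,
    mode: str = "scaled",
    sample_every_h: float | None = None,
    dt_fast_s: float = 5.0,
    cap_s: float = 60.0,
    stop_on_commit: bool = True,
    y0: np.ndarray | None = None,
) -> SsaRun:
    """One seeded hybrid/exact Gillespie run under a protocol.

    The phenotype must already be applied to ``network``.  With
    ``sample_every_h`` set, a thinned trajectory is recorded (events at a
    sample time are applied before the sample).
    """
    if horizon_h is None:
        horizon_h = protocol.duration_h
    c, sparse, discrete_sp, disc_rxn, fast_rxn, evs, inf_rxn = _prepare(
        network, protocol, mode)
    if y0 is None:
        y0 = _initial_state(network, c, discrete_sp)
    t_end = horizon_h * SECONDS_PER_HOUR
    if sample_every_h is not None:
        n_t = int(np.floor(horizon_h / sample_every_h + 1e-9)) + 1
        sample_t = np.arange(n_t) * sample_every_h * SECONDS_PER_HOUR
        out = np.empty((n_t, c.n_species))
    else:
        sample_t = np.empty(0)
        out = np.empty((0, c.n_species))

    committed, commit_s, written, _ = _kernels.hybrid_ssa_run(
        y0, c.k, c.ma_idx, c.reg_idx, c.reg_kind, c.reg_K, c.reg_n,
        *sparse,
        discrete_sp, disc_rxn, fast_rxn,
        *evs,
        c.index["DSB"], c.index["INH_depot"], inf_rxn,
        network.params["dsb_per_gy"], True,
        t_end, dt_fast_s, cap_s,
        c.index["Caspase"], CAS_COMMIT, stop_on_commit,
        seed,
        sample_t, out,
    )
    run = SsaRun(
        seed=seed,
        committed=bool(committed),
        commit_time_h=(commit_s / SECONDS_PER_HOUR) if committed else None,
        species_names=c.species_names,
    )
    if sample_every_h is not None:
        run.times_h = sample_t[:written] / SECONDS_PER_HOUR
        run.states = out[:written]
    return run


def apoptotic_fraction(
    network: ReactionNetwork,
    protocol: Protocol,
    n_cells: int,
    horizon_h: float | None = None,
    seed0: int = 0,
    *,
    mode: str = "scaled",
    dt_fast_s: float = 5.0,
    cap_s: float = 60.0,
) -> ApoptoticFraction:
    """Fraction of cells committing to apoptosis within the horizon.

    Runs ``n_cells`` independent seeded simulations (per-cell streams spawned
    from ``seed0`` by a counter-based hash) and reports the committed
    fraction with an exact binomial 95% CI.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if horizon_h is None:
        horizon_h = protocol.duration_h
    # shared preparation: compile once, reuse the initial state
    c, sparse, discrete_sp, disc_rxn, fast_rxn, evs, inf_rxn = _prepare(
        network, protocol, mode)
    y_init = _initial_state(network, c, discrete_sp)
    t_end = horizon_h * SECONDS_PER_HOUR
    empty_t = np.empty(0)
    empty_out = np.empty((0, c.n_species))
    commit_times = []
    for i in range(n_cells):
        seed = spawn_seed(seed0, i)
        committed, commit_s, _, _ = _kernels.hybrid_ssa_run(
            y_init.copy(), c.k, c.ma_idx, c.reg_idx, c.reg_kind, c.reg_K,
            c.reg_n, *sparse,
            discrete_sp, disc_rxn, fast_rxn, *evs,
            c.index["DSB"], c.index["INH_depot"], inf_rxn,
            network.params["dsb_per_gy"], True,
            t_end, dt_fast_s, cap_s,
            c.index["Caspase"], CAS_COMMIT, True,
            seed, empty_t, empty_out,
        )
        if committed:
            commit_times.append(commit_s / SECONDS_PER_HOUR)
    return ApoptoticFraction(
        n_cells=n_cells,
        n_apoptotic=len(commit_times),
        commit_times_h=tuple(sorted(commit_times)),
        horizon_h=horizon_h,
    )
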