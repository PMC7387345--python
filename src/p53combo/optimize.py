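"""Two-step protocol selection and optimization.

Step one (deterministic): for each candidate protocol, compute the
critical-irradiation-dose ratio R(d) = IR_crit(normal) / IR_crit(cancer) as
a function of inhibitor dose d, where normal cells receive d/specificity
(inhibitor doses are always referenced to cancer cells).  The maximum of
R suggests the protocol's optimal inhibitor dose.

Step two (stochastic): at a chosen inhibitor dose, scan irradiation doses
over [0.8, 1.5] x IR_crit(cancer) and estimate apoptotic fractions for
cancer cells (full dose) and for normal tissue neighbouring the tumor
(one third of the irradiation dose — intersecting beams — and a
specificity-reduced inhibitor exposure).  A protocol is *plausible* at an
irradiation dose when the cancer apoptotic fraction is at least 95% and
the normal fraction at most 10%; IR_opt is the lowest plausible dose in
the scan.  Finally the inhibitor dose is minimized subject to plausibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .deterministic import IrCritResult, find_ir_crit
from .network import CellPhenotype, ReactionNetwork
from .protocols import Protocol
from .stochastic import ApoptoticFraction, apoptotic_fraction, spawn_seed, ssa_run

__all__ = [
    "RatioCurve",
    "IrScanPoint",
    "PlausibilityVerdict",
    "OptimizationResult",
    "ratio_curve",
    "optimal_inhibitor_dose",
    "verify_protocol",
    "minimize_inhibitor_dose",
    "NoOptimumError",
    "PLAUSIBLE_CANCER_MIN",
    "PLAUSIBLE_NORMAL_MAX",
    "IRRADIATION_RATIO",
]

#: Plausibility thresholds and the tumor-to-neighbour irradiation ratio.
PLAUSIBLE_CANCER_MIN = 0.95
PLAUSIBLE_NORMAL_MAX = 0.10
IRRADIATION_RATIO = 3.0

#: Default inhibitor-dose grid, IC50 units (covers every dose studied).
DEFAULT_DOSE_GRID = tuple(np.arange(0.0, 20.5, 0.5))


class NoOptimumError(ValueError):
    """Ratio curve is identically zero: no inhibitor dose helps."""


class MultimodalRatioCurve(UserWarning):
    """The IR_crit ratio curve has more than one local maximum."""


def _verification_cycles(cycle_h: int) -> int:
    """7 cycles for 24/36-h protocols; matched ~168-h duration otherwise."""
    if cycle_h in (24, 36):
        return 7
    return int(round(7 * 24.0 / cycle_h))


@dataclass(frozen=True)
class RatioCurve:
    """IR_crit ratio (normal over cancer) versus inhibitor dose."""

    protocol: str
    phenotype: str
    specificity: float
    doses: tuple[float, ...]
    ratios: tuple[float, ...]
    ir_crit_cancer: tuple[float, ...]
    ir_crit_normal: tuple[float, ...]
    failed_points: tuple[int, ...] = ()

    def max_ratio(self) -> float:
        return max(self.ratios)


@dataclass(frozen=True)
class IrScanPoint:
    ir_cancer: float
    cancer_fraction: float
    cancer_ci: tuple[float, float]
    normal_fraction: float
    normal_ci: tuple[float, float]

    @property
    def ir_normal(self) -> float:
        return self.ir_cancer / IRRADIATION_RATIO

    @property
    def plausible(self) -> bool:
        return (self.cancer_fraction >= PLAUSIBLE_CANCER_MIN
                and self.normal_fraction <= PLAUSIBLE_NORMAL_MAX)


@dataclass(frozen=True)
class PlausibilityVerdict:
    """Stochastic verification of one (protocol, phenotype, dose) setting."""

    protocol: str
    phenotype: str
    specificity: float
    inh_dose: float
    ir_crit_cancer: float
    scan: tuple[IrScanPoint, ...]
    n_cells: int
    seed0: int
    #: exposure bookkeeping: normal cells received (IR/3, dose/specificity)
    normal_ir_factor: float = 1.0 / IRRADIATION_RATIO
    normal_dose_factor: float = field(default=0.0)

    @property
    def plausible(self) -> bool:
        return any(p.plausible for p in self.scan)

    @property
    def ir_opt(self) -> float | None:
        for p in self.scan:
            if p.plausible:
                return p.ir_cancer
        return None


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of inhibitor-dose minimization for one protocol."""

    protocol: str
    phenotype: str
    specificity: float
    start_dose: float
    minimal_dose: float
    verdict: PlausibilityVerdict
    tried: tuple[tuple[float, bool], ...]


def ratio_curve(
    network: ReactionNetwork,
    protocol: Protocol,
    cancer_phenotype: CellPhenotype,
    specificity: float,
    dose_grid=DEFAULT_DOSE_GRID,
    *,
    bracket: tuple[float, float] = (0.0, 10.0),
    tolerance: float = 0.02,
    horizon_h: float | None = None,
) -> RatioCurve:
    """IR_crit ratio of normal to cancer cells as a function of inhibitor
    dose (doses referenced to cancer cells; normal cells get dose/specificity).

    ``network`` is the nominal (phenotype-free) network.  Engine failures at
    individual grid points are flagged, not fatal.  R = 0 wherever the
    cancer IR_crit is unbounded (radiation-resistant at that dose).
    """
    doses = tuple(float(d) for d in dose_grid)
    if any(b < a for a, b in zip(doses, doses[1:])):
        raise ValueError("dose grid must be ascending")
    if doses[0] != 0.0:
        raise ValueError("dose grid must start at 0")
    normal = network.apply_phenotype(
        CellPhenotype("normal", uptake_specificity=specificity))
    cancer = network.apply_phenotype(cancer_phenotype)

    ratios, irc_c, irc_n, failed = [], [], [], []
    warm_c = warm_n = None
    for i, d in enumerate(doses):
        try:
            rc = find_ir_crit(cancer, protocol.with_inh_dose(d) if d or protocol.mode != "none" else protocol,
                              bracket=bracket, tolerance=tolerance,
                              horizon_h=horizon_h, warm_bracket=warm_c)
            # normal cells: specificity is already folded into k_a;
            # the administered dose is the same per-protocol dose
            rn = find_ir_crit(normal, protocol.with_inh_dose(d) if d or protocol.mode != "none" else protocol,
                              bracket=bracket, tolerance=tolerance,
                              horizon_h=horizon_h, warm_bracket=warm_n)
        except Exception as exc:  # pragma: no cover - engine failure path
            warnings.warn(f"IR_crit failed at dose {d}: {exc}")
            failed.append(i)
            ratios.append(np.nan)
            irc_c.append(np.nan)
            irc_n.append(np.nan)
            continue
        irc_c.append(rc.ir_crit)
        irc_n.append(rn.ir_crit)
        if not np.isfinite(rc.ir_crit):
            ratios.append(0.0)
        elif not np.isfinite(rn.ir_crit):
            ratios.append(np.inf)
        else:
            ratios.append(rn.ir_crit / rc.ir_crit)
        margin = 10 * tolerance
        if np.isfinite(rc.ir_crit):
            warm_c = (max(0.0, rc.bracket[0] - margin), rc.bracket[1] + margin)
        if np.isfinite(rn.ir_crit):
            warm_n = (max(0.0, rn.bracket[0] - margin), rn.bracket[1] + margin)
    return RatioCurve(protocol.name, cancer_phenotype.label, specificity,
                      doses, tuple(ratios), tuple(irc_c), tuple(irc_n),
                      tuple(failed))


def optimal_inhibitor_dose(curve: RatioCurve) -> float:
    """Inhibitor dose at the ratio maximum (ties broken toward the lower
    dose); warns on multimodality; raises :class:`NoOptimumError` when the
    curve is identically zero."""
    r = np.asarray(curve.ratios, dtype=float)
    r = np.where(np.isnan(r), -np.inf, r)
    if not len(r):
        raise NoOptimumError("empty curve")
    if np.nanmax(np.where(np.isfinite(r), r, 0.0)) <= 0.0 and not np.isinf(r).any():
        raise NoOptimumError("IR_crit ratio is zero everywhere on the grid")
    best = int(np.argmax(r))  # argmax takes the first (lowest-dose) maximum
    # count strict local maxima for the multimodality warning
    finite = np.where(np.isfinite(r), r, 0.0)
    n_max = 0
    for i in range(len(finite)):
        left = finite[i - 1] if i > 0 else -np.inf
        right = finite[i + 1] if i < len(finite) - 1 else -np.inf
        if finite[i] > left and finite[i] > right:
            n_max += 1
    if n_max > 1:
        warnings.warn(
            f"ratio curve for {curve.protocol}/{curve.phenotype} has {n_max} "
            "local maxima", MultimodalRatioCurve)
    return curve.doses[best]


def _fraction_early_stop(network, protocol, n_cells, horizon_h, seed0, *,
                         fail_above=None, fail_below=None, dt_fast_s=5.0):
    """Apoptotic fraction with sequential early stopping.

    ``fail_above``: stop as soon as more than fail_above*n cells committed
    (the <= bound is already violated).  ``fail_below``: stop as soon as the
    >= bound can no longer be reached.  Returns (fraction, (lo, hi), n_run,
    decided) where the CI is exact binomial over the cells actually run.
    """
    committed = 0
    times = []
    for i in range(n_cells):
        run = ssa_run(network, protocol, horizon_h, spawn_seed(seed0, i),
                      dt_fast_s=dt_fast_s)
        if run.committed:
            committed += 1
            times.append(run.commit_time_h)
        remaining = n_cells - (i + 1)
        if fail_above is not None and committed > fail_above * n_cells:
            return committed / (i + 1), (i + 1), True, times
        if fail_below is not None and committed + remaining < fail_below * n_cells:
            return committed / (i + 1), (i + 1), True, times
    return committed / n_cells, n_cells, False, times


def verify_protocol(
    network: ReactionNetwork,
    protocol: Protocol,
    cancer_phenotype: CellPhenotype,
    inh_dose: float,
    specificity: float,
    n_cells: int = 1000,
    seed0: int = 0,
    *,
    ir_range: tuple[float, float] = (0.8, 1.5),
    n_ir: int = 15,
    ir_crit_cancer: float | None = None,
    early_stop: bool = True,
    stop_at_first_plausible: bool = False,
) -> PlausibilityVerdict:
    """Stochastic plausibility verification of one protocol setting.

    Scans irradiation doses over ``ir_range`` x IR_crit(cancer).  For each
    dose, cancer cells receive (IR, inh_dose) and normal cells receive
    (IR/3, inh_dose at 1/specificity effective uptake) over a 7-cycle
    horizon.  With ``early_stop``, a dose is abandoned as soon as its
    verdict is decided (the reported fraction then covers the cells
    actually simulated).
    """
    dosed = protocol.with_inh_dose(inh_dose)
    cancer = network.apply_phenotype(cancer_phenotype)
    normal = network.apply_phenotype(
        CellPhenotype("normal", uptake_specificity=specificity))
    n_cyc = _verification_cycles(protocol.cycle_h)
    dosed = replace(dosed, n_cycles=n_cyc)
    if ir_crit_cancer is None:
        ir_crit_cancer = find_ir_crit(cancer, dosed, tolerance=0.02).ir_crit
    if not np.isfinite(ir_crit_cancer):
        raise ValueError(
            "deterministic IR_crit for cancer cells is unbounded at this "
            "inhibitor dose; verification range is undefined")
    irs = np.linspace(ir_range[0], ir_range[1], n_ir) * ir_crit_cancer
    scan = []
    for j, ir in enumerate(irs):
        seed_c = spawn_seed(seed0, 1_000_000 + j)
        seed_n = spawn_seed(seed0, 2_000_000 + j)
        if early_stop:
            fc, nc_run, decided_c, _ = _fraction_early_stop(
                cancer, dosed.with_ir_dose(ir), n_cells, None, seed_c,
                fail_below=PLAUSIBLE_CANCER_MIN)
            # normal arm only matters if the cancer arm can still pass
            if fc >= PLAUSIBLE_CANCER_MIN or not decided_c:
                fn, nn_run, _, _ = _fraction_early_stop(
                    normal, dosed.with_ir_dose(ir / IRRADIATION_RATIO),
                    n_cells, None, seed_n, fail_above=PLAUSIBLE_NORMAL_MAX)
            else:
                fn, nn_run = float("nan"), 0  # cancer arm already failed
            ci_c = ApoptoticFraction(nc_run, round(fc * nc_run), (), 0.0).ci95
            ci_n = (ApoptoticFraction(nn_run, round(fn * nn_run), (), 0.0).ci95
                    if nn_run else (float("nan"), float("nan")))
            scan.append(IrScanPoint(float(ir), fc, ci_c, fn, ci_n))
            if stop_at_first_plausible and scan[-1].plausible:
                break
        else:
            afc = apoptotic_fraction(cancer, dosed.with_ir_dose(ir),
                                     n_cells, seed0=seed_c)
            afn = apoptotic_fraction(normal,
                                     dosed.with_ir_dose(ir / IRRADIATION_RATIO),
                                     n_cells, seed0=seed_n)
            scan.append(IrScanPoint(float(ir), afc.fraction, afc.ci95,
                                    afn.fraction, afn.ci95))
    return PlausibilityVerdict(
        protocol=protocol.name, phenotype=cancer_phenotype.label,
        specificity=specificity, inh_dose=inh_dose,
        ir_crit_cancer=float(ir_crit_cancer), scan=tuple(scan),
        n_cells=n_cells, seed0=seed0,
        normal_dose_factor=1.0 / specificity)


def minimize_inhibitor_dose(
    network: ReactionNetwork,
    protocol: Protocol,
    cancer_phenotype: CellPhenotype,
    specificity: float,
    start_dose: float,
    n_cells: int = 1000,
    seed0: int = 0,
    *,
    dose_step: float = 0.5,
    min_dose: float = 0.5,
    n_ir: int = 15,
    early_stop: bool = True,
) -> OptimizationResult:
    """Descend from ``start_dose`` to the smallest inhibitor dose at which
    the protocol is still plausible (apoptotic fraction >= 95% in cancer,
    <= 10% in normal cells, for some irradiation dose in the scan range).

    Raises ``ValueError`` if the protocol is not plausible at the starting
    dose (precondition of the descent).
    """
    tried: list[tuple[float, bool]] = []
    best: PlausibilityVerdict | None = None
    best_dose = None
    dose = start_dose
    while dose >= min_dose - 1e-9:
        verdict = verify_protocol(network, protocol, cancer_phenotype,
                                  dose, specificity, n_cells, seed0,
                                  n_ir=n_ir, early_stop=early_stop)
        tried.append((dose, verdict.plausible))
        if dose == start_dose and not verdict.plausible:
            raise ValueError(
                f"protocol {protocol.name} is not plausible at the starting "
                f"dose {start_dose} IC50")
        if not verdict.plausible:
            break
        best, best_dose = verdict, dose
        dose = round(dose - dose_step, 10)
    assert best is not None and best_dose is not None
    return OptimizationResult(
        protocol=protocol.name, phenotype=cancer_phenotype.label,
        specificity=specificity, start_dose=start_dose,
        minimal_dose=best_dose, verdict=best, tried=tuple(tried))
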