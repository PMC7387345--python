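"""Recompute the quantities behind the published figure panels.

Each ``fig*`` function reruns the relevant part of the pipeline from
scratch — deterministic critical-dose bisections, stochastic apoptotic
fractions, ratio curves, plausibility verification — at either smoke-test
(``fast=True``: 100 stochastic cells, coarse dose grids, 3-point
irradiation scans) or paper scale.  They return both tabular files for
inspection and a flat dict of headline scalar values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deterministic import find_ir_crit, oscillation_period, simulate
from .network import NORMAL, PTEN_CANCER, WIP1_CANCER, build_network
from .optimize import (
    NoOptimumError,
    minimize_inhibitor_dose,
    optimal_inhibitor_dose,
    ratio_curve,
    verify_protocol,
)
from .pk import PKParameters, peak_time, relaxation_time_h
from .protocols import make_protocol, protocol_catalog
from .stochastic import apoptotic_fraction, spawn_seed

__all__ = ["FIGURES", "ReproOut"]

PHENOTYPES3 = (NORMAL, PTEN_CANCER, WIP1_CANCER)

#: The four protocols highlighted in color in the relative-resistance and
#: apoptotic-fraction panels (one 24-h and the three 36-h cycle variants).
HIGHLIGHTED = ("24h_6_18", "36h_0_24", "36h_6_30", "36h_0_18")

#: The combination protocol studied in detail: 24-h cycles, inhibitor twice
#: per cycle at 6 and 18 h after irradiation, 10 IC50 per administration.
FIG3_PROTOCOL = dict(cycle_h=24, offsets=(6.0, 18.0), inh_dose=10.0,
                     mode="oral")


@dataclass
class ReproOut:
    files: dict
    provenance: dict
    values: dict = field(default_factory=dict)


def _fig3_protocol(days: float = 6.0):
    p = FIG3_PROTOCOL
    return make_protocol(p["cycle_h"], int(days * 24 / p["cycle_h"]), None,
                         p["offsets"], p["inh_dose"], p["mode"],
                         name="24h_6_18")


def fig2a(seed: int = 0, fast: bool = True) -> ReproOut:
    """Monotherapy critical doses for normal cells by cycle length and
    treatment duration."""
    net = build_network().apply_phenotype(NORMAL)
    days_list = (3, 6) if fast else (3, 6, 15)
    tol = 0.02
    rows = []
    for days in days_list:
        for cyc in (12, 18, 24, 36):
            r = find_ir_crit(net, make_protocol(cyc, int(days * 24 / cyc), None),
                             tolerance=tol)
            rows.append({"days": days, "cycle_h": cyc, "ir_crit": r.ir_crit})
    df = pd.DataFrame(rows)
    v18 = float(df[(df.days == 6) & (df.cycle_h == 18)].ir_crit.iloc[0])
    return ReproOut(
        files={"fig2a_ircrit.tsv": df},
        provenance={"figure": "2A", "seed": seed, "tolerance": tol},
        values={"mono_ircrit_18h_6day": v18,
                "mono_ircrit_24h_6day": float(
                    df[(df.days == 6) & (df.cycle_h == 24)].ir_crit.iloc[0])},
    )


def fig2bcd(seed: int = 0, fast: bool = True) -> ReproOut:
    """3-day, 24-h-cycle monotherapy trajectories: normal cells at sub- and
    supercritical doses; cancer cells under persistent damage."""
    net = build_network()
    runs = {
        "normal_0.8": (NORMAL, 0.8),
        "normal_1.3": (NORMAL, 1.3),
        "pten_10": (PTEN_CANCER, 10.0),
        "wip1_10": (WIP1_CANCER, 10.0),
    }
    files, values = {}, {}
    for tag, (phen, dose) in runs.items():
        tr = simulate(net.apply_phenotype(phen), make_protocol(24, 3, dose))
        files[f"fig2_{tag}.csv"] = tr.to_frame()
        apo = tr.apoptosis_time_h
        per = oscillation_period(tr, "p53_killer")
        values[f"apoptosis_h_{tag}"] = apo if apo is not None else float("nan")
        if per is not None:
            values[f"period_h_{tag}"] = per
    values["apoptosis_cycle_normal_1.3"] = (
        int(values["apoptosis_h_normal_1.3"] // 24) + 1
        if np.isfinite(values["apoptosis_h_normal_1.3"]) else -1)
    return ReproOut(files=files,
                    provenance={"figure": "2B-D", "seed": seed},
                    values=values)


def fig3(seed: int = 0, fast: bool = True) -> ReproOut:
    """Critical doses without and with the inhibitor (24-h cycle, 6-day):
    the three phenotype landmarks of the (s1, s2) landscape."""
    net = build_network()
    mono = make_protocol(24, 6, None)
    comb = _fig3_protocol(6)
    rows = []
    for phen in PHENOTYPES3:
        n = net.apply_phenotype(phen)
        rm = find_ir_crit(n, mono, tolerance=0.02)
        rc = find_ir_crit(n, comb, tolerance=0.02)
        rows.append({"phenotype": phen.label,
                     "ir_crit_mono": rm.ir_crit, "ir_crit_comb": rc.ir_crit})
    df = pd.DataFrame(rows)
    by = {r["phenotype"]: r for r in rows}
    return ReproOut(
        files={"fig3_ircrit.tsv": df},
        provenance={"figure": "3", "seed": seed},
        values={
            "comb_ircrit_normal": by["normal"]["ir_crit_comb"],
            "comb_ircrit_pten": by["PTEN-cancer"]["ir_crit_comb"],
            "comb_ircrit_wip1": by["Wip1-cancer"]["ir_crit_comb"],
            "mono_ircrit_pten": by["PTEN-cancer"]["ir_crit_mono"],
            "mono_ircrit_wip1": by["Wip1-cancer"]["ir_crit_mono"],
        },
    )


def fig4a(seed: int = 0, fast: bool = True) -> ReproOut:
    """Combination critical doses across the 6-day protocol catalog."""
    net = build_network()
    phens = (NORMAL,) if fast else PHENOTYPES3
    rows = []
    for name, prot in protocol_catalog(days=6).items():
        for phen in phens:
            r = find_ir_crit(net.apply_phenotype(phen), prot, tolerance=0.02)
            rows.append({"protocol": name, "phenotype": phen.label,
                         "ir_crit": r.ir_crit})
    df = pd.DataFrame(rows)
    sub = df[df.phenotype == "normal"].set_index("protocol").ir_crit
    oral = sub.drop("drip")
    return ReproOut(
        files={"fig4a_ircrit.tsv": df},
        provenance={"figure": "4A", "seed": seed},
        values={"drip_minus_best_oral_ircrit_normal":
                float(sub["drip"] - oral.min()),
                "n_protocols": len(protocol_catalog()) - 1},
    )


def fig5(seed: int = 0, fast: bool = True) -> ReproOut:
    """Stochastic apoptotic fractions for normal cells under the 24-h
    combination protocol, above and below its critical dose."""
    net = build_network().apply_phenotype(NORMAL)
    n = 100 if fast else 1000
    files, values = {}, {}
    for dose, days in ((0.72, 6), (0.5, 6), (0.5, 15)):
        prot = _fig3_protocol(days).with_ir_dose(dose)
        af = apoptotic_fraction(net, prot, n, seed0=spawn_seed(seed, 17))
        tag = f"{dose}_{days}d"
        values[f"frac_{tag}"] = af.fraction
        values[f"n_apoptotic_{tag}"] = af.n_apoptotic
        files[f"fig5_commits_{tag}.csv"] = pd.DataFrame(
            {"commit_time_h": list(af.commit_times_h)})
        files[f"fig5_fraction_{tag}.json"] = {
            "n_cells": n, "n_apoptotic": af.n_apoptotic,
            "fraction": af.fraction, "ci95": af.ci95,
            "per_day": af.per_day_counts()}
    values["n_cells"] = n
    return ReproOut(files=files, provenance={"figure": "5", "seed": seed,
                                             "n_cells": n}, values=values)


def fig6(seed: int = 0, fast: bool = True, specificity: float = 10.0,
         protocols=None) -> ReproOut:
    """Relative radio-resistance (IR_crit ratio) versus inhibitor dose."""
    net = build_network()
    names = protocols or (HIGHLIGHTED if fast else
                          tuple(n for n in protocol_catalog() if n != "drip"))
    grid = np.arange(0.0, 21.0, 2.5 if fast else 0.5)
    cat = protocol_catalog(days=6)
    rows = []
    values = {}
    for name in names:
        for phen in (PTEN_CANCER, WIP1_CANCER):
            curve = ratio_curve(net, cat[name], phen, specificity, grid,
                                tolerance=0.05 if fast else 0.02)
            for d, r in zip(curve.doses, curve.ratios):
                rows.append({"protocol": name, "phenotype": phen.label,
                             "specificity": specificity,
                             "inh_dose": d, "ratio": r})
            key = "pten" if phen is PTEN_CANCER else "wip1"
            values[f"max_ratio_{key}_{name}"] = curve.max_ratio()
            values[f"ratio_at_zero_{key}_{name}"] = curve.ratios[0]
            try:
                values[f"argmax_dose_{key}_{name}"] = optimal_inhibitor_dose(curve)
            except NoOptimumError:
                values[f"argmax_dose_{key}_{name}"] = float("nan")
    df = pd.DataFrame(rows)
    values[f"max_ratio_pten_spec{specificity:g}"] = max(
        v for k, v in values.items() if k.startswith("max_ratio_pten"))
    values[f"max_ratio_wip1_spec{specificity:g}"] = max(
        v for k, v in values.items() if k.startswith("max_ratio_wip1"))
    return ReproOut(files={f"fig6_ratio_curves_spec{specificity:g}.tsv": df},
                    provenance={"figure": "6", "seed": seed,
                                "specificity": specificity,
                                "protocols": list(names)},
                    values=values)


def fig7(seed: int = 0, fast: bool = True, specificities=(10.0, 1.0),
         protocols=None) -> ReproOut:
    """Plausibility counts: stochastic verification of every catalog
    protocol at its ratio-argmax inhibitor dose.

    Two economies keep the smoke-scale run tractable: the cancer arm is
    independent of the inhibitor-specificity ratio (doses are referenced to
    cancer cells) so it is shared across specificities, and since both kill
    fractions grow monotonically with irradiation dose, the normal arm is
    evaluated once, at the lowest cancer-passing dose, where normal cells
    fare best.
    """
    from dataclasses import replace

    from .deterministic import find_ir_crit
    from .network import CellPhenotype
    from .optimize import (
        IRRADIATION_RATIO,
        PLAUSIBLE_CANCER_MIN,
        PLAUSIBLE_NORMAL_MAX,
        _fraction_early_stop,
        _verification_cycles,
    )

    net = build_network()
    names = protocols or tuple(n for n in protocol_catalog() if n != "drip")
    cat = protocol_catalog(days=3 if fast else 6)
    cat_full = protocol_catalog(days=6)
    n_cells = 100 if fast else 1000
    n_ir = 3 if fast else 15
    dt_fast = 8.0 if fast else 5.0
    grid = (0.0, 5.0, 10.0, 20.0) if fast else tuple(np.arange(0.0, 20.5, 0.5))
    rows = []
    values = {}
    normals = {spec: net.apply_phenotype(
        CellPhenotype("normal", uptake_specificity=spec))
        for spec in specificities}
    counts = {(spec, phen.label): 0 for spec in specificities
              for phen in (PTEN_CANCER, WIP1_CANCER)}
    for name in names:
        for phen in (PTEN_CANCER, WIP1_CANCER):
            # step 1: deterministic dose selection (coarse preselection
            # horizon at smoke scale)
            curve = ratio_curve(net, cat[name], phen, 10.0, grid,
                                tolerance=0.1 if fast else 0.02)
            try:
                dose = optimal_inhibitor_dose(curve)
            except NoOptimumError:
                dose = None
            if not dose:
                for spec in specificities:
                    rows.append({"protocol": name, "phenotype": phen.label,
                                 "specificity": spec, "inh_dose": 0.0,
                                 "plausible": False, "ir_opt": None})
                continue
            # step 2: stochastic verification over 7 cycles
            cancer = net.apply_phenotype(phen)
            prot = replace(cat_full[name].with_inh_dose(dose),
                           n_cycles=_verification_cycles(cat_full[name].cycle_h))
            irc = find_ir_crit(cancer, prot, tolerance=0.05).ir_crit
            if not np.isfinite(irc):
                for spec in specificities:
                    rows.append({"protocol": name, "phenotype": phen.label,
                                 "specificity": spec, "inh_dose": dose,
                                 "plausible": False, "ir_opt": None})
                continue
            irs = np.linspace(0.8, 1.5, n_ir) * irc
            plaus = {spec: None for spec in specificities}
            for j, ir in enumerate(irs):
                fc, _, decided, _ = _fraction_early_stop(
                    cancer, prot.with_ir_dose(ir), n_cells, None,
                    spawn_seed(seed, 1_000_000 + j),
                    fail_below=PLAUSIBLE_CANCER_MIN, dt_fast_s=dt_fast)
                if not (fc >= PLAUSIBLE_CANCER_MIN and not decided):
                    continue
                for spec in specificities:
                    fn, _, _, _ = _fraction_early_stop(
                        normals[spec],
                        prot.with_ir_dose(ir / IRRADIATION_RATIO),
                        n_cells, None, spawn_seed(seed, 2_000_000 + j),
                        fail_above=PLAUSIBLE_NORMAL_MAX, dt_fast_s=dt_fast)
                    if fn <= PLAUSIBLE_NORMAL_MAX:
                        plaus[spec] = float(ir)
                break
            for spec in specificities:
                ok = plaus[spec] is not None
                counts[(spec, phen.label)] += ok
                rows.append({"protocol": name, "phenotype": phen.label,
                             "specificity": spec, "inh_dose": dose,
                             "plausible": ok, "ir_opt": plaus[spec]})
    for spec in specificities:
        values[f"n_plausible_pten_spec{spec:g}"] = counts[(spec, "PTEN-cancer")]
        values[f"n_plausible_wip1_spec{spec:g}"] = counts[(spec, "Wip1-cancer")]
    df = pd.DataFrame(rows)
    return ReproOut(files={"fig7_plausibility.tsv": df},
                    provenance={"figure": "7", "seed": seed,
                                "n_cells": n_cells, "n_ir": n_ir,
                                "specificities": list(specificities)},
                    values=values)


def fig8(seed: int = 0, fast: bool = True, protocols=HIGHLIGHTED,
         specificity: float = 10.0) -> ReproOut:
    """Inhibitor-dose minimization for the highlighted protocols."""
    net = build_network()
    cat = protocol_catalog(days=6)
    n_cells = 100 if fast else 1000
    n_ir = 3 if fast else 15
    grid = np.arange(0.0, 21.0, 4.0) if fast else np.arange(0.0, 20.5, 0.5)
    rows = []
    values = {}
    for name in protocols:
        for phen in (PTEN_CANCER, WIP1_CANCER):
            curve = ratio_curve(net, cat[name], phen, specificity, grid,
                                tolerance=0.05)
            try:
                start = optimal_inhibitor_dose(curve)
            except NoOptimumError:
                continue
            try:
                res = minimize_inhibitor_dose(
                    net, cat[name], phen, specificity, start, n_cells,
                    spawn_seed(seed, 29), dose_step=2.0 if fast else 0.5,
                    n_ir=n_ir)
            except ValueError:
                rows.append({"protocol": name, "phenotype": phen.label,
                             "start_dose": start, "minimal_dose": None,
                             "ir_opt": None})
                continue
            rows.append({"protocol": name, "phenotype": phen.label,
                         "start_dose": start,
                         "minimal_dose": res.minimal_dose,
                         "ir_opt": res.verdict.ir_opt})
            key = "pten" if phen is PTEN_CANCER else "wip1"
            values[f"min_dose_{key}_{name}"] = res.minimal_dose
    df = pd.DataFrame(rows)
    mins = [r["minimal_dose"] for r in rows if r["minimal_dose"] is not None]
    if mins:
        values["lowest_min_dose"] = min(mins)
    return ReproOut(files={"fig8_min_dose.tsv": df},
                    provenance={"figure": "8", "seed": seed,
                                "n_cells": n_cells,
                                "specificity": specificity},
                    values=values)


def pk_summary(seed: int = 0, fast: bool = True) -> ReproOut:
    """Closed-form pharmacokinetic landmarks."""
    params = PKParameters()
    values = {
        "pk_peak_time_h": peak_time(params),
        "pk_drip_relaxation_h": relaxation_time_h(params),
    }
    return ReproOut(files={"pk_summary.json": values},
                    provenance={"figure": "methods-PK"}, values=values)


FIGURES = {
    "fig2a": fig2a,
    "fig2bcd": fig2bcd,
    "fig3": fig3,
    "fig4a": fig4a,
    "fig5": fig5,
    "fig6": fig6,
    "fig7": fig7,
    "fig8": fig8,
    "pk": pk_summary,
}
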