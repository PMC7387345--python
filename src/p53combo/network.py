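"""Reaction-network core of the p53 pathway model.

The model couples the DNA-damage-sensing module (double-strand breaks, ATM)
to p53 and its two phosphoforms: *p53_arrester* (Ser15/20-phosphorylated,
transactivating Mdm2, Wip1 and p21) and *p53_killer* (additionally Ser46-
phosphorylated, transactivating PTEN and driving the caspase switch).  Two
negative feedback loops (p53 -> Mdm2 -| p53 and p53 -> Wip1 -| ATM/p53
phosphoforms) generate damage-driven pulses; one positive feedback loop
(p53_killer -> PTEN -| PIP3 -> AKT -> nuclear Mdm2 -| p53) converts
sustained damage into an irreversible commitment.  An Mdm2 inhibitor
(nutlin-like) enters through one-compartment blood pharmacokinetics and
sequesters Mdm2 by mass-action association/dissociation.

A single declarative table of species and reactions is compiled once into
flat numpy arrays consumed by both the deterministic (ODE) and stochastic
(Gillespie) engines, so the two can never drift apart.  Rate constants are
expressed per second (transcription coefficients in mRNA/s); every
user-facing interface speaks hours and converts through
:func:`hours_to_seconds` / :func:`seconds_to_hours` only.
"""

from __future__ import annotations

import copy
import io
import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "Regulator",
    "Reaction",
    "ParameterSet",
    "CellPhenotype",
    "ModelState",
    "ReactionNetwork",
    "CompiledNetwork",
    "build_network",
    "apply_phenotype",
    "deterministic_rates",
    "stochastic_propensities",
    "default_parameters",
    "NORMAL",
    "WIP1_CANCER",
    "PTEN_CANCER",
    "hours_to_seconds",
    "seconds_to_hours",
]

SECONDS_PER_HOUR = 3600.0

SPECIES_ROLES = (
    "mRNA",
    "protein",
    "protein-complex",
    "DNA-state",
    "damage-lesion",
    "drug-pool",
)

# Regulator kinds understood by both engines.
REG_NONE, REG_HILL, REG_INHIB, REG_POW = 0, 1, 2, 3
_REG_CODES = {"hill": REG_HILL, "inhib": REG_INHIB, "pow": REG_POW}
_REG_NAMES = {v: k for k, v in _REG_CODES.items()}

_MAX_MA = 3  # mass-action factors per reaction
_MAX_REG = 2  # regulators per reaction


def hours_to_seconds(t_h: float) -> float:
    """Convert user-facing hours to internal seconds."""
    return float(t_h) * SECONDS_PER_HOUR


def seconds_to_hours(t_s: float) -> float:
    """Convert internal seconds to user-facing hours."""
    return float(t_s) / SECONDS_PER_HOUR


class SchemaError(ValueError):
    """Structural problem in a network definition (dangling references,
    duplicate names, malformed rate laws)."""


class MissingParameterError(KeyError):
    """A rate law references a parameter absent from the parameter set."""

    def __init__(self, name: str, reaction: str | None = None):
        self.parameter = name
        self.reaction = reaction
        where = f" (required by reaction '{reaction}')" if reaction else ""
        super().__init__(f"missing parameter '{name}'{where}")


@dataclass(frozen=True)
class Species:
    """A molecular species.

    ``scalable`` marks species eligible for the scaling acceleration of the
    stochastic engine (abundant pools advanced deterministically); promoter
    states and damage lesions stay discrete.
    """

    name: str
    role: str
    initial_amount: float = 0.0
    scalable: bool = True

    def __post_init__(self):
        if self.role not in SPECIES_ROLES:
            raise SchemaError(f"unknown species role '{self.role}'")
        if self.initial_amount < 0:
            raise SchemaError(f"negative initial amount for '{self.name}'")


@dataclass(frozen=True)
class Regulator:
    """Multiplicative modulation of a reaction rate by a modifier species.

    kind 'hill'  -> x^n / (K^n + x^n)      (activation, saturating)
    kind 'inhib' -> K^n / (K^n + x^n)      (inhibition, saturating)
    kind 'pow'   -> (x / K)^n              (linear/power scaling)

    ``K`` may be a number or the name of a parameter to resolve at
    compile time.
    """

    species: str
    kind: str
    K: float | str
    n: float = 1.0

    def __post_init__(self):
        if self.kind not in _REG_CODES:
            raise SchemaError(f"unknown regulator kind '{self.kind}'")
        if not isinstance(self.K, str) and self.K <= 0:
            raise SchemaError("regulator K must be positive")


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    The rate is ``params[rate_param] * rate_scale`` times the mass-action
    product over ``mass_action`` species (defaulting to the reactants with
    stoichiometric multiplicity) times every regulator factor.  Modifier
    species (catalysts) appear in ``mass_action`` or ``regulators`` without
    being consumed.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_param: str
    rate_scale: float = 1.0
    mass_action: tuple[str, ...] | None = None
    regulators: tuple[Regulator, ...] = ()

    def __post_init__(self):
        for _, s in (*self.reactants, *self.products):
            if not (isinstance(s, int) and s > 0):
                raise SchemaError(f"non-integer stoichiometry in '{self.name}'")
        ma = self.effective_mass_action()
        if len(ma) > _MAX_MA:
            raise SchemaError(f"too many mass-action factors in '{self.name}'")
        if len(self.regulators) > _MAX_REG:
            raise SchemaError(f"too many regulators in '{self.name}'")

    def effective_mass_action(self) -> tuple[str, ...]:
        if self.mass_action is not None:
            return tuple(self.mass_action)
        out: list[str] = []
        for sp, st in self.reactants:
            out.extend([sp] * st)
        return tuple(out)


class ParameterSet(Mapping):
    """Named, validated rate constants (all per second; amounts per cell)."""

    def __init__(self, values: Mapping[str, float]):
        vals = {}
        for k, v in values.items():
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter '{k}' must be finite and non-negative")
            vals[k] = v
        self._values = vals

    def __getitem__(self, key):
        try:
            return self._values[key]
        except KeyError:
            raise MissingParameterError(key) from None

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def updated(self, **changes: float) -> "ParameterSet":
        merged = dict(self._values)
        merged.update(changes)
        return ParameterSet(merged)

    def __repr__(self):
        return f"ParameterSet({len(self)} parameters)"


@dataclass(frozen=True)
class CellPhenotype:
    """Cell type expressed as multipliers on the Wip1 (s1) and PTEN (s2)
    transcription coefficients, plus the inhibitor-uptake specificity
    divisor applied to k_a for normal cells."""

    label: str
    s1_multiplier: float = 1.0
    s2_multiplier: float = 1.0
    uptake_specificity: float = 1.0

    def __post_init__(self):
        if self.s1_multiplier <= 0 or self.s2_multiplier <= 0:
            raise ValueError("phenotype multipliers must be positive")
        if self.uptake_specificity < 1.0:
            raise ValueError("uptake specificity must be >= 1")
        if self.label == "normal" and (
            self.s1_multiplier != 1.0 or self.s2_multiplier != 1.0
        ):
            raise ValueError("normal phenotype must keep nominal s1 and s2")


NORMAL = CellPhenotype("normal")
#: Fivefold increased Wip1 transcription.
WIP1_CANCER = CellPhenotype("Wip1-cancer", s1_multiplier=5.0)
#: Fivefold reduced PTEN transcription.
PTEN_CANCER = CellPhenotype("PTEN-cancer", s2_multiplier=0.2)

PHENOTYPES = {p.label: p for p in (NORMAL, WIP1_CANCER, PTEN_CANCER)}


@dataclass
class ModelState:
    """A timestamped point of a trajectory with the absorbing apoptosis flag."""

    amounts: np.ndarray
    time_h: float
    apoptosis_committed: bool = False
    commitment_time_h: float | None = None

    def commit(self, when_h: float) -> None:
        if not self.apoptosis_committed:
            self.apoptosis_committed = True
            self.commitment_time_h = when_h

    def uncommit(self) -> None:
        raise ValueError("apoptosis commitment is absorbing and cannot revert")


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat-array form of a network shared by both engines."""

    species_names: tuple[str, ...]
    n_species: int
    n_reactions: int
    stoich: np.ndarray          # (n_reactions, n_species) int64
    k: np.ndarray               # (n_reactions,) rate constants
    ma_idx: np.ndarray          # (n_reactions, _MAX_MA) int64, -1 padded
    reg_idx: np.ndarray         # (n_reactions, _MAX_REG) int64, -1 padded
    reg_kind: np.ndarray        # (n_reactions, _MAX_REG) int64
    reg_K: np.ndarray
    reg_n: np.ndarray
    scalable: np.ndarray        # (n_species,) bool
    y0: np.ndarray              # (n_species,) initial amounts
    index: dict = field(repr=False, default_factory=dict)


class ReactionNetwork:
    """Species + reactions + parameters; single source for both engines."""

    def __init__(self, species, reactions, params: ParameterSet):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.params = params
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate species names")
        self.index = {n: i for i, n in enumerate(names)}
        self._validate()

    def _validate(self) -> None:
        for rxn in self.reactions:
            for sp, _ in (*rxn.reactants, *rxn.products):
                if sp not in self.index:
                    raise SchemaError(
                        f"reaction '{rxn.name}' references unknown species '{sp}'"
                    )
            for sp in rxn.effective_mass_action():
                if sp not in self.index:
                    raise SchemaError(
                        f"reaction '{rxn.name}' mass-action factor '{sp}' unknown"
                    )
            for reg in rxn.regulators:
                if reg.species not in self.index:
                    raise SchemaError(
                        f"reaction '{rxn.name}' regulator '{reg.species}' unknown"
                    )
                if isinstance(reg.K, str):
                    try:
                        self.params[reg.K]
                    except MissingParameterError:
                        raise MissingParameterError(reg.K, rxn.name) from None
            try:
                self.params[rxn.rate_param]
            except MissingParameterError:
                raise MissingParameterError(rxn.rate_param, rxn.name) from None

    # -- phenotype specialisation ------------------------------------------

    def with_params(self, **changes: float) -> "ReactionNetwork":
        return ReactionNetwork(self.species, self.reactions, self.params.updated(**changes))

    def apply_phenotype(self, phenotype: CellPhenotype) -> "ReactionNetwork":
        """Return a copy specialised for a phenotype; the original is untouched.

        s1 and s2 are scaled by the phenotype multipliers; for normal cells
        the inhibitor-Mdm2 association constant k_a is divided by the
        uptake-specificity ratio (inhibitor doses are always referenced to
        cancer cells).
        """
        p = self.params
        return self.with_params(
            s1=p["s1"] * phenotype.s1_multiplier,
            s2=p["s2"] * phenotype.s2_multiplier,
            k_a=p["k_a"] / phenotype.uptake_specificity,
        )

    # -- compilation --------------------------------------------------------

    def compile(self) -> CompiledNetwork:
        cached = self.__dict__.get("_compiled")
        if cached is not None:
            return cached
        n_s, n_r = len(self.species), len(self.reactions)
        stoich = np.zeros((n_r, n_s), dtype=np.int64)
        k = np.zeros(n_r)
        ma_idx = np.full((n_r, _MAX_MA), -1, dtype=np.int64)
        reg_idx = np.full((n_r, _MAX_REG), -1, dtype=np.int64)
        reg_kind = np.zeros((n_r, _MAX_REG), dtype=np.int64)
        reg_K = np.ones((n_r, _MAX_REG))
        reg_n = np.ones((n_r, _MAX_REG))
        for j, rxn in enumerate(self.reactions):
            for sp, st in rxn.reactants:
                stoich[j, self.index[sp]] -= st
            for sp, st in rxn.products:
                stoich[j, self.index[sp]] += st
            k[j] = self.params[rxn.rate_param] * rxn.rate_scale
            for m, sp in enumerate(rxn.effective_mass_action()):
                ma_idx[j, m] = self.index[sp]
            for m, reg in enumerate(rxn.regulators):
                reg_idx[j, m] = self.index[reg.species]
                reg_kind[j, m] = _REG_CODES[reg.kind]
                reg_K[j, m] = self.params[reg.K] if isinstance(reg.K, str) else reg.K
                reg_n[j, m] = reg.n
        y0 = np.array([s.initial_amount for s in self.species], dtype=np.float64)
        scalable = np.array([s.scalable for s in self.species], dtype=np.bool_)
        self._compiled = CompiledNetwork(
            species_names=tuple(s.name for s in self.species),
            n_species=n_s,
            n_reactions=n_r,
            stoich=stoich,
            k=k,
            ma_idx=ma_idx,
            reg_idx=reg_idx,
            reg_kind=reg_kind,
            reg_K=reg_K,
            reg_n=reg_n,
            scalable=scalable,
            y0=y0,
            index=dict(self.index),
        )
        return self._compiled

    # -- TSV round trip ------------------------------------------------------

    def to_tsv(self) -> str:
        """Serialise the definition as tabular text (species, reactions,
        parameters sections)."""
        buf = io.StringIO()
        buf.write("#species\tname\trole\tinitial_amount\tscalable\n")
        for s in self.species:
            buf.write(f"species\t{s.name}\t{s.role}\t{s.initial_amount!r}\t{int(s.scalable)}\n")
        buf.write("#reaction\tname\treactants\tproducts\trate_param\trate_scale"
                  "\tmass_action\tregulators\n")
        for r in self.reactions:
            rs = ",".join(f"{st}*{sp}" for sp, st in r.reactants) or "-"
            ps = ",".join(f"{st}*{sp}" for sp, st in r.products) or "-"
            ma = ("auto" if r.mass_action is None
                  else ",".join(r.mass_action) or "-")
            regs = ";".join(
                f"{g.species}:{g.kind}:{g.K if isinstance(g.K, str) else repr(g.K)}:{g.n!r}"
                for g in r.regulators
            ) or "-"
            buf.write(
                f"reaction\t{r.name}\t{rs}\t{ps}\t{r.rate_param}\t{r.rate_scale!r}\t{ma}\t{regs}\n"
            )
        buf.write("#parameter\tname\tvalue\n")
        for name in sorted(self.params):
            buf.write(f"parameter\t{name}\t{self.params[name]!r}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "ReactionNetwork":
        species, reactions, params = [], [], {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            kind = parts[0]
            if kind == "species":
                _, name, role, init, scal = parts
                species.append(Species(name, role, float(init), bool(int(scal))))
            elif kind == "reaction":
                _, name, rs, ps, rp, scale, ma, regs = parts

                def side(txt):
                    if txt == "-":
                        return ()
                    out = []
                    for term in txt.split(","):
                        st, sp = term.split("*")
                        out.append((sp, int(st)))
                    return tuple(out)

                regulators = []
                if regs != "-":
                    for term in regs.split(";"):
                        sp, kd, K, n = term.split(":")
                        try:
                            Kv: float | str = float(K)
                        except ValueError:
                            Kv = K
                        regulators.append(Regulator(sp, kd, Kv, float(n)))
                if ma == "auto":
                    ma_t = None
                elif ma == "-":
                    ma_t = ()
                else:
                    ma_t = tuple(ma.split(","))
                reactions.append(
                    Reaction(name, side(rs), side(ps), rp, float(scale),
                             ma_t, tuple(regulators))
                )
            elif kind == "parameter":
                _, name, value = parts
                params[name] = float(value)
            else:
                raise SchemaError(f"unknown record kind '{kind}'")
        return cls(species, reactions, ParameterSet(params))


# ---------------------------------------------------------------------------
# Rate-law evaluation (reference, non-compiled; the engines carry jitted
# twins of these two functions)
# ---------------------------------------------------------------------------


def _regulator_factor(kind: int, x: float, K: float, n: float) -> float:
    if kind == REG_NONE:
        return 1.0
    if x < 0:
        x = 0.0
    if kind == REG_HILL:
        xn = (x / K) ** n
        return xn / (1.0 + xn)
    if kind == REG_INHIB:
        xn = (x / K) ** n
        return 1.0 / (1.0 + xn)
    return (x / K) ** n  # REG_POW


def deterministic_rates(net: ReactionNetwork | CompiledNetwork, state: np.ndarray) -> np.ndarray:
    """Per-reaction flux vector for the ODE right-hand side.

    The ODE rhs is ``stoich.T @ deterministic_rates(net, y)``.
    """
    c = net.compile() if isinstance(net, ReactionNetwork) else net
    y = np.asarray(state, dtype=float)
    if y.shape != (c.n_species,):
        raise ValueError("state length does not match species count")
    if np.any(y < 0):
        raise ValueError("negative state entry")
    flux = np.empty(c.n_reactions)
    for j in range(c.n_reactions):
        v = c.k[j]
        for m in range(_MAX_MA):
            i = c.ma_idx[j, m]
            if i >= 0:
                v *= y[i]
        for m in range(_MAX_REG):
            i = c.reg_idx[j, m]
            if i >= 0:
                v *= _regulator_factor(c.reg_kind[j, m], y[i], c.reg_K[j, m], c.reg_n[j, m])
        flux[j] = v
    return flux


def stochastic_propensities(net: ReactionNetwork | CompiledNetwork, state: np.ndarray) -> np.ndarray:
    """Gillespie propensity vector.

    Mass-action factors use falling factorials (x, x-1, ...) for repeated
    species so that e.g. a dimerisation A+A with one copy has propensity 0.
    Drug-pool species are continuous and exempt from the integrality check.
    """
    c = net.compile() if isinstance(net, ReactionNetwork) else net
    y = np.asarray(state, dtype=float)
    if y.shape != (c.n_species,):
        raise ValueError("state length does not match species count")
    if np.any(y < 0):
        raise ValueError("negative copy number")
    names = c.species_names
    if isinstance(net, ReactionNetwork):
        roles = {s.name: s.role for s in net.species}
        for i, n in enumerate(names):
            if roles[n] != "drug-pool" and y[i] != np.floor(y[i]):
                raise ValueError(f"non-integer copy number for '{n}'")
    prop = np.empty(c.n_reactions)
    for j in range(c.n_reactions):
        a = c.k[j]
        seen: dict[int, int] = {}
        for m in range(_MAX_MA):
            i = c.ma_idx[j, m]
            if i >= 0:
                r = seen.get(i, 0)
                a *= max(y[i] - r, 0.0)
                seen[i] = r + 1
        for m in range(_MAX_REG):
            i = c.reg_idx[j, m]
            if i >= 0:
                a *= _regulator_factor(c.reg_kind[j, m], y[i], c.reg_K[j, m], c.reg_n[j, m])
        prop[j] = a
    return prop


def apply_phenotype(network: ReactionNetwork, phenotype: CellPhenotype) -> ReactionNetwork:
    """Functional alias of :meth:`ReactionNetwork.apply_phenotype`."""
    return network.apply_phenotype(phenotype)


# ---------------------------------------------------------------------------
# The p53-pathway model definition
# ---------------------------------------------------------------------------

#: Nominal parameter values.  Transcription coefficients s1 (Wip1) and
#: s2 (PTEN) are the printed nominal rates; the remaining constants were
#: calibrated once against the published deterministic reference behaviour
#: (resting stability, ~7-h damage-driven pulses, cancer-cell
#: radioresistance, critical-dose landmarks) and are not tuning dials.
_DEFAULTS = {
    # irradiation / DNA damage
    "dsb_per_gy": 35.0,          # double-strand breaks per Gy
    "rep_vmax": 1.0e-3,          # lesions/s, saturating repair
    "rep_km": 10.0,
    # ATM sensing
    "k_atm_basal": 2.0e-4,
    "k_atm_act": 6.0e-3,
    "K_dsb": 6.0,
    "K_atma": 2000.0,
    "k_atm_deact": 4.0e-4,
    "k_atm_deact_w": 1.6e-2,     # at saturating Wip1
    "K_wip1_atm": 1.5e4,
    # p53 synthesis / degradation
    "s_p53": 10.0,               # molecules/s
    "d_p53_0": 1.0e-4,
    "d_p53_mdm2": 2.5e-7,        # per nuclear Mdm2 molecule
    # p53 phosphorylation cascade
    "k_ph1": 3.0e-3,             # x (ATMa/ATM_tot)
    "k_dph1_0": 1.0e-4,
    "k_dph1_w": 8.0e-3,          # at saturating Wip1
    "k_ph2": 5.0e-3,             # x (HIPK2/K_hipk2)
    "s_hipk2": 2.0,
    "d_hipk2": 8.0e-5,
    "d_hipk2_off": 6.0e-4,       # extra decay once damage is repaired
    "K_hipk2": 8.0e3,
    "k_dph2_0": 1.0e-4,
    "k_dph2_w": 8.0e-3,          # at saturating Wip1
    "K_wsat": 1.0e5,
    # two-state promoters (2 copies each)
    "q0": 3.0e-4,                # gene deactivation
    "q1": 1.0e-3,                # activation at TF = K_tf
    "K_tf": 2500.0,
    "K_tf_mdm2": 2500.0,
    "K_tf_pten": 6.5e3,
    "q1b_mdm2": 3.0e-4,          # p53-independent basal Mdm2 promoter activity
    "q1b_wip1": 0.0,
    # transcription coefficients (mRNA/s at full 2-copy occupancy)
    "s1": 0.1,                   # Wip1 (nominal)
    "s2": 0.03,                  # PTEN (nominal)
    "s_mdm2": 0.1,
    "s_p21": 0.1,
    "d_mrna": 2.5e-4,
    # translation / protein turnover
    "k_tl_w": 0.02,
    "d_w": 2.0e-4,
    "k_tl_m": 0.02,
    "d_m": 2.0e-4,
    "d_m_atm": 2.2e-3,           # ATM-dependent Mdm2 destabilisation
    "k_tl_p": 0.018,
    "d_pt": 8.0e-6,
    "k_tl_q": 0.03,
    "d_q": 2.0e-4,
    # Mdm2 localisation and inhibitor binding
    "k_nuc": 8.0e-3,             # x (AKTp/AKT_tot)
    "k_cyt": 3.0e-4,
    "k_a": 1.0e-3,               # /s per IC50 unit of blood inhibitor
    "k_diss": 1.0e-3,            # equal to k_a so that F = INH_B/(1+INH_B)
    # PIP3/AKT arm
    "k_pi3k": 1.0e-3,
    "k_pten": 6.0e-8,            # per PTEN molecule
    "k_akt_act": 3.0e-3,
    "K_pip": 6000.0,
    "k_akt_deact": 3.0e-4,
    # caspase switch
    "k_cas_p53": 1.0e-3,
    "K_pk": 1.8e4,
    "k_cas_auto": 1.5e-3,
    "K_cas": 3500.0,
    "d_cas": 5.0e-4,
    # pharmacokinetics (per second; 1/h and 0.25/h nominal)
    "d_r1": 1.0 / 3600.0,
    "d_r2": 0.25 / 3600.0,
    "k_inf": 0.0,                # drip infusion rate, IC50 units/s
}

#: Conserved totals (molecules/cell).
ATM_TOTAL = 1.0e4
PIP_TOTAL = 1.0e4
AKT_TOTAL = 1.0e4
CAS_TOTAL = 1.0e4
GENE_COPIES = 2.0

#: Caspase commitment threshold (absorbing apoptosis criterion).
CAS_COMMIT = 0.5 * CAS_TOTAL


def default_parameters(**overrides: float) -> ParameterSet:
    """The nominal parameter set, optionally with overrides."""
    return ParameterSet({**_DEFAULTS, **overrides})


def _gene(tag: str, tf: str, K: str = "K_tf", n: float = 2.0):
    """Two-state promoter (2 copies) activated by transcription factor tf."""
    off, on = f"G{tag}_off", f"G{tag}_on"
    sp = [
        Species(off, "DNA-state", GENE_COPIES, scalable=False),
        Species(on, "DNA-state", 0.0, scalable=False),
    ]
    rxns = [
        Reaction(
            f"gene_{tag}_on",
            ((off, 1),),
            ((on, 1),),
            "q1",
            regulators=(Regulator(tf, "pow", K, n),),
        ),
        Reaction(f"gene_{tag}_off", ((on, 1),), ((off, 1),), "q0"),
    ]
    return sp, rxns


def build_network(params: ParameterSet | None = None) -> ReactionNetwork:
    """Assemble the full p53-pathway network with inhibitor pharmacokinetics.

    Raises :class:`MissingParameterError` if any rate constant referenced by
    a rate law is absent (no partial network is returned) and
    :class:`SchemaError` on dangling species references.
    """
    if params is None:
        params = default_parameters()

    species: list[Species] = [
        Species("DSB", "damage-lesion", 0.0, scalable=False),
        Species("ATMo", "protein", ATM_TOTAL),
        Species("ATMa", "protein", 0.0),
        Species("p53", "protein", 0.0),
        Species("p53_arrester", "protein", 0.0),
        Species("p53_killer", "protein", 0.0),
        Species("HIPK2", "protein", 0.0),
        Species("Mdm2_mRNA", "mRNA", 0.0),
        Species("Mdm2_cyt", "protein", 0.0),
        Species("Mdm2_nuc", "protein", 0.0),
        Species("Mdm2_inh", "protein-complex", 0.0),
        Species("Wip1_mRNA", "mRNA", 0.0),
        Species("Wip1", "protein", 0.0),
        Species("PTEN_mRNA", "mRNA", 0.0),
        Species("PTEN", "protein", 0.0),
        Species("PIP2", "protein", PIP_TOTAL),
        Species("PIP3", "protein", 0.0),
        Species("AKT", "protein", AKT_TOTAL),
        Species("AKTp", "protein", 0.0),
        Species("p21_mRNA", "mRNA", 0.0),
        Species("p21", "protein", 0.0),
        Species("proCaspase", "protein", CAS_TOTAL),
        Species("Caspase", "protein", 0.0),
        Species("INH_depot", "drug-pool", 0.0),
        Species("INH_blood", "drug-pool", 0.0),
    ]

    reactions: list[Reaction] = [
        # DNA damage repair (saturating; persistent damage at high dose)
        Reaction("dsb_repair", (("DSB", 1),), (), "rep_vmax",
                 mass_action=(),
                 regulators=(Regulator("DSB", "hill", "rep_km", 1.0),)),
        # ATM: damage-gated autoactivating switch, reset basally and by Wip1
        Reaction("atm_act", (("ATMo", 1),), (("ATMa", 1),), "k_atm_basal",
                 regulators=(Regulator("DSB", "hill", "K_dsb", 2.0),)),
        Reaction("atm_act_auto", (("ATMo", 1),), (("ATMa", 1),), "k_atm_act",
                 regulators=(Regulator("DSB", "hill", "K_dsb", 2.0),
                             Regulator("ATMa", "hill", "K_atma", 2.0))),
        Reaction("atm_deact", (("ATMa", 1),), (("ATMo", 1),), "k_atm_deact"),
        Reaction("atm_deact_wip1", (("ATMa", 1),), (("ATMo", 1),), "k_atm_deact_w",
                 regulators=(Regulator("Wip1", "hill", "K_wip1_atm", 4.0),)),
        # p53 synthesis and degradation (Mdm2-mediated on all phosphoforms)
        Reaction("p53_synth", (), (("p53", 1),), "s_p53", mass_action=()),
        Reaction("p53_deg0", (("p53", 1),), (), "d_p53_0"),
        Reaction("p53a_deg0", (("p53_arrester", 1),), (), "d_p53_0"),
        Reaction("p53k_deg0", (("p53_killer", 1),), (), "d_p53_0"),
        Reaction("p53_deg_mdm2", (("p53", 1),), (), "d_p53_mdm2",
                 mass_action=("p53", "Mdm2_nuc")),
        Reaction("p53a_deg_mdm2", (("p53_arrester", 1),), (), "d_p53_mdm2",
                 mass_action=("p53_arrester", "Mdm2_nuc")),
        Reaction("p53k_deg_mdm2", (("p53_killer", 1),), (), "d_p53_mdm2",
                 mass_action=("p53_killer", "Mdm2_nuc")),
        # phosphorylation cascade
        Reaction("p53_phos1", (("p53", 1),), (("p53_arrester", 1),), "k_ph1",
                 regulators=(Regulator("ATMa", "pow", ATM_TOTAL, 1.0),)),
        Reaction("p53_dephos1_0", (("p53_arrester", 1),), (("p53", 1),), "k_dph1_0"),
        Reaction("p53_dephos1_w", (("p53_arrester", 1),), (("p53", 1),), "k_dph1_w",
                 regulators=(Regulator("Wip1", "hill", "K_wsat", 1.0),)),
        Reaction("p53_phos2", (("p53_arrester", 1),), (("p53_killer", 1),), "k_ph2",
                 regulators=(Regulator("HIPK2", "hill", "K_hipk2", 4.0),)),
        # HIPK2 integrates damage duration: steady synthesis, rapid decay
        # once ATM has been switched off (repair complete)
        Reaction("hipk2_synth", (), (("HIPK2", 1),), "s_hipk2", mass_action=(),
                 regulators=(Regulator("DSB", "hill", "K_dsb", 2.0),)),
        Reaction("hipk2_deg", (("HIPK2", 1),), (), "d_hipk2"),
        Reaction("hipk2_deg_offdamage", (("HIPK2", 1),), (), "d_hipk2_off",
                 regulators=(Regulator("DSB", "inhib", "K_dsb", 2.0),)),
        Reaction("p53_dephos2_0", (("p53_killer", 1),), (("p53_arrester", 1),), "k_dph2_0"),
        Reaction("p53_dephos2_w", (("p53_killer", 1),), (("p53_arrester", 1),), "k_dph2_w",
                 regulators=(Regulator("Wip1", "hill", "K_wsat", 1.0),)),
        # Mdm2 expression, localisation, degradation, inhibitor binding
        Reaction("mdm2_transcr", (), (("Mdm2_mRNA", 1),), "s_mdm2",
                 rate_scale=1.0 / GENE_COPIES, mass_action=("GM_on",)),
        Reaction("mdm2_mrna_deg", (("Mdm2_mRNA", 1),), (), "d_mrna"),
        Reaction("mdm2_transl", (), (("Mdm2_cyt", 1),), "k_tl_m",
                 mass_action=("Mdm2_mRNA",)),
        Reaction("mdm2_nuc_in", (("Mdm2_cyt", 1),), (("Mdm2_nuc", 1),), "k_nuc",
                 regulators=(Regulator("AKTp", "pow", AKT_TOTAL, 2.0),)),
        Reaction("mdm2_nuc_out", (("Mdm2_nuc", 1),), (("Mdm2_cyt", 1),), "k_cyt"),
        Reaction("mdm2c_deg", (("Mdm2_cyt", 1),), (), "d_m"),
        Reaction("mdm2n_deg", (("Mdm2_nuc", 1),), (), "d_m"),
        Reaction("mdm2i_deg", (("Mdm2_inh", 1),), (), "d_m"),
        Reaction("mdm2c_deg_atm", (("Mdm2_cyt", 1),), (), "d_m_atm",
                 regulators=(Regulator("ATMa", "pow", ATM_TOTAL, 1.0),)),
        Reaction("mdm2n_deg_atm", (("Mdm2_nuc", 1),), (), "d_m_atm",
                 regulators=(Regulator("ATMa", "pow", ATM_TOTAL, 1.0),)),
        Reaction("inh_bind_cyt", (("Mdm2_cyt", 1),), (("Mdm2_inh", 1),), "k_a",
                 regulators=(Regulator("INH_blood", "pow", 1.0, 1.0),)),
        Reaction("inh_bind_nuc", (("Mdm2_nuc", 1),), (("Mdm2_inh", 1),), "k_a",
                 regulators=(Regulator("INH_blood", "pow", 1.0, 1.0),)),
        Reaction("inh_unbind", (("Mdm2_inh", 1),), (("Mdm2_cyt", 1),), "k_diss"),
        # Wip1 expression
        Reaction("wip1_transcr", (), (("Wip1_mRNA", 1),), "s1",
                 rate_scale=1.0 / GENE_COPIES, mass_action=("GW_on",)),
        Reaction("wip1_mrna_deg", (("Wip1_mRNA", 1),), (), "d_mrna"),
        Reaction("wip1_transl", (), (("Wip1", 1),), "k_tl_w",
                 mass_action=("Wip1_mRNA",)),
        Reaction("wip1_deg", (("Wip1", 1),), (), "d_w"),
        # PTEN expression (p53_killer target) and lipid/AKT arm
        Reaction("pten_transcr", (), (("PTEN_mRNA", 1),), "s2",
                 rate_scale=1.0 / GENE_COPIES, mass_action=("GP_on",)),
        Reaction("pten_mrna_deg", (("PTEN_mRNA", 1),), (), "d_mrna"),
        Reaction("pten_transl", (), (("PTEN", 1),), "k_tl_p",
                 mass_action=("PTEN_mRNA",)),
        Reaction("pten_deg", (("PTEN", 1),), (), "d_pt"),
        Reaction("pip_phos", (("PIP2", 1),), (("PIP3", 1),), "k_pi3k"),
        Reaction("pip_dephos", (("PIP3", 1),), (("PIP2", 1),), "k_pten",
                 mass_action=("PIP3", "PTEN")),
        Reaction("akt_act", (("AKT", 1),), (("AKTp", 1),), "k_akt_act",
                 regulators=(Regulator("PIP3", "hill", "K_pip", 4.0),)),
        Reaction("akt_deact", (("AKTp", 1),), (("AKT", 1),), "k_akt_deact"),
        # p21 arrest arm (p53_arrester target)
        Reaction("p21_transcr", (), (("p21_mRNA", 1),), "s_p21",
                 rate_scale=1.0 / GENE_COPIES, mass_action=("GQ_on",)),
        Reaction("p21_mrna_deg", (("p21_mRNA", 1),), (), "d_mrna"),
        Reaction("p21_transl", (), (("p21", 1),), "k_tl_q",
                 mass_action=("p21_mRNA",)),
        Reaction("p21_deg", (("p21", 1),), (), "d_q"),
        # caspase switch (p53_killer drive + cooperative self-amplification)
        Reaction("cas_act_p53", (("proCaspase", 1),), (("Caspase", 1),), "k_cas_p53",
                 regulators=(Regulator("p53_killer", "hill", "K_pk", 4.0),)),
        Reaction("cas_auto", (("proCaspase", 1),), (("Caspase", 1),), "k_cas_auto",
                 regulators=(Regulator("Caspase", "hill", "K_cas", 4.0),)),
        Reaction("cas_deact", (("Caspase", 1),), (("proCaspase", 1),), "d_cas"),
        # pharmacokinetics: depot -> blood -> elimination; optional drip
        Reaction("pk_liberation", (("INH_depot", 1),), (("INH_blood", 1),), "d_r1"),
        Reaction("pk_elimination", (("INH_blood", 1),), (), "d_r2"),
        Reaction("pk_infusion", (), (("INH_blood", 1),), "k_inf", mass_action=()),
    ]

    # promoters: Mdm2, Wip1, p21 read p53_arrester; PTEN reads p53_killer
    for tag, tf, K, n in (("M", "p53_arrester", "K_tf_mdm2", 2.0),
                          ("W", "p53_arrester", "K_tf", 2.0),
                          ("P", "p53_killer", "K_tf_pten", 3.0),
                          ("Q", "p53_arrester", "K_tf", 2.0)):
        sp, rx = _gene(tag, tf, K, n)
        species.extend(sp)
        reactions.extend(rx)
    # p53-independent basal promoter activity: Mdm2's keeps resting p53 low;
    # Wip1's sets the pre-stimulus Wip1 tone (elevated in Wip1-cancer cells)
    reactions.append(Reaction("gene_M_on_basal", (("GM_off", 1),), (("GM_on", 1),),
                              "q1b_mdm2"))
    reactions.append(Reaction("gene_W_on_basal", (("GW_off", 1),), (("GW_on", 1),),
                              "q1b_wip1"))

    return ReactionNetwork(species, reactions, params)
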