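"""Reaction-network model definitions.

A :class:`ReactionNetwork` couples an ordered species list, integer
stoichiometry and symbolic propensity (rate-law) expressions over species
copy numbers and named parameters.  The same propensity vector drives both
the exact stochastic simulation (as jump intensities) and the deterministic
ODE analysis (as fluxes), so the two regimes are consistent by
construction.

Two models ship with the package:

* a constitutive gene-expression circuit (mRNA/protein birth-death), and
* an interferon-driven IRF7 gene-expression circuit with positive feedback
  through promoter activation by ISGF3 and the IRF7 dimer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from sympy.printing.pycode import pycode


class ModelError(ValueError):
    """Raised for malformed network definitions or parameter sets."""


class ConfigurationError(ValueError):
    """Raised when a parameter set does not match its network."""


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by a network.

    ``discrete`` marks species carried as integer copy numbers in the
    stochastic regime (promoter occupancy is the classic 0/1 example; it
    becomes a fractional occupancy in the ODE regime).
    """

    name: str
    description: str = ""
    discrete: bool = True


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel.

    ``changes`` maps species name -> integer stoichiometric change.
    ``rate_law`` is an expression over species names and parameter names,
    parsed with sympy; it must evaluate to a finite nonnegative propensity
    for any nonnegative state and positive parameters.
    """

    name: str
    changes: Mapping[str, int]
    rate_law: str


@dataclass(frozen=True)
class ObservationMap:
    """Maps a state vector to the measured observable.

    The observable is ``scale * sum(copy numbers of observable_species)``,
    where ``scale`` (phi) converts molecule counts to the arbitrary
    fluorescence units of the measurement.
    """

    observable_species: tuple[str, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.observable_species:
            raise ModelError("observation map needs at least one species")
        if not (self.scale > 0):
            raise ModelError("observation scale (phi) must be positive")

    def indices(self, network: "ReactionNetwork") -> np.ndarray:
        names = network.species_names
        missing = [s for s in self.observable_species if s not in names]
        if missing:
            raise ModelError(f"observable species not in network: {missing}")
        return np.array([names.index(s) for s in self.observable_species])

    def apply_state(self, network: "ReactionNetwork", state: np.ndarray) -> float:
        idx = self.indices(network)
        return float(self.scale * np.asarray(state, dtype=float)[..., idx].sum(axis=-1))


class ParameterSet(dict):
    """Named, positive, finite parameter values for one network."""

    def __init__(self, values: Mapping[str, float]):
        super().__init__({k: float(v) for k, v in values.items()})
        for k, v in self.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"parameter {k!r} is not finite: {v}")

    def vector(self, network: "ReactionNetwork") -> np.ndarray:
        """Values ordered like ``network.parameter_names``."""
        missing = [p for p in network.parameter_names if p not in self]
        if missing:
            raise ConfigurationError(f"missing parameters: {missing}")
        extra = [p for p in self if p not in network.parameter_names]
        if extra:
            raise ConfigurationError(f"unknown parameters: {extra}")
        return np.array([self[p] for p in network.parameter_names], dtype=np.float64)


@dataclass(frozen=True)
class ParameterSpace:
    """Box bounds for the searched parameters plus fixed values.

    Bounds are strictly positive with lower < upper; sampling is uniform on
    the linear scale of the bounds.
    """

    bounds: Mapping[str, tuple[float, float]]
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ModelError(f"bad bounds for {name!r}: ({lo}, {hi})")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def sample(self, rng: np.random.Generator) -> ParameterSet:
        values = dict(self.fixed)
        for name, (lo, hi) in self.bounds.items():
            values[name] = rng.uniform(lo, hi)
        return ParameterSet(values)

    def contains(self, params: Mapping[str, float]) -> bool:
        return all(lo <= params[n] <= hi for n, (lo, hi) in self.bounds.items())


def _compile(source: str, name: str):
    namespace: dict = {"np": np}
    exec(compile(source, f"<modefit:{name}>", "exec"), namespace)
    return namespace[name]


class ReactionNetwork:
    """Species, stoichiometry and parameterized propensity laws."""

    def __init__(
        self,
        name: str,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        parameter_names: Sequence[str],
        default_initial_state: Sequence[float],
        observation: ObservationMap | None = None,
        default_parameters: Mapping[str, float] | None = None,
    ) -> None:
        self.name = name
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.parameter_names = tuple(parameter_names)
        self.default_initial_state = np.asarray(default_initial_state, dtype=np.float64)
        self.observation = observation
        self.default_parameters = (
            ParameterSet(default_parameters) if default_parameters else None
        )
        self._validate()
        self._symbols = {n: sp.Symbol(n, nonnegative=True) for n in self.species_names}
        self._symbols.update({n: sp.Symbol(n, positive=True) for n in self.parameter_names})
        self._rate_exprs = [
            sp.sympify(r.rate_law, locals=dict(self._symbols)) for r in self.reactions
        ]
        self._propensity_fn = None
        self._compiled_propensity = None

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("species names must be unique")
        known = set(names) | set(self.parameter_names)
        for r in self.reactions:
            for s, c in r.changes.items():
                if s not in names:
                    raise ModelError(f"reaction {r.name!r} changes unknown species {s!r}")
                if int(c) != c:
                    raise ModelError(f"reaction {r.name!r} has non-integer stoichiometry")
            free = {str(x) for x in sp.sympify(r.rate_law).free_symbols}
            unknown = free - known
            if unknown:
                raise ModelError(f"reaction {r.name!r} uses unknown symbols {sorted(unknown)}")
        if len(self.default_initial_state) != len(names):
            raise ModelError("initial state length does not match species")

    # -- structure -----------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def stoichiometry(self) -> np.ndarray:
        """Change matrix, shape (n_species, n_reactions), integer."""
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        names = self.species_names
        for j, r in enumerate(self.reactions):
            for s, c in r.changes.items():
                S[names.index(s), j] = int(c)
        return S

    # -- evaluation ----------------------------------------------------
    def _propensity_source(self) -> str:
        lines = ["def _propensities(state, params, out):"]
        for i, n in enumerate(self.species_names):
            lines.append(f"    {n} = state[{i}]")
        for i, n in enumerate(self.parameter_names):
            lines.append(f"    {n} = params[{i}]")
        for j, expr in enumerate(self._rate_exprs):
            lines.append(f"    out[{j}] = {pycode(expr)}")
        return "\n".join(lines) + "\n"

    def propensity_function(self):
        """Plain-python ``f(state, params, out)`` filling the rate vector."""
        if self._propensity_fn is None:
            self._propensity_fn = _compile(self._propensity_source(), "_propensities")
        return self._propensity_fn

    def compiled_propensity_function(self):
        """JIT-compiled propensity evaluator (shared by the SSA kernel)."""
        if self._compiled_propensity is None:
            import numba

            fn = _compile(self._propensity_source(), "_propensities")
            # numpy error model (and no fastmath): a pathological rate law
            # yields inf/nan that the kernel's finiteness check converts
            # into a SimulationError naming the reaction, instead of a
            # raw ZeroDivisionError from the jitted code
            self._compiled_propensity = numba.njit(
                "void(float64[::1], float64[::1], float64[::1])",
                error_model="numpy",
            )(fn)
        return self._compiled_propensity

    def propensities(self, state: Sequence[float], params: ParameterSet) -> np.ndarray:
        state = np.asarray(state, dtype=np.float64)
        if state.shape != (self.n_species,):
            raise ModelError(
                f"state has shape {state.shape}, expected ({self.n_species},)"
            )
        if np.any(state < 0):
            raise ModelError("state contains negative copy numbers")
        theta = params.vector(self) if isinstance(params, ParameterSet) else ParameterSet(params).vector(self)
        out = np.empty(self.n_reactions, dtype=np.float64)
        self.propensity_function()(state, theta, out)
        if not np.all(np.isfinite(out)):
            bad = self.reactions[int(np.argmax(~np.isfinite(out)))].name
            raise ModelError(f"non-finite propensity for reaction {bad!r}")
        return out

    # -- symbolic ODE pieces (used by deterministic analysis) ----------
    def symbolic_rhs(self) -> list[sp.Expr]:
        S = self.stoichiometry
        return [
            sp.Add(*[S[i, j] * self._rate_exprs[j] for j in range(self.n_reactions)])
            for i in range(self.n_species)
        ]

    def symbolic_jacobian(self) -> list[list[sp.Expr]]:
        rhs = self.symbolic_rhs()
        xs = [self._symbols[n] for n in self.species_names]
        return [[sp.diff(f, x) for x in xs] for f in rhs]

    # -- provenance export ---------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "species": [
                {"name": s.name, "description": s.description, "discrete": s.discrete}
                for s in self.species
            ],
            "reactions": [
                {"name": r.name, "changes": dict(r.changes), "rate_law": r.rate_law}
                for r in self.reactions
            ],
            "parameters": list(self.parameter_names),
            "default_initial_state": self.default_initial_state.tolist(),
            "observation": None
            if self.observation is None
            else {
                "species": list(self.observation.observable_species),
                "scale": self.observation.scale,
            },
        }
        return json.dumps(doc, indent=2)


def evaluate_propensities(
    network: ReactionNetwork, state: Sequence[float], params: ParameterSet
) -> np.ndarray:
    """One finite nonnegative rate per reaction, in reaction order."""
    return network.propensities(state, params)


# ---------------------------------------------------------------------------
# Bundled models
# ---------------------------------------------------------------------------

#: True parameters of the constitutive circuit used for in-silico studies:
#: (transcription, mRNA decay, translation, protein decay), units 1/min
#: except the zeroth-order transcription rate (molecules/min).
CONSTITUTIVE_TRUE_PARAMS: Mapping[str, float] = {
    "k_tx": 5.0,
    "d_mrna": 0.03,
    "k_tl": 0.1,
    "d_prot": 0.03,
}


def build_constitutive_model() -> ReactionNetwork:
    """Constitutive gene expression: mRNA and protein birth-death.

    Four mass-action reactions: constant transcription (k_tx), first-order
    mRNA decay (d_mrna), translation proportional to mRNA (k_tl) and
    first-order protein decay (d_prot).  The measured observable is the
    protein copy number (phi = 1).
    """
    return ReactionNetwork(
        name="constitutive",
        species=[
            Species("mRNA", "messenger RNA copies"),
            Species("Protein", "protein copies"),
        ],
        reactions=[
            Reaction("transcription", {"mRNA": +1}, "k_tx"),
            Reaction("mrna_decay", {"mRNA": -1}, "d_mrna*mRNA"),
            Reaction("translation", {"Protein": +1}, "k_tl*mRNA"),
            Reaction("protein_decay", {"Protein": -1}, "d_prot*Protein"),
        ],
        parameter_names=["k_tx", "d_mrna", "k_tl", "d_prot"],
        default_initial_state=[0, 0],
        observation=ObservationMap(("Protein",), 1.0),
        default_parameters=CONSTITUTIVE_TRUE_PARAMS,
    )


#: Nominal IRF7-circuit parameters (units: rates 1/min unless noted;
#: V_IFN molecules/(cell*min); saturation constants molecules/cell;
#: k_IRF7dimer cell/(molecule*min); n_hill dimensionless and not searched).
IRF7_NOMINAL_PARAMS: Mapping[str, float] = {
    "V_IFN": 6.135,
    "n_hill": 2.0,
    "k_IFN": 0.0055,
    "k_dIFN": 0.0492,
    "k_ISGF3": 0.0003,
    "k_dISGF3": 0.0017,
    "k_on": 522.59,
    "k_aI3": 22687.02,
    "k_aI7": 35281.99,
    "k_off": 0.0013,
    "k_Active": 1.144,
    "k_Basal": 0.0861,
    "k_dmRNA": 0.0715,
    "k_IRF7": 43.867,
    "k_dIRF7": 3.877,
    "k_IRF7dimer": 0.602,
    "k_dIRF7dimer": 0.439,
}

#: Search ranges for the IRF7 circuit (the Hill coefficient is fixed at 2).
IRF7_BOUNDS: Mapping[str, tuple[float, float]] = {
    "V_IFN": (2.8, 11.2),
    "k_IFN": (0.0022, 0.0088),
    "k_dIFN": (0.0232, 0.0926),
    "k_ISGF3": (0.00012, 0.00048),
    "k_dISGF3": (0.00068, 0.00272),
    "k_on": (184.55, 738.2),
    "k_aI3": (7681.6, 30727.0),
    "k_aI7": (13399.0, 53597.0),
    "k_off": (0.00044, 0.00176),
    "k_Active": (0.5402, 2.161),
    "k_Basal": (0.0312, 0.125),
    "k_dmRNA": (0.029, 0.116),
    "k_IRF7": (14.0, 56.0),
    "k_dIRF7": (1.540, 6.160),
    "k_IRF7dimer": (0.235, 0.94),
    "k_dIRF7dimer": (0.209, 0.836),
}


def constitutive_parameter_space() -> ParameterSpace:
    """Demo search space for the constitutive circuit.

    The synthesis and translation rates are treated as unknown within a
    broad box around the true values; both decay rates are held fixed at
    their known values, mirroring the standard in-silico recovery setup.
    """
    return ParameterSpace(
        bounds={"k_tx": (1.0, 10.0), "k_tl": (0.02, 0.5)},
        fixed={"d_mrna": 0.03, "d_prot": 0.03},
    )


def irf7_parameter_space() -> ParameterSpace:
    """Box search space of the IRF7 circuit with the Hill coefficient fixed."""
    return ParameterSpace(bounds=IRF7_BOUNDS, fixed={"n_hill": 2.0})


def build_irf7_model() -> ReactionNetwork:
    """IRF7 gene-expression circuit driven by interferon stimulation.

    Seven species and thirteen reactions.  IFN amplifies itself through a
    saturable (Hill, n=2) activation of the JAK-STAT pathway and produces
    ISGF3.  The IRF7 promoter switches to its active state (Pa = 1) at a
    rate requiring both ISGF3 and the IRF7 dimer; the ``(1 - Pa)`` factor
    caps occupancy at a single active copy.  Transcription runs at an
    active rate from Pa and a basal rate from the inactive promoter;
    translation, phosphorylation and dimerization complete the positive
    feedback loop.  The dimerization propensity is the printed product form
    k_IRF7dimer * IRF7phosp**2 rather than the combinatorial
    n*(n-1)/2 convention (a deliberate fidelity choice; see the methods
    note).  The observable is total IRF7 protein: free + phosphorylated +
    dimer, phi = 1.
    """
    return ReactionNetwork(
        name="irf7",
        species=[
            Species("IFN", "interferon-beta stimulus"),
            Species("ISGF3", "JAK-STAT pathway output transcription factor"),
            Species("Pa", "active-promoter occupancy (0/1 stochastic)"),
            Species("mRNA", "IRF7 transcript"),
            Species("IRF7", "unphosphorylated IRF7 protein"),
            Species("IRF7phosp", "phosphorylated IRF7"),
            Species("IRF7dimer", "IRF7 dimer"),
        ],
        reactions=[
            Reaction(
                "ifn_amplification",
                {"IFN": +1},
                "V_IFN*IFN**n_hill/(k_IFN**n_hill + IFN**n_hill)",
            ),
            Reaction("isgf3_production", {"ISGF3": +1}, "k_ISGF3*IFN"),
            Reaction(
                "promoter_activation",
                {"Pa": +1},
                "k_on*(ISGF3*IRF7dimer/"
                "(k_aI3*k_aI7 + k_aI3*ISGF3 + k_aI7*IRF7dimer + ISGF3*IRF7dimer))"
                "*(1 - Pa)",
            ),
            Reaction("transcription_active", {"mRNA": +1}, "k_Active*Pa"),
            Reaction("transcription_basal", {"mRNA": +1}, "k_Basal*(1 - Pa)"),
            Reaction("translation", {"IRF7": +1}, "k_IRF7*mRNA"),
            Reaction("phosphorylation", {"IRF7": -1, "IRF7phosp": +1}, "k_dIRF7*IRF7"),
            Reaction(
                "dimerization",
                {"IRF7phosp": -2, "IRF7dimer": +1},
                "k_IRF7dimer*IRF7phosp*IRF7phosp",
            ),
            Reaction("promoter_inactivation", {"Pa": -1}, "k_off*Pa"),
            Reaction("ifn_decay", {"IFN": -1}, "k_dIFN*IFN"),
            Reaction("mrna_decay", {"mRNA": -1}, "k_dmRNA*mRNA"),
            Reaction("dimer_decay", {"IRF7dimer": -1}, "k_dIRF7dimer*IRF7dimer"),
            Reaction("isgf3_decay", {"ISGF3": -1}, "k_dISGF3*ISGF3"),
        ],
        parameter_names=list(IRF7_NOMINAL_PARAMS),
        default_initial_state=[150, 1, 0, 1, 1, 0, 0],
        observation=ObservationMap(("IRF7", "IRF7phosp", "IRF7dimer"), 1.0),
        default_parameters=IRF7_NOMINAL_PARAMS,
    )


_BUILDERS = {
    "constitutive": build_constitutive_model,
    "irf7": build_irf7_model,
}


def get_model(name: str) -> ReactionNetwork:
    """Look up a bundled model by id (``constitutive`` or ``irf7``)."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ModelError(f"unknown model {name!r}; choose from {sorted(_BUILDERS)}")
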