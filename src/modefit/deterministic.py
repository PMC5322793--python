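"""Deterministic (ODE) analysis of a reaction network.

The ODE right-hand side is the stoichiometry matrix times the propensity
vector, i.e. the macroscopic limit of the jump process.  Steady states are
located by multi-start root finding, classified by the eigenvalues of the
analytic Jacobian, and compared with the modes of the measured
distribution through the *deterministic precondition*: a parameter set is
worth a stochastic evaluation only when the number of stable steady states
equals the number of modes and each stable state, mapped to observation
units, brackets its mode within the relative band
``beta_low * h(X*) <= alpha <= beta_up * h(X*)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .models import ObservationMap, ParameterSet, ReactionNetwork


@dataclass(frozen=True)
class SteadyState:
    state: np.ndarray
    lambda_max: float  # max real part of Jacobian eigenvalues
    stable: bool
    residual: float = 0.0


@dataclass
class SteadyStateSet:
    """Deduplicated fixed points with their stability labels."""

    states: list[SteadyState] = field(default_factory=list)

    @property
    def n_stable(self) -> int:
        return sum(s.stable for s in self.states)

    @property
    def stable_states(self) -> list[SteadyState]:
        return [s for s in self.states if s.stable]

    def to_json_dict(self) -> dict:
        return {
            "states": [
                {
                    "state": s.state.tolist(),
                    "lambda_max": s.lambda_max,
                    "stable": s.stable,
                    "residual": s.residual,
                }
                for s in self.states
            ],
            "n_stable": self.n_stable,
        }


@dataclass(frozen=True)
class PreconditionConfig:
    """Relative acceptance band and numerical tolerances of the filter.

    ``penalty`` is the finite stand-in for the "infinitely bad" objective
    assigned to rejected parameter sets, chosen far above any attainable
    squared-difference value so optimizers can still rank.
    """

    beta_low: float | Sequence[float] = 0.95
    beta_up: float | Sequence[float] = 1.05
    penalty: float = 1e12
    tol_residual: float = 1e-9
    tol_eig: float = 1e-9

    def bands(self, q: int) -> tuple[np.ndarray, np.ndarray]:
        low = np.broadcast_to(np.asarray(self.beta_low, dtype=float), (q,)).copy()
        up = np.broadcast_to(np.asarray(self.beta_up, dtype=float), (q,)).copy()
        if np.any(low < 0) or np.any(low > 1) or np.any(up < 1):
            raise ValueError("require 0 <= beta_low <= 1 <= beta_up")
        return low, up


@dataclass
class PreconditionResult:
    passed: bool
    reason: str  # "passed" | "count mismatch" | "out of range" | "no stable state"
    n_stable: int
    n_modes: int
    pairs: list[tuple[float, float]] = field(default_factory=list)  # (mode, h(X*))
    pair_ok: list[bool] = field(default_factory=list)


def ode_rhs(
    network: ReactionNetwork, state: Sequence[float], params: ParameterSet
) -> np.ndarray:
    """Derivative vector = stoichiometry @ propensities at ``state``."""
    state = np.asarray(state, dtype=np.float64)
    theta = params.vector(network) if isinstance(params, ParameterSet) else ParameterSet(params).vector(network)
    out = np.empty(network.n_reactions)
    # clamp tiny negatives produced by root iterations before evaluating
    network.propensity_function()(np.maximum(state, 0.0), theta, out)
    return network.stoichiometry @ out


class _OdeSystem:
    """Callable RHS/Jacobian pair compiled once per network."""

    _cache: dict[int, "_OdeSystem"] = {}

    def __init__(self, network: ReactionNetwork):
        import sympy as sp

        xs = [sp.Symbol(n, nonnegative=True) for n in network.species_names]
        ps = [sp.Symbol(n, positive=True) for n in network.parameter_names]
        rhs = network.symbolic_rhs()
        # merge powers like x**(2*n)/x -> x**(2*n - 1) so the Jacobian stays
        # finite on the state-space boundary (e.g. Hill terms at zero)
        jac = [
            [sp.powsimp(e, force=True) for e in row]
            for row in network.symbolic_jacobian()
        ]
        self.S = network.stoichiometry
        self.f = sp.lambdify((xs, ps), rhs, modules="numpy")
        self.j = sp.lambdify((xs, ps), jac, modules="numpy")

    @classmethod
    def for_network(cls, network: ReactionNetwork) -> "_OdeSystem":
        key = id(network)
        if key not in cls._cache:
            cls._cache[key] = cls(network)
        return cls._cache[key]

    def rhs(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        # evaluated on the raw (possibly slightly negative) iterate so the
        # root iteration sees a smooth function consistent with its Jacobian
        return np.asarray(self.f(x, theta), dtype=float)

    def jacobian(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self.j(x, theta), dtype=float)


def default_starts(
    network: ReactionNetwork,
    n_random: int = 20,
    seed: int = 0,
    low: float = 1e-3,
    high: float = 1e4,
) -> np.ndarray:
    """Fixed multi-start lattice for steady-state searches.

    An origin neighborhood, the model's default initial state, and
    ``n_random`` log-uniform random states per species in ``[low, high]``
    drawn from a dedicated seeded generator, so the lattice is identical
    across calls.
    """
    rng = np.random.default_rng(seed)
    d = network.n_species
    starts = [np.zeros(d), network.default_initial_state.astype(float)]
    starts.extend(
        np.exp(rng.uniform(np.log(low), np.log(high), size=(n_random, d)))
    )
    return np.asarray(starts)


def classify_stability(
    network: ReactionNetwork,
    params: ParameterSet,
    state: Sequence[float],
    tol_eig: float = 1e-9,
) -> tuple[float, bool]:
    """(max real eigenvalue part, stable flag) of the Jacobian at a fixed point.

    The Jacobian is analytic (symbolic differentiation of the rate laws);
    if it evaluates non-finite the point is conservatively labelled
    unstable.  Strict stability requires every eigenvalue real part below
    ``-tol_eig``; marginal points are rejected.
    """
    sys = _OdeSystem.for_network(network)
    theta = params.vector(network)
    J = sys.jacobian(np.asarray(state, dtype=float), theta)
    if not np.all(np.isfinite(J)):
        return np.inf, False
    lam = float(np.max(np.linalg.eigvals(J).real))
    return lam, lam < -tol_eig


def find_steady_states(
    network: ReactionNetwork,
    params: ParameterSet,
    starts: Sequence[Sequence[float]] | None = None,
    *,
    tol_residual: float = 1e-9,
    tol_eig: float = 1e-9,
    tol_neg: float = 1e-6,
    dedup_rtol: float = 1e-6,
    dedup_atol: float = 1e-9,
    boundary_tol: float = 1e-3,
    starts_seed: int = 0,
) -> SteadyStateSet:
    """Locate and classify the fixed points of the ODE system.

    Each start is refined by a damped quasi-Newton root iteration
    (Powell hybrid) with the analytic Jacobian.  Roots with components
    below ``-tol_neg`` (relative to scale) are discarded as nonphysical;
    small negative components within tolerance are clamped to zero.
    Converged roots closer than ``dedup_atol + dedup_rtol*scale``
    componentwise are merged.  Finding no root is an empty set, not an
    error.

    Fixed points on the state-space boundary get special care: an interior
    root with components below ``boundary_tol`` is also tested with those
    components clamped to exactly zero, and the clamped point is kept as a
    distinct root when it satisfies the residual tolerance itself.  This
    recovers absorbing branches (e.g. an unstimulated branch with zero
    stimulus) that sit arbitrarily close to interior repellers.
    """
    sys = _OdeSystem.for_network(network)
    theta = params.vector(network)
    if starts is None:
        starts = default_starts(network, seed=starts_seed)

    roots: list[np.ndarray] = []
    for x0 in np.asarray(starts, dtype=float):
        sol = optimize.root(
            lambda x: sys.rhs(x, theta),
            x0,
            jac=lambda x: sys.jacobian(x, theta),
            method="hybr",
            options={"xtol": 1e-12},
        )
        if not sol.success:
            continue
        x = np.asarray(sol.x, dtype=float)
        scale = 1.0 + np.abs(x).max()
        if np.any(x < -tol_neg * scale):
            continue
        x = np.maximum(x, 0.0)
        if np.max(np.abs(sys.rhs(x, theta))) >= tol_residual * scale:
            continue
        candidates = [x]
        near_zero = (x > 0) & (x < boundary_tol)
        if near_zero.any():
            clamped = x.copy()
            clamped[near_zero] = 0.0
            if np.max(np.abs(sys.rhs(clamped, theta))) < tol_residual * scale:
                candidates.append(clamped)
        for cand in candidates:
            merged = False
            for r in roots:
                tol = dedup_atol + dedup_rtol * np.maximum(np.abs(r), np.abs(cand))
                if np.all(np.abs(r - cand) <= tol):
                    merged = True
                    break
            if not merged:
                roots.append(cand)

    out = SteadyStateSet()
    for x in roots:
        lam, stable = classify_stability(network, params, x, tol_eig=tol_eig)
        res = float(np.max(np.abs(sys.rhs(x, theta))))
        out.states.append(SteadyState(state=x, lambda_max=lam, stable=stable, residual=res))
    out.states.sort(key=lambda s: tuple(s.state))
    return out


def check_precondition(
    sss: SteadyStateSet,
    modes: Sequence[float],
    obs: ObservationMap,
    network: ReactionNetwork,
    cfg: PreconditionConfig | None = None,
) -> PreconditionResult:
    """Test whether stable steady states bracket the distribution modes.

    Stable states are mapped to observation units (phi times the sum over
    observable species), sorted ascending and paired index-wise with the
    ascending modes.  The test passes iff the stable count equals the mode
    count and every pair satisfies the relative band.
    """
    cfg = cfg or PreconditionConfig()
    modes = np.sort(np.asarray(modes, dtype=float))
    q = len(modes)
    if q < 1:
        raise ValueError("need at least one mode")
    low, up = cfg.bands(q)

    if sss.n_stable == 0:
        return PreconditionResult(False, "no stable state", 0, q)
    mapped = np.sort([obs.apply_state(network, s.state) for s in sss.stable_states])
    if sss.n_stable != q:
        return PreconditionResult(False, "count mismatch", sss.n_stable, q)
    ok = [
        bool(low[k] * mapped[k] <= modes[k] <= up[k] * mapped[k]) for k in range(q)
    ]
    pairs = list(zip(modes.tolist(), mapped.tolist()))
    if all(ok):
        return PreconditionResult(True, "passed", q, q, pairs, ok)
    return PreconditionResult(False, "out of range", q, q, pairs, ok)
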