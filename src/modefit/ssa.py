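"""Exact stochastic simulation of reaction networks.

Trajectories are statistically exact samples of the continuous-time Markov
jump process defined by the propensities and integer stoichiometry
(direct-method sampling: exponential waiting time at the total rate,
channel chosen proportionally to its propensity).  The inner loop is
JIT-compiled per network; a 48-hour trajectory of the bundled IRF7 circuit
(millions of events) runs in well under a second after warm-up.

Reproducibility contract: every trajectory is determined by its seed, and
ensemble member seeds are derived from ``(base_seed, member_index)`` with
``numpy.random.SeedSequence``, so results do not depend on execution order
and growing an ensemble reproduces its prefix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import ParameterSet, ReactionNetwork


class SimulationError(RuntimeError):
    """Raised when a propensity evaluates non-finite or negative."""


@dataclass(frozen=True)
class TrajectorySample:
    """States (integer copy numbers) of one realization at sample times.

    The recording convention is piecewise-constant interpolation: the state
    reported at t_i is the state immediately before/at t_i (last event time
    <= t_i).
    """

    times: np.ndarray  # (n_times,), minutes, strictly increasing
    states: np.ndarray  # (n_times, n_species), int64
    seed: int


@dataclass(frozen=True)
class Ensemble:
    """ns trajectories sharing times and initial state."""

    times: np.ndarray
    states: np.ndarray  # (ns, n_times, n_species), int64
    base_seed: int

    @property
    def ns(self) -> int:
        return self.states.shape[0]

    def member(self, j: int) -> TrajectorySample:
        return TrajectorySample(self.times, self.states[j], _member_seed(self.base_seed, j))


_KERNELS: dict[int, object] = {}

# kernel exit codes
_OK = 0
_BAD_PROPENSITY = 1


def _build_kernel(network: ReactionNetwork):
    """Compile the direct-method event loop specialized to one network."""
    import numba

    prop = network.compiled_propensity_function()
    n_reactions = network.n_reactions
    # copies of species i consumed by one firing of reaction j; channels
    # lacking the required copies get zero propensity, which keeps every
    # sampled state nonnegative even for rate laws (like the printed
    # quadratic dimerization) that are positive at a single copy
    consumed = np.maximum(0, -network.stoichiometry).astype(np.float64)

    @numba.njit(cache=False)
    def kernel(S, init, params, times, seed):
        n_times = times.shape[0]
        n_species = init.shape[0]
        out = np.empty((n_times, n_species), dtype=np.int64)
        a = np.empty(n_reactions, dtype=np.float64)
        state = init.astype(np.float64)
        np.random.seed(seed)
        t = 0.0
        idx = 0
        bad = -1
        while idx < n_times:
            prop(state, params, a)
            a0 = 0.0
            for j in range(n_reactions):
                aj = a[j]
                if not np.isfinite(aj) or aj < 0.0:
                    bad = j
                    break
                for i in range(n_species):
                    if state[i] < consumed[i, j]:
                        aj = 0.0
                        a[j] = 0.0
                        break
                a0 += aj
            if bad >= 0:
                break
            if a0 <= 0.0:
                # frozen: state persists to the final sample time
                while idx < n_times:
                    for i in range(n_species):
                        out[idx, i] = np.int64(state[i])
                    idx += 1
                break
            tau = -np.log(np.random.random()) / a0
            while idx < n_times and t + tau > times[idx]:
                for i in range(n_species):
                    out[idx, i] = np.int64(state[i])
                idx += 1
            if idx >= n_times:
                break
            t += tau
            r = np.random.random() * a0
            acc = 0.0
            chosen = n_reactions - 1
            for j in range(n_reactions):
                acc += a[j]
                if r <= acc:
                    chosen = j
                    break
            for i in range(n_species):
                state[i] += S[i, chosen]
        return out, bad

    return kernel


def _kernel_for(network: ReactionNetwork):
    key = id(network)
    if key not in _KERNELS:
        _KERNELS[key] = _build_kernel(network)
    return _KERNELS[key]


def _member_seed(base_seed: int, j: int) -> int:
    return int(np.random.SeedSequence([base_seed, j]).generate_state(1, np.uint32)[0])


def _check_inputs(network, init, times):
    init = np.asarray(init, dtype=np.float64)
    if init.shape != (network.n_species,):
        raise ValueError(f"init has shape {init.shape}, expected ({network.n_species},)")
    if np.any(init < 0) or np.any(init != np.floor(init)):
        raise ValueError("initial state must be nonnegative integers")
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("need at least one sample time")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("sample times must be nonnegative and strictly increasing")
    return init, times


def simulate_trajectory(
    network: ReactionNetwork,
    params: ParameterSet,
    init: Sequence[float],
    times: Sequence[float],
    seed: int,
) -> TrajectorySample:
    """One exact realization of the jump process, sampled at ``times``."""
    init, times = _check_inputs(network, init, times)
    theta = params.vector(network) if isinstance(params, ParameterSet) else ParameterSet(params).vector(network)
    kernel = _kernel_for(network)
    states, bad = kernel(network.stoichiometry, init, theta, times, np.uint32(seed))
    if bad >= 0:
        raise SimulationError(
            f"non-finite or negative propensity in reaction "
            f"{network.reactions[bad].name!r}"
        )
    return TrajectorySample(times=times, states=states, seed=int(seed))


def simulate_ensemble(
    network: ReactionNetwork,
    params: ParameterSet,
    init: Sequence[float],
    times: Sequence[float],
    ns: int,
    base_seed: int,
) -> Ensemble:
    """ns independent trajectories with order-independent member seeds."""
    if ns < 1:
        raise ValueError("ns must be >= 1")
    init, times = _check_inputs(network, init, times)
    theta = params.vector(network) if isinstance(params, ParameterSet) else ParameterSet(params).vector(network)
    kernel = _kernel_for(network)
    S = network.stoichiometry
    states = np.empty((ns, len(times), network.n_species), dtype=np.int64)
    for j in range(ns):
        member_states, bad = kernel(S, init, theta, times, np.uint32(_member_seed(base_seed, j)))
        if bad >= 0:
            raise SimulationError(
                f"member {j}: non-finite or negative propensity in reaction "
                f"{network.reactions[bad].name!r}"
            )
        states[j] = member_states
    return Ensemble(times=times, states=states, base_seed=int(base_seed))


def trajectory_to_csv(sample: TrajectorySample, network: ReactionNetwork, path) -> None:
    """Dump one trajectory as CSV (time column plus one column per species)."""
    import pandas as pd

    df = pd.DataFrame(sample.states, columns=network.species_names)
    df.insert(0, "time_min", sample.times)
    df.to_csv(path, index=False)
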