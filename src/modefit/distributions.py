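"""Histograms, mode finding and the distribution-matching objective.

Measured single-cell data and simulated ensembles are reduced to binned
probability mass functions on a shared grid per measurement time: the
experimental data fixes equal-width bin edges spanning its own range, the
bin count is ``round(sqrt(nm))`` from the experimental sample size, and
simulated values falling outside the range are clipped into the terminal
bins.  The fit objective is the summed squared difference of the paired
masses over all times and bins; its conditional form first runs the
deterministic precondition and only simulates when the filter passes,
otherwise returning a large penalty without any stochastic work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .deterministic import (
    PreconditionConfig,
    PreconditionResult,
    check_precondition,
    find_steady_states,
)
from .models import ObservationMap, ParameterSet, ReactionNetwork
from .ssa import Ensemble, SimulationError, simulate_ensemble


logger = logging.getLogger("modefit")


class InputError(ValueError):
    """Raised for malformed or mismatched distribution inputs."""


@dataclass(frozen=True)
class EventTable:
    """Per-cell observable values (a.u.) at each measurement time."""

    times: np.ndarray  # (n,), minutes
    values: tuple[np.ndarray, ...]  # one array of per-cell values per time

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise InputError("one value list per time point required")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        for t, v in zip(self.times, self.values):
            if len(v) < 2:
                raise InputError(f"need >= 2 events at t={t}")
            if not np.all(np.isfinite(v)):
                raise InputError(f"non-finite event values at t={t}")

    @property
    def nm(self) -> int:
        """Events per time point (minimum over times)."""
        return min(len(v) for v in self.values)

    @property
    def final_time(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class BinnedDistributionSet:
    """Normalized histogram (probability mass per bin) per time point."""

    times: np.ndarray
    edges: tuple[np.ndarray, ...]  # (L+1,) per time, strictly increasing
    masses: tuple[np.ndarray, ...]  # (L,) per time, sums to 1
    degenerate: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        for e, m in zip(self.edges, self.masses):
            if np.any(np.diff(e) <= 0):
                raise InputError("bin edges must be strictly increasing")
            if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-12:
                raise InputError("masses must be nonnegative and sum to 1")
        if len({len(m) for m in self.masses}) != 1:
            raise InputError("same bin count required at all time points")

    @property
    def L(self) -> int:
        return len(self.masses[0])

    def centers(self, i: int) -> np.ndarray:
        e = self.edges[i]
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class ModeSet:
    """Ascending mode locations of the final-time distribution."""

    locations: np.ndarray  # (q,), a.u.; bin centers of the source distribution
    prominences: np.ndarray

    @property
    def q(self) -> int:
        return len(self.locations)


def apply_observation(ensemble: Ensemble, obs: ObservationMap, network: ReactionNetwork) -> list[np.ndarray]:
    """Map ensemble states to observable values per time point.

    Returns one array of ``ns`` values per sample time:
    ``phi * sum(observable copy numbers)``.
    """
    idx = obs.indices(network)
    mapped = obs.scale * ensemble.states[:, :, idx].sum(axis=2).astype(np.float64)
    return [mapped[:, i] for i in range(len(ensemble.times))]


def bin_count(nm: int) -> int:
    """Square-root bin-count rule with a floor of 2 bins."""
    if nm < 2:
        raise InputError("need at least 2 events to bin")
    return max(2, int(round(np.sqrt(nm))))


def build_distributions(
    times: Sequence[float],
    values_per_time: Sequence[np.ndarray],
    L: int,
    edges: Sequence[np.ndarray] | None = None,
) -> BinnedDistributionSet:
    """Equal-width normalized histograms with ``L`` bins per time point.

    When ``edges`` (the reference/experimental grid) is given, values are
    clipped into its range so outliers land in the terminal bins.  A
    zero-range time point yields a degenerate single-support distribution,
    flagged via ``degenerate``.
    """
    if L < 2:
        raise InputError("L must be >= 2")
    out_edges, out_masses, out_degenerate = [], [], []
    for i, v in enumerate(values_per_time):
        v = np.asarray(v, dtype=float)
        if edges is not None:
            e = np.asarray(edges[i], dtype=float)
            if len(e) != L + 1:
                raise InputError("edges do not match L")
            v = np.clip(v, e[0], e[-1])
            degenerate = False
        else:
            lo, hi = float(v.min()), float(v.max())
            degenerate = hi == lo
            if degenerate:
                lo, hi = lo - 0.5, hi + 0.5
            e = np.linspace(lo, hi, L + 1)
        counts, _ = np.histogram(v, bins=e)
        out_edges.append(e)
        out_masses.append(counts / counts.sum())
        out_degenerate.append(degenerate)
    return BinnedDistributionSet(
        times=np.asarray(times, dtype=float),
        edges=tuple(out_edges),
        masses=tuple(out_masses),
        degenerate=tuple(out_degenerate),
    )


def distributions_from_events(data: EventTable, L: int | None = None) -> BinnedDistributionSet:
    """Experimental PDFs with the square-root bin rule on the data's range."""
    if L is None:
        L = bin_count(data.nm)
    return build_distributions(data.times, data.values, L)


def find_modes(
    dist: BinnedDistributionSet,
    min_prominence: float = 0.05,
    min_separation_bins: int = 3,
    smooth_bins: int = 5,
    time_index: int = -1,
) -> ModeSet:
    """Local maxima of the binned final-time mass sequence.

    Peaks are detected on a centered moving average (``smooth_bins`` bins)
    of the mass sequence, which suppresses the sampling noise of
    square-root-rule histograms that would otherwise read as spurious
    shoulder modes; each detected peak is then refined to the raw-mass
    argmax within the smoothing half-window, so narrow skewed peaks are
    not dragged by the averaging.  Peaks must exceed a prominence of
    ``min_prominence * max(smoothed mass)`` and be at least
    ``min_separation_bins`` bins apart; boundary bins can be modes (the
    sequence is zero-padded before both steps).  Mode locations are bin
    centers of the source grid.  Raises if no peak qualifies or the
    distribution is degenerate.
    """
    i = range(len(dist.times))[time_index]
    if dist.degenerate and dist.degenerate[i]:
        raise InputError("cannot find modes of a degenerate distribution")
    m = dist.masses[i]
    w = max(1, min(smooth_bins, len(m)))
    pad = w // 2 + 1
    padded = np.concatenate([np.zeros(pad), m, np.zeros(pad)])
    smoothed = np.convolve(padded, np.ones(w) / w, mode="same")
    peaks, props = find_peaks(
        smoothed,
        prominence=min_prominence * smoothed.max(),
        distance=max(1, min_separation_bins),
    )
    inside = (peaks >= pad) & (peaks < pad + len(m))
    peaks = peaks[inside]
    if len(peaks) == 0:
        raise InputError("no mode found")
    half = w // 2
    refined, prominences = [], []
    for p, prom in zip(peaks - pad, props["prominences"][inside]):
        lo, hi = max(0, p - half), min(len(m), p + half + 1)
        j = lo + int(np.argmax(m[lo:hi]))
        if j not in refined:
            refined.append(j)
            prominences.append(prom)
    centers = dist.centers(i)
    locations = centers[np.array(refined)]
    prominences = np.array(prominences)
    order = np.argsort(locations)
    return ModeSet(locations=locations[order], prominences=prominences[order])


def objective_F(P_e: BinnedDistributionSet, P_s: BinnedDistributionSet) -> float:
    """Summed squared difference of paired bin masses over times and bins."""
    if len(P_e.times) != len(P_s.times) or P_e.L != P_s.L:
        raise InputError("distribution sets must share times and bin count")
    total = 0.0
    for i in range(len(P_e.times)):
        if not np.allclose(P_e.edges[i], P_s.edges[i], rtol=1e-9, atol=1e-9):
            raise InputError(f"bin edges differ at time index {i}")
        d = P_e.masses[i] - P_s.masses[i]
        total += float(d @ d)
    return total


@dataclass
class FcondConfig:
    """Everything the conditional objective needs besides the data.

    ``ns`` is the ensemble size per accepted parameter set; the observation
    map and initial state default to the network's bundled ones.
    """

    ns: int = 1000
    precondition: PreconditionConfig = field(default_factory=PreconditionConfig)
    observation: ObservationMap | None = None
    initial_state: np.ndarray | None = None
    mode_min_prominence: float = 0.05
    mode_min_separation_bins: int = 3

    def obs_for(self, network: ReactionNetwork) -> ObservationMap:
        obs = self.observation or network.observation
        if obs is None:
            raise InputError("no observation map configured")
        return obs

    def init_for(self, network: ReactionNetwork) -> np.ndarray:
        if self.initial_state is not None:
            return np.asarray(self.initial_state, dtype=float)
        return network.default_initial_state


def objective_Fcond(
    network: ReactionNetwork,
    params: ParameterSet,
    data: EventTable,
    modes: ModeSet | Sequence[float],
    cfg: FcondConfig | None = None,
    seed: int = 0,
    data_pdfs: BinnedDistributionSet | None = None,
) -> tuple[float, PreconditionResult, dict]:
    """Precondition-gated objective for one parameter set.

    Runs steady-state location + stability + the mode-bracketing test; on
    failure returns the penalty without any stochastic simulation.  On a
    pass, simulates an ``ns``-member ensemble at the data's sample times,
    maps it through the observation and scores the squared-difference
    objective on the experimental grid.  SSA failures are also converted to
    the penalty (with a diagnostic) so optimizers keep running.

    Returns ``(value, precondition_result, diagnostics)``; diagnostics
    record the number of stochastic runs performed and any error.
    """
    cfg = cfg or FcondConfig()
    obs = cfg.obs_for(network)
    mode_locs = modes.locations if isinstance(modes, ModeSet) else np.asarray(modes, float)

    sss = find_steady_states(
        network,
        params,
        tol_residual=cfg.precondition.tol_residual,
        tol_eig=cfg.precondition.tol_eig,
    )
    pre = check_precondition(sss, mode_locs, obs, network, cfg.precondition)
    diagnostics: dict = {"n_ssa_runs": 0, "n_stable": sss.n_stable, "error": None}
    theta_tag = hash(tuple(sorted(params.items()))) & 0xFFFFFF
    if not pre.passed:
        logger.info(
            "theta=%06x precondition=rejected reason=%r value=penalty",
            theta_tag,
            pre.reason,
        )
        return float(cfg.precondition.penalty), pre, diagnostics

    if data_pdfs is None:
        data_pdfs = distributions_from_events(data)
    try:
        ens = simulate_ensemble(
            network, params, cfg.init_for(network), data.times, cfg.ns, base_seed=seed
        )
    except SimulationError as exc:
        diagnostics["error"] = str(exc)
        return float(cfg.precondition.penalty), pre, diagnostics
    diagnostics["n_ssa_runs"] = cfg.ns
    sim_values = apply_observation(ens, obs, network)
    sim_pdfs = build_distributions(data.times, sim_values, data_pdfs.L, edges=data_pdfs.edges)
    value = objective_F(data_pdfs, sim_pdfs)
    logger.info("theta=%06x precondition=passed value=%.6g ns=%d", theta_tag, value, cfg.ns)
    return value, pre, diagnostics
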