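"""Stochastic generation of two-channel fluorescence trajectories.

Latent state dynamics are continuous-time Markov chains realized exactly
(Gillespie algorithm).  State paths are rendered into donor/acceptor
intensity traces with exact time-weighted frame integration, Gaussian
detection noise and single-step acceptor photobleaching (dark E~0 state).

Two model builders cover the two experiment geometries:

* :func:`build_nucleation_model` -- two states (``unbound`` <-> ``nucleated``),
  the nucleating multimer binding/unbinding as one atomic kinetic step.
* :func:`build_end_dynamics_model` -- linear occupancy chain
  ``M0 <-> M1 <-> M2`` with concentration-scaled binding steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StatePath",
    "RateModel",
    "EmissionModel",
    "SimulationParams",
    "TimeTrace",
    "simulate_state_path",
    "build_nucleation_model",
    "build_end_dynamics_model",
    "render_intensities",
    "simulate_experiment",
    "trace_rng",
    "DEFAULT_FRAME_TIME",
    "DEFAULT_TOTAL_INTENSITY",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BLEACH_RATE",
    "NUCLEATION_FRET_LEVELS",
    "END_DYNAMICS_FRET_LEVELS",
]

DEFAULT_FRAME_TIME = 0.1  # s
DEFAULT_TOTAL_INTENSITY = 500.0  # counts / frame
DEFAULT_NOISE_SD = 25.0  # counts
DEFAULT_BLEACH_RATE = 0.005  # s^-1, acceptor photobleaching

NUCLEATION_FRET_LEVELS = {"unbound": 0.7, "nucleated": 0.2}
END_DYNAMICS_FRET_LEVELS = {"M0": 0.7, "M1": 0.5, "M2": 0.3}

_TIME_ATOL = 1e-9


@dataclass(frozen=True)
class StatePath:
    """Piecewise-constant latent trajectory.

    ``segments`` is an ordered tuple of ``(state_label, start_s, duration_s)``;
    segments are contiguous, non-overlapping, with positive durations summing
    to ``total_duration`` and no two consecutive segments in the same state.
    """

    segments: tuple[tuple[str, float, float], ...]
    total_duration: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("StatePath needs at least one segment")
        t = 0.0
        prev_state = None
        for state, start, duration in self.segments:
            if duration <= 0:
                raise ValueError(f"non-positive segment duration {duration!r}")
            if abs(start - t) > _TIME_ATOL * max(1.0, abs(t)):
                raise ValueError("segments are not contiguous")
            if state == prev_state:
                raise ValueError("consecutive segments share a state")
            prev_state = state
            t = start + duration
        if abs(t - self.total_duration) > 1e-6 * max(1.0, self.total_duration):
            raise ValueError("segment durations do not sum to total_duration")

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.segments)

    def occupancy_time(self) -> dict[str, float]:
        """Total time spent in each state over the whole path."""
        occ: dict[str, float] = {}
        for state, _, duration in self.segments:
            occ[state] = occ.get(state, 0.0) + duration
        return occ

    def state_at(self, t: float) -> str:
        if not 0 <= t <= self.total_duration:
            raise ValueError("time outside path")
        for state, start, duration in self.segments:
            if t < start + duration:
                return state
        return self.segments[-1][0]

    def truncated(self, t: float) -> "StatePath":
        """Path restricted to [0, t)."""
        if t <= 0 or t > self.total_duration:
            raise ValueError("truncation time outside (0, total_duration]")
        kept = []
        for state, start, duration in self.segments:
            if start >= t:
                break
            kept.append((state, start, min(duration, t - start)))
        return StatePath(tuple(kept), t)


@dataclass
class RateModel:
    """First-order transition rates between a finite set of labelled states.

    ``rates`` maps ``(from_state, to_state)`` to a rate in s^-1 (already at
    the working concentration).  ``concentration_scaled`` records which
    transitions were scaled by the RecA concentration when the model was
    built, for introspection only.
    """

    states: tuple[str, ...]
    rates: dict[tuple[str, str], float]
    concentration_scaled: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        for (a, b), r in self.rates.items():
            if a not in self.states or b not in self.states:
                raise ValueError(f"transition {a}->{b} uses unknown state")
            if a == b:
                raise ValueError("self-transition rates are not allowed")
            if not math.isfinite(r) or r < 0:
                raise ValueError(f"rate({a},{b})={r!r} must be finite and >= 0")

    def transitions_from(self, state: str) -> list[tuple[str, float]]:
        return [(b, r) for (a, b), r in self.rates.items() if a == state and r > 0]

    def exit_rate(self, state: str) -> float:
        return sum(r for _, r in self.transitions_from(state))

    def generator_matrix(self) -> np.ndarray:
        """Infinitesimal generator Q with rows summing to zero."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for (a, b), r in self.rates.items():
            q[idx[a], idx[b]] = r
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Solve pi Q = 0, sum(pi) = 1 (least squares; exact for irreducible chains)."""
        q = self.generator_matrix()
        n = len(self.states)
        a = np.vstack([q.T, np.ones((1, n))])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass(frozen=True)
class EmissionModel:
    """Maps latent states to two-channel photon counts per frame."""

    mean_fret: Mapping[str, float]
    total_intensity: float = DEFAULT_TOTAL_INTENSITY
    noise_sd: float = DEFAULT_NOISE_SD
    bleach_rate: float = DEFAULT_BLEACH_RATE
    background: float = 0.0

    def __post_init__(self) -> None:
        for s, e in self.mean_fret.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"mean_fret[{s!r}]={e!r} outside [0, 1]")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Everything needed to regenerate one experiment deterministically."""

    rate_model: RateModel
    emission_model: EmissionModel
    reca_concentration: float = 1.0  # uM
    frame_time: float = DEFAULT_FRAME_TIME
    n_molecules: int = 100
    trace_duration: float = 100.0
    seed: int = 0
    initial_state: str | None = "stationary"
    donor_only_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.trace_duration < self.frame_time:
            raise ValueError("trace_duration must be >= frame_time")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 0.0 <= self.donor_only_fraction <= 1.0:
            raise ValueError("donor_only_fraction must be in [0, 1]")


@dataclass
class TimeTrace:
    """Per-frame donor/acceptor intensities for one molecule."""

    trace_id: str
    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float
    ground_truth: StatePath | None = None
    bleach_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.times) == len(self.donor) == len(self.acceptor)):
            raise ValueError("times/donor/acceptor length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, self.frame_time, rtol=1e-6):
                raise ValueError("times must increase with constant spacing frame_time")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.times)


def trace_rng(seed: int, trace_index: int) -> np.random.Generator:
    """Deterministic per-trace substream derived from (seed, trace_index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(trace_index)]))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    rate_model: RateModel,
    duration: float,
    seed,
    initial_state: str | None = None,
) -> StatePath:
    """Exact stochastic realization of the continuous-time Markov chain.

    Dwell time in each state is exponential with its total exit rate; the
    next state is chosen with probability proportional to its rate.  A state
    with zero exit rate is absorbing.  ``seed`` may be an int or a
    ``numpy.random.Generator`` (consumed in place).
    """
    if not math.isfinite(duration) or duration <= 0:
        raise ValueError("duration must be finite and > 0")
    rng = _as_rng(seed)
    state = initial_state if initial_state is not None else rate_model.states[0]
    if state not in rate_model.states:
        raise ValueError(f"unknown initial state {state!r}")

    segments: list[tuple[str, float, float]] = []
    t = 0.0
    while t < duration:
        exits = rate_model.transitions_from(state)
        total = sum(r for _, r in exits)
        if total <= 0:
            segments.append((state, t, duration - t))
            break
        dwell = rng.exponential(1.0 / total)
        end = min(t + dwell, duration)
        segments.append((state, t, end - t))
        if end >= duration:
            break
        u = rng.random() * total
        acc = 0.0
        for target, r in exits:
            acc += r
            if u < acc:
                state = target
                break
        t = end
    return StatePath(tuple(segments), duration)


def build_nucleation_model(k_nuc: float, k_disassembly: float) -> RateModel:
    """Two-state scheme: bare strand <-> nucleated cluster.

    The multimeric cluster binds and unbinds as a single kinetic step, as
    resolved at 0.1 s framing, so ``k_nuc`` is an aggregate per-molecule
    nucleation rate at fixed solution conditions (s^-1).
    """
    if k_nuc < 0 or k_disassembly < 0:
        raise ValueError("rates must be >= 0")
    return RateModel(
        states=("unbound", "nucleated"),
        rates={
            ("unbound", "nucleated"): float(k_nuc),
            ("nucleated", "unbound"): float(k_disassembly),
        },
    )


def build_end_dynamics_model(
    k_on: float, k_off: float, reca_concentration: float
) -> RateModel:
    """Linear occupancy chain M0 <-> M1 <-> M2 at the probed filament end.

    Each binding step proceeds at ``k_on * [RecA]`` and each dissociation at
    ``k_off``; no direct M0 <-> M2 transitions (single-monomer resolution).
    """
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be >= 0")
    if reca_concentration < 0:
        raise ValueError("concentration must be >= 0")
    kb = float(k_on) * float(reca_concentration)
    return RateModel(
        states=("M0", "M1", "M2"),
        rates={
            ("M0", "M1"): kb,
            ("M1", "M2"): kb,
            ("M1", "M0"): float(k_off),
            ("M2", "M1"): float(k_off),
        },
        concentration_scaled=frozenset({("M0", "M1"), ("M1", "M2")}),
    )


def _frame_mean_fret(
    path: StatePath,
    levels: Mapping[str, float],
    frame_time: float,
    n_frames: int,
    bleach_time: float,
) -> np.ndarray:
    """Exact time-weighted mean FRET per frame, with FRET -> 0 after bleach."""
    starts = np.array([s for _, s, _ in path.segments])
    durs = np.array([d for _, _, d in path.segments])
    lv = np.array([levels[state] for state, _, _ in path.segments])
    knots = np.concatenate([starts, [path.total_duration]])
    cum = np.concatenate([[0.0], np.cumsum(lv * durs)])
    edges = np.arange(n_frames + 1) * frame_time
    # FRET contribution stops accruing at the bleach time (dark E=0 after).
    eff_edges = np.minimum(edges, bleach_time)
    cum_at_edges = np.interp(eff_edges, knots, cum)
    return np.diff(cum_at_edges) / frame_time


def render_intensities(
    path: StatePath,
    emission: EmissionModel,
    frame_time: float,
    seed,
    trace_id: str = "trace0",
) -> TimeTrace:
    """Render a latent path into a noisy two-channel intensity trace.

    Per frame the true FRET is the time-weighted mean of the state FRET
    levels across the frame.  Acceptor = I*E + background + noise, donor =
    I*(1-E) + background + noise.  After an exponentially distributed
    acceptor bleach time the trace emits E~0 (dark state).
    """
    if frame_time <= 0:
        raise ValueError("frame_time must be > 0")
    n_frames = int(math.floor(path.total_duration / frame_time + 1e-9))
    if n_frames < 1:
        raise ValueError("path shorter than one frame")
    rng = _as_rng(seed)
    bleach = math.inf
    if emission.bleach_rate > 0:
        bleach = rng.exponential(1.0 / emission.bleach_rate)

    mean_e = _frame_mean_fret(path, emission.mean_fret, frame_time, n_frames, bleach)
    itot = emission.total_intensity
    acceptor = itot * mean_e + emission.background
    donor = itot * (1.0 - mean_e) + emission.background
    if emission.noise_sd > 0:
        donor = donor + rng.normal(0.0, emission.noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, emission.noise_sd, n_frames)
    return TimeTrace(
        trace_id=trace_id,
        times=np.arange(n_frames) * frame_time,
        donor=donor,
        acceptor=acceptor,
        frame_time=frame_time,
        ground_truth=path,
        bleach_time=None if math.isinf(bleach) else bleach,
    )


def simulate_experiment(params: SimulationParams) -> list[TimeTrace]:
    """Generate ``n_molecules`` labelled traces, bit-reproducible per seed.

    Each trace uses an independent substream derived from
    ``(params.seed, trace_index)`` so any subset regenerates identically.
    ``initial_state="stationary"`` draws the starting state from the chain's
    stationary distribution (molecules are in steady state when imaging
    starts); a state label pins it; ``None`` uses the first model state.
    A ``donor_only_fraction`` of molecules is rendered with a dark acceptor
    (E~0) to emulate donor-only contaminants.
    """
    model = params.rate_model
    stationary = None
    if params.initial_state == "stationary":
        stationary = model.stationary_distribution()
    traces = []
    dark_emission = replace(
        params.emission_model,
        mean_fret={s: 0.0 for s in params.emission_model.mean_fret},
    )
    for i in range(params.n_molecules):
        rng = trace_rng(params.seed, i)
        donor_only = rng.random() < params.donor_only_fraction
        if stationary is not None:
            init = model.states[rng.choice(len(model.states), p=stationary)]
        else:
            init = params.initial_state
        path = simulate_state_path(model, params.trace_duration, rng, initial_state=init)
        emission = dark_emission if donor_only else params.emission_model
        traces.append(
            render_intensities(
                path, emission, params.frame_time, rng, trace_id=f"mol{i:05d}"
            )
        )
    return traces
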