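"""Kinetic quantities from idealized trajectories.

Dwell-time sets with censoring, exponential lifetime fits, nucleation
frequency, transition density plots, per-condition binding/dissociation
rate constants and the net filament growth rate.

Rates are estimated with the exact continuous-time Markov chain estimator:
transition counts divided by occupancy time of the source state.  The first
and last segment of every trace are flagged censored (their true duration
is cut by the observation window or by photobleaching) and excluded from
exponential dwell fits; occupancy-time exposure keeps all segments, which
is the unbiased count/exposure maximum-likelihood estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hmm import IdealizedTrace

__all__ = [
    "DwellSet",
    "Transition",
    "TransitionSet",
    "TDP",
    "KineticRates",
    "NucleationStats",
    "SequenceCondition",
    "extract_dwells",
    "pool_dwells",
    "fit_exponential_dwell",
    "collect_transitions",
    "build_tdp",
    "estimate_rates",
    "nucleation_kinetics",
    "growth_rate",
]


@dataclass
class DwellSet:
    """Dwell durations per state with first/last-segment censoring flags."""

    condition: str | None
    states: np.ndarray  # state index per dwell
    durations: np.ndarray  # s
    censored: np.ndarray  # bool
    trace_ids: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be > 0")

    def __len__(self) -> int:
        return len(self.durations)

    def uncensored(self, state: int | None = None) -> np.ndarray:
        keep = ~self.censored
        if state is not None:
            keep &= self.states == state
        return self.durations[keep]


@dataclass(frozen=True)
class Transition:
    trace_id: str
    time: float
    e_before: float
    e_after: float
    state_before: int
    state_after: int


@dataclass
class TransitionSet:
    records: list[Transition]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.state_before == r.state_after:
                raise ValueError("transition must change state")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_molecules(self) -> int:
        return len({r.trace_id for r in self.records})


@dataclass
class TDP:
    """2D histogram of (E before, E after) over all decoded transitions."""

    bin_edges: np.ndarray
    counts: np.ndarray  # shape (n_bins, n_bins), [before, after]
    n_transitions: int
    n_molecules: int

    def populated_clusters(self, min_count: int = 1) -> list[tuple[float, float, int]]:
        """Connected off-diagonal clusters as (E_before, E_after, count).

        Bins closer than one bin width in both coordinates are merged, so a
        transition class split across adjacent bins counts as one cluster.
        """
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        ij = np.argwhere(self.counts >= min_count)
        clusters: list[list[tuple[int, int]]] = []
        for i, j in ij:
            placed = False
            for cl in clusters:
                if any(abs(i - a) <= 1 and abs(j - b) <= 1 for a, b in cl):
                    cl.append((i, j))
                    placed = True
                    break
            if not placed:
                clusters.append([(i, j)])
        # merge transitively-overlapping clusters
        merged = True
        while merged:
            merged = False
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    if any(
                        abs(i1 - i2) <= 1 and abs(j1 - j2) <= 1
                        for i1, j1 in clusters[a]
                        for i2, j2 in clusters[b]
                    ):
                        clusters[a] += clusters.pop(b)
                        merged = True
                        break
                if merged:
                    break
        out = []
        for cl in clusters:
            w = np.array([self.counts[i, j] for i, j in cl], dtype=float)
            ii = np.array([i for i, _ in cl])
            jj = np.array([j for _, j in cl])
            out.append(
                (
                    float(np.average(centers[ii], weights=w)),
                    float(np.average(centers[jj], weights=w)),
                    int(w.sum()),
                )
            )
        return sorted(out, key=lambda c: -c[2])


@dataclass
class KineticRates:
    """Per-condition monomer binding/dissociation rate constants."""

    condition: str
    k_on: float  # uM^-1 s^-1
    k_on_err: float
    k_off: float  # s^-1
    k_off_err: float
    reca_concentration: float  # uM
    n_binding: int
    n_dissociation: int
    binding_exposure_s: float
    dissociation_exposure_s: float
    n_skipped: int = 0  # decoded multi-step jumps, excluded

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if self.k_on_err < 0 or self.k_off_err < 0:
            raise ValueError("errors must be >= 0")


@dataclass
class NucleationStats:
    condition: str | None
    tau_s: float  # mean nucleated-state lifetime; NaN when no events
    tau_err_s: float
    f_nuc: float  # nucleation events per second of unbound time
    f_nuc_err: float
    n_events: int
    unbound_time_s: float


@dataclass(frozen=True)
class SequenceCondition:
    label: str
    atpase_rate: float  # arbitrary consistent per-time units
    reca_concentration: float  # uM

    def __post_init__(self) -> None:
        if self.atpase_rate < 0:
            raise ValueError("atpase_rate must be >= 0")


def extract_dwells(
    ideal: IdealizedTrace, condition: str | None = None
) -> DwellSet:
    """One dwell per segment; first and last segments flagged censored."""
    n = ideal.n_segments
    states, durations, censored, ids = [], [], [], []
    for i, (state, _, duration, _) in enumerate(ideal.segments):
        states.append(state)
        durations.append(duration)
        censored.append(i == 0 or i == n - 1)
        ids.append(ideal.trace_id)
    return DwellSet(
        condition=condition,
        states=np.array(states, dtype=int),
        durations=np.array(durations),
        censored=np.array(censored, dtype=bool),
        trace_ids=ids,
    )


def pool_dwells(dwell_sets: Iterable[DwellSet], condition: str | None = None) -> DwellSet:
    sets = list(dwell_sets)
    if not sets:
        return DwellSet(condition, np.array([], int), np.array([]), np.array([], bool), [])
    return DwellSet(
        condition=condition,
        states=np.concatenate([s.states for s in sets]),
        durations=np.concatenate([s.durations for s in sets]),
        censored=np.concatenate([s.censored for s in sets]),
        trace_ids=[t for s in sets for t in s.trace_ids],
    )


def fit_exponential_dwell(
    dwells: DwellSet | np.ndarray, state: int | None = None, min_n: int = 5
) -> tuple[float, float, int]:
    """Maximum-likelihood exponential lifetime of uncensored dwells.

    The MLE of the exponential mean is the sample mean; the standard error
    is tau / sqrt(n).  Returns ``(tau, stderr, n)``.
    """
    if isinstance(dwells, DwellSet):
        durations = dwells.uncensored(state)
    else:
        durations = np.asarray(dwells, dtype=float)
    n = len(durations)
    if n < min_n:
        raise ValueError(f"need >= {min_n} uncensored dwells, got {n}")
    tau = float(durations.mean())
    return tau, tau / math.sqrt(n), n


def collect_transitions(ideals: Sequence[IdealizedTrace]) -> TransitionSet:
    """All decoded state changes, with E coordinates at the state means."""
    records = []
    for ideal in ideals:
        for prev, nxt in zip(ideal.segments[:-1], ideal.segments[1:]):
            records.append(
                Transition(
                    trace_id=ideal.trace_id,
                    time=nxt[1],
                    e_before=prev[3],
                    e_after=nxt[3],
                    state_before=prev[0],
                    state_after=nxt[0],
                )
            )
    return TransitionSet(records)


def build_tdp(transitions: TransitionSet, bin_width: float = 0.02) -> TDP:
    """2D transition density histogram on [0, 1]^2.

    Coordinates are the decoded state emission means, so each transition
    class lands in a sharp cluster; the diagonal is empty by construction.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if len(transitions) == 0:
        return TDP(edges, np.zeros((n_bins, n_bins), dtype=int), 0, 0)
    eb = np.clip([r.e_before for r in transitions.records], 0.0, 1.0)
    ea = np.clip([r.e_after for r in transitions.records], 0.0, 1.0)
    counts, _, _ = np.histogram2d(eb, ea, bins=[edges, edges])
    return TDP(edges, counts.astype(int), len(transitions), transitions.n_molecules)


def _occupancy_rank(ideals: Sequence[IdealizedTrace]) -> dict[int, int]:
    """Map decoded state index -> occupancy level (0 = unbound, highest E)."""
    means: dict[int, float] = {}
    for ideal in ideals:
        for state, _, _, mean_e in ideal.segments:
            means[state] = mean_e
    order = sorted(means, key=lambda s: -means[s])  # descending E
    return {state: level for level, state in enumerate(order)}


def estimate_rates(
    ideals: Sequence[IdealizedTrace], condition: SequenceCondition
) -> KineticRates:
    """Binding/dissociation rate constants from decoded trajectories.

    Decoded states are ranked by emission mean (descending E = increasing
    monomer occupancy).  Occupancy +1 steps are binding events, pooled over
    all source levels and divided by source-state exposure time and the
    RecA concentration to give k_on; -1 steps pooled the same way give
    k_off.  Multi-level jumps (decoder artifacts) are excluded and counted.
    Errors are counting statistics (sqrt(N) on the event count).  Dark-state
    frames must have been removed upstream (photobleach truncation).
    """
    rank = _occupancy_rank(ideals)
    if len(rank) < 2:
        raise ValueError("need at least two occupied states to estimate rates")
    max_level = max(rank.values())
    occupancy = np.zeros(max_level + 1)
    n_bind = n_diss = n_skip = 0
    for ideal in ideals:
        for state, _, duration, _ in ideal.segments:
            occupancy[rank[state]] += duration
        for prev, nxt in zip(ideal.segments[:-1], ideal.segments[1:]):
            step = rank[nxt[0]] - rank[prev[0]]
            if step == 1:
                n_bind += 1
            elif step == -1:
                n_diss += 1
            else:
                n_skip += 1
    if n_bind + n_diss == 0:
        raise ValueError("no transitions observed")
    bind_exposure = float(occupancy[:-1].sum())  # levels that can still bind
    diss_exposure = float(occupancy[1:].sum())  # levels that can dissociate
    if bind_exposure <= 0 or diss_exposure <= 0:
        raise ValueError("zero exposure time for a transition class")
    conc = condition.reca_concentration
    if conc <= 0:
        raise ValueError("RecA concentration must be > 0 to report k_on")
    k_on = n_bind / bind_exposure / conc
    k_off = n_diss / diss_exposure
    return KineticRates(
        condition=condition.label,
        k_on=k_on,
        k_on_err=math.sqrt(n_bind) / bind_exposure / conc if n_bind else 0.0,
        k_off=k_off,
        k_off_err=math.sqrt(n_diss) / diss_exposure if n_diss else 0.0,
        reca_concentration=conc,
        n_binding=n_bind,
        n_dissociation=n_diss,
        binding_exposure_s=bind_exposure,
        dissociation_exposure_s=diss_exposure,
        n_skipped=n_skip,
    )


def nucleation_kinetics(
    ideals: Sequence[IdealizedTrace],
    condition: str | None = None,
    unbound_state: int | None = None,
) -> NucleationStats:
    """Nucleation frequency and nucleated-cluster lifetime.

    The unbound state is the decoded state with the highest emission mean
    (bare strand) unless given explicitly.  Both quantities use the
    unbiased count/exposure estimator: frequency is nucleation events per
    second of total observed unbound time, and the lifetime is total
    nucleated-state time over the number of observed disassembly exits
    (plain uncensored-mean fits suffer right-truncation bias when the
    lifetime is comparable to the observation window).
    """
    rank = _occupancy_rank(ideals)
    if not rank:
        raise ValueError("no segments in input")
    if unbound_state is None:
        unbound_state = next(s for s, lvl in rank.items() if lvl == 0)

    unbound_time = 0.0
    nucleated_time = 0.0
    n_events = 0
    n_exits = 0
    for ideal in ideals:
        for state, _, duration, _ in ideal.segments:
            if state == unbound_state:
                unbound_time += duration
            else:
                nucleated_time += duration
        for prev, nxt in zip(ideal.segments[:-1], ideal.segments[1:]):
            if prev[0] == unbound_state and nxt[0] != unbound_state:
                n_events += 1
            elif prev[0] != unbound_state and nxt[0] == unbound_state:
                n_exits += 1

    f_nuc = n_events / unbound_time if unbound_time > 0 else 0.0
    f_err = math.sqrt(n_events) / unbound_time if unbound_time > 0 else 0.0
    if n_exits > 0:
        tau = nucleated_time / n_exits
        tau_err = tau / math.sqrt(n_exits)
    else:
        tau, tau_err = math.nan, math.nan
    return NucleationStats(
        condition=condition,
        tau_s=tau,
        tau_err_s=tau_err,
        f_nuc=f_nuc,
        f_nuc_err=f_err,
        n_events=n_events,
        unbound_time_s=unbound_time,
    )


def growth_rate(rates: KineticRates, concentration: float) -> float:
    """Net monomer flux at the filament end: k_on * [RecA] - k_off.

    Positive values mean net growth; the same difference with opposite sign
    convention is the apparent shrinkage rate.  Zero at the critical
    concentration k_off / k_on.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return rates.k_on * concentration - rates.k_off
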