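"""Shared helpers and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np

from fretkin.fret import compute_fret
from fretkin.hmm import HmmModel, fit_hmm, idealize, truncate_photobleach
from fretkin.simulate import (
    EmissionModel,
    END_DYNAMICS_FRET_LEVELS,
    NUCLEATION_FRET_LEVELS,
    SimulationParams,
    build_end_dynamics_model,
    build_nucleation_model,
    simulate_experiment,
)


def brute_force_viterbi(model: HmmModel, efficiency: np.ndarray):
    """Exhaustive max over all n_states**T paths; independent of the decoder.

    NaN frames contribute no emission term, matching the decoder contract.
    Returns (best_path, best_log_prob); ties resolved lexicographically
    toward lower state indices (iteration order of itertools.product).
    """
    e = np.asarray(efficiency, dtype=float)
    k = model.n_states
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transmat)
        log_pi = np.log(model.startprob)

    def log_b(t, s):
        if not np.isfinite(e[t]):
            return 0.0
        z = (e[t] - model.means[s]) / model.sds[s]
        return float(-0.5 * z * z - np.log(np.sqrt(2 * np.pi) * model.sds[s]))

    best_path, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=len(e)):
        score = log_pi[path[0]] + log_b(0, path[0])
        for t in range(1, len(e)):
            score += log_a[path[t - 1], path[t]] + log_b(t, path[t])
        if score > best_score:
            best_path, best_score = path, score
    return np.array(best_path), best_score


def random_hmm(rng: np.random.Generator, n_states: int = 3) -> HmmModel:
    means = np.sort(rng.uniform(0.1, 0.9, n_states))
    sds = rng.uniform(0.02, 0.15, n_states)
    transmat = rng.dirichlet(np.ones(n_states), size=n_states)
    startprob = rng.dirichlet(np.ones(n_states))
    return HmmModel(means=means, sds=sds, transmat=transmat, startprob=startprob)


def sample_hmm_series(
    model: HmmModel, n_frames: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (states, noisy E values) from a discrete-time Gaussian HMM."""
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.startprob)
    for t in range(1, n_frames):
        states[t] = rng.choice(model.n_states, p=model.transmat[states[t - 1]])
    e = rng.normal(model.means[states], model.sds[states])
    return states, e


def end_dynamics_params(
    n_molecules: int = 100,
    trace_duration: float = 100.0,
    seed: int = 0,
    k_on: float = 0.2,
    k_off: float = 0.2,
    concentration: float = 1.0,
    bleach_rate: float = 0.005,
    noise_sd: float = 25.0,
    donor_only_fraction: float = 0.0,
) -> SimulationParams:
    return SimulationParams(
        rate_model=build_end_dynamics_model(k_on, k_off, concentration),
        emission_model=EmissionModel(
            mean_fret=END_DYNAMICS_FRET_LEVELS,
            noise_sd=noise_sd,
            bleach_rate=bleach_rate,
        ),
        reca_concentration=concentration,
        n_molecules=n_molecules,
        trace_duration=trace_duration,
        seed=seed,
        donor_only_fraction=donor_only_fraction,
    )


def nucleation_params(
    n_molecules: int = 100,
    trace_duration: float = 100.0,
    seed: int = 0,
    k_nuc: float = 0.02,
    k_disassembly: float = 0.1,
    bleach_rate: float = 0.005,
    noise_sd: float = 25.0,
) -> SimulationParams:
    return SimulationParams(
        rate_model=build_nucleation_model(k_nuc, k_disassembly),
        emission_model=EmissionModel(
            mean_fret=NUCLEATION_FRET_LEVELS,
            noise_sd=noise_sd,
            bleach_rate=bleach_rate,
        ),
        n_molecules=n_molecules,
        trace_duration=trace_duration,
        seed=seed,
    )


def analyze_traces(traces, n_states: int, min_frames: int = 20, init_means=None):
    """FRET -> photobleach truncation -> pooled HMM -> per-trace decoding."""
    frets = []
    for tr in traces:
        ft = truncate_photobleach(compute_fret(tr))
        if len(ft) >= min_frames:
            frets.append(ft)
    model = fit_hmm(frets, n_states=n_states, init_means=init_means)
    ideals = [idealize(model, f) for f in frets]
    return frets, model, ideals


def truth_frame_states(trace, frame_time: float) -> np.ndarray:
    """Ground-truth state label at each frame midpoint."""
    path = trace.ground_truth
    mids = trace.times + frame_time / 2
    return np.array([path.state_at(min(t, path.total_duration)) for t in mids])
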