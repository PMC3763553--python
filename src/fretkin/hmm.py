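"""Gaussian-emission hidden Markov modelling of FRET trajectories.

One model is trained per experimental condition on the pooled traces
(Baum-Welch), then each trace is decoded individually (Viterbi) into an
idealized piecewise-constant trajectory.  Invalid frames (NaN efficiency)
are bridged: the transition structure still applies across them but their
emission term is skipped.

The forward-backward pass is vectorized across traces: traces are padded to
the longest length and padded frames carry unit emission likelihood, which
leaves per-trace quantities exactly unchanged (scaling constants are 1 past
the end of a trace because transition rows sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fret import FretTrace
from .simulate import StatePath

__all__ = [
    "HmmModel",
    "IdealizedTrace",
    "fit_hmm",
    "idealize",
    "truncate_photobleach",
    "viterbi_path",
    "idealized_from_state_path",
]

SD_FLOOR = 1e-3


@dataclass
class HmmModel:
    """Gaussian-emission HMM with per-frame transition probabilities."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float = np.nan
    n_iter: int = 0
    converged: bool = False
    sd_floored: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        n = self.n_states
        if self.transmat.shape != (n, n):
            raise ValueError("transmat shape mismatch")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transmat rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("startprob must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be > 0")

    @property
    def n_states(self) -> int:
        return len(self.means)

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            transmat=np.array(d["transmat"]),
            startprob=np.array(d["startprob"]),
            log_likelihood=float(d.get("log_likelihood", np.nan)),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", False)),
        )


@dataclass
class IdealizedTrace:
    """Decoded state path: contiguous segments of constant state."""

    trace_id: str
    segments: list[tuple[int, float, float, float]]  # (state, start_s, duration_s, mean_E)
    log_prob: float
    frame_time: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_duration(self) -> float:
        if not self.segments:
            return 0.0
        last = self.segments[-1]
        return last[1] + last[2]

    def state_sequence(self) -> list[int]:
        return [s for s, _, _, _ in self.segments]


def _pad_traces(traces: Sequence[FretTrace]):
    """Stack ragged traces into (T_max, N) arrays with existence/valid masks."""
    lengths = np.array([len(t) for t in traces])
    t_max, n = int(lengths.max()), len(traces)
    x = np.zeros((t_max, n))
    exist = np.zeros((t_max, n), dtype=bool)
    for j, tr in enumerate(traces):
        x[: len(tr), j] = np.nan_to_num(tr.efficiency, nan=0.0)
        exist[: len(tr), j] = True
    valid = exist.copy()
    for j, tr in enumerate(traces):
        valid[: len(tr), j] &= np.isfinite(tr.efficiency)
    return x, exist, valid, lengths


def _emission_probs(x, valid, means, sds):
    """Gaussian densities, shape (T, N, K); 1.0 where the emission is skipped."""
    z = (x[:, :, None] - means[None, None, :]) / sds[None, None, :]
    b = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * sds[None, None, :])
    b = np.where(valid[:, :, None], b, 1.0)
    # guard against total underflow on extreme outliers
    return np.maximum(b, 1e-300)


def _default_init(pooled: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray]:
    # evenly spaced means over the central data range; robust to unequal
    # state occupancy, unlike occupancy quantiles
    lo, hi = np.quantile(pooled, [0.005, 0.995])
    if hi - lo < 1e-3 * n_states:
        hi = lo + 1e-3 * n_states
    means = np.linspace(lo, hi, n_states)
    sd = max(float(pooled.std()) / n_states, 0.02)
    return means, np.full(n_states, sd)


def fit_hmm(
    traces: Sequence[FretTrace],
    n_states: int,
    init: HmmModel | None = None,
    init_means: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> HmmModel:
    """Baum-Welch on pooled traces with Gaussian emissions.

    Deterministic given the initialization: emission means start at the
    supplied values, at ``init``'s parameters, or at evenly spaced quantiles
    of the pooled data; the log-likelihood is asserted non-decreasing every
    iteration.  Emission sds collapsing below ``SD_FLOOR`` are floored and
    flagged on the returned model.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    traces = [t for t in traces if len(t) > 0]
    if not traces:
        raise ValueError("no non-empty traces")
    x, exist, valid, lengths = _pad_traces(traces)
    pooled = x[valid]
    if pooled.size < 10 * n_states:
        raise ValueError(
            f"need >= {10 * n_states} valid frames, got {pooled.size}"
        )

    if init is not None:
        means, sds = init.means.copy(), init.sds.copy()
        transmat, startprob = init.transmat.copy(), init.startprob.copy()
    else:
        if init_means is not None:
            means = np.asarray(init_means, dtype=float).copy()
            if len(means) != n_states:
                raise ValueError("init_means length must equal n_states")
            sds = np.full(n_states, max(float(pooled.std()) / n_states, 0.02))
        else:
            means, sds = _default_init(pooled, n_states)
        transmat = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(transmat, 0.9)
        startprob = np.full(n_states, 1.0 / n_states)

    t_max, n = x.shape
    prev_ll = -np.inf
    ll = -np.inf
    sd_floored = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b = _emission_probs(x, valid, means, sds)

        # forward pass with per-step normalization; padded frames keep c=1
        alpha = np.empty((t_max, n, n_states))
        c = np.empty((t_max, n))
        a = startprob[None, :] * b[0]
        c[0] = a.sum(axis=1)
        alpha[0] = a / c[0][:, None]
        for t in range(1, t_max):
            a = (alpha[t - 1] @ transmat) * b[t]
            c[t] = a.sum(axis=1)
            alpha[t] = a / c[t][:, None]

        ll = float(np.log(c[exist]).sum())
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll} at iter {it}"
            )

        # backward pass
        beta = np.empty_like(alpha)
        beta[-1] = 1.0
        for t in range(t_max - 2, -1, -1):
            beta[t] = (beta[t + 1] * b[t + 1] / c[t + 1][:, None]) @ transmat.T

        gamma = alpha * beta  # rows already normalized by the scaling
        # transition statistics, only across steps where frame t+1 exists
        xi_sum = np.zeros((n_states, n_states))
        for t in range(t_max - 1):
            active = exist[t + 1]
            if not active.any():
                break
            w = (beta[t + 1] * b[t + 1] / c[t + 1][:, None])[active]
            xi_sum += alpha[t][active].T @ w * transmat

        gv = gamma * valid[:, :, None]
        occ = gv.sum(axis=(0, 1))
        occ = np.maximum(occ, 1e-12)
        new_means = (gv * x[:, :, None]).sum(axis=(0, 1)) / occ
        new_var = (gv * (x[:, :, None] - new_means[None, None, :]) ** 2).sum(
            axis=(0, 1)
        ) / occ
        new_sds = np.sqrt(np.maximum(new_var, 0.0))
        if np.any(new_sds < SD_FLOOR):
            new_sds = np.maximum(new_sds, SD_FLOOR)
            sd_floored = True

        row = xi_sum.sum(axis=1, keepdims=True)
        new_transmat = np.where(row > 0, xi_sum / np.maximum(row, 1e-300), transmat)
        new_transmat /= new_transmat.sum(axis=1, keepdims=True)
        new_start = gamma[0].mean(axis=0)
        new_start /= new_start.sum()

        means, sds, transmat, startprob = new_means, new_sds, new_transmat, new_start
        if ll - prev_ll < tol * max(1.0, abs(ll)) and it > 1:
            converged = True
            break
        prev_ll = ll

    return HmmModel(
        means=means,
        sds=sds,
        transmat=transmat,
        startprob=startprob,
        log_likelihood=ll,
        n_iter=it,
        converged=converged,
        sd_floored=sd_floored,
    )


def viterbi_path(
    model: HmmModel, efficiency: np.ndarray
) -> tuple[np.ndarray, float]:
    """Most likely state sequence for one trace (log-domain Viterbi).

    NaN frames contribute no emission term (bridged by the transition
    structure).  Ties break toward the lower state index (``argmax`` keeps
    the first maximizer at every step and in the final state).
    """
    e = np.asarray(efficiency, dtype=float)
    t_len = len(e)
    if t_len == 0:
        raise ValueError("empty trace")
    k = model.n_states
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transmat)
        log_pi = np.log(model.startprob)
    valid = np.isfinite(e)
    z = (np.where(valid, e, 0.0)[:, None] - model.means[None, :]) / model.sds[None, :]
    log_b = -0.5 * z**2 - np.log(np.sqrt(2 * np.pi) * model.sds)[None, :]
    log_b = np.where(valid[:, None], log_b, 0.0)

    delta = log_pi + log_b[0]
    psi = np.zeros((t_len, k), dtype=np.intp)
    for t in range(1, t_len):
        scores = delta[:, None] + log_a
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(k)] + log_b[t]
    path = np.empty(t_len, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    best = float(delta[path[-1]])
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, best


def _segments_from_frames(
    path: np.ndarray, frame_time: float, means: np.ndarray
) -> list[tuple[int, float, float, float]]:
    segments = []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            s = int(path[start])
            segments.append(
                (s, start * frame_time, (t - start) * frame_time, float(means[s]))
            )
            start = t
    return segments


def idealize(model: HmmModel, fret: FretTrace) -> IdealizedTrace:
    """Viterbi-decode one trace into contiguous constant-state segments."""
    path, log_prob = viterbi_path(model, fret.efficiency)
    segments = _segments_from_frames(path, fret.frame_time, model.means)
    return IdealizedTrace(
        trace_id=fret.trace_id,
        segments=segments,
        log_prob=log_prob,
        frame_time=fret.frame_time,
    )


def truncate_photobleach(
    fret: FretTrace, dark_threshold: float = 0.1, min_dark_frames: int = 5
) -> FretTrace:
    """Cut a trace at the first sustained dark (E ~ 0) run.

    The acceptor-bleached dark state must be excluded from kinetics; the
    trace is truncated at the first run of at least ``min_dark_frames``
    consecutive valid frames below ``dark_threshold``.  The truncation time
    is recorded on the returned trace; a trace that is dark from the start
    comes back empty (flagged by ``truncated_at == 0``).
    """
    if min_dark_frames < 1:
        raise ValueError("min_dark_frames must be >= 1")
    dark = np.isfinite(fret.efficiency) & (fret.efficiency < dark_threshold)
    run = 0
    cut = None
    for i, d in enumerate(dark):
        run = run + 1 if d else 0
        if run >= min_dark_frames:
            cut = i - min_dark_frames + 1
            break
    if cut is None:
        return fret
    return FretTrace(
        trace_id=fret.trace_id,
        times=fret.times[:cut],
        efficiency=fret.efficiency[:cut],
        frame_time=fret.frame_time,
        truncated_at=float(cut * fret.frame_time),
    )


def idealized_from_state_path(
    path: StatePath,
    state_index: Mapping[str, int],
    state_means: Mapping[str, float],
    trace_id: str = "truth",
) -> IdealizedTrace:
    """Wrap a ground-truth latent path as an IdealizedTrace.

    Lets the kinetic estimators run on exact simulator output, bypassing the
    decoder, to separate estimator bias from decoding bias.
    """
    segments = [
        (state_index[s], start, dur, float(state_means[s]))
        for s, start, dur in path.segments
    ]
    return IdealizedTrace(
        trace_id=trace_id, segments=segments, log_prob=0.0, frame_time=np.nan
    )
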