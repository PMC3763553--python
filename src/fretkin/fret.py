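"""FRET efficiency computation, per-molecule histograms and mixture fits.

E is the proximity ratio acceptor/(acceptor+donor) with no gamma or
crosstalk correction.  Histograms are built from one summary value per
molecule (mean of the first frames of its trace) and fitted with a sum of
Gaussian populations plus an optional near-zero peak for donor-only
molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .simulate import TimeTrace

__all__ = [
    "FretTrace",
    "FretHistogram",
    "GaussianComponent",
    "MixtureFit",
    "ShortTraceError",
    "MixtureFitError",
    "compute_fret",
    "summarize_molecule",
    "build_fret_histogram",
    "fit_fret_populations",
]

logger = logging.getLogger(__name__)

E_CLIP_LO = -0.1
E_CLIP_HI = 1.1


class ShortTraceError(ValueError):
    """Trace too short for the requested per-molecule summary."""


class MixtureFitError(RuntimeError):
    """Gaussian mixture fit did not converge; carries diagnostics."""


@dataclass
class FretTrace:
    """Per-frame FRET efficiency; invalid frames are NaN."""

    trace_id: str
    times: np.ndarray
    efficiency: np.ndarray
    frame_time: float
    truncated_at: float | None = None  # photobleach truncation point, if applied

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if len(self.times) != len(self.efficiency):
            raise ValueError("times/efficiency length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.efficiency)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float


@dataclass
class MixtureFit:
    """Sum-of-Gaussians fit to a binned FRET histogram.

    ``components`` are sorted by mean; the donor-only peak near E=0 is kept
    separate in ``zero_peak``.  Weights (including the zero peak) sum to 1.
    """

    components: list[GaussianComponent]
    zero_peak: GaussianComponent | None
    goodness: float  # R^2 of the binned fit
    n_molecules: int

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])


def compute_fret(trace: TimeTrace) -> FretTrace:
    """Proximity-ratio FRET per frame.

    Frames with non-positive total intensity are flagged invalid (NaN).
    Values are clipped to [-0.1, 1.1] to bound noise excursions.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    total = trace.donor + trace.acceptor
    valid = total > 0
    if not valid.any():
        raise ValueError("no frame with positive total intensity")
    e = np.full(len(trace), np.nan)
    e[valid] = np.clip(trace.acceptor[valid] / total[valid], E_CLIP_LO, E_CLIP_HI)
    return FretTrace(
        trace_id=trace.trace_id,
        times=trace.times.copy(),
        efficiency=e,
        frame_time=trace.frame_time,
    )


def summarize_molecule(fret: FretTrace, n_first: int = 10) -> float:
    """Per-molecule FRET value: mean of the first ``n_first`` frames.

    Invalid frames among the first ``n_first`` are ignored; a trace shorter
    than ``n_first`` frames raises :class:`ShortTraceError` so the caller can
    exclude it from the histogram.
    """
    if len(fret) < n_first:
        raise ShortTraceError(
            f"trace {fret.trace_id}: {len(fret)} frames < n_first={n_first}"
        )
    head = fret.efficiency[:n_first]
    if not np.isfinite(head).any():
        raise ShortTraceError(f"trace {fret.trace_id}: no valid frame in first {n_first}")
    return float(np.nanmean(head))


def build_fret_histogram(values, bin_width: float = 0.02) -> FretHistogram:
    """Histogram per-molecule E values on [0, 1] with fixed bin width.

    Out-of-range values are clipped into the edge bins; every finite input
    value is counted (count conservation).
    """
    values = np.asarray(list(values), dtype=float)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if values.size == 0:
        return FretHistogram(edges, np.zeros(n_bins, dtype=int), 0)
    finite = values[np.isfinite(values)]
    if finite.size < values.size:
        logger.warning("dropping %d non-finite values", values.size - finite.size)
    clipped = np.clip(finite, 0.0, 1.0)
    counts, _ = np.histogram(clipped, bins=edges)
    return FretHistogram(edges, counts, int(finite.size))


def _peak_init_means(x, y, n_components, lo, hi):
    """Deterministic seeding: the tallest local maxima of the smoothed
    histogram within [lo, hi], padded with interior-spaced positions."""
    ys = gaussian_filter1d(y, sigma=1.0, mode="nearest")
    in_range = (x >= lo) & (x <= hi)
    idx, _ = find_peaks(np.where(in_range, ys, 0.0))
    idx = idx[np.argsort(-ys[idx])]
    means = list(x[idx[:n_components]])
    fallback = lo + (np.arange(n_components) + 1.0) / (n_components + 1.0) * (hi - lo)
    for m in fallback:
        if len(means) >= n_components:
            break
        if all(abs(m - mu) > 0.05 for mu in means):
            means.append(float(m))
    while len(means) < n_components:  # pathological: flat histogram
        means.append(float(np.mean([lo, hi])))
    return np.sort(np.asarray(means[:n_components]))


def _gauss_sum(x, *params):
    y = np.zeros_like(x)
    for k in range(len(params) // 3):
        amp, mu, sd = params[3 * k : 3 * k + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_fret_populations(
    hist: FretHistogram,
    n_components: int,
    include_zero_peak: bool = False,
    init_means=None,
    zero_peak_mean_bound: float = 0.05,
) -> MixtureFit:
    """Least-squares fit of a sum of Gaussians to histogram counts.

    Initialization is deterministic: component means equally spaced over the
    populated data range (or user supplied), sd 0.05, amplitudes at the peak
    count.  With ``include_zero_peak`` an extra component is fitted with its
    mean constrained to |mean| <= ``zero_peak_mean_bound``.  Raises
    :class:`MixtureFitError` with diagnostics on non-convergence.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if hist.n_molecules == 0 or hist.counts.sum() == 0:
        raise ValueError("histogram is empty")

    x = hist.bin_centers
    y = hist.counts.astype(float)
    populated = x[y > 0]
    lo, hi = float(populated.min()), float(populated.max())
    if include_zero_peak:
        lo = max(lo, 3 * zero_peak_mean_bound)  # keep components off the zero peak
    if init_means is None:
        init_means = _peak_init_means(x, y, n_components, lo, hi)
    else:
        init_means = np.asarray(init_means, dtype=float)
        if len(init_means) != n_components:
            raise ValueError("init_means length must equal n_components")

    # a real population is never narrower than a bin
    sd_lo = max(0.008, hist.bin_width / 2)
    p0: list[float] = []
    lower: list[float] = []
    upper: list[float] = []
    for mu in init_means:
        local = float(y[np.argmin(np.abs(x - mu))])
        p0 += [max(local, 0.1 * float(y.max()), 1.0), float(mu), 0.05]
        lower += [0.0, 0.0, sd_lo]
        upper += [np.inf, 1.0, 0.5]
    if include_zero_peak:
        local0 = float(y[np.argmin(np.abs(x))])
        p0 += [max(local0, 1.0), 0.0, 0.03]
        lower += [0.0, -zero_peak_mean_bound, sd_lo]
        upper += [np.inf, zero_peak_mean_bound, 0.1]

    try:
        popt, _ = curve_fit(
            _gauss_sum, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise MixtureFitError(
            f"mixture fit failed: {exc}; p0={p0}, n_molecules={hist.n_molecules}"
        ) from exc

    raw = [tuple(popt[3 * k : 3 * k + 3]) for k in range(len(popt) // 3)]
    areas = np.array([amp * sd * np.sqrt(2 * np.pi) for amp, _, sd in raw])
    total_area = areas.sum()
    if total_area <= 0:
        raise MixtureFitError("mixture fit collapsed to zero total weight")
    weights = areas / total_area

    zero_peak = None
    comps = []
    for k, (amp, mu, sd) in enumerate(raw):
        comp = GaussianComponent(mean=float(mu), sd=float(sd), weight=float(weights[k]))
        if include_zero_peak and k == len(raw) - 1:
            zero_peak = comp
        else:
            comps.append(comp)
    comps.sort(key=lambda c: c.mean)

    resid = y - _gauss_sum(x, *popt)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
    return MixtureFit(
        components=comps, zero_peak=zero_peak, goodness=r2, n_molecules=hist.n_molecules
    )
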