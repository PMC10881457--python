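"""Chunk-recognition metrics: TOPA, peak z-scores, histograms, modes.

TOPA (time offset of peak activity) is the latency of the readout's
maximum within a chunk-presentation window, measured from chunk onset.
Small offsets indicate recognition of the chunk's beginning
("Start-cell"-like signaling); offsets near the window end indicate
boundary signaling at chunk termination ("Stop-cell"-like).  Peak
heights are standardized against the mean and standard deviation of the
whole post-training readout trace, giving the peak z-score used as the
recognition-significance measure.

Pooled TOPA values are summarized as histograms over the chunk window;
the number of histogram modes ("clusters") reflects how many distinct
within-chunk positions attract peak activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TOPAResult",
    "topa",
    "topa_global",
    "window_minima",
    "peak_zscore",
    "topa_histogram",
    "count_modes",
    "count_clusters",
    "aggregate_over_seeds",
]

#: Bins below this fraction of the tallest bin are treated as noise
#: floor (gaps) when counting histogram modes.
MODE_NOISE_FLOOR = 0.05


@dataclass
class TOPAResult:
    """Per-window peak metrics of one population's post-training readout.

    ``zscores`` (and ``min_zscores``) are NaN when the trace is
    degenerate (zero standard deviation); consumers should treat NaN as
    "undefined", not as a value.
    """

    offsets: np.ndarray  # ms from window start, one per window
    peaks: np.ndarray  # readout value at each peak
    zscores: np.ndarray  # standardized peak heights
    min_peaks: np.ndarray  # most-negative within-window extremum
    min_zscores: np.ndarray
    window_length: float
    #: offset/z-score of the single tallest in-window peak of the whole
    #: trace (the per-simulation peak); NaN when no windows were scored.
    global_offset: float = float("nan")
    global_zscore: float = float("nan")
    global_min_zscore: float = float("nan")

    @property
    def n_windows(self) -> int:
        return self.offsets.size

    @property
    def mean_offset(self) -> float:
        return float(np.mean(self.offsets)) if self.offsets.size else float("nan")

    @property
    def mean_zscore(self) -> float:
        return float(np.mean(self.zscores)) if self.zscores.size else float("nan")


def _window_bounds(
    window: tuple[float, float], dt: float, n_samples: int
) -> tuple[int, int]:
    start, end = window
    i0 = int(round(start / dt))
    i1 = int(round(end / dt))
    if i0 < 0 or i1 > n_samples or i1 <= i0:
        raise IndexError(
            f"window [{start}, {end}) ms lies outside the trace "
            f"({n_samples} samples at dt={dt} ms)"
        )
    return i0, i1


def topa(
    trace: np.ndarray,
    windows: Sequence[tuple[float, float]],
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window peak offsets and values.

    For each window the offset is the argmax of the trace over in-window
    samples, measured in ms from window start; ties break to the
    earliest sample.
    """
    trace = np.asarray(trace)
    offsets = np.empty(len(windows))
    peaks = np.empty(len(windows))
    for j, win in enumerate(windows):
        i0, i1 = _window_bounds(win, dt, trace.size)
        seg = trace[i0:i1]
        k = int(np.argmax(seg))
        offsets[j] = k * dt
        peaks[j] = seg[k]
    return offsets, peaks


def topa_global(
    trace: np.ndarray,
    windows: Sequence[tuple[float, float]],
    dt: float,
) -> tuple[float, float]:
    """Offset and value of the single tallest in-window peak of the trace.

    Alternative scoring mode: instead of one offset per window, the
    global post-training peak (restricted to chunk windows) yields a
    single offset relative to its window's onset.
    """
    if not len(windows):
        raise ValueError("no windows to score")
    offsets, peaks = topa(trace, windows, dt)
    j = int(np.argmax(peaks))
    return float(offsets[j]), float(peaks[j])


def window_minima(
    trace: np.ndarray,
    windows: Sequence[tuple[float, float]],
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window most-negative extrema (offsets and values).

    Used in the kappa-sweep experiment, where unrectified teaching
    signals let readouts develop negative chunk-locked deflections.
    """
    neg_offsets, neg_peaks = topa(-np.asarray(trace), windows, dt)
    return neg_offsets, -neg_peaks


def peak_zscore(trace: np.ndarray, peak_value: float | np.ndarray):
    """Standardize peak height(s) against the whole trace.

    Returns ``(peak - mean(trace)) / std(trace)``; for a degenerate
    trace (zero standard deviation) returns NaN for arrays or ``None``
    for a scalar peak, flagging "undefined" rather than dividing.
    """
    trace = np.asarray(trace)
    mu = float(trace.mean())
    sd = float(trace.std())
    scalar = np.isscalar(peak_value) or np.ndim(peak_value) == 0
    if sd < 1e-12:
        return None if scalar else np.full(np.shape(peak_value), np.nan)
    out = (np.asarray(peak_value) - mu) / sd
    return float(out) if scalar else out


def score_trace(
    trace: np.ndarray,
    windows: Sequence[tuple[float, float]],
    dt: float,
    window_length: float,
) -> TOPAResult:
    """Full per-window scoring of one post-training readout trace."""
    offsets, peaks = topa(trace, windows, dt)
    _, mins = window_minima(trace, windows, dt)
    z = peak_zscore(trace, peaks)
    zmin = peak_zscore(trace, mins)
    if z is None or np.ndim(z) == 0:  # empty or degenerate
        z = np.full(offsets.shape, np.nan)
        zmin = np.full(offsets.shape, np.nan)
    z = np.asarray(z)
    zmin = np.asarray(zmin)
    if offsets.size:
        j = int(np.argmax(peaks))
        g_off, g_z = float(offsets[j]), float(z[j])
        g_zmin = float(zmin[int(np.argmin(mins))])
    else:
        g_off = g_z = g_zmin = float("nan")
    return TOPAResult(
        offsets=offsets,
        peaks=peaks,
        zscores=z,
        min_peaks=mins,
        min_zscores=zmin,
        window_length=window_length,
        global_offset=g_off,
        global_zscore=g_z,
        global_min_zscore=g_zmin,
    )


def topa_histogram(
    offsets: np.ndarray,
    window_length: float,
    bin_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of TOPA offsets over ``[0, window_length)``.

    The default bin width is one fifth of a character epoch for a
    4-character window (``window_length / 20``): fine enough that peak
    clusters at distinct within-chunk positions are separated by
    below-floor bins, coarse enough to average over seed noise.  Pass
    ``bin_width`` explicitly (e.g. the character duration) for coarser
    summaries.
    """
    if bin_width is None:
        bin_width = window_length / 20.0
    edges = np.arange(0.0, window_length + bin_width * 0.5, bin_width)
    if edges[-1] < window_length:
        edges = np.append(edges, window_length)
    counts, edges = np.histogram(offsets, bins=edges)
    return counts, edges


def count_modes(counts: np.ndarray, noise_floor: float = MODE_NOISE_FLOOR) -> int:
    """Number of local maxima in a histogram, after noise-floor removal.

    Bins below ``noise_floor`` times the tallest bin are zeroed and act
    as gaps.  A run of equal positive values counts as a single
    candidate and is a mode when strictly greater than the bins flanking
    the run (one-sided at the boundaries).  Invariant under uniform
    rescaling of all counts.
    """
    c = np.asarray(counts, dtype=float).copy()
    if c.size == 0 or c.max() <= 0:
        return 0
    c[c < noise_floor * c.max()] = 0.0

    modes = 0
    i = 0
    n = c.size
    while i < n:
        j = i
        while j + 1 < n and c[j + 1] == c[i]:
            j += 1
        left_ok = i == 0 or c[i - 1] < c[i]
        right_ok = j == n - 1 or c[j + 1] < c[i]
        if c[i] > 0 and left_ok and right_ok:
            modes += 1
        i = j + 1
    return modes


def count_clusters(
    offsets: np.ndarray,
    window_length: float,
    char_duration: float,
    noise_floor: float = MODE_NOISE_FLOOR,
) -> int:
    """Number of character positions attracting non-negligible TOPA mass.

    Pooled offsets are binned at character resolution (one bin per
    presented chunk character) and the bins exceeding ``noise_floor``
    times the tallest bin are counted.  This realizes the reading of
    histogram "clusters" as peak-activity concentrations at distinct
    chunk characters; it is robust to the bin-level jaggedness that
    local-maximum counting (:func:`count_modes`) picks up on pooled
    argmax data.
    """
    counts, _ = topa_histogram(offsets, window_length, bin_width=char_duration)
    if counts.max() <= 0:
        return 0
    return int(np.sum(counts >= noise_floor * counts.max()))


def aggregate_over_seeds(
    per_seed_values: Iterable[np.ndarray],
    policy: str = "mean",
):
    """Combine per-seed window-level values across seeds.

    ``mean`` returns the grand mean of all windows pooled across seeds;
    ``pooled`` returns the concatenated values (for histograms).
    """
    arrays = [np.asarray(v, dtype=float).ravel() for v in per_seed_values]
    pooled = np.concatenate(arrays) if arrays else np.array([])
    if policy == "pooled":
        return pooled
    if policy == "mean":
        return float(np.nanmean(pooled)) if pooled.size else float("nan")
    raise ValueError(f"unknown aggregation policy: {policy!r}")
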