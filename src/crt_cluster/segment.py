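"""Segmentation of a 5CRT recording into its active span and five cycles.

The recording starts and ends with the participant sitting quietly, so the
trace is at a rest baseline before and after the test. The active span is
found by locating the departure from (and return to) the leading/trailing
rest level. Within the span, each chair-rise cycle produces two prominent
force peaks - the seat-off peak of the rise and the impact peak of the
sit-down - separated by the sub-body-weight stabilization dip; between the
sit-down impact of one cycle and the seat-off of the next the force returns
to the seated baseline. Cycle boundaries are placed at that baseline return:
the first prominent local minimum after each sit-down peak.

All indices are 0-based half-open spans, so the five cycle durations
partition the active span exactly. Segmentation is all-or-nothing: a
recording that does not yield exactly the expected number of cycles raises
``IncompleteTestError`` (mirroring the exclusion of participants who do not
complete five rises) rather than returning a partial result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .grf_io import NormalizedSeries

__all__ = [
    "SegmentationError",
    "IncompleteTestError",
    "CycleSegment",
    "SegmentationResult",
    "lowpass",
    "detect_active_span",
    "split_cycles",
    "grf_duration",
]


class SegmentationError(RuntimeError):
    """The recording could not be segmented."""


class IncompleteTestError(SegmentationError):
    """The recording does not contain the expected number of chair rises."""

    def __init__(self, detected: int, expected: int = 5):
        self.detected = detected
        self.expected = expected
        super().__init__(
            f"detected {detected} chair-rise cycle(s), expected {expected}")


@dataclass(frozen=True)
class CycleSegment:
    cycle_number: int          # 1..5
    start_idx: int
    end_idx: int               # half-open

    def __post_init__(self):
        if self.start_idx >= self.end_idx:
            raise ValueError("cycle span must be non-empty")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(frozen=True)
class SegmentationResult:
    cycles: tuple[CycleSegment, ...]
    test_start_idx: int
    test_end_idx: int
    t_grf_s: float

    def __post_init__(self):
        spans = [(c.start_idx, c.end_idx) for c in self.cycles]
        if spans != sorted(spans) or any(
                spans[i][1] != spans[i + 1][0] for i in range(len(spans) - 1)):
            raise ValueError("cycles must be ordered and contiguous")


def lowpass(values: np.ndarray, cutoff_hz: float, rate_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (landmark finding only)."""
    values = np.asarray(values, dtype=float)
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        return values.copy()
    b, a = butter(4, cutoff_hz / nyq)
    padlen = min(3 * (max(len(b), len(a)) - 1), values.shape[0] - 2)
    if padlen < 1:
        return values.copy()
    return filtfilt(b, a, values, padlen=padlen)


def _rest_stats(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, 1.4826 * mad


def detect_active_span(series, rate_hz: float | None = None,
                       rest_tol: float = 0.05,
                       min_rest_s: float = 0.5) -> tuple[int, int]:
    """Locate the half-open sample span of the 5CRT within a recording.

    ``series`` is body-weight normalized. The leading/trailing ``min_rest_s``
    windows estimate the rest level; the span runs from the last leading
    sample still at rest to the first trailing sample back at rest. After the
    coarse threshold crossing at ``rest_tol`` the edge is refined by walking
    back to the rest level at a tighter, noise-adaptive threshold so the
    detected edge sits within a few samples of the true movement onset.
    """
    if isinstance(series, NormalizedSeries):
        values, rate_hz = series.values, series.sampling_rate_hz
    else:
        values = np.asarray(series, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz is required for plain arrays")
    n = values.shape[0]
    k = max(2, int(round(min_rest_s * rate_hz)))
    if n < 3 * k:
        raise SegmentationError("recording too short for rest detection")

    lead_med, lead_sig = _rest_stats(values[:k])
    tail_med, tail_sig = _rest_stats(values[-k:])

    dev_lead = np.abs(values - lead_med) > rest_tol
    if not dev_lead.any():
        raise SegmentationError("no active span: series never leaves rest level")
    first = int(np.argmax(dev_lead))
    if first == 0:
        raise SegmentationError("no leading rest window before activity")
    fine = max(3.0 * lead_sig, 0.05 * rest_tol)
    start = first - 1
    while start > 0 and abs(values[start] - lead_med) > fine:
        start -= 1

    dev_tail = np.abs(values - tail_med) > rest_tol
    last = n - 1 - int(np.argmax(dev_tail[::-1]))
    if last == n - 1:
        raise SegmentationError("no trailing rest window after activity")
    fine_t = max(3.0 * tail_sig, 0.05 * rest_tol)
    end = last + 1
    while end < n - 1 and abs(values[end] - tail_med) > fine_t:
        end += 1
    end += 1  # half-open

    if start >= end:
        raise SegmentationError("active span collapsed")
    return start, end


def split_cycles(series, span: tuple[int, int] | None = None,
                 rate_hz: float | None = None,
                 expected_cycles: int = 5,
                 peak_prominence: float = 0.18,
                 boundary_prominence: float = 0.05,
                 smooth_cutoff_hz: float = 10.0,
                 rest_tol: float = 0.05,
                 min_rest_s: float = 0.5) -> SegmentationResult:
    """Split the active span into chair-rise cycles.

    Major force peaks (prominence >= ``peak_prominence`` body weights on a
    smoothed copy) alternate seat-off, sit-down within the span; boundaries
    are the first prominent local minimum after each sit-down peak, refined
    to the raw-sample minimum. Raises ``IncompleteTestError`` when the
    number of seat-off peaks differs from ``expected_cycles``.
    """
    if isinstance(series, NormalizedSeries):
        values, rate_hz = series.values, series.sampling_rate_hz
    else:
        values = np.asarray(series, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz is required for plain arrays")
    if span is None:
        span = detect_active_span(values, rate_hz, rest_tol=rest_tol,
                                  min_rest_s=min_rest_s)
    start, end = span
    seg = values[start:end]
    smooth = lowpass(seg, smooth_cutoff_hz, rate_hz)

    peaks, _ = find_peaks(smooth, prominence=peak_prominence)
    if peaks.size == 0:
        raise IncompleteTestError(0, expected_cycles)
    if peaks.size % 2 != 0:
        raise SegmentationError(
            f"ambiguous peak structure: {peaks.size} prominent peaks "
            "(expected alternating seat-off / sit-down pairs)")
    n_cycles = peaks.size // 2
    if n_cycles != expected_cycles:
        raise IncompleteTestError(n_cycles, expected_cycles)
    sitdowns = peaks[1::2]
    seatoffs = peaks[0::2]

    refine = max(3, int(round(0.04 * rate_hz)))
    bounds = [0]
    for i in range(n_cycles - 1):
        lo, hi = sitdowns[i], seatoffs[i + 1]
        window = smooth[lo:hi]
        minima, _ = find_peaks(-window, prominence=boundary_prominence)
        b = lo + (int(minima[0]) if minima.size else int(np.argmin(window)))
        a, z = max(0, b - refine), min(seg.shape[0], b + refine + 1)
        b = a + int(np.argmin(seg[a:z]))
        bounds.append(b)
    bounds.append(seg.shape[0])
    if bounds != sorted(set(bounds)):
        raise SegmentationError("cycle boundaries are not strictly increasing")

    cycles = tuple(
        CycleSegment(cycle_number=i + 1,
                     start_idx=start + bounds[i],
                     end_idx=start + bounds[i + 1])
        for i in range(n_cycles))
    return SegmentationResult(cycles=cycles, test_start_idx=start,
                              test_end_idx=end,
                              t_grf_s=(end - start) / rate_hz)


def grf_duration(seg: SegmentationResult, rate_hz: float | None = None) -> float:
    """Force-plate-derived 5CRT duration in seconds (full active span)."""
    if rate_hz is not None:
        return (seg.test_end_idx - seg.test_start_idx) / rate_hz
    return seg.t_grf_s
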