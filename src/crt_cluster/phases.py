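"""Schenkman phase landmarks and per-phase forces of one chair-rise cycle.

A sit-to-stand decomposes into four phases: flexion momentum (trunk lean),
momentum transfer (seat unloading up to maximal dorsiflexion), extension
(ending at the super-body-weight seat-off force peak region) and
stabilization (deceleration to quiet standing, visible as a sub-body-weight
dip in Fz followed by the standing value). On a body-weight-normalized
cycle the four reported quantities are the signed extrema characteristic of
each phase: the seat-unloading minimum, the seat-off maximum, the
stabilization minimum and the subsequent standing local maximum.

Landmarks are located as turning points of a 10 Hz low-pass smoothed copy of
the cycle and then refined to the raw-sample extremum in a small window, so
noise-free cycles are recovered exactly and noisy cycles are read with
errors on the order of the noise amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .grf_io import NormalizedSeries
from .segment import lowpass

__all__ = [
    "PhaseDetectionError",
    "PhaseLandmarks",
    "PhaseForces",
    "detect_landmarks",
    "phase_forces",
]


class PhaseDetectionError(RuntimeError):
    """The cycle does not show the expected phase structure."""


@dataclass(frozen=True)
class PhaseLandmarks:
    """Sample indices of the four phase landmarks within the cycle."""

    unload_min_idx: int
    seatoff_peak_idx: int
    stab_min_idx: int
    stand_idx: int

    def __post_init__(self):
        if not (self.unload_min_idx < self.seatoff_peak_idx
                < self.stab_min_idx < self.stand_idx):
            raise ValueError("landmark indices must be strictly increasing")


@dataclass(frozen=True)
class PhaseForces:
    """Body-weight-normalized force at the four landmarks (a.u.)."""

    unload: float
    seatoff: float
    stab: float
    stand: float

    def __post_init__(self):
        vals = (self.unload, self.seatoff, self.stab, self.stand)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("phase forces must be finite and non-negative")
        if self.stab >= 1.0:
            raise ValueError("stabilization force must be below body weight")
        if self.seatoff < self.stand:
            # possible for individual cycles; distributions overlap
            warnings.warn("seat-off force below standing force for this cycle",
                          stacklevel=2)


def _refine(values: np.ndarray, idx: int, radius: int, kind: str) -> int:
    lo, hi = max(0, idx - radius), min(values.shape[0], idx + radius + 1)
    w = values[lo:hi]
    return lo + int(np.argmax(w) if kind == "max" else np.argmin(w))


def detect_landmarks(cycle, rate_hz: float | None = None,
                     peak_search_frac: float = 0.5,
                     min_prominence: float = 0.02,
                     smooth_cutoff_hz: float = 10.0) -> PhaseLandmarks:
    """Locate the four phase landmarks of a body-weight-normalized cycle.

    The seat-off peak is the raw maximum within the first
    ``peak_search_frac`` of the cycle (the sit-down impact peak lies later);
    the unloading minimum is the last prominent local minimum of the
    smoothed cycle before seat-off; the stabilization minimum is the first
    prominent local minimum after seat-off; the standing value is the first
    prominent local maximum after stabilization. Raises
    ``PhaseDetectionError`` when that structure is absent (e.g. monotone
    input or a cycle without a post-peak dip).
    """
    if isinstance(cycle, NormalizedSeries):
        values, rate_hz = cycle.values, cycle.sampling_rate_hz
    else:
        values = np.asarray(cycle, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz is required for plain arrays")
    n = values.shape[0]
    if n < 10:
        raise PhaseDetectionError("cycle too short")
    smooth = lowpass(values, smooth_cutoff_hz, rate_hz)
    radius = max(3, int(round(0.02 * n)))

    cap = max(2, int(round(peak_search_frac * n)))
    so = _refine(values, int(np.argmax(smooth[:cap])), radius, "max")
    if so < 2:
        raise PhaseDetectionError("no rise before the candidate seat-off peak")

    pre_min, _ = find_peaks(-smooth[:so], prominence=min_prominence)
    unload = int(pre_min[-1]) if pre_min.size else int(np.argmin(smooth[:so]))
    unload = _refine(values, unload, radius, "min")
    if unload >= so:
        raise PhaseDetectionError("unloading minimum not before seat-off")

    post_min, _ = find_peaks(-smooth[so:], prominence=min_prominence)
    if post_min.size == 0:
        raise PhaseDetectionError("no stabilization dip after seat-off")
    stab = _refine(values, so + int(post_min[0]), radius, "min")

    post_max, _ = find_peaks(smooth[stab:], prominence=min_prominence)
    if post_max.size == 0:
        raise PhaseDetectionError("no standing value after stabilization")
    stand = _refine(values, stab + int(post_max[0]), radius, "max")

    if not (unload < so < stab < stand):
        raise PhaseDetectionError("landmarks out of order")
    return PhaseLandmarks(unload_min_idx=unload, seatoff_peak_idx=so,
                          stab_min_idx=stab, stand_idx=stand)


def phase_forces(cycle, landmarks: PhaseLandmarks) -> PhaseForces:
    """Read the series values at the four landmark indices."""
    values = cycle.values if isinstance(cycle, NormalizedSeries) else np.asarray(cycle, dtype=float)
    return PhaseForces(
        unload=float(values[landmarks.unload_min_idx]),
        seatoff=float(values[landmarks.seatoff_peak_idx]),
        stab=float(values[landmarks.stab_min_idx]),
        stand=float(values[landmarks.stand_idx]),
    )
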