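"""Reading, writing and normalizing force-plate recordings.

Recordings are plain CSV (comma-separated, header row, UTF-8, '.' decimal)
with columns ``time_s`` and ``fz_n``; the sampling rate is inferred from the
median time step. Two normalizations are supported: body-weight units
(Fz / (m*g), quiet standing ~ 1; used for all force quantification) and
per-cycle peak normalization (series / max; used as the clustering input so
cycles are comparable across participants regardless of body mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "G_DEFAULT",
    "ForceRecording",
    "NormalizedSeries",
    "read_recording",
    "write_recording",
    "read_cohort_dir",
    "normalize_bodyweight",
    "normalize_peak",
    "downsample",
]

G_DEFAULT = 9.81  # m/s^2


@dataclass(frozen=True)
class ForceRecording:
    """One participant's continuous vertical-force trace plus metadata."""

    participant_id: str
    sampling_rate_hz: float
    fz_raw: np.ndarray = field(repr=False)
    mass_kg: float
    sex: str = "u"
    stopwatch_s: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "fz_raw",
                           np.ascontiguousarray(self.fz_raw, dtype=np.float64))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if self.fz_raw.ndim != 1 or self.fz_raw.shape[0] < 2:
            raise ValueError("fz_raw must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.fz_raw)):
            raise ValueError("fz_raw contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.fz_raw.shape[0] / self.sampling_rate_hz


@dataclass(frozen=True)
class NormalizedSeries:
    """A dimensionless view of (part of) a recording.

    ``mode`` is "bodyweight" (values = Fz/(m*g)) or "peak" (values scaled so
    the maximum is exactly 1). ``start_idx``/``end_idx`` locate the values in
    the parent recording (half-open span).
    """

    values: np.ndarray = field(repr=False)
    mode: str
    sampling_rate_hz: float
    start_idx: int = 0
    end_idx: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.ascontiguousarray(self.values, dtype=np.float64))
        if self.mode not in ("bodyweight", "peak"):
            raise ValueError("mode must be 'bodyweight' or 'peak'")
        if self.end_idx is None:
            object.__setattr__(self, "end_idx",
                               self.start_idx + self.values.shape[0])

    def slice(self, start: int, end: int) -> "NormalizedSeries":
        return replace(self, values=self.values[start:end],
                       start_idx=self.start_idx + start,
                       end_idx=self.start_idx + end)


def read_recording(path, metadata=None) -> ForceRecording:
    """Read a recording CSV, inferring the rate from the median time step.

    ``metadata`` (mapping or pandas Series) supplies mass_kg and optionally
    participant_id, sex, stopwatch_s; participant_id defaults to the file
    stem. The time column must be monotonically increasing with a constant
    step within 1%.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "fz_n"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column is not monotonically increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > 0.01 * step):
        raise ValueError(f"{path}: sampling interval varies by more than 1%")
    meta = dict(metadata) if metadata is not None else {}
    rate = 1.0 / step
    if "sampling_rate_hz" in meta and abs(rate - float(meta["sampling_rate_hz"])) > 0.01 * rate:
        raise ValueError(f"{path}: inferred rate {rate:.3f} Hz disagrees with metadata")
    sw = meta.get("stopwatch_s")
    return ForceRecording(
        participant_id=str(meta.get("participant_id", path.stem)),
        sampling_rate_hz=rate,
        fz_raw=df["fz_n"].to_numpy(dtype=float),
        mass_kg=float(meta.get("mass_kg", np.nan)),
        sex=str(meta.get("sex", "u")),
        stopwatch_s=None if sw is None or (isinstance(sw, float) and np.isnan(sw)) else float(sw),
    )


def write_recording(rec: ForceRecording, path) -> None:
    t = np.arange(rec.fz_raw.shape[0]) / rec.sampling_rate_hz
    pd.DataFrame({"time_s": t, "fz_n": rec.fz_raw}).to_csv(
        path, index=False, float_format="%.10g")


def read_cohort_dir(directory):
    """Read all recordings of a cohort directory written by the generator.

    Expects ``cohort.csv`` metadata alongside one ``<participant_id>.csv``
    per participant; returns a list of ForceRecording in metadata order.
    """
    directory = Path(directory)
    meta = pd.read_csv(directory / "cohort.csv")
    out = []
    for _, row in meta.iterrows():
        out.append(read_recording(directory / f"{row['participant_id']}.csv",
                                  metadata=row))
    return out


def normalize_bodyweight(rec: ForceRecording, g: float = G_DEFAULT) -> NormalizedSeries:
    """Express the trace in body-weight units: Fz / (m*g)."""
    if rec.mass_kg <= 0 or not np.isfinite(rec.mass_kg):
        raise ValueError("body mass must be positive to normalize")
    if g <= 0:
        raise ValueError("g must be positive")
    return NormalizedSeries(values=rec.fz_raw / (rec.mass_kg * g),
                            mode="bodyweight",
                            sampling_rate_hz=rec.sampling_rate_hz)


def normalize_peak(series) -> NormalizedSeries:
    """Scale a series so its maximum is exactly 1 (idempotent)."""
    if isinstance(series, NormalizedSeries):
        values, rate, start = series.values, series.sampling_rate_hz, series.start_idx
    else:
        values, rate, start = np.asarray(series, dtype=float), float("nan"), 0
    peak = values.max() if values.size else 0.0
    if values.size == 0 or peak <= 0:
        raise ValueError("peak normalization requires a positive maximum")
    return NormalizedSeries(values=values / peak, mode="peak",
                            sampling_rate_hz=rate, start_idx=start)


def downsample(series: NormalizedSeries, factor: int) -> NormalizedSeries:
    """Keep every ``factor``-th sample (integer decimation, no filtering)."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return series
    return replace(series, values=series.values[::factor],
                   sampling_rate_hz=series.sampling_rate_hz / factor)
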