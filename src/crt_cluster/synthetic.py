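"""Synthetic 5CRT force-plate cohort generator with a ground-truth channel.

The five time chair rise test (5CRT) asks a participant to stand up from a
chair and sit back down five times as fast as possible while a force plate
under the feet records the vertical ground reaction force Fz at 200 Hz. No
public recording set exists for this protocol, so this module synthesizes
recordings whose statistical structure matches what is reported for real
cohorts: two movement-pattern archetypes that differ chiefly in the
stabilization-phase force (0.39 vs 0.69 body weights) and in test duration
(9.84 +- 1.41 s vs 12.59 +- 2.47 s), a linear relation between the
stopwatch-timed and force-plate-derived durations
(t_GRF = 0.89 * t_stopwatch + 2.86 s), and quiet-sitting rest baselines
before and after the test.

Amplitude model. Landmark amplitudes are drawn per participant from normal
distributions truncated to physiological ranges (a seat-off peak cannot be
below body weight, the standing value cannot exceed ~1.15 body weights
without leaving the ground, forces are positive), with a few ordering
constraints (standing above the stabilization dip, seat-off clearly above
both). Truncation and clipping would bias naive sampling, so the location
parameters are calibrated once per archetype - by common-random-number
fixed-point iteration - such that the *generated* amplitude means equal the
archetype means exactly. Cycle-to-cycle amplitudes are re-jittered at a
configurable fraction of the between-participant SD.

Waveform. Every cycle is a smooth, shape-preserving (PCHIP) curve through
fixed landmark fractions, so each phase landmark is a genuine local extremum
of the noise-free waveform and downstream detectors can recover amplitudes
exactly. Two auxiliary shape knots mirror real chair-rise traces and, at the
same time, bound the detection problem: the forward-lean loading bump before
seat unloading keeps the inter-cycle baseline joint a true local minimum,
and the descent-onset dip between standing and the sit-down impact caps the
topographic prominence of the standing peak below 0.15 a.u., while seat-off
and sit-down peaks are guaranteed prominences of at least 0.20 a.u. - so
cycle detection separates the two peak families by prominence with a
structural margin, not by luck of the draw.

Generation is fully seeded; each participant draws from an independent
substream of a single master seed, so cohorts are reproducible and
order-independent. The ground-truth channel (archetype, landmark
indices/amplitudes, true durations) exists purely so that recovery can be
measured; real pipelines never see it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import ndtr, ndtri

from .grf_io import G_DEFAULT, ForceRecording, write_recording

__all__ = [
    "ArchetypeParams",
    "CohortConfig",
    "CycleAmplitudes",
    "CycleTruth",
    "GroundTruth",
    "default_archetypes",
    "synth_cycle",
    "synth_participant",
    "synth_cohort",
    "write_cohort",
]

# Landmark time fractions within one full sit-to-stand-to-sit cycle.
FRAC_LEAN = 0.07
FRAC_UNLOAD = 0.15
FRAC_SEATOFF = 0.30
FRAC_STAB = 0.45
FRAC_STAND = 0.58
FRAC_DIP = 0.66
FRAC_SITDOWN = 0.72

# Physiological amplitude bounds (a.u.) used for truncated sampling.
UNLOAD_BOUNDS = (0.08, 0.95)
STAB_BOUNDS = (0.02, 0.95)
STAND_MAX = 1.15
SEATOFF_MIN = 1.02
# Ordering margins.
STAND_ABOVE_STAB = 0.08
SEATOFF_ABOVE_STAB = 0.20
SEATOFF_ABOVE_UNLOAD = 0.15


@dataclass(frozen=True)
class ArchetypeParams:
    """Population parameters of one movement-pattern archetype.

    Amplitudes are in body-weight units (a.u.: vertical force divided by
    m*g, quiet standing ~ 1). Means/SDs are between-participant.
    """

    label: str
    unload_mean: float
    unload_sd: float
    seatoff_mean: float
    seatoff_sd: float
    stab_mean: float
    stab_sd: float
    stand_mean: float
    stand_sd: float
    stopwatch_mean_s: float
    stopwatch_sd_s: float
    sit_baseline: float = 0.45
    sitdown_peak: float = 1.20

    def __post_init__(self):
        sds = (self.unload_sd, self.seatoff_sd, self.stab_sd, self.stand_sd,
               self.stopwatch_sd_s)
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if not (self.seatoff_mean > 1.0 > self.stab_mean):
            raise ValueError("expected seatoff_mean > 1 > stab_mean")
        if not (0.0 < self.sit_baseline < 1.0):
            raise ValueError("sit_baseline must lie in (0, 1)")
        if self.stopwatch_mean_s <= 0:
            raise ValueError("stopwatch_mean_s must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings.

    ``grf_slope``/``grf_intercept``/``grf_noise_sd`` parameterize the linear
    relation of the force-plate-derived test duration to the stopwatch time;
    ``within_participant_sd_scale`` scales the between-participant SD down to
    the cycle-to-cycle amplitude jitter of one participant.
    """

    n_per_archetype: tuple[int, ...] = (72, 100)
    sampling_rate_hz: float = 200.0
    noise_sd: float = 0.005
    within_participant_sd_scale: float = 0.3
    rest_pad_s: float = 2.0
    grf_slope: float = 0.89
    grf_intercept: float = 2.86
    grf_noise_sd: float = 0.3
    duration_jitter: float = 0.05
    mass_mean_kg: float = 75.1
    mass_sd_kg: float = 13.4
    male_fraction: float = 0.42
    seed: int = 42

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if any(n < 1 for n in self.n_per_archetype):
            raise ValueError("n_per_archetype entries must be >= 1")
        if self.rest_pad_s <= 0:
            raise ValueError("rest_pad_s must be positive")
        if not 0.0 <= self.within_participant_sd_scale <= 1.0:
            raise ValueError("within_participant_sd_scale must be in [0, 1]")


@dataclass(frozen=True)
class CycleAmplitudes:
    """Per-cycle landmark amplitudes in body-weight units."""

    base: float
    unload: float
    seatoff: float
    stab: float
    stand: float
    sitdown: float


@dataclass(frozen=True)
class CycleTruth:
    """Ground truth for one synthesized chair-rise cycle (absolute indices)."""

    start_idx: int
    end_idx: int
    unload_idx: int
    seatoff_idx: int
    stab_idx: int
    stand_idx: int
    unload: float
    seatoff: float
    stab: float
    stand: float


@dataclass(frozen=True)
class GroundTruth:
    participant_id: str
    archetype_label: str
    cycles: tuple[CycleTruth, ...]
    t_stopwatch_s: float
    t_grf_s: float
    active_start_idx: int
    active_end_idx: int

    def __post_init__(self):
        for c in self.cycles:
            if not (c.unload_idx < c.seatoff_idx < c.stab_idx < c.stand_idx):
                raise ValueError("landmark indices must be strictly increasing")


def default_archetypes() -> tuple[ArchetypeParams, ArchetypeParams]:
    """The two calibrated movement-pattern archetypes.

    Archetype 1 is the efficient pattern: low stabilization-phase force and
    short test duration. Archetype 2 stabilizes against higher residual
    force and takes longer.
    """
    a1 = ArchetypeParams(
        label="archetype1",
        unload_mean=0.50, unload_sd=0.18,
        seatoff_mean=1.16, seatoff_sd=0.13,
        stab_mean=0.39, stab_sd=0.16,
        stand_mean=1.04, stand_sd=0.09,
        stopwatch_mean_s=9.84, stopwatch_sd_s=1.41,
    )
    a2 = ArchetypeParams(
        label="archetype2",
        unload_mean=0.55, unload_sd=0.17,
        seatoff_mean=1.15, seatoff_sd=0.12,
        stab_mean=0.69, stab_sd=0.13,
        stand_mean=1.01, stand_sd=0.067,
        stopwatch_mean_s=12.59, stopwatch_sd_s=2.47,
    )
    return a1, a2


# ---------------------------------------------------------------------------
# amplitude sampling (truncated normals with calibrated locations)
# ---------------------------------------------------------------------------

def _trunc_normal(loc, sd, low, high, u):
    """Inverse-CDF sample of a truncated normal from uniforms ``u``.

    Smooth in ``loc`` for fixed ``u``, which is what lets the calibration
    below converge with common random numbers.
    """
    a = ndtr((low - loc) / sd) if np.isfinite(low) else 0.0
    b = ndtr((high - loc) / sd) if np.isfinite(high) else 1.0
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return loc + sd * ndtri(a + u * (b - a))


def _structured_amplitudes(locs, arch: ArchetypeParams, u):
    """Map uniforms to a constrained amplitude vector.

    ``u`` has shape (..., 4) for (unload, seatoff, stab, stand). Ordering
    clips: standing stays above the stabilization dip, seat-off stays
    clearly above both the stabilization dip and the unloading minimum.
    """
    unload = _trunc_normal(locs[0], arch.unload_sd, *UNLOAD_BOUNDS, u=u[..., 0])
    stab = _trunc_normal(locs[2], arch.stab_sd, *STAB_BOUNDS, u=u[..., 2])
    stand = _trunc_normal(locs[3], arch.stand_sd, -np.inf, STAND_MAX, u=u[..., 3])
    stand = np.maximum(stand, stab + STAND_ABOVE_STAB)
    seatoff = _trunc_normal(locs[1], arch.seatoff_sd, SEATOFF_MIN, np.inf, u=u[..., 1])
    seatoff = np.maximum(seatoff, stab + SEATOFF_ABOVE_STAB)
    unload = np.minimum(unload, seatoff - SEATOFF_ABOVE_UNLOAD)
    return unload, seatoff, stab, stand


@lru_cache(maxsize=16)
def _calibrated_locs(key) -> tuple[float, ...]:
    """Location parameters such that generated amplitude means hit targets.

    Fixed-point iteration with common random numbers: with the uniforms held
    fixed, the generated means are smooth increasing functions of the
    locations, and ``loc += target - mean`` converges in a few steps. The
    residual calibration error is the Monte-Carlo error at n=200,000
    (< 5e-4 a.u.).
    """
    arch = ArchetypeParams(*key)
    targets = np.array([arch.unload_mean, arch.seatoff_mean,
                        arch.stab_mean, arch.stand_mean])
    u = np.random.default_rng(123456789).uniform(size=(200_000, 4))
    locs = targets.copy()
    for _ in range(12):
        means = np.array([a.mean() for a in _structured_amplitudes(locs, arch, u)])
        step = targets - means
        locs += step
        if np.max(np.abs(step)) < 1e-5:
            break
    return tuple(locs)


def _arch_key(arch: ArchetypeParams):
    return tuple(getattr(arch, f) for f in arch.__dataclass_fields__)


def _draw_amplitudes(arch: ArchetypeParams, rng: np.random.Generator) -> CycleAmplitudes:
    """Participant-level amplitude draw from the calibrated truncated model."""
    locs = np.array(_calibrated_locs(_arch_key(arch)))
    u = rng.uniform(size=4)
    unload, seatoff, stab, stand = _structured_amplitudes(locs, arch, u)
    return CycleAmplitudes(arch.sit_baseline, float(unload), float(seatoff),
                           float(stab), float(stand), arch.sitdown_peak)


def _clip_cycle(a: CycleAmplitudes) -> CycleAmplitudes:
    """Re-impose bounds and ordering after cycle-level jitter."""
    unload = float(np.clip(a.unload, *UNLOAD_BOUNDS))
    stab = float(np.clip(a.stab, *STAB_BOUNDS))
    stand = min(a.stand, STAND_MAX)
    stand = max(stand, stab + STAND_ABOVE_STAB)
    seatoff = max(a.seatoff, SEATOFF_MIN, stab + SEATOFF_ABOVE_STAB)
    unload = min(unload, seatoff - SEATOFF_ABOVE_UNLOAD)
    return CycleAmplitudes(a.base, unload, seatoff, stab, stand, a.sitdown)


def _jitter_amplitudes(base: CycleAmplitudes, arch: ArchetypeParams,
                       scale: float, rng: np.random.Generator) -> CycleAmplitudes:
    """Cycle-to-cycle re-jitter at ``scale`` times the between-participant SD."""
    if scale == 0:
        return base
    return _clip_cycle(CycleAmplitudes(
        base=base.base,
        unload=base.unload + rng.normal(0, scale * arch.unload_sd),
        seatoff=base.seatoff + rng.normal(0, scale * arch.seatoff_sd),
        stab=base.stab + rng.normal(0, scale * arch.stab_sd),
        stand=base.stand + rng.normal(0, scale * arch.stand_sd),
        sitdown=base.sitdown + rng.normal(0, scale * 0.05),
    ))


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _shape_knots(a: CycleAmplitudes):
    """Knot fractions/amplitudes incl. the two auxiliary shape knots.

    lean: forward-lean loading bump; always above the seated baseline so the
    inter-cycle joint is a local minimum, never more than 0.15 a.u. proud of
    its surroundings. dip: descent-onset unloading before the sit-down
    impact; keeps the standing peak's prominence <= 0.15 a.u. and stays at
    or below body weight so the sit-down impact keeps prominence >= 0.20.
    """
    lean = min(max(a.unload + 0.15, a.base + 0.10), a.seatoff - 0.05)
    dip = a.stand - min(0.15, 0.5 * (a.stand - a.stab))
    dip = min(dip, 1.0)
    fracs = np.array([0.0, FRAC_LEAN, FRAC_UNLOAD, FRAC_SEATOFF, FRAC_STAB,
                      FRAC_STAND, FRAC_DIP, FRAC_SITDOWN, 1.0])
    vals = np.array([a.base, lean, a.unload, a.seatoff, a.stab,
                     a.stand, dip, a.sitdown, a.base])
    return fracs, vals


def synth_cycle(amps: CycleAmplitudes, duration_s: float, rate_hz: float,
                noise_sd: float, rng: np.random.Generator):
    """One chair-rise cycle: shape-preserving curve through the landmarks.

    Returns ``(values, landmark_indices)`` where values are in body-weight
    units and ``landmark_indices`` maps landmark names to sample indices
    within the cycle. PCHIP interpolation through the knots is monotone
    between knots, so no sample overshoots a landmark extremum and the
    landmark samples carry the amplitudes exactly (before noise).
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    vec = [amps.base, amps.unload, amps.seatoff, amps.stab, amps.stand, amps.sitdown]
    if not np.all(np.isfinite(vec)):
        raise ValueError("amplitudes must be finite")
    n = int(round(duration_s * rate_hz))
    if n < 12:
        raise ValueError("cycle too short for the landmark layout")
    fracs, vals = _shape_knots(amps)
    knots = np.round(fracs * (n - 1)).astype(int)
    for i in range(1, len(knots)):        # degenerate short cycles: keep knots apart
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + 1
    curve = PchipInterpolator(knots, vals)(np.arange(n))
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd, size=n)
    idx = {"unload": int(knots[2]), "seatoff": int(knots[3]),
           "stab": int(knots[4]), "stand": int(knots[5])}
    return curve, idx


def synth_participant(arch: ArchetypeParams, cfg: CohortConfig,
                      rng: np.random.Generator, participant_id: str = "p000",
                      n_cycles: int = 5) -> tuple[ForceRecording, GroundTruth]:
    """One participant's recording (in Newtons) plus its ground truth.

    Amplitudes are drawn once per participant and re-jittered per cycle; the
    stopwatch time is drawn from the archetype's duration distribution and
    mapped to the force-plate duration through the configured linear
    relation; the force-plate duration is split into ``n_cycles`` cycles with
    small multiplicative jitter. The trace is de-normalized to Newtons with a
    drawn body mass so that downstream body-weight normalization is
    exercised.
    """
    amps = _draw_amplitudes(arch, rng)
    for _ in range(100):
        t_sw = rng.normal(arch.stopwatch_mean_s, arch.stopwatch_sd_s)
        t_grf = cfg.grf_slope * t_sw + cfg.grf_intercept + rng.normal(0, cfg.grf_noise_sd)
        if t_sw > 3.0 and t_grf > 1.2 * n_cycles:
            break
    else:
        raise RuntimeError("could not draw a positive test duration")
    w = 1.0 + cfg.duration_jitter * rng.normal(size=n_cycles)
    w = np.clip(w, 0.5, 1.5)
    durations = t_grf * w / w.sum()

    rate = cfg.sampling_rate_hz
    pad_n = int(round(cfg.rest_pad_s * rate))
    pieces = [amps.base + (rng.normal(0, cfg.noise_sd, size=pad_n)
                           if cfg.noise_sd > 0 else np.zeros(pad_n))]
    cycles: list[CycleTruth] = []
    pos = pad_n
    for d in durations:
        c_amps = _jitter_amplitudes(amps, arch, cfg.within_participant_sd_scale, rng)
        series, idx = synth_cycle(c_amps, d, rate, cfg.noise_sd, rng)
        n = series.shape[0]
        cycles.append(CycleTruth(
            start_idx=pos, end_idx=pos + n,
            unload_idx=pos + idx["unload"], seatoff_idx=pos + idx["seatoff"],
            stab_idx=pos + idx["stab"], stand_idx=pos + idx["stand"],
            unload=c_amps.unload, seatoff=c_amps.seatoff,
            stab=c_amps.stab, stand=c_amps.stand,
        ))
        pieces.append(series)
        pos += n
    active_start, active_end = pad_n, pos
    pieces.append(amps.base + (rng.normal(0, cfg.noise_sd, size=pad_n)
                               if cfg.noise_sd > 0 else np.zeros(pad_n)))
    au = np.concatenate(pieces)

    mass = float(np.clip(rng.normal(cfg.mass_mean_kg, cfg.mass_sd_kg), 48.0, 126.0))
    sex = "m" if rng.random() < cfg.male_fraction else "f"
    rec = ForceRecording(
        participant_id=participant_id,
        sampling_rate_hz=rate,
        fz_raw=au * mass * G_DEFAULT,
        mass_kg=mass,
        sex=sex,
        stopwatch_s=float(t_sw),
    )
    truth = GroundTruth(
        participant_id=participant_id,
        archetype_label=arch.label,
        cycles=tuple(cycles),
        t_stopwatch_s=float(t_sw),
        t_grf_s=(active_end - active_start) / rate,
        active_start_idx=active_start,
        active_end_idx=active_end,
    )
    return rec, truth


def synth_cohort(cfg: CohortConfig | None = None, archetypes=None):
    """Seeded cohort of ``sum(cfg.n_per_archetype)`` recordings.

    Each participant is generated from an independent child stream of the
    master seed, so the output is byte-reproducible and independent of
    generation order.
    """
    cfg = cfg or CohortConfig()
    archetypes = archetypes or default_archetypes()
    if len(archetypes) != len(cfg.n_per_archetype):
        raise ValueError("one count per archetype required")
    total = sum(cfg.n_per_archetype)
    streams = np.random.SeedSequence(cfg.seed).spawn(total)
    out = []
    i = 0
    for arch, n in zip(archetypes, cfg.n_per_archetype):
        for _ in range(n):
            rng = np.random.default_rng(streams[i])
            pid = f"p{i:03d}"
            out.append(synth_participant(arch, cfg, rng, participant_id=pid))
            i += 1
    return out


def write_cohort(cohort, out_dir) -> None:
    """Write one CSV per participant plus cohort metadata and truth JSON."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = {}
    for rec, truth in cohort:
        write_recording(rec, out_dir / f"{rec.participant_id}.csv")
        rows.append({
            "participant_id": rec.participant_id,
            "sex": rec.sex,
            "mass_kg": rec.mass_kg,
            "stopwatch_s": rec.stopwatch_s,
            "archetype": truth.archetype_label,
        })
        truths[rec.participant_id] = asdict(truth)
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, default=float)
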