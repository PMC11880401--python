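"""End-to-end 5CRT analysis: segmentation, phases, clustering, reports.

This module wires the pieces together the way a cohort analysis runs them:

1. body-weight-normalize each recording and segment it into five cycles;
2. extract the four phase forces of every cycle;
3. peak-normalize each participant's first cycle (optionally decimated) and
   fit DTW/DBA k-means with k = 2 on those series;
4. assign cycles 2-5 with the fitted model and canonicalize labels by
   ascending mean first-cycle stabilization force, so cluster 0 is always
   the low-stabilization-force pattern;
5. compute duration regression, cluster comparisons, the consistency table
   and the cohort summary.

Participants whose recordings cannot be segmented into exactly five cycles
are excluded (with the reason recorded), mirroring how incomplete tests are
excluded from real cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as clu
from . import stats as st
from .grf_io import ForceRecording, downsample, normalize_bodyweight, normalize_peak
from .phases import PhaseDetectionError, detect_landmarks, phase_forces
from .segment import SegmentationError, split_cycles

__all__ = ["PipelineConfig", "CohortResult", "analyze_recording", "run_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    k: int = 2
    n_init: int = 10
    max_iter: int = 100
    dba_max_iter: int = 10
    seed: int = 7
    cluster_downsample: int = 4    # decimation factor for clustered series
    expected_cycles: int = 5
    rest_tol: float = 0.05
    min_rest_s: float = 0.5
    alpha: float = 0.01


@dataclass
class CohortResult:
    per_participant: pd.DataFrame          # one row per analyzed participant
    per_cycle: pd.DataFrame                # one row per cycle (labels, forces)
    model: clu.ClusterModel | None
    label_mapping: dict | None
    regression: st.DurationRegression | None
    consistency: st.ConsistencyTable | None
    summary: dict | None
    validation: clu.ValidationScores | None = None
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_cycles(self) -> int:
        return int(len(self.per_cycle))


def analyze_recording(rec: ForceRecording, cfg: PipelineConfig = PipelineConfig()):
    """Segment one recording and extract per-cycle phase forces.

    Returns ``(segmentation, cycles)`` where cycles is a list of dicts with
    the cycle series (body-weight units), landmarks and forces.
    """
    bw = normalize_bodyweight(rec)
    seg = split_cycles(bw, expected_cycles=cfg.expected_cycles,
                       rest_tol=cfg.rest_tol, min_rest_s=cfg.min_rest_s)
    out = []
    for c in seg.cycles:
        cyc = bw.slice(c.start_idx, c.end_idx)
        lm = detect_landmarks(cyc)
        pf = phase_forces(cyc, lm)
        out.append({"cycle_number": c.cycle_number, "series": cyc,
                    "landmarks": lm, "forces": pf,
                    "duration_s": c.n_samples / rec.sampling_rate_hz})
    return seg, out


def run_cohort(recordings, cfg: PipelineConfig = PipelineConfig(),
               validate_k: bool = False, k_range=range(2, 11)) -> CohortResult:
    """Run the full analysis over a list of recordings."""
    rows_p, rows_c, failures = [], [], []
    clustered_series, stab_first = [], []
    kept_ids = []
    cycles_by_pid = {}
    for rec in recordings:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seg, cycles = analyze_recording(rec, cfg)
        except (SegmentationError, PhaseDetectionError, ValueError) as exc:
            failures.append({"participant_id": rec.participant_id,
                             "reason": f"{type(exc).__name__}: {exc}"})
            continue
        kept_ids.append(rec.participant_id)
        cycles_by_pid[rec.participant_id] = cycles
        first = cycles[0]
        stab_first.append(first["forces"].stab)
        ds = downsample(first["series"], cfg.cluster_downsample)
        clustered_series.append(normalize_peak(ds).values)
        rows_p.append({
            "participant_id": rec.participant_id, "sex": rec.sex,
            "mass_kg": rec.mass_kg, "stopwatch_s": rec.stopwatch_s,
            "t_grf_s": seg.t_grf_s,
            **{k: getattr(first["forces"], k)
               for k in ("unload", "seatoff", "stab", "stand")},
        })
        for c in cycles:
            rows_c.append({
                "participant_id": rec.participant_id,
                "cycle_number": c["cycle_number"],
                "duration_s": c["duration_s"],
                **{k: getattr(c["forces"], k)
                   for k in ("unload", "seatoff", "stab", "stand")},
            })
    per_participant = pd.DataFrame(rows_p)
    per_cycle = pd.DataFrame(rows_c)
    failures = pd.DataFrame(failures, columns=["participant_id", "reason"])

    if len(per_participant) < cfg.k:
        return CohortResult(per_participant, per_cycle, None, None, None,
                            None, None, failures=failures)

    model = clu.fit(clustered_series, k=cfg.k, n_init=cfg.n_init,
                    max_iter=cfg.max_iter, seed=cfg.seed,
                    dba_max_iter=cfg.dba_max_iter)
    raw_first = model.labels_
    canon_first, mapping = clu.canonicalize_labels(raw_first, stab_first)
    per_participant["cluster"] = canon_first

    # assign cycles 2..5 with the same model
    label_col = []
    for _, row in per_cycle.iterrows():
        pid, cyc_no = row["participant_id"], int(row["cycle_number"])
        if cyc_no == 1:
            label_col.append(int(canon_first[kept_ids.index(pid)]))
            continue
        cyc = cycles_by_pid[pid][cyc_no - 1]["series"]
        s = normalize_peak(downsample(cyc, cfg.cluster_downsample)).values
        label_col.append(mapping[clu.assign(model, s)])
    per_cycle["label"] = label_col

    wide = per_cycle.pivot(index="participant_id", columns="cycle_number",
                           values="label").loc[kept_ids]
    consistency = st.consistency_table(wide)

    regression = None
    sw = per_participant["stopwatch_s"]
    if sw.notna().all():
        regression = st.duration_regression(
            np.column_stack([sw.to_numpy(float),
                             per_participant["t_grf_s"].to_numpy(float)]))

    summary = st.cohort_summary(per_participant, alpha=cfg.alpha)

    validation = None
    if validate_k:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            validation = clu.silhouette_sweep(
                clustered_series, k_range=k_range, seed=cfg.seed,
                n_init=cfg.n_init, max_iter=cfg.max_iter,
                dba_max_iter=cfg.dba_max_iter)
            db = clu.davies_bouldin(clustered_series, raw_first, model)
            validation = clu.ValidationScores(
                silhouette_by_k=validation.silhouette_by_k, davies_bouldin=db)

    return CohortResult(per_participant, per_cycle, model, mapping,
                        regression, consistency, summary,
                        validation=validation, failures=failures)
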