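"""Scoring, hypothesis tests, regression and cohort reports.

Covers the evaluation layer of the pipeline: SPPB chair-rise scoring from
test duration (Guralnik bands), per-variable cluster comparisons
(Shapiro-Wilk normality audit + two-sided Mann-Whitney U at alpha = 0.01),
the ordinary-least-squares relation between stopwatch and force-plate test
durations, the cycle-to-cluster consistency table, and a cohort summary.

The Mann-Whitney test is always the reported comparison regardless of the
Shapiro-Wilk outcome (the normality tests are an audit trail, not a
switch); no multiple-testing correction is applied across phase variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GuralnikScore",
    "guralnik_score",
    "ClusterComparison",
    "compare_clusters",
    "DurationRegression",
    "duration_regression",
    "ConsistencyTable",
    "consistency_table",
    "cohort_summary",
]


# ---------------------------------------------------------------------------
# SPPB chair-rise scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuralnikScore:
    points: int
    duration_s: float | None

    def __post_init__(self):
        if not 0 <= self.points <= 4:
            raise ValueError("points must be in 0..4")


# (upper band edge in seconds, points); durations are rounded half-up to
# 2 decimals first, matching the printed precision of the band limits.
_BANDS = [(11.19, 4), (13.69, 3), (16.69, 2), (60.0, 1)]


def guralnik_score(duration_s: float | None, unable: bool = False) -> GuralnikScore:
    """SPPB points for a 5CRT duration: <=11.19 s scores 4, 11.20-13.69 s
    scores 3, 13.70-16.69 s scores 2, 16.70-60 s scores 1, >60 s or an
    incomplete test scores 0."""
    if unable:
        return GuralnikScore(points=0, duration_s=duration_s)
    if duration_s is None or not np.isfinite(duration_s) or duration_s <= 0:
        raise ValueError("duration must be positive unless flagged unable")
    d = float(Decimal(repr(float(duration_s))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))
    for edge, pts in _BANDS:
        if d <= edge:
            return GuralnikScore(points=pts, duration_s=duration_s)
    return GuralnikScore(points=0, duration_s=duration_s)


# ---------------------------------------------------------------------------
# cluster comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterComparison:
    variable: str
    group_stats: dict                    # label -> (n, mean, sd)
    shapiro_p: dict                      # label -> p (or None if degenerate)
    mannwhitney_p: float
    alpha: float = 0.01
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.mannwhitney_p < self.alpha


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both groups have n <= 8 and there are no
    ties; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    exact = (len(x) <= 8 and len(y) <= 8
             and np.unique(np.concatenate([x, y])).size == len(x) + len(y))
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def compare_clusters(values_by_cluster: dict, variable: str = "value",
                     alpha: float = 0.01) -> ClusterComparison:
    """Compare one variable between two clusters.

    Reports per-group mean +- SD and Shapiro-Wilk p (the normality audit),
    then the two-sided Mann-Whitney U p-value; the significance flag is
    p < alpha. Groups need >= 3 values; constant groups are flagged
    degenerate (the rank test is still computed, Shapiro-Wilk is not).
    """
    if len(values_by_cluster) != 2:
        raise ValueError("exactly two clusters required")
    (la, xa), (lb, xb) = sorted(values_by_cluster.items())
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 values per group")
    degenerate = bool(np.ptp(xa) == 0 or np.ptp(xb) == 0)
    shapiro = {}
    for lab, v in ((la, xa), (lb, xb)):
        shapiro[lab] = None if np.ptp(v) == 0 else float(sps.shapiro(v).pvalue)
    return ClusterComparison(
        variable=variable,
        group_stats={la: (len(xa), float(xa.mean()), float(xa.std(ddof=1))),
                     lb: (len(xb), float(xb.mean()), float(xb.std(ddof=1)))},
        shapiro_p=shapiro,
        mannwhitney_p=mann_whitney_p(xa, xb),
        alpha=alpha,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# stopwatch vs force-plate duration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DurationRegression:
    slope: float
    intercept_s: float
    stderr_slope: float
    stderr_intercept: float
    r_value: float
    pairs: np.ndarray = field(repr=False)    # (n, 2): stopwatch, grf

    def predict(self, t_stopwatch):
        return self.slope * np.asarray(t_stopwatch, float) + self.intercept_s

    @property
    def residuals(self) -> np.ndarray:
        return self.pairs[:, 1] - self.predict(self.pairs[:, 0])


def duration_regression(pairs) -> DurationRegression:
    """OLS of force-plate duration on stopwatch duration.

    ``pairs`` is a sequence of (t_stopwatch, t_grf) in seconds; at least 3
    pairs with a non-constant predictor are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (t_stopwatch, t_grf) pairs")
    if np.ptp(arr[:, 0]) == 0:
        raise ValueError("stopwatch durations are constant; slope undefined")
    res = sps.linregress(arr[:, 0], arr[:, 1])
    return DurationRegression(slope=float(res.slope),
                              intercept_s=float(res.intercept),
                              stderr_slope=float(res.stderr),
                              stderr_intercept=float(res.intercept_stderr),
                              r_value=float(res.rvalue),
                              pairs=arr)


# ---------------------------------------------------------------------------
# cycle-to-cluster consistency
# ---------------------------------------------------------------------------

_CONSISTENCY_CATS = ["all", "four", "three", "two", "only_first"]


@dataclass(frozen=True)
class ConsistencyTable:
    """Per first-cycle cluster: fraction of participants whose five cycles
    match their first-cycle label in exactly 5 ('all') down to 1
    ('only_first') cycles."""

    table: pd.DataFrame

    def __post_init__(self):
        sums = self.table[_CONSISTENCY_CATS].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=0.01):
            raise ValueError("consistency fractions must sum to 1 per cluster")


def consistency_table(labels: pd.DataFrame) -> ConsistencyTable:
    """Tabulate how often cycles 2-5 stay in the first-cycle cluster.

    ``labels`` must have one row per participant and five columns of integer
    cluster labels (cycle order). A participant whose five labels all equal
    the first falls in 'all'; one whose cycles 2-5 all differ falls in
    'only_first'.
    """
    arr = labels.to_numpy()
    if arr.ndim != 2 or arr.shape[1] != 5:
        raise ValueError("need exactly 5 cycle labels per participant")
    if np.any(pd.isna(arr)):
        raise ValueError("missing cycle labels")
    first = arr[:, 0]
    n_match = (arr == first[:, None]).sum(axis=1)     # 1..5, includes cycle 1
    rows = []
    for c in np.unique(first):
        sel = n_match[first == c]
        n = sel.size
        counts = {cat: int((sel == 5 - i).sum()) for i, cat in
                  enumerate(_CONSISTENCY_CATS)}
        rows.append({"cluster": int(c), "n": n,
                     **{cat: counts[cat] / n for cat in _CONSISTENCY_CATS}})
    sel = n_match
    rows.append({"cluster": "total", "n": sel.size,
                 **{cat: int((sel == 5 - i).sum()) / sel.size
                    for i, cat in enumerate(_CONSISTENCY_CATS)}})
    return ConsistencyTable(pd.DataFrame(rows).set_index("cluster"))


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def cohort_summary(per_participant: pd.DataFrame,
                   phase_vars=("unload", "seatoff", "stab", "stand"),
                   alpha: float = 0.01) -> dict:
    """Per-cluster descriptive statistics with cluster comparisons.

    ``per_participant`` needs columns ``cluster`` (canonical label),
    ``stopwatch_s``, ``t_grf_s``, the phase-force columns in ``phase_vars``,
    and optionally ``sex`` and ``mass_kg``. Returns a JSON-serializable dict
    mirroring the usual cohort tables: group sizes, sex split, duration and
    phase-force means +- SD per cluster, and Mann-Whitney p-values per
    variable. Single-member groups report SD 0 with a flag.
    """
    df = per_participant
    clusters = sorted(df["cluster"].unique())
    out = {"n_total": int(len(df)), "clusters": {}, "comparisons": {}}
    for c in clusters:
        g = df[df["cluster"] == c]
        entry = {"n": int(len(g)), "sd_degenerate": bool(len(g) < 2)}
        if "sex" in g:
            entry["sex_counts"] = g["sex"].value_counts().to_dict()
        for col in ("stopwatch_s", "t_grf_s", "mass_kg", *phase_vars):
            if col in g:
                v = g[col].to_numpy(float)
                entry[col] = {"min": float(v.min()), "max": float(v.max()),
                              "mean": float(v.mean()),
                              "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
        out["clusters"][str(c)] = entry
    if len(clusters) == 2:
        for col in ("stopwatch_s", "t_grf_s", *phase_vars):
            if col not in df:
                continue
            groups = {c: df.loc[df["cluster"] == c, col].to_numpy(float)
                      for c in clusters}
            if any(len(v) < 3 for v in groups.values()):
                continue
            comp = compare_clusters(groups, variable=col, alpha=alpha)
            out["comparisons"][col] = {
                "mannwhitney_p": comp.mannwhitney_p,
                "significant": comp.significant,
                "shapiro_p": {str(k): v for k, v in comp.shapiro_p.items()},
            }
    return out
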