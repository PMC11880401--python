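"""Scoring bands, rank tests vs exact enumeration, regression, consistency."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crt_cluster import stats as st


class TestGuralnikScore:
    @pytest.mark.parametrize("duration,points", [
        (6.0, 4), (11.19, 4), (11.20, 3), (12.0, 3), (13.69, 3),
        (13.70, 2), (16.69, 2), (16.70, 1), (60.0, 1), (60.01, 0), (61.0, 0),
    ])
    def test_band_boundaries(self, duration, points):
        assert st.guralnik_score(duration).points == points

    def test_unable_scores_zero(self):
        assert st.guralnik_score(None, unable=True).points == 0
        assert st.guralnik_score(25.0, unable=True).points == 0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            st.guralnik_score(0.0)
        with pytest.raises(ValueError):
            st.guralnik_score(-3.0)

    def test_sub_centisecond_gap_rounds_half_up(self):
        # durations inside the printed band gap (11.19, 11.20)
        assert st.guralnik_score(11.194).points == 4
        assert st.guralnik_score(11.195).points == 3

    def test_monotone_step_function_on_grid(self):
        """Score never increases with duration over a 0.01 s grid on (0, 70]."""
        grid = np.round(np.arange(0.01, 70.01, 0.01), 2)
        pts = [st.guralnik_score(d).points for d in grid]
        assert all(a >= b for a, b in zip(pts, pts[1:]))
        assert pts[0] == 4 and pts[-1] == 0


def exact_mw_p(x, y):
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating all
    group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_obs = min(u_obs, n1 * len(y) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        u = min(u, n1 * len(y) - u)
        count += u <= u_obs
        total += 1
    return count / total


class TestMannWhitney:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_for_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8, size=2)
        x, y = rng.normal(size=n1), rng.normal(0.8, 1, size=n2)
        assert st.mann_whitney_p(x, y) == pytest.approx(exact_mw_p(x, y))

    def test_identical_groups_not_significant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        comp = st.compare_clusters({0: x, 1: x.copy()}, "v")
        assert comp.mannwhitney_p > 0.9
        assert not comp.significant

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=40)
        assert st.mann_whitney_p(x, y) == pytest.approx(st.mann_whitney_p(y, x))

    def test_degenerate_groups_flagged(self):
        comp = st.compare_clusters({0: np.ones(5), 1: [1.0, 2.0, 3.0]}, "v")
        assert comp.degenerate
        assert comp.shapiro_p[0] is None

    def test_group_size_minimum(self):
        with pytest.raises(ValueError):
            st.compare_clusters({0: [1.0, 2.0], 1: [1.0, 2.0, 3.0]}, "v")


class TestDurationRegression:
    def test_exact_line_recovered(self):
        t = np.linspace(6, 20, 25)
        reg = st.duration_regression(np.column_stack([t, 0.89 * t + 2.86]))
        assert reg.slope == pytest.approx(0.89, abs=1e-12)
        assert reg.intercept_s == pytest.approx(2.86, abs=1e-9)
        assert np.allclose(reg.residuals, 0.0, atol=1e-9)

    def test_duplicated_dataset_leaves_fit_unchanged(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(6, 20, 40)
        pairs = np.column_stack([t, 0.9 * t + 2 + rng.normal(0, 0.4, 40)])
        a = st.duration_regression(pairs)
        b = st.duration_regression(np.vstack([pairs, pairs]))
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept_s == pytest.approx(b.intercept_s)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            st.duration_regression([(10.0, 11.0), (10.0, 12.0), (10.0, 13.0)])


class TestConsistencyTable:
    def test_fully_consistent_cohort(self):
        df = pd.DataFrame([[0] * 5] * 4 + [[1] * 5] * 6)
        table = st.consistency_table(df).table
        assert table.loc[0, "all"] == 1.0
        assert table.loc[1, "all"] == 1.0
        assert table.loc["total", "only_first"] == 0.0

    def test_only_first_category(self):
        df = pd.DataFrame([[0, 1, 1, 1, 1], [0, 0, 0, 0, 0], [1, 1, 1, 1, 1]])
        table = st.consistency_table(df).table
        assert table.loc[0, "only_first"] == pytest.approx(0.5)
        assert table.loc[0, "all"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(0, 2, size=(30, 5)))
        table = st.consistency_table(df).table
        cats = ["all", "four", "three", "two", "only_first"]
        assert np.allclose(table[cats].sum(axis=1), 1.0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            st.consistency_table(pd.DataFrame([[0, 1, 0]]))


class TestCohortSummary:
    def test_structure_and_degenerate_flag(self):
        df = pd.DataFrame({
            "cluster": [0, 0, 0, 1, 1, 1],
            "stopwatch_s": [9.0, 10.0, 9.5, 12.0, 13.0, 12.5],
            "t_grf_s": [11.0, 12.0, 11.5, 13.5, 14.5, 14.0],
            "sex": list("mfmffm"),
            "unload": [0.5] * 6, "seatoff": [1.2, 1.1, 1.15, 1.2, 1.1, 1.15],
            "stab": [0.3, 0.4, 0.35, 0.7, 0.65, 0.6],
            "stand": [1.0, 1.05, 1.02, 1.0, 1.01, 0.99],
        })
        out = st.cohort_summary(df)
        assert out["n_total"] == 6
        assert out["clusters"]["0"]["n"] == 3
        assert out["clusters"]["0"]["stopwatch_s"]["mean"] == pytest.approx(9.5)
        assert "stab" in out["comparisons"]
        single = st.cohort_summary(df.iloc[[0, 3, 4, 5]])
        assert single["clusters"]["0"]["sd_degenerate"]
        assert single["clusters"]["0"]["stab"]["sd"] == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "cluster": rng.integers(0, 2, 20),
            "stopwatch_s": rng.uniform(8, 15, 20),
            "t_grf_s": rng.uniform(10, 17, 20),
            "stab": rng.uniform(0.2, 0.8, 20),
            "unload": rng.uniform(0.3, 0.7, 20),
            "seatoff": rng.uniform(1.0, 1.4, 20),
            "stand": rng.uniform(0.9, 1.1, 20),
        })
        assert st.cohort_summary(df) == st.cohort_summary(df.copy())
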