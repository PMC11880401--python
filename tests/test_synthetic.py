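"""Generator: calibrated amplitudes, waveform landmarks, reproducibility."""

import numpy as np
import pytest
from scipy import stats as sps

from crt_cluster import CohortConfig, synth_cohort
from crt_cluster.synthetic import (ArchetypeParams, CycleAmplitudes,
                                   _draw_amplitudes, synth_cycle,
                                   synth_participant)


class TestDefaultArchetypes:
    def test_calibrated_parameters(self, archetypes):
        a1, a2 = archetypes
        assert (a1.stab_mean, a2.stab_mean) == (0.39, 0.69)
        assert a1.seatoff_mean == 1.16
        assert (a1.stopwatch_mean_s, a2.stopwatch_mean_s) == (9.84, 12.59)
        assert (a1.unload_mean, a1.unload_sd) == (0.50, 0.18)
        assert a2.stand_sd == 0.067

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeParams("bad", 0.5, 0.1, 0.9, 0.1, 0.4, 0.1, 1.0, 0.1,
                            10.0, 1.0)  # seatoff_mean not > 1
        with pytest.raises(ValueError):
            ArchetypeParams("bad", 0.5, -0.1, 1.2, 0.1, 0.4, 0.1, 1.0, 0.1,
                            10.0, 1.0)  # negative sd


class TestSynthCycle:
    AMPS = CycleAmplitudes(base=0.45, unload=0.50, seatoff=1.16, stab=0.39,
                           stand=1.04, sitdown=1.20)

    def test_landmarks_are_exact_extrema_without_noise(self):
        rng = np.random.default_rng(0)
        y, idx = synth_cycle(self.AMPS, 2.4, 200.0, 0.0, rng)
        assert y[idx["seatoff"]] == pytest.approx(1.16, abs=1e-9)
        assert y.max() == pytest.approx(1.20, abs=1e-9)          # sit-down impact
        assert y[: int(0.5 * len(y))].max() == pytest.approx(1.16, abs=1e-9)
        # stabilization dip is the minimum after the seat-off peak
        post = y[idx["seatoff"]: idx["stand"]]
        assert post.min() == pytest.approx(0.39, abs=1e-9)
        assert y[idx["unload"]] == pytest.approx(0.50, abs=1e-9)

    def test_deterministic_given_rng_state(self):
        y1, _ = synth_cycle(self.AMPS, 2.0, 200.0, 0.01, np.random.default_rng(7))
        y2, _ = synth_cycle(self.AMPS, 2.0, 200.0, 0.01, np.random.default_rng(7))
        assert np.array_equal(y1, y2)

    @pytest.mark.parametrize("dur,rate", [(0.0, 200.0), (-1.0, 200.0), (2.0, 0.0)])
    def test_nonpositive_duration_or_rate_rejected(self, dur, rate):
        with pytest.raises(ValueError):
            synth_cycle(self.AMPS, dur, rate, 0.0, np.random.default_rng(0))

    def test_landmark_order(self):
        _, idx = synth_cycle(self.AMPS, 2.0, 200.0, 0.0, np.random.default_rng(0))
        assert idx["unload"] < idx["seatoff"] < idx["stab"] < idx["stand"]


class TestAmplitudeCalibration:
    @pytest.mark.parametrize("which", [0, 1])
    def test_sample_means_match_targets(self, archetypes, which):
        """Mean-matched truncated sampling: n=10,000 means within ~4 SE."""
        arch = archetypes[which]
        rng = np.random.default_rng(11)
        draws = np.array([[a.unload, a.seatoff, a.stab, a.stand]
                          for a in (_draw_amplitudes(arch, rng)
                                    for _ in range(10_000))])
        targets = [arch.unload_mean, arch.seatoff_mean, arch.stab_mean,
                   arch.stand_mean]
        for sample, target in zip(draws.T, targets):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - target) < 4 * se + 1e-3

    def test_physiological_bounds_hold(self, archetypes):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            a = _draw_amplitudes(archetypes[1], rng)
            assert 0.08 <= a.unload <= 0.95
            assert a.seatoff >= 1.02
            assert 0.02 < a.stab < 0.95
            assert a.stab + 0.08 <= a.stand <= 1.15
            assert a.seatoff >= a.stab + 0.20


class TestSynthParticipant:
    def test_structure_and_length(self, archetypes, noise_free_cfg):
        rng = np.random.default_rng(4)
        rec, truth = synth_participant(archetypes[0], noise_free_cfg, rng)
        rate = noise_free_cfg.sampling_rate_hz
        expected = truth.t_grf_s * rate + 2 * noise_free_cfg.rest_pad_s * rate
        assert rec.fz_raw.shape[0] == pytest.approx(expected, abs=2)
        assert len(truth.cycles) == 5
        for c in truth.cycles:
            assert c.start_idx < c.unload_idx < c.seatoff_idx \
                < c.stab_idx < c.stand_idx < c.end_idx

    def test_zero_jitter_cycles_share_amplitudes(self, archetypes, noise_free_cfg):
        rng = np.random.default_rng(4)
        _, truth = synth_participant(archetypes[0], noise_free_cfg, rng)
        stabs = {round(c.stab, 12) for c in truth.cycles}
        assert len(stabs) == 1

    def test_duration_relation_embedded(self, archetypes):
        """OLS on the truth channel recovers the configured linear relation."""
        cfg = CohortConfig(n_per_archetype=(150, 150), noise_sd=0.0, seed=9)
        cohort = synth_cohort(cfg)
        sw = np.array([t.t_stopwatch_s for _, t in cohort])
        grf = np.array([t.t_grf_s for _, t in cohort])
        fit = sps.linregress(sw, grf)
        assert abs(fit.slope - cfg.grf_slope) < 2 * fit.stderr
        assert abs(fit.intercept - cfg.grf_intercept) < 2 * fit.intercept_stderr

    def test_bounded_in_au_at_default_noise(self, archetypes):
        cfg = CohortConfig(n_per_archetype=(3, 3), seed=13)
        for rec, _ in synth_cohort(cfg):
            au = rec.fz_raw / (rec.mass_kg * 9.81)
            assert np.all(np.isfinite(au))
            assert au.min() > 0.0 and au.max() < 2.0


class TestSynthCohort:
    def test_counts_labels_and_unique_ids(self):
        cohort = synth_cohort(CohortConfig(n_per_archetype=(3, 4), seed=5))
        assert len(cohort) == 7
        ids = [r.participant_id for r, _ in cohort]
        assert len(set(ids)) == 7
        labels = [t.archetype_label for _, t in cohort]
        assert labels.count("archetype1") == 3
        assert labels.count("archetype2") == 4

    def test_same_seed_reproduces_exactly(self):
        cfg = CohortConfig(n_per_archetype=(2, 2), seed=21)
        a, b = synth_cohort(cfg), synth_cohort(cfg)
        for (ra, ta), (rb, tb) in zip(a, b):
            assert np.array_equal(ra.fz_raw, rb.fz_raw)
            assert ta == tb

    def test_minimal_cohort(self):
        assert len(synth_cohort(CohortConfig(n_per_archetype=(1, 1), seed=0))) == 2
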