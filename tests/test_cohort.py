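"""Synthetic cohort generator: calibration, construction, determinism."""

import numpy as np
import pytest

from ppgage.bayes import bayes_mae_from_asi
from ppgage.cohort import (CohortConfig, InfeasibleSubjectError, Subject,
                           generate_cohort, median_asi_curve, sample_true_asi,
                           synthesize_pulse)


class TestMedianCurve:
    @pytest.mark.parametrize("age,expected", [(40, 7.3), (50, 8.4), (70, 9.9)])
    def test_printed_anchor_medians(self, age, expected):
        assert median_asi_curve(age) == pytest.approx(expected)

    def test_linear_midpoint(self):
        assert median_asi_curve(45, anchors=((40, 7.3), (50, 8.4))) == pytest.approx(7.85)

    def test_outside_anchor_range_raises(self):
        with pytest.raises(ValueError, match="anchor range"):
            median_asi_curve(39.0)
        with pytest.raises(ValueError, match="anchor range"):
            median_asi_curve(71.0)

    def test_non_monotone_anchors_rejected(self):
        cfg = CohortConfig(median_asi_anchors=((40, 8.0), (50, 7.0)))
        with pytest.raises(ValueError, match="increasing"):
            cfg.validate()


class TestTrueAsiLaw:
    def test_degenerate_dispersion_is_exact(self):
        cfg = CohortConfig(dispersion_sigma=0.0)
        rng = np.random.default_rng(0)
        draws = [sample_true_asi(40.0, cfg, rng) for _ in range(20)]
        assert draws == [pytest.approx(7.3)] * 20

    def test_median_calibration_at_anchor_ages(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(1)
        for age in (40.0, 50.0, 70.0):
            draws = sample_true_asi(np.full(10_000, age), cfg, rng)
            target = median_asi_curve(age)
            assert np.median(draws) == pytest.approx(target, rel=0.02)

    def test_age40_third_quartile_matches_printed_value(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(2)
        draws = sample_true_asi(np.full(100_000, 40.0), cfg, rng)
        assert np.percentile(draws, 75) == pytest.approx(8.8, rel=0.02)

    def test_zero_signal_strength_removes_age_dependence(self):
        from scipy.stats import ks_2samp

        cfg = CohortConfig(signal_strength=0.0)
        rng = np.random.default_rng(3)
        a40 = sample_true_asi(np.full(10_000, 40.0), cfg, rng)
        a70 = sample_true_asi(np.full(10_000, 70.0), cfg, rng)
        assert ks_2samp(a40, a70).pvalue > 0.01


class TestPulseSynthesis:
    @staticmethod
    def _subject(dt=0.20, stature=1.69, mclass=0, age=55.0):
        return Subject(id="x", age=age, sex="female", stature=stature,
                       true_asi=stature / dt, true_dt=dt,
                       morphology_class=mclass)

    def test_reflected_peak_lags_by_exact_sample_count(self):
        from scipy.signal import find_peaks

        cfg = CohortConfig(noise_sd=0.0)
        w = synthesize_pulse(self._subject(dt=0.20), cfg)
        y = w.samples
        sys_idx = int(np.argmax(y))
        peaks, _ = find_peaks(y[sys_idx + 1:])
        assert peaks.size >= 1
        assert peaks[-1] + 1 == 20  # lag in samples

    def test_age_enters_only_through_transit_time(self):
        cfg = CohortConfig(noise_sd=0.0)
        w1 = synthesize_pulse(self._subject(age=41.0), cfg)
        w2 = synthesize_pulse(self._subject(age=69.0), cfg)
        assert np.array_equal(w1.samples, w2.samples)

    def test_normalized_range_and_systolic_global_max(self):
        cfg = CohortConfig(noise_sd=0.0)
        w = synthesize_pulse(self._subject(), cfg)
        assert w.samples.min() == pytest.approx(0.0)
        assert w.samples.max() == pytest.approx(1.0)
        assert np.argmax(w.samples) == 15

    def test_morphology_classes_cluster(self):
        cfg = CohortConfig(noise_sd=0.01, n_morphology_classes=2)
        rng = np.random.default_rng(4)
        waves = []
        for i in range(12):
            s = self._subject(dt=0.18 + 0.002 * (i % 3), mclass=i % 2)
            waves.append(synthesize_pulse(s, cfg, rng).samples)
        waves = np.stack(waves)
        dist = np.linalg.norm(waves[:, None] - waves[None, :], axis=-1)
        same = np.array([[i % 2 == j % 2 for j in range(12)] for i in range(12)])
        off = ~np.eye(12, dtype=bool)
        assert dist[same & off].mean() < dist[~same].mean()

    def test_infeasible_transit_time_raises(self):
        cfg = CohortConfig(noise_sd=0.0)
        with pytest.raises(InfeasibleSubjectError):
            synthesize_pulse(self._subject(dt=0.05), cfg)   # lag below floor
        with pytest.raises(InfeasibleSubjectError):
            synthesize_pulse(self._subject(dt=0.90), cfg)   # beyond pulse end


class TestGenerateCohort:
    def test_empty_cohort(self):
        subjects, waveforms = generate_cohort(CohortConfig(n=0))
        assert subjects == [] and waveforms == []

    def test_seeded_bit_reproducibility(self):
        cfg = CohortConfig(n=50, seed=9)
        s1, w1 = generate_cohort(cfg)
        s2, w2 = generate_cohort(cfg)
        assert s1 == s2
        assert all(np.array_equal(a.samples, b.samples) for a, b in zip(w1, w2))

    def test_subject_invariants(self, small_cohort):
        cfg, subjects, waveforms = small_cohort
        for s in subjects:
            assert s.true_dt > 0 and s.true_asi > 0
            assert s.true_dt == pytest.approx(s.stature / s.true_asi)
            assert cfg.age_range[0] <= s.age <= cfg.age_range[1]
        assert {w.subject_id for w in waveforms} == {s.id for s in subjects}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n=-1).validate()
        with pytest.raises(ValueError):
            CohortConfig(signal_strength=1.5).validate()
        with pytest.raises(ValueError):
            CohortConfig(age_distribution="fixed").validate()


def test_prediction_ceiling_monotone_in_dispersion():
    """The Bayes-optimal MAE of age-from-ASI never improves as spread grows."""
    maes = [bayes_mae_from_asi(CohortConfig(dispersion_sigma=s), n_mc=20_000, seed=3)
            for s in (0.0, 0.05, 0.1, 0.2, 0.277, 0.4)]
    assert all(b >= a - 1e-9 for a, b in zip(maes, maes[1:]))
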