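"""ASI extraction: peak detection, the stiffness formula, robust quartiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgage.asi import (compute_asi, detect_peaks, extract_asi_table,
                        quantile_summary, robust_quartiles, PeakDetectionError)
from ppgage.cohort import CohortConfig, PulseWaveform, generate_cohort


def _wave(samples, dt=0.01):
    return PulseWaveform(subject_id="w", samples=np.asarray(samples, float),
                         dt_sample=dt)


def _two_bump(sys_idx=20, ref_idx=40, a_ref=0.5, n=100):
    t = np.arange(n, dtype=float)
    y = np.exp(-0.5 * ((t - sys_idx) / 2.0) ** 2)
    y += a_ref * np.exp(-0.5 * ((t - ref_idx) / 3.5) ** 2)
    return y


class TestDetectPeaks:
    def test_impulse_pair(self):
        y = np.zeros(100)
        y[20], y[40] = 1.0, 0.5
        peaks, flag = detect_peaks(_wave(y))
        assert (peaks.systolic_idx, peaks.reflected_idx) == (20, 40)
        assert peaks.dt == pytest.approx(0.20)
        assert flag == "ok"

    def test_monotone_ramp_rejected(self):
        with pytest.raises(PeakDetectionError):
            detect_peaks(_wave(np.linspace(1, 0, 100)))

    def test_constant_signal_rejected(self):
        with pytest.raises(PeakDetectionError):
            detect_peaks(_wave(np.ones(100)))

    def test_earliest_global_maximum_wins_ties(self):
        y = np.zeros(100)
        y[[10, 30]] = 1.0  # tie at the maximum
        y[50] = 0.4
        peaks, _ = detect_peaks(_wave(y))
        assert peaks.systolic_idx == 10

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, scale):
        y = _two_bump()
        p1, f1 = detect_peaks(_wave(y))
        p2, f2 = detect_peaks(_wave(scale * y))
        assert (p1, f1) == (p2, f2)

    def test_time_shift_equivariance(self):
        y = _two_bump()
        p1, _ = detect_peaks(_wave(y))
        shifted = np.r_[np.full(7, y[0]), y]
        p2, _ = detect_peaks(_wave(shifted))
        assert p2.systolic_idx == p1.systolic_idx + 7
        assert p2.reflected_idx == p1.reflected_idx + 7
        assert p2.dt == pytest.approx(p1.dt)


class TestComputeAsi:
    def test_direct_formula(self):
        res = compute_asi(_wave(_two_bump(20, 40)), stature=1.6)
        assert res.asi == pytest.approx(1.6 / 0.20)
        res = compute_asi(_wave(_two_bump(20, 37)), stature=1.7)
        assert res.asi == pytest.approx(10.0)

    def test_rejection_propagates_without_raising(self):
        res = compute_asi(_wave(np.linspace(1, 0, 100)), stature=1.7)
        assert res.quality_flag == "rejected"
        assert res.asi is None and res.peaks is None

    def test_nonpositive_stature_rejected(self):
        with pytest.raises(ValueError):
            compute_asi(_wave(_two_bump()), stature=0.0)

    def test_noise_free_roundtrip_within_one_sample_bound(self):
        cfg = CohortConfig(n=200, seed=7, noise_sd=0.0)
        subjects, waveforms = generate_cohort(cfg)
        table = extract_asi_table(waveforms, subjects)
        for s, asi in zip(subjects, table["asi"]):
            bound = s.true_asi * cfg.dt_sample / s.true_dt
            assert abs(asi - s.true_asi) <= bound + 1e-12


class TestQuantileSummary:
    def test_small_symmetric_set_untouched(self):
        out = robust_quartiles([1, 2, 3, 4, 5])
        assert out["n_removed"] == 0
        assert (out["q1"], out["median"], out["q3"]) == (2, 3, 4)

    def test_gross_outlier_removed_by_3iqr_rule(self):
        out = robust_quartiles([1, 2, 3, 4, 100])
        # Q1=2, Q3=4, IQR=2 on raw values -> upper bound 10 -> 100 removed
        assert out["n_removed"] == 1
        assert out["n_retained"] == 4

    def test_identical_values_degenerate(self):
        out = robust_quartiles([5.0] * 9)
        assert out["n_removed"] == 0
        assert out["q1"] == out["median"] == out["q3"] == 5.0

    @pytest.mark.parametrize("seed", range(6))
    def test_removal_idempotent_on_continuous_data(self, seed):
        """Once outliers are gone, a second 3-IQR pass removes nothing.

        Checked on log-normal draws shaped like the ASI distribution (the
        rule is applied to continuous unimodal data in this pipeline).
        """
        rng = np.random.default_rng(seed)
        vals = 8.4 * np.exp(0.277 * rng.standard_normal(500))
        first = robust_quartiles(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        kept = vals[(vals >= q1 - 3 * iqr) & (vals <= q3 + 3 * iqr)]
        second = robust_quartiles(kept)
        assert second["n_removed"] == 0
        assert first["median"] == pytest.approx(second["median"])

    def test_bucketed_summary_and_empty_buckets(self):
        ages = np.array([41.0, 42.0, 67.0])
        vals = np.array([7.0, 7.5, 9.8])
        out = quantile_summary(vals, ages)
        out = out.set_index("bucket")
        assert out.loc["[40,45)", "n_retained"] == 2
        assert out.loc["[65,70)", "median"] == pytest.approx(9.8)
        assert out.loc["[50,55)", "n_retained"] == 0
        assert np.isnan(out.loc["[50,55)", "median"])
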