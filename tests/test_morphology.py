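"""Cross-bucket similarity groups and per-bucket waveform summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgage.buckets import make_age_buckets
from ppgage.cohort import CohortConfig, PulseWaveform, generate_cohort
from ppgage.morphology import (bucket_mean_overlay, cross_bucket_groups,
                               normalize_waveform)


def _wave(samples, sid):
    return PulseWaveform(subject_id=sid, samples=np.asarray(samples, float),
                         dt_sample=0.01)


class TestNormalize:
    def test_basic_scaling(self):
        assert np.allclose(normalize_waveform([0, 5, 10] + [0] * 13),
                           [0, 0.5, 1.0] + [0] * 13)

    def test_idempotent_on_unit_range(self):
        y = np.linspace(0, 1, 30)
        assert np.allclose(normalize_waveform(y), y)

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(0.01, 50), b=st.floats(-10, 10))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        y = rng.random(40)
        assert np.allclose(normalize_waveform(a * y + b), normalize_waveform(y),
                           atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_waveform(np.ones(20))


def _cohort_buckets(n, seed):
    cfg = CohortConfig(n=n, seed=seed)
    subjects, waveforms = generate_cohort(cfg)
    ages = np.array([s.age for s in subjects])
    ids = [s.id for s in subjects]
    return subjects, waveforms, make_age_buckets(ages, ids)


class TestCrossBucketGroups:
    def test_planted_identical_waveform_found_with_zero_spread(self):
        subjects, waveforms, buckets = _cohort_buckets(60, 1)
        template = waveforms[0].samples
        wmap = {w.subject_id: w for w in waveforms}
        planted = []
        for b in buckets:
            sid = b.member_ids[0]
            wmap[sid] = _wave(template, sid)
            planted.append(sid)
        waves2 = [wmap[s.id] for s in subjects]
        groups = cross_bucket_groups(waves2, buckets, group_size=6, n_groups=1)
        assert set(groups[0].member_ids) == set(planted)
        assert groups[0].intra_distance == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_exhaustive_on_small_instances(self, seed):
        _, waveforms, buckets = _cohort_buckets(30, seed)
        size = len([b for b in buckets if b.member_ids])
        g = cross_bucket_groups(waveforms, buckets, group_size=size, n_groups=1)
        e = cross_bucket_groups(waveforms, buckets, group_size=size, n_groups=1,
                                method="exhaustive")
        assert set(g[0].member_ids) == set(e[0].member_ids)
        assert g[0].intra_distance == pytest.approx(e[0].intra_distance)

    def test_two_planted_morphologies_yield_two_pure_groups(self):
        t = np.arange(100.0)
        shape_a = np.exp(-0.5 * ((t - 25) / 4) ** 2)
        shape_b = np.exp(-0.5 * ((t - 70) / 9) ** 2)
        waves, ages, ids = [], [], []
        rng = np.random.default_rng(0)
        for k, lo in enumerate(range(40, 70, 5)):
            for shape, tag in ((shape_a, "a"), (shape_b, "b")):
                sid = f"{tag}{k}"
                waves.append(_wave(shape + rng.normal(0, 0.005, 100), sid))
                ages.append(lo + 2.0)
                ids.append(sid)
        buckets = make_age_buckets(ages, ids)
        groups = cross_bucket_groups(waves, buckets, group_size=6, n_groups=2)
        assert len(groups) == 2
        for g in groups:
            tags = {m[0] for m in g.member_ids}
            assert len(tags) == 1            # each group is pure
            assert len(set(g.source_buckets)) == 6

    def test_grouping_invariant_to_amplitude_rescaling(self):
        _, waveforms, buckets = _cohort_buckets(40, 2)
        scaled = [_wave(w.samples * 11.0, w.subject_id) for w in waveforms]
        size = len([b for b in buckets if b.member_ids])
        g1 = cross_bucket_groups(waveforms, buckets, group_size=size, n_groups=1)
        g2 = cross_bucket_groups(scaled, buckets, group_size=size, n_groups=1)
        assert set(g1[0].member_ids) == set(g2[0].member_ids)

    def test_empty_bucket_is_an_itemized_error(self):
        _, waveforms, _ = _cohort_buckets(20, 3)
        buckets = make_age_buckets([41.0] * 20,
                                   [w.subject_id for w in waveforms])
        with pytest.raises(ValueError, match=r"\[45,50\)"):
            cross_bucket_groups(waveforms, buckets, group_size=6)


class TestBucketOverlay:
    def test_identical_members_mean_equals_them_spread_zero(self):
        b = make_age_buckets([41.0, 42.0], ["x", "y"], age_range=(40, 45))
        y = np.r_[np.zeros(50), np.linspace(0, 1, 50)]
        out = bucket_mean_overlay([_wave(y, "x"), _wave(y, "y")], b)
        mean, sd = out["[40,45)"]
        assert np.allclose(mean, normalize_waveform(y))
        assert np.allclose(sd, 0.0)

    def test_mirror_pair_averages_to_half(self):
        b = make_age_buckets([41.0, 42.0], ["x", "y"], age_range=(40, 45))
        y = np.linspace(0, 1, 60)
        out = bucket_mean_overlay([_wave(y, "x"), _wave(1 - y, "y")], b)
        mean, _ = out["[40,45)"]
        assert np.allclose(mean, 0.5)

    def test_default_cohort_every_bucket_has_spread(self):
        _, waveforms, buckets = _cohort_buckets(300, 0)
        out = bucket_mean_overlay(waveforms, buckets)
        for label, (_, sd) in out.items():
            assert sd.max() > 0.0, label


def test_buckets_tile_the_age_range():
    ages = np.linspace(40, 70, 121)
    buckets = make_age_buckets(ages, np.arange(ages.size))
    assert [b.label for b in buckets] == [
        "[40,45)", "[45,50)", "[50,55)", "[55,60)", "[60,65)", "[65,70)"]
    counts = sum(len(b.member_ids) for b in buckets)
    assert counts == ages.size  # every age in exactly one bucket
    for b in buckets:
        for sid in b.member_ids:
            age = ages[sid]
            assert b.lo <= age <= b.hi  # top edge closed on the last bucket
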