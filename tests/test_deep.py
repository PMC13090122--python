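"""NumPy waveform-to-age networks: gradients, determinism, invariances."""

import numpy as np
import pytest

import ppgage.models.deep as deep_mod
from ppgage.models import (ResNetConfig, ResnetAgeModel, SmolkAgeModel,
                           SmolkConfig, TrainConfig, MeanAgeModel,
                           load_checkpoint)
from ppgage.models.base import UnsupportedOperationError


def _numerical_gradient(net, x, y, key, eps=1e-6):
    p = net.params[key]
    g = np.zeros_like(p, dtype=float)
    it = np.nditer(p, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = p[idx]
        p[idx] = orig + eps
        up = np.mean((net.forward(x) - y) ** 2)
        p[idx] = orig - eps
        dn = np.mean((net.forward(x) - y) ** 2)
        p[idx] = orig
        g[idx] = (up - dn) / (2 * eps)
    return g


@pytest.mark.parametrize("arch", ["smolk", "resnet"])
def test_backprop_matches_numerical_gradient(arch, monkeypatch):
    monkeypatch.setattr(deep_mod, "_DTYPE", np.float64)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((4, 40))
    y = rng.standard_normal(4)
    if arch == "smolk":
        net = deep_mod._SmolkNet(SmolkConfig(n_kernels=6, kernel_lengths=(4, 8)),
                                 40, rng)
    else:
        net = deep_mod._ResNet(ResNetConfig(n_blocks=2, channels=4,
                                            kernel_size=3, stem_kernel=3),
                               40, rng)
    cache = {}
    pred = net.forward(x, cache)
    grads = net.backward(x, cache, (2.0 / 4) * (pred - y))
    for key, g in grads.items():
        ng = _numerical_gradient(net, x, y, key)
        denom = np.max(np.abs(ng)) + 1e-12
        assert np.max(np.abs(g - ng)) / denom < 1e-2, key


def test_training_is_bit_reproducible(det_arrays):
    ages, wav = det_arrays
    tc = TrainConfig(seed=5, max_epochs=12, early_stop_patience=12)
    r1 = SmolkAgeModel(ages[:300], wav[:300]).fit(tc)
    r2 = SmolkAgeModel(ages[:300], wav[:300]).fit(tc)
    assert all(np.array_equal(r1.params[k], r2.params[k]) for k in r1.params)
    assert np.array_equal(r1.predict(wav[300:350]), r2.predict(wav[300:350]))


def test_predictions_invariant_to_amplitude_rescaling(trained_smolk, det_arrays):
    _, wav = det_arrays
    p1 = trained_smolk.predict(wav[1000:1100])
    p2 = trained_smolk.predict(wav[1000:1100] * 37.5)
    assert np.allclose(p1, p2, atol=1e-3)


def test_learns_age_from_peak_spacing(trained_smolk, det_arrays):
    """With all dispersion off, the lag determines age: MAE well under the
    ~7.5-year no-skill level."""
    ages, wav = det_arrays
    mae = np.mean(np.abs(trained_smolk.predict(wav[1000:]) - ages[1000:]))
    assert mae < 3.0


def test_resnet_capacity_at_least_matches_smolk(trained_smolk, trained_resnet,
                                                det_arrays):
    ages, wav = det_arrays
    mae_s = np.mean(np.abs(trained_smolk.predict(wav[1000:]) - ages[1000:]))
    mae_r = np.mean(np.abs(trained_resnet.predict(wav[1000:]) - ages[1000:]))
    assert mae_r <= mae_s + 1.0


class TestEmbeddings:
    def test_identical_waveforms_identical_rows(self, trained_smolk, det_arrays):
        _, wav = det_arrays
        batch = np.stack([wav[1000], wav[1000], wav[1001]])
        emb = trained_smolk.embed(batch)
        assert np.array_equal(emb[0], emb[1])
        assert not np.array_equal(emb[0], emb[2])

    def test_dimension_equals_head_input_width(self, trained_smolk, det_arrays):
        _, wav = det_arrays
        emb = trained_smolk.embed(wav[:20])
        assert emb.shape[1] == trained_smolk.embedding_dim
        assert emb.shape[1] == trained_smolk.params["w"].size
        assert np.all(np.isfinite(emb))

    def test_first_pc_tracks_age_on_lag_dominant_cohort(self, trained_smolk,
                                                        det_arrays):
        ages, wav = det_arrays
        emb = trained_smolk.embed(wav[1000:])
        centred = emb - emb.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        r = np.corrcoef(centred @ vt[0], ages[1000:])[0, 1]
        assert abs(r) > 0.5

    def test_non_deep_predictor_has_no_embedding(self):
        res = MeanAgeModel([40.0, 50.0]).fit()
        with pytest.raises(UnsupportedOperationError):
            res.embed()


def test_checkpoint_roundtrip(tmp_path, trained_smolk, det_arrays):
    ages, wav = det_arrays
    path = tmp_path / "smolk.npz"
    trained_smolk.save(path)
    loaded = load_checkpoint(path, ages[:1000], wav[:1000])
    assert np.allclose(loaded.predict(wav[1000:1050]),
                       trained_smolk.predict(wav[1000:1050]))


def test_divergent_training_raises(det_arrays):
    ages, wav = det_arrays
    tc = TrainConfig(seed=0, max_epochs=5, learning_rate=1e12)
    with pytest.raises(deep_mod.TrainingError):
        SmolkAgeModel(ages[:200], wav[:200]).fit(tc)


def test_config_validation():
    with pytest.raises(ValueError):
        SmolkConfig(kernel_lengths=(8, 200)).validate(100)
    with pytest.raises(ValueError):
        ResNetConfig(n_blocks=0).validate(100)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1.0).validate()
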