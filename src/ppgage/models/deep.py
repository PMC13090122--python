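"""Waveform-to-age regressors: learned-kernel (SMoLK-style) and residual nets.

Both architectures are implemented directly in NumPy with hand-written
reverse-mode gradients — the networks are tiny (100-sample inputs, tens of
thousands of parameters) and a dependency-free CPU implementation keeps
training bit-reproducible from a single integer seed.

SMoLK-style model: a small bank of learnable convolution kernels of mixed
lengths, ReLU, global average pooling of each kernel's response map, and a
linear head.  Each pooled feature is the average activation of one kernel
over the pulse, so the kernels themselves are interpretable templates.

ResNet-style model: a 1-D convolutional stem, residual blocks (conv-ReLU-conv
plus identity skip), global average pooling over time, and a linear head.

Every pulse is amplitude-standardized (zero mean, unit variance) inside the
input stage, which makes predictions invariant to positive rescaling of the
raw signal.  Squared-error loss on standardized ages; Adam; early stopping on
a tuning split carved from the training data (never the validation fold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .base import AgeModel, AgeModelResults, FitError

__all__ = [
    "SmolkConfig", "ResNetConfig", "TrainConfig",
    "SmolkAgeModel", "ResnetAgeModel", "NeuralAgeResults",
    "TrainingError", "load_checkpoint",
]

_DTYPE = np.float32


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass(frozen=True)
class SmolkConfig:
    n_kernels: int = 32
    kernel_lengths: tuple = (8, 16, 32)   # split evenly across lengths
    activation: str = "relu"

    def validate(self, waveform_length: int):
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if any(L >= waveform_length for L in self.kernel_lengths):
            raise ValueError("every kernel must be shorter than the waveform")


@dataclass(frozen=True)
class ResNetConfig:
    n_blocks: int = 4
    channels: int = 16
    kernel_size: int = 5
    stem_kernel: int = 7

    def validate(self, waveform_length: int):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel_size >= waveform_length:
            raise ValueError("kernel_size must be shorter than the waveform")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 3e-3
    early_stop_patience: int = 15
    tuning_fraction: float = 0.1
    seed: int = 0

    def validate(self):
        if min(self.max_epochs, self.batch_size,
               self.early_stop_patience) < 1 or self.learning_rate <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not 0.0 < self.tuning_fraction < 0.5:
            raise ValueError("tuning_fraction must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# primitive ops (forward + exact backward)
# ---------------------------------------------------------------------------

def standardize_pulses(x: np.ndarray) -> np.ndarray:
    """Per-pulse amplitude standardization: zero mean, unit variance."""
    x = np.asarray(x, dtype=_DTYPE)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return (x - mu) / np.maximum(sd, 1e-8)


def _conv_valid(x, W, b):
    """x (B, T), W (m, L), b (m,) -> (B, T-L+1, m) valid correlation."""
    L = W.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(x, L, axis=1)
    return win @ W.T + b, win


def _conv_valid_backward(grad, win, W):
    dW = np.einsum("bpm,bpl->ml", grad, win)
    db = grad.sum(axis=(0, 1))
    return dW, db  # input gradient unused: kernels sit on the raw pulse


def _conv_same(x, W, b):
    """x (B, C, T), W (O, C, K), b (O,) -> (B, O, T), same padding (odd K)."""
    B, C, T = x.shape
    K = W.shape[2]
    p = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    out = np.zeros((B, W.shape[0], T), dtype=_DTYPE)
    for j in range(K):
        out += np.einsum("bct,oc->bot", xp[:, :, j:j + T], W[:, :, j],
                         optimize=True)
    return out + b[None, :, None], xp


def _conv_same_backward(grad, xp, W, input_grad=True):
    B, O, T = grad.shape
    K = W.shape[2]
    p = K // 2
    dW = np.empty_like(W)
    for j in range(K):
        dW[:, :, j] = np.einsum("bot,bct->oc", grad, xp[:, :, j:j + T],
                                optimize=True)
    db = grad.sum(axis=(0, 2))
    dx = None
    if input_grad:
        dxp = np.zeros_like(xp)
        for j in range(K):
            dxp[:, :, j:j + T] += np.einsum("bot,oc->bct", grad, W[:, :, j],
                                            optimize=True)
        dx = dxp[:, :, p:p + T]
    return dx, dW, db


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DTYPE)


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------

class _SmolkNet:
    def __init__(self, config: SmolkConfig, waveform_length: int,
                 rng: np.random.Generator):
        config.validate(waveform_length)
        lengths = list(config.kernel_lengths)
        base, extra = divmod(config.n_kernels, len(lengths))
        self.group_sizes = [base + (1 if i < extra else 0)
                            for i in range(len(lengths))]
        self.lengths = lengths
        self.params = {}
        for i, (L, m) in enumerate(zip(lengths, self.group_sizes)):
            self.params[f"K{i}"] = (rng.standard_normal((m, L)) / np.sqrt(L)).astype(_DTYPE)
            self.params[f"kb{i}"] = np.zeros(m, dtype=_DTYPE)
        F = config.n_kernels
        self.params["w"] = (rng.standard_normal(F) / np.sqrt(F)).astype(_DTYPE)
        self.params["b"] = np.zeros(1, dtype=_DTYPE)
        self.feature_dim = F

    def features(self, x, cache=None):
        feats = []
        for i, L in enumerate(self.lengths):
            pre, win = _conv_valid(x, self.params[f"K{i}"], self.params[f"kb{i}"])
            act = np.maximum(pre, 0.0)
            feats.append(act.mean(axis=1))
            if cache is not None:
                cache[i] = (pre, win)
        return np.concatenate(feats, axis=1)

    def forward(self, x, cache=None):
        f = self.features(x, cache)
        if cache is not None:
            cache["f"] = f
        return f @ self.params["w"] + self.params["b"][0]

    def backward(self, x, cache, dy):
        grads = {}
        f = cache["f"]
        grads["w"] = dy @ f
        grads["b"] = np.array([dy.sum()], dtype=_DTYPE)
        dfeat = np.outer(dy, self.params["w"])
        col = 0
        for i, m in enumerate(self.group_sizes):
            pre, win = cache[i]
            n_pos = pre.shape[1]
            dpre = (dfeat[:, None, col:col + m] / n_pos) * (pre > 0)
            grads[f"K{i}"], grads[f"kb{i}"] = _conv_valid_backward(
                dpre.astype(_DTYPE), win, self.params[f"K{i}"])
            col += m
        return grads


class _ResNet:
    def __init__(self, config: ResNetConfig, waveform_length: int,
                 rng: np.random.Generator):
        config.validate(waveform_length)
        C, K = config.channels, config.kernel_size
        self.config = config
        self.params = {
            "stem_W": (rng.standard_normal((C, 1, config.stem_kernel))
                       / np.sqrt(config.stem_kernel)).astype(_DTYPE),
            "stem_b": np.zeros(C, dtype=_DTYPE),
            "w": (rng.standard_normal(C) / np.sqrt(C)).astype(_DTYPE),
            "b": np.zeros(1, dtype=_DTYPE),
        }
        for i in range(config.n_blocks):
            for j in (1, 2):
                self.params[f"blk{i}_W{j}"] = (
                    rng.standard_normal((C, C, K)) / np.sqrt(C * K)).astype(_DTYPE)
                self.params[f"blk{i}_b{j}"] = np.zeros(C, dtype=_DTYPE)
        self.feature_dim = C

    def features(self, x, cache=None):
        h = x[:, None, :]
        out, xp = _conv_same(h, self.params["stem_W"], self.params["stem_b"])
        a = np.maximum(out, 0.0)
        if cache is not None:
            cache["stem"] = (out, xp)
        h = a
        for i in range(self.config.n_blocks):
            o1, xp1 = _conv_same(h, self.params[f"blk{i}_W1"], self.params[f"blk{i}_b1"])
            a1 = np.maximum(o1, 0.0)
            o2, xp2 = _conv_same(a1, self.params[f"blk{i}_W2"], self.params[f"blk{i}_b2"])
            s = o2 + h
            out_blk = np.maximum(s, 0.0)
            if cache is not None:
                cache[f"blk{i}"] = (o1, xp1, o2, xp2, s)
            h = out_blk
        feats = h.mean(axis=2)
        if cache is not None:
            cache["pooled_from"] = h
        return feats

    def forward(self, x, cache=None):
        f = self.features(x, cache)
        if cache is not None:
            cache["f"] = f
        return f @ self.params["w"] + self.params["b"][0]

    def backward(self, x, cache, dy):
        grads = {}
        f = cache["f"]
        grads["w"] = dy @ f
        grads["b"] = np.array([dy.sum()], dtype=_DTYPE)
        T = x.shape[1]
        dh = (np.outer(dy, self.params["w"])[:, :, None] / T).astype(_DTYPE)
        dh = np.broadcast_to(dh, cache["pooled_from"].shape).copy()
        for i in reversed(range(self.config.n_blocks)):
            o1, xp1, o2, xp2, s = cache[f"blk{i}"]
            ds = dh * (s > 0)
            do2 = ds
            da1, grads[f"blk{i}_W2"], grads[f"blk{i}_b2"] = _conv_same_backward(
                do2, xp2, self.params[f"blk{i}_W2"])
            do1 = da1 * (o1 > 0)
            dh_in, grads[f"blk{i}_W1"], grads[f"blk{i}_b1"] = _conv_same_backward(
                do1, xp1, self.params[f"blk{i}_W1"])
            dh = dh_in + ds  # skip connection
        out, xp = cache["stem"]
        dstem = dh * (out > 0)
        _, grads["stem_W"], grads["stem_b"] = _conv_same_backward(
            dstem, xp, self.params["stem_W"], input_grad=False)
        return grads


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class NeuralAgeResults(AgeModelResults):
    """Fitted deep regressor: weights, training history, embeddings."""

    def __init__(self, model, net, arch_config, train_config, history):
        super().__init__(model, dict(net.params))
        self.kind = model.kind
        self._net = net
        self.arch_config = arch_config
        self.train_config = train_config
        self.history = history
        self.y_mean = model._y_mean
        self.y_sd = model._y_sd

    @property
    def embedding_dim(self) -> int:
        return self._net.feature_dim

    def predict(self, exog=None, batch_size: int = 512) -> np.ndarray:
        x = standardize_pulses(self.model.exog if exog is None else exog)
        out = [self._net.forward(x[i:i + batch_size])
               for i in range(0, x.shape[0], batch_size)]
        yhat = np.concatenate(out)
        return (self.y_mean + self.y_sd * yhat).astype(float)

    def embed(self, exog=None, batch_size: int = 512) -> np.ndarray:
        """Pooled pre-head representation, one row per subject."""
        x = standardize_pulses(self.model.exog if exog is None else exog)
        out = [self._net.features(x[i:i + batch_size])
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out).astype(float)

    def save(self, path):
        meta = {
            "kind": self.kind,
            "arch_config": asdict(self.arch_config),
            "train_config": asdict(self.train_config),
            "y_mean": float(self.y_mean),
            "y_sd": float(self.y_sd),
            "waveform_length": int(self.model.exog.shape[1]),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **{k: v for k, v in self._net.params.items()})


class _DeepAgeModel(AgeModel):
    """Shared training loop for the two architectures."""

    input_kind = "waveform"
    kind = "deep"

    def __init__(self, endog, waveforms, config):
        waveforms = np.asarray(waveforms, dtype=float)
        if waveforms.ndim != 2:
            raise FitError("waveforms must be a (n, length) matrix")
        super().__init__(endog, exog=waveforms)
        if self.exog.shape[0] != self.endog.size:
            raise FitError("ages and waveforms must align")
        self.config = config
        self._y_mean = float(np.mean(self.endog))
        self._y_sd = float(np.std(self.endog)) or 1.0

    def _make_net(self, rng):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, train_config: TrainConfig | None = None) -> NeuralAgeResults:
        tc = train_config or TrainConfig()
        tc.validate()
        rng = np.random.default_rng(np.random.SeedSequence([tc.seed & 0x7FFFFFFF]))
        net = self._make_net(rng)
        x = standardize_pulses(self.exog)
        y = ((self.endog - self._y_mean) / self._y_sd).astype(_DTYPE)

        n = y.size
        n_tune = max(1, int(round(tc.tuning_fraction * n)))
        perm = rng.permutation(n)
        tune_idx, fit_idx = perm[:n_tune], perm[n_tune:]
        if fit_idx.size == 0:
            raise FitError("training set too small for a tuning split")

        opt = _Adam(net.params, tc.learning_rate)
        best = {k: v.copy() for k, v in net.params.items()}
        best_loss = np.inf
        patience = tc.early_stop_patience
        history = []
        for epoch in range(tc.max_epochs):
            order = rng.permutation(fit_idx.size)
            for start in range(0, fit_idx.size, tc.batch_size):
                idx = fit_idx[order[start:start + tc.batch_size]]
                xb, yb = x[idx], y[idx]
                cache = {}
                pred = net.forward(xb, cache)
                err = (pred - yb).astype(_DTYPE)
                with np.errstate(over="ignore", invalid="ignore"):
                    loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}: try a lower "
                        f"learning rate (lr={tc.learning_rate})")
                dy = (2.0 / err.size) * err
                grads = net.backward(xb, cache, dy)
                opt.step(net.params, grads)
            tune_pred = net.forward(x[tune_idx])
            tune_loss = float(np.mean((tune_pred - y[tune_idx]) ** 2))
            if not np.isfinite(tune_loss):
                raise TrainingError(f"non-finite tuning loss at epoch {epoch}")
            history.append(tune_loss)
            if tune_loss < best_loss - 1e-6:
                best_loss = tune_loss
                best = {k: v.copy() for k, v in net.params.items()}
                patience = tc.early_stop_patience
            else:
                patience -= 1
                if patience == 0:
                    break
        net.params.update(best)
        return NeuralAgeResults(self, net, self.config, tc,
                                {"tuning_mse": history, "best": best_loss})


class SmolkAgeModel(_DeepAgeModel):
    """Learned-kernel (SMoLK-style) waveform-to-age regressor."""

    kind = "smolk"

    def __init__(self, endog, waveforms, config: SmolkConfig | None = None):
        super().__init__(endog, waveforms, config or SmolkConfig())

    def _make_net(self, rng):
        return _SmolkNet(self.config, self.exog.shape[1], rng)


class ResnetAgeModel(_DeepAgeModel):
    """Small 1-D residual network for waveform-to-age regression."""

    kind = "resnet"

    def __init__(self, endog, waveforms, config: ResNetConfig | None = None):
        super().__init__(endog, waveforms, config or ResNetConfig())

    def _make_net(self, rng):
        return _ResNet(self.config, self.exog.shape[1], rng)


def load_checkpoint(path, endog, waveforms) -> NeuralAgeResults:
    """Rebuild a fitted deep predictor from a saved checkpoint archive.

    ``endog``/``waveforms`` re-attach data for prediction; the stored weights
    and normalization constants are used verbatim.
    """
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        weights = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta["kind"] == "smolk":
        model = SmolkAgeModel(endog, waveforms, SmolkConfig(
            n_kernels=meta["arch_config"]["n_kernels"],
            kernel_lengths=tuple(meta["arch_config"]["kernel_lengths"]),
            activation=meta["arch_config"]["activation"]))
    elif meta["kind"] == "resnet":
        model = ResnetAgeModel(endog, waveforms, ResNetConfig(**meta["arch_config"]))
    else:  # pragma: no cover - corrupt archive
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    tc = TrainConfig(**meta["train_config"])
    rng = np.random.default_rng(0)
    net = model._make_net(rng)
    net.params.update({k: v.astype(_DTYPE) for k, v in weights.items()})
    model._y_mean = meta["y_mean"]
    model._y_sd = meta["y_sd"]
    return NeuralAgeResults(model, net, model.config, tc, {"loaded": True})
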