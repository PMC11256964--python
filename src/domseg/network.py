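"""Fully convolutional co-membership network, with training.

The model maps the 5 x L x L feature stack to an L x L matrix of logits
through a truncated trRosetta-style residual network: a 1x1 projection to
``n_filters`` channels, then ``n_blocks`` residual blocks of two 3x3
convolutions with instance normalization and ELU, the dilation rate
cycling through [1, 2, 4, 8, 16] to widen the receptive field.  The final
1x1 convolution produces logits Z; the output is symmetrized in logit
space, S = Z + Z^T, and passed through a sigmoid, so the predicted soft
adjacency is exactly symmetric and a proper probability.  Being fully
convolutional, one weight set serves chains of any length.

The learning objective is the mean binary cross-entropy between the
predicted soft adjacency and the true co-membership matrix over residue
pairs i < j (the diagonal carries no pair information and is excluded).

Layers are implemented directly on NumPy with hand-derived backward
passes; convolutions are BLAS matrix products over im2col patch matrices,
and the data gradient of a convolution is itself a convolution with the
spatially flipped, channel-transposed kernel.  Training uses Adam with a
batch of one chain per step (variable L forbids naive batching) and
class-weighted sampling of multi- vs single-domain chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .assigner import SoftAdjacency
from .features import FeatureStack
from .labels import AdjacencyLabel

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "CoMembershipNet",
    "build_model",
    "predict_soft_adjacency",
    "bce_loss",
    "train",
    "TrainResult",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters (defaults follow the full-size model:
    31 residual blocks of 32 filters; the mini-training tests use 8/16)."""

    n_blocks: int = 31
    n_filters: int = 32
    kernel: int = 3
    dilation_cycle: tuple[int, ...] = (1, 2, 4, 8, 16)
    in_channels: int = 5
    activation: str = "elu"
    norm: str = "instance"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_filters < 1:
            raise ValueError("n_blocks and n_filters must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.activation != "elu" or self.norm != "instance":
            raise ValueError("only elu activation and instance norm are implemented")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    Multi-domain chains are sampled with probability ``p_multi`` and
    single-domain chains with ``p_single`` at every step.
    """

    p_multi: float = 0.65
    p_single: float = 0.35
    learning_rate: float = 1e-3
    batch_size: int = 1
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.p_multi + self.p_single - 1.0) > 1e-9:
            raise ValueError("p_multi + p_single must equal 1")
        if not (0.0 <= self.p_multi <= 1.0):
            raise ValueError("p_multi must be in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers


class _Conv2d:
    """Same-padded dilated 2-D convolution (stride 1, odd kernel)."""

    def __init__(self, c_in, c_out, kernel, dilation, rng, dtype, w_std=None):
        fan_in = c_in * kernel * kernel
        std = w_std if w_std is not None else np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.kernel = kernel
        self.dilation = dilation
        self._x = None

    @staticmethod
    def _im2col(x, kernel, dilation):
        c, L, _ = x.shape
        if kernel == 1:
            return x.reshape(c, L * L)
        p = dilation * (kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        extent = dilation * (kernel - 1) + 1
        view = sliding_window_view(xp, (extent, extent), axis=(1, 2))
        view = view[:, :, :, ::dilation, ::dilation]  # (c, L, L, k, k)
        return np.ascontiguousarray(view.transpose(0, 3, 4, 1, 2)).reshape(
            c * kernel * kernel, L * L
        )

    def _conv(self, x, W):
        c_out = W.shape[0]
        L = x.shape[1]
        cols = self._im2col(x, self.kernel, self.dilation)
        y = W.reshape(c_out, -1) @ cols
        return y.reshape(c_out, L, L)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return self._conv(x, self.W) + self.b[:, None, None]

    def backward(self, dy):
        x = self._x
        c_out = dy.shape[0]
        cols = self._im2col(x, self.kernel, self.dilation)
        dy2 = dy.reshape(c_out, -1)
        self.dW = (dy2 @ cols.T).reshape(self.W.shape)
        self.db = dy2.sum(axis=1)
        # data gradient: convolve dy with the flipped, channel-swapped kernel
        Wt = np.ascontiguousarray(self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        return self._conv(dy, Wt)

    def params(self):
        return [("W", self), ("b", self)]


class _InstanceNorm:
    """Per-channel normalization over the spatial grid, with affine scale."""

    EPS = 1e-5

    def __init__(self, channels, dtype):
        self.g = np.ones(channels, dtype=dtype)
        self.b = np.zeros(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        return self.g[:, None, None] * xhat + self.b[:, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        self.dg = (dy * xhat).sum(axis=(1, 2))
        self.db = dy.sum(axis=(1, 2))
        dxhat = dy * self.g[:, None, None]
        m1 = dxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class _ELU:
    def forward(self, x, train=False):
        y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        if train:
            self._cache = (x > 0, y)
        return y

    def backward(self, dy):
        pos, y = self._cache
        return dy * np.where(pos, 1.0, y + 1.0)


class _ResidualBlock:
    def __init__(self, filters, kernel, dilation, rng, dtype):
        self.conv1 = _Conv2d(filters, filters, kernel, dilation, rng, dtype)
        self.norm1 = _InstanceNorm(filters, dtype)
        self.act1 = _ELU()
        self.conv2 = _Conv2d(filters, filters, kernel, dilation, rng, dtype)
        self.norm2 = _InstanceNorm(filters, dtype)
        self.act_out = _ELU()

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.norm1.forward(h, train)
        h = self.act1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.norm2.forward(h, train)
        return self.act_out.forward(x + h, train)

    def backward(self, dy):
        d = self.act_out.backward(dy)
        dh = self.norm2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.act1.backward(dh)
        dh = self.norm1.backward(dh)
        dh = self.conv1.backward(dh)
        return d + dh

    def layers(self):
        return [self.conv1, self.norm1, self.conv2, self.norm2]


class CoMembershipNet:
    """Feature stack (5, L, L) -> symmetric logits (L, L), any L."""

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = config.kernel
        self.proj = _Conv2d(config.in_channels, config.n_filters, 1, 1, rng, dtype)
        self.proj_norm = _InstanceNorm(config.n_filters, dtype)
        self.proj_act = _ELU()
        cycle = config.dilation_cycle
        self.blocks = [
            _ResidualBlock(config.n_filters, k, cycle[i % len(cycle)], rng, dtype)
            for i in range(config.n_blocks)
        ]
        # small output init keeps untrained logits near zero (BCE ~ ln 2)
        self.out = _Conv2d(config.n_filters, 1, 1, 1, rng, dtype, w_std=0.01)

    # -- forward / backward -------------------------------------------------

    def logits(self, features: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(features, dtype=self.dtype)
        if x.ndim != 3 or x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected ({self.config.in_channels}, L, L) features, got {x.shape}"
            )
        h = self.proj.forward(x, train)
        h = self.proj_norm.forward(h, train)
        h = self.proj_act.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train)
        z = self.out.forward(h, train)[0]
        return z + z.T  # symmetric by construction

    def backward(self, d_sym: np.ndarray) -> None:
        dz = (d_sym + d_sym.T).astype(self.dtype)[None]
        dh = self.out.backward(dz)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        dh = self.proj_act.backward(dh)
        dh = self.proj_norm.backward(dh)
        self.proj.backward(dh)

    # -- parameters ---------------------------------------------------------

    def _layers(self):
        layers = [self.proj, self.proj_norm]
        for block in self.blocks:
            layers.extend(block.layers())
        layers.append(self.out)
        return layers

    def parameters(self):
        """(name, holder, attr) triples for every trainable array."""
        out = []
        for i, layer in enumerate(self._layers()):
            if isinstance(layer, _Conv2d):
                out.append((f"layer{i}.W", layer, "W"))
                out.append((f"layer{i}.b", layer, "b"))
            else:
                out.append((f"layer{i}.g", layer, "g"))
                out.append((f"layer{i}.b", layer, "b"))
        return out

    def n_parameters(self) -> int:
        return sum(getattr(h, a).size for _, h, a in self.parameters())


def build_model(
    config: NetworkConfig | None = None, seed: int = 0, dtype=np.float32
) -> CoMembershipNet:
    """Construct a randomly initialized model."""
    return CoMembershipNet(config or NetworkConfig(), seed=seed, dtype=dtype)


def predict_soft_adjacency(
    model: CoMembershipNet, features: FeatureStack, eps: float = 1e-4
) -> SoftAdjacency:
    """Sigmoid of the symmetrized logits, clipped to [eps, 1 − eps]."""
    s = model.logits(features.tensor, train=False).astype(np.float64)
    prob = 1.0 / (1.0 + np.exp(-s))
    return SoftAdjacency(np.clip(prob, eps, 1.0 - eps), eps=eps)


def bce_loss(pred: SoftAdjacency | np.ndarray, target: AdjacencyLabel) -> float:
    """Mean binary cross-entropy over the L(L−1)/2 pairs i < j."""
    p = pred.matrix if isinstance(pred, SoftAdjacency) else np.asarray(pred, float)
    a = target.matrix.astype(np.float64)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    iu = np.triu_indices(p.shape[0], k=1)
    terms = -(a[iu] * np.log(p[iu]) + (1.0 - a[iu]) * np.log1p(-p[iu]))
    return float(terms.mean())


def _loss_and_grad(model, features, target):
    """Stable BCE on logits; returns (loss, d loss / d symmetric logits)."""
    s = model.logits(features, train=True)
    a = target.astype(s.dtype)
    L = s.shape[0]
    mask = np.triu(np.ones((L, L), dtype=s.dtype), k=1)
    npairs = L * (L - 1) / 2
    # softplus(s) - a*s  ==  -[a log σ(s) + (1-a) log(1-σ(s))]
    softplus = np.logaddexp(0.0, s)
    loss = float(((softplus - a * s) * mask).sum() / npairs)
    sig = 1.0 / (1.0 + np.exp(-s))
    grad = ((sig - a) * mask / npairs).astype(s.dtype)
    return loss, grad


@dataclass
class TrainResult:
    model: CoMembershipNet
    loss_history: list[float]
    sampled_flags: list[str]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {n: np.zeros_like(getattr(h, a)) for n, h, a in params}
        self.v = {n: np.zeros_like(getattr(h, a)) for n, h, a in params}
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, holder, attr in self.params:
            grad = getattr(holder, "d" + attr)
            m = self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * grad
            v = self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * grad**2
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            setattr(holder, attr, getattr(holder, attr) - update.astype(grad.dtype))


def train(
    model: CoMembershipNet,
    dataset: list[tuple[FeatureStack, AdjacencyLabel, str]],
    config: TrainingConfig | None = None,
) -> TrainResult:
    """Train in place with class-weighted per-step sampling.

    One epoch is ``len(dataset)`` steps; at each step a chain class
    (multi/single) is drawn with the configured probabilities and a chain
    is drawn uniformly within the class.  Deterministic given the seed.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)
    by_class = {"multi": [], "single": []}
    for idx, (_, _, flag) in enumerate(dataset):
        if flag not in by_class:
            raise ValueError(f"unknown class flag {flag!r}")
        by_class[flag].append(idx)

    optimizer = _Adam(model.parameters(), config.learning_rate)
    history: list[float] = []
    flags: list[str] = []
    for _ in range(config.epochs):
        for _ in range(len(dataset)):
            cls = "multi" if rng.random() < config.p_multi else "single"
            if not by_class[cls]:
                cls = "single" if cls == "multi" else "multi"
            idx = by_class[cls][int(rng.integers(len(by_class[cls])))]
            features, target, _ = dataset[idx]
            loss, grad = _loss_and_grad(model, features.tensor, target.matrix)
            model.backward(grad)
            optimizer.step()
            history.append(loss)
            flags.append(cls)
    return TrainResult(model=model, loss_history=history, sampled_flags=flags)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: CoMembershipNet, path: str | Path) -> None:
    """Serialize weights and config to an .npz checkpoint."""
    arrays = {name: getattr(h, a) for name, h, a in model.parameters()}
    meta = {"config": asdict(model.config), "seed": model.seed}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path, dtype=np.float32) -> CoMembershipNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["dilation_cycle"] = tuple(cfg["dilation_cycle"])
        model = CoMembershipNet(NetworkConfig(**cfg), seed=meta["seed"], dtype=dtype)
        for name, holder, attr in model.parameters():
            setattr(holder, attr, data[name].astype(dtype))
    return model
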