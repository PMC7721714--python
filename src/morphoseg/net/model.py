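"""Pseudo-3D encoder-decoder predicting discrete distance-to-membrane classes.

The network consumes a block of consecutive confocal slices (default 24)
and predicts, for every voxel of the central slices (boundary slices are
excluded from the loss and the output), a probability over the ordinal
distance classes {0..K}. The data flow is pseudo-3D: in-plane 3x3x1
convolutions carry the spatial reasoning, a 1x1x3 convolution fuses
neighboring slices before each pooling step, pooling/upsampling act
in-plane only. Dilated convolutions widen the receptive field at the
coarsest level, the raw input is average-pooled and concatenated at every
level, and the decoder linearly upsamples every level's features back to
full resolution, convolves them, concatenates everything and maps to
class probabilities.

Training minimizes a distance-aware weighted cross-entropy: a fixed
per-class weight xi_k favoring classes near the membrane, times a dynamic
interclass weight exp(|k - truth|/K) that punishes predictions far from
the true ordinal class harder than near misses.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Adam, Node, Tape
from .layers import (Conv, GroupNorm, PReLU, add, avgpool_hw, concat_channels,
                     constant, crop_depth, maxpool_hw, upsample_hw)


@dataclass(frozen=True)
class NetworkConfig:
    input_depth: int = 24
    boundary_exclude: int = 4          # slices dropped per side of the output
    tile_hw: int = 128
    K: int = 16
    levels: int = 3
    base_filters: int = 8
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    binary: bool = False               # ablation: 2-channel membrane/background head
    group_norm_groups: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.output_depth <= 0:
            raise ValueError("output_depth = input_depth - 2*boundary_exclude "
                             "must be positive")
        if self.tile_hw % (2 ** self.levels):
            raise ValueError("tile_hw must be divisible by 2**levels")
        if self.levels < 1 or self.base_filters < 1 or self.K < 2:
            raise ValueError("invalid network size parameters")

    @property
    def output_depth(self) -> int:
        return self.input_depth - 2 * self.boundary_exclude

    @property
    def n_classes(self) -> int:
        return 2 if self.binary else self.K + 1


def tiny_config(**overrides) -> NetworkConfig:
    """A CPU-sized variant used for desk-scale training experiments."""
    kw = dict(input_depth=16, boundary_exclude=2, tile_hw=64, K=16,
              levels=2, base_filters=4, dilation_rates=(1, 2), seed=0)
    kw.update(overrides)
    return NetworkConfig(**kw)


class _ResBlock:
    def __init__(self, c_in, c_out, groups, rng):
        self.conv1 = Conv(c_in, c_out, (1, 3, 3), rng=rng)
        self.gn1 = GroupNorm(c_out, groups)
        self.act1 = PReLU()
        self.conv2 = Conv(c_out, c_out, (1, 3, 3), rng=rng)
        self.gn2 = GroupNorm(c_out, groups)
        self.proj = Conv(c_in, c_out, (1, 1, 1), rng=rng) if c_in != c_out else None
        self.act2 = PReLU()

    def layers(self):
        out = [self.conv1, self.gn1, self.act1, self.conv2, self.gn2, self.act2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def __call__(self, tape, x):
        y = self.act1(tape, self.gn1(tape, self.conv1(tape, x)))
        y = self.gn2(tape, self.conv2(tape, y))
        skip = self.proj(tape, x) if self.proj is not None else x
        return self.act2(tape, add(tape, y, skip))


class DMapNet:
    """Model handle: layers, forward pass, persistence."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        g = config.group_norm_groups
        self.down = []
        c_prev = 1
        for lvl in range(config.levels):
            f = config.base_filters * 2 ** lvl
            block = _ResBlock(c_prev + 1, f, g, rng)     # +1 raw-input channel
            zfuse = Conv(f, f, (3, 1, 1), rng=rng)
            zact = PReLU()
            self.down.append((block, zfuse, zact))
            c_prev = f
        self.dilated = []
        f_bot = config.base_filters * 2 ** (config.levels - 1)
        for r in config.dilation_rates:
            self.dilated.append((Conv(f_bot, f_bot, (1, 3, 3), dilation=(1, r, r),
                                      rng=rng),
                                 GroupNorm(f_bot, g), PReLU()))
        self.up = []
        for lvl in range(config.levels):
            f = config.base_filters * 2 ** lvl
            self.up.append((Conv(f, config.base_filters, (1, 3, 3), rng=rng),
                            PReLU()))
        self.head = Conv(config.base_filters * config.levels, config.n_classes,
                         (1, 1, 1), rng=rng)

    # -- parameters ---------------------------------------------------------
    def _all_layers(self):
        out = []
        for block, zfuse, zact in self.down:
            out += block.layers() + [zfuse, zact]
        for conv, gn, act in self.dilated:
            out += [conv, gn, act]
        for conv, act in self.up:
            out += [conv, act]
        out.append(self.head)
        return out

    def params(self):
        ps = []
        for layer in self._all_layers():
            ps += layer.params()
        return ps

    # -- forward ------------------------------------------------------------
    def forward(self, tape: Tape, x: np.ndarray) -> Node:
        """Raw logits (N, n_classes, output_depth, H, W) for input
        (N, 1, input_depth, H, W)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, D, H, W)")
        cfg = self.config
        pyramid = [x]
        for _ in range(cfg.levels - 1):
            pyramid.append(avgpool_hw(pyramid[-1]))

        feat = constant(tape, x)
        skips = []
        for lvl, (block, zfuse, zact) in enumerate(self.down):
            if lvl > 0:
                feat = maxpool_hw(tape, feat)
            feat = concat_channels(tape, [feat, constant(tape, pyramid[lvl])])
            feat = block(tape, feat)
            feat = zact(tape, zfuse(tape, feat))
            skips.append(feat)
        bot = skips[-1]
        for conv, gn, act in self.dilated:
            bot = act(tape, gn(tape, conv(tape, bot)))
        skips[-1] = bot

        ups = []
        for lvl, (conv, act) in enumerate(self.up):
            u = skips[lvl]
            for _ in range(lvl):
                u = upsample_hw(tape, u)
            ups.append(act(tape, conv(tape, u)))
        assembled = concat_channels(tape, ups)
        logits = self.head(tape, assembled)
        return crop_depth(tape, logits, cfg.boundary_exclude)

    def predict_probabilities(self, x: np.ndarray) -> np.ndarray:
        """(N, output_depth, H, W, n_classes) class probabilities."""
        tape = Tape()
        logits = self.forward(tape, x)
        return np.moveaxis(softmax(logits.value, axis=1), 1, -1)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["dilation_rates"] = list(cfg["dilation_rates"])
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        with open(path, "wb") as fh:
            np.savez(fh, __config__=np.frombuffer(
                json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DMapNet":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            cfg["dilation_rates"] = tuple(cfg["dilation_rates"])
            model = cls(NetworkConfig(**cfg))
            for i, p in enumerate(model.params()):
                p.value[...] = z[f"p{i}"]
        return model


def build_network(config: NetworkConfig) -> DMapNet:
    """Construct the network with deterministic, seed-controlled weights."""
    return DMapNet(config)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def interclass_weight(k, truth, K: int):
    """Ordinal penalty omega = exp(|k - truth| / K).

    Equals 1 when the predicted class matches the truth and grows
    exponentially with the ordinal distance, so predicting class 15 for a
    truth of 1 costs more than predicting class 2.
    """
    k = np.asarray(k)
    truth = np.asarray(truth)
    if (k < 0).any() or (k > K).any() or (truth < 0).any() or (truth > K).any():
        raise ValueError(f"classes must lie in 0..{K}")
    return np.exp(np.abs(k.astype(float) - truth.astype(float)) / K)


def weighted_cross_entropy(P: np.ndarray, target: np.ndarray,
                           xi: np.ndarray | None = None, *,
                           reduction: str = "sum", tol: float = 1e-6) -> float:
    """Distance-aware weighted cross-entropy of probabilities vs classes.

    ``P`` has classes in the last axis; ``target`` holds integer classes of
    the same leading shape. Every class term at a voxel is weighted by
    xi_k * exp(|k - truth|/K); both the hit term log(P) and the complement
    term log(1-P) are included, and the sign is chosen so smaller is
    better.
    """
    P = np.asarray(P, dtype=float)
    target = np.asarray(target)
    n_classes = P.shape[-1]
    K = n_classes - 1
    if P.min() < -tol or P.max() > 1 + tol:
        raise ValueError("probabilities outside [0, 1]")
    eps = 1e-12
    Pc = np.clip(P, eps, 1 - eps)
    classes = np.arange(n_classes)
    onehot = (target[..., None] == classes).astype(float)
    omega = np.exp(np.abs(classes - target[..., None]).astype(float) / max(K, 1))
    xi = np.ones(n_classes) if xi is None else np.asarray(xi, dtype=float)
    terms = xi * omega * (onehot * np.log(Pc) + (1 - onehot) * np.log(1 - Pc))
    total = -terms.sum()
    if reduction == "mean":
        return float(total / target.size)
    if reduction == "sum":
        return float(total)
    raise ValueError(f"unknown reduction {reduction!r}")


def _loss_node(tape: Tape, logits: Node, target: np.ndarray,
               xi: np.ndarray) -> Node:
    """Fused softmax + weighted cross-entropy (per-voxel mean) with gradient."""
    z = logits.value
    n_classes = z.shape[1]
    K = n_classes - 1
    P = softmax(z, axis=1)
    eps = 1e-12
    Pc = np.clip(P, eps, 1 - eps)
    classes = np.arange(n_classes).reshape(1, n_classes, 1, 1, 1)
    t = target[:, None]
    onehot = (t == classes).astype(float)
    wt = xi.reshape(1, n_classes, 1, 1, 1) \
        * np.exp(np.abs(classes - t).astype(float) / max(K, 1))
    nvox = target.size
    loss = -(wt * (onehot * np.log(Pc) + (1 - onehot) * np.log(1 - Pc))).sum() / nvox

    dP = -wt * (onehot / Pc - (1 - onehot) / (1 - Pc)) / nvox

    def bw(g):
        inner = (dP * P).sum(axis=1, keepdims=True)
        return (g * P * (dP - inner),)

    return tape.node(np.float64(loss), (logits,), bw)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

@dataclass
class TrainSettings:
    epochs: int = 30
    lr: float = 5e-4
    batch_size: int = 2
    seed: int = 0
    xi_schedule: str = "linear"


def _normalize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / (x.std() + 1e-6)


def train(model: DMapNet, data, settings: TrainSettings | None = None):
    """Train on (image, discrete-distance-map) volume pairs.

    Each step draws ``batch_size`` random crops of (input_depth, tile_hw,
    tile_hw) from random volumes; targets are cropped to the boundary-
    excluded output window. Returns (model, per-epoch mean-loss list);
    fully deterministic given the settings seed.
    """
    from ..distance import class_weights
    settings = settings or TrainSettings()
    cfg = model.config
    if not data:
        raise ValueError("need at least one training volume")
    for img, tgt in data:
        if any(s < m for s, m in zip(img.shape,
                                     (cfg.input_depth, cfg.tile_hw, cfg.tile_hw))):
            raise ValueError("training volume smaller than the input tile")
        if img.shape != tgt.shape:
            raise ValueError("image/target shape mismatch")
    if settings.epochs == 0:
        return model, []
    xi = class_weights(cfg.K, settings.xi_schedule) if not cfg.binary \
        else np.ones(2)
    rng = np.random.default_rng(settings.seed)
    opt = Adam(model.params(), lr=settings.lr)
    steps = max(1, int(np.ceil(len(data) / settings.batch_size)))
    trace = []
    for _ in range(settings.epochs):
        losses = []
        for _ in range(steps):
            xs, ts = [], []
            for _ in range(settings.batch_size):
                img, tgt = data[rng.integers(len(data))]
                d0 = rng.integers(img.shape[0] - cfg.input_depth + 1)
                h0 = rng.integers(img.shape[1] - cfg.tile_hw + 1)
                w0 = rng.integers(img.shape[2] - cfg.tile_hw + 1)
                crop = img[d0:d0 + cfg.input_depth,
                           h0:h0 + cfg.tile_hw, w0:w0 + cfg.tile_hw]
                tcrop = tgt[d0 + cfg.boundary_exclude:
                            d0 + cfg.input_depth - cfg.boundary_exclude,
                            h0:h0 + cfg.tile_hw, w0:w0 + cfg.tile_hw]
                xs.append(_normalize(crop)[None])
                ts.append(tcrop)
            x = np.stack(xs)
            t = np.stack(ts).astype(np.int64)
            tape = Tape()
            logits = model.forward(tape, x)
            loss = _loss_node(tape, logits, t, xi)
            opt.zero_grad()
            tape.backward(loss)
            opt.step()
            losses.append(float(loss.value))
        trace.append(float(np.mean(losses)))
    return model, trace


def predict_distance_map(model: DMapNet, stack: np.ndarray) -> np.ndarray:
    """Predict the discrete distance map for a whole volume.

    The stack is reflect-padded in depth by the boundary exclusion, tiled
    with windows covering every voxel, probabilities are averaged in
    overlaps, and the per-voxel argmax class is returned.
    """
    cfg = model.config
    stack = np.asarray(stack, dtype=np.float64)
    D, H, W = stack.shape
    if H < cfg.tile_hw or W < cfg.tile_hw or D < cfg.output_depth:
        raise ValueError("stack smaller than the minimum tile")
    be = cfg.boundary_exclude
    padded = np.pad(stack, ((be, be), (0, 0), (0, 0)), mode="reflect")

    def _starts(total, size, stride):
        s = list(range(0, total - size + 1, stride))
        if s[-1] != total - size:
            s.append(total - size)
        return s

    d_starts = _starts(padded.shape[0], cfg.input_depth, cfg.output_depth)
    h_starts = _starts(H, cfg.tile_hw, cfg.tile_hw)
    w_starts = _starts(W, cfg.tile_hw, cfg.tile_hw)

    acc = np.zeros((D, H, W, cfg.n_classes))
    cnt = np.zeros((D, H, W, 1))
    for d0 in d_starts:
        for h0 in h_starts:
            for w0 in w_starts:
                crop = padded[d0:d0 + cfg.input_depth,
                              h0:h0 + cfg.tile_hw, w0:w0 + cfg.tile_hw]
                probs = model.predict_probabilities(
                    _normalize(crop)[None, None])[0]
                od = d0  # output starts be slices into the window, minus pad be
                acc[od:od + cfg.output_depth,
                    h0:h0 + cfg.tile_hw, w0:w0 + cfg.tile_hw] += probs
                cnt[od:od + cfg.output_depth,
                    h0:h0 + cfg.tile_hw, w0:w0 + cfg.tile_hw] += 1
    probs = acc / np.maximum(cnt, 1)
    return probs.argmax(axis=-1).astype(np.int32)
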