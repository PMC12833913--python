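"""Super-resolution GAN for normalized quantitative maps.

Generator: 9x9 head convolution + ReLU, five residual blocks (two 3x3
convolutions with batch normalization and ReLU, identity skip), a
post-residual 3x3 convolution whose output is summed with the head
activation (long skip), a 1x1 convolution feeding one sub-pixel
(pixel-shuffle) x2 stage per factor of 2, and a final tanh so outputs
live in [-1, 1].  Single input/output channel (one parameter map per
model).

Discriminator: eight 3x3 convolutions (stride 1/2 alternating, channel
plan doubling) with leaky-ReLU, batch normalization on all but the
first, then a global-average-pooled fully connected head with sigmoid
output — the probability that the input is a real high-resolution map.

Composite generator loss: L1 pixel loss + 1e-3 adversarial loss
(-sum log D(G(x))) + 2e-6 perceptual loss (mean squared distance in
the feature space of a fixed convolutional feature network of VGG-style
topology).  The feature extractor defaults to a seeded, fixed,
randomly-initialized stack — the perceptual distance is well defined
for any fixed feature map — with a hook to substitute externally
trained weights.

``SRGANSuperResolver`` wraps training and inference as a scikit-learn
style estimator: ``fit(X_lr, y_hr)`` then ``transform(X_lr)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .acquisition import NormalizationSpec, normalize, denormalize
from .phantom import QuantMap

__all__ = [
    "SRGANConfig", "LossWeights", "build_generator", "build_discriminator",
    "build_feature_extractor", "loss_mae", "loss_adversarial",
    "loss_perceptual", "loss_total", "SRGANSuperResolver", "train",
    "super_resolve",
]

_PCLIP = 1e-7  # probability clamp before logs


@dataclass
class SRGANConfig:
    base_channels: int = 64
    n_residual_blocks: int = 5
    upsample_factor: int = 2
    disc_channel_plan: tuple = (64, 64, 128, 128, 256, 256, 512, 512)
    feat_channel_plan: tuple = (64, 64, 128, 128)
    leaky_slope: float = 0.2
    learning_rate: float = 1e-3
    lr_decay_interval: int = 1000
    lr_decay_factor: float = 0.5
    batch_size: int = 8
    epochs: int = 200
    max_iterations: int | None = None   # cap for desk-scale runs
    rng_seed: int = 0

    def __post_init__(self):
        f = self.upsample_factor
        if f < 2 or f & (f - 1):
            raise ValueError("upsample_factor must be a power of 2, >= 2")
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class LossWeights:
    w_mae: float = 1.0
    w_gan: float = 1e-3
    w_vgg: float = 2e-6

    def __post_init__(self):
        if min(self.w_mae, self.w_gan, self.w_vgg) < 0:
            raise ValueError("loss weights must be >= 0")


class Generator(nn.Layer):
    """Fully convolutional apart from the pixel-shuffle stages."""

    def __init__(self, config: SRGANConfig, rng: np.random.Generator):
        super().__init__()
        c = config.base_channels
        self.head = nn.Sequential(nn.Conv2d(1, c, 9, rng=rng), nn.ReLU())
        self.res = nn.Sequential(*[nn.ResidualBlock(c, rng)
                                   for _ in range(config.n_residual_blocks)])
        self.post = nn.Conv2d(c, c, 3, rng=rng)
        self.post_act = nn.ReLU()
        stages = []
        n_stages = int(np.log2(config.upsample_factor))
        for s in range(n_stages):
            out_ch = 1 if s == n_stages - 1 else c
            conv = nn.Conv2d(c, 4 * out_ch, 1, rng=rng)
            # ICNR: identical sub-pixel kernel groups so the shuffle starts
            # as nearest-neighbour upsampling (no checkerboard at init)
            base = conv.w[::4].copy()
            conv.w[...] = np.repeat(base, 4, axis=0)
            stages += [conv, nn.PixelShuffle(2)]
            if s != n_stages - 1:
                stages.append(nn.ReLU())
        self.up = nn.Sequential(*stages)
        self.tail = nn.Tanh()
        for part in (self.head, self.res, self.post, self.up):
            self.params.extend(part.params)
            self.grads.extend(part.grads)
        self._parts = (self.head, self.res, self.post, self.up)

    def forward(self, x, train=True):
        h0 = self.head.forward(x, train=train)
        r = self.res.forward(h0, train=train)
        t = self.post_act.forward(self.post.forward(r, train=train) + h0,
                                  train=train)
        return self.tail.forward(self.up.forward(t, train=train), train=train)

    def backward(self, dout):
        d = self.up.backward(self.tail.backward(dout))
        d = self.post_act.backward(d)
        dh0 = d  # long-skip branch
        d = self.res.backward(self.post.backward(d))
        return self.head.backward(d + dh0)

    def zero_grads(self):
        for part in self._parts:
            part.zero_grads()


class Discriminator(nn.Layer):
    def __init__(self, config: SRGANConfig, rng: np.random.Generator):
        super().__init__()
        plan = config.disc_channel_plan
        layers: list[nn.Layer] = []
        in_ch = 1
        for i, out_ch in enumerate(plan):
            stride = 1 if i % 2 == 0 else 2
            layers.append(nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng))
            if i > 0:
                layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.LeakyReLU(config.leaky_slope))
            in_ch = out_ch
        head_width = max(64, plan[-1] * 2)
        layers += [nn.GlobalAvgPool(),
                   nn.Linear(plan[-1], head_width, rng=rng),
                   _LeakyVec(config.leaky_slope),
                   nn.Linear(head_width, 1, rng=rng),
                   nn.Sigmoid()]
        self.net = nn.Sequential(*layers)
        self.params = self.net.params
        self.grads = self.net.grads

    def forward(self, x, train=True):
        return self.net.forward(x, train=train)

    def backward(self, dout):
        return self.net.backward(dout)

    def zero_grads(self):
        self.net.zero_grads()


class _LeakyVec(nn.LeakyReLU):
    """LeakyReLU over (N, F) activations (same math, clearer intent)."""


def build_generator(config: SRGANConfig,
                    rng: np.random.Generator | None = None) -> Generator:
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    return Generator(config, rng)


def build_discriminator(config: SRGANConfig,
                        rng: np.random.Generator | None = None) -> Discriminator:
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    return Discriminator(config, rng)


def build_feature_extractor(config: SRGANConfig,
                            rng: np.random.Generator | None = None,
                            weights: list[np.ndarray] | None = None) -> nn.Sequential:
    """Fixed perceptual feature network (VGG-style topology).

    conv3x3-ReLU x2, 2x2 max pool, conv3x3-ReLU x2; features are taken
    at the fourth convolution's post-activation output.  Weights are
    seeded-random and fixed by default; pass ``weights`` (a flat list of
    conv kernels/biases) to substitute externally trained filters.
    Inputs are expected in [0, 1] (shift normalized maps before use).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 2)
    p = config.feat_channel_plan
    net = nn.Sequential(
        nn.Conv2d(1, p[0], 3, rng=rng), nn.ReLU(),
        nn.Conv2d(p[0], p[1], 3, rng=rng), nn.ReLU(),
        nn.MaxPool2d(),
        nn.Conv2d(p[1], p[2], 3, rng=rng), nn.ReLU(),
        nn.Conv2d(p[2], p[3], 3, rng=rng), nn.ReLU(),
    )
    if weights is not None:
        for tgt, src in zip(net.params, weights):
            tgt[...] = src
    return net


# ---------------------------------------------------------------- losses

def loss_mae(dl_image: np.ndarray, gt_image: np.ndarray) -> float:
    """Mean absolute (L1) pixel error, 1/(CHW) sum |dl - gt| per image,
    averaged over the batch if 4-D."""
    if dl_image.shape != gt_image.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(dl_image - gt_image)))


def loss_adversarial(disc_outputs: np.ndarray) -> float:
    """-sum_i log D_i over the batch (probabilities clamped away from 0)."""
    p = np.clip(np.asarray(disc_outputs, dtype=float), _PCLIP, 1 - _PCLIP)
    return float(-np.sum(np.log(p)))


def loss_perceptual(dl_features: np.ndarray, gt_features: np.ndarray) -> float:
    """Mean squared feature distance, 1/(C_j H_j W_j) sum (d - g)^2."""
    if dl_features.shape != gt_features.shape:
        raise ValueError("feature shape mismatch")
    diff = dl_features - gt_features
    per_image_denom = np.prod(diff.shape[-3:])
    return float(np.sum(diff ** 2) / (per_image_denom *
                                      (diff.shape[0] if diff.ndim == 4 else 1)))


def loss_total(mae: float, gan: float, vgg: float,
               weights: LossWeights = LossWeights()) -> float:
    if not all(np.isfinite([mae, gan, vgg])):
        raise ValueError("loss components must be finite")
    return weights.w_mae * mae + weights.w_gan * gan + weights.w_vgg * vgg


# ---------------------------------------------------------------- training

@dataclass
class TrainingLog:
    """Per-iteration loss trajectory (columns mirror the CSV layout)."""
    iteration: list = field(default_factory=list)
    l_mae: list = field(default_factory=list)
    l_gan: list = field(default_factory=list)
    l_vgg: list = field(default_factory=list)
    l_total: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)

    def append(self, it, mae, gan, vgg, total, dloss):
        self.iteration.append(it)
        self.l_mae.append(mae)
        self.l_gan.append(gan)
        self.l_vgg.append(vgg)
        self.l_total.append(total)
        self.d_loss.append(dloss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "iteration": self.iteration, "L_mae": self.l_mae,
            "L_gan": self.l_gan, "L_VGG": self.l_vgg,
            "L_total": self.l_total, "D_loss": self.d_loss})

    def smoothed_total(self, window: int = 25) -> np.ndarray:
        x = np.asarray(self.l_total)
        w = min(window, len(x))
        kernel = np.ones(w) / w
        return np.convolve(x, kernel, mode="valid")


class SRGANSuperResolver(BaseEstimator, TransformerMixin):
    """Single-channel SRGAN as a scikit-learn style transformer.

    Parameters mirror :class:`SRGANConfig`; ``fit`` expects normalized
    ([-1, 1]) low-resolution inputs ``X`` of shape (n, h, w) and paired
    high-resolution targets ``y`` of shape (n, h*factor, w*factor).
    ``transform`` maps normalized LR stacks to SR stacks.

    Fitted attributes: ``generator_``, ``discriminator_``,
    ``feature_net_``, ``log_`` (loss trajectory), ``n_iterations_``.
    """

    def __init__(self, base_channels=64, n_residual_blocks=5, upsample_factor=2,
                 disc_channel_plan=(64, 64, 128, 128, 256, 256, 512, 512),
                 feat_channel_plan=(64, 64, 128, 128), leaky_slope=0.2,
                 learning_rate=1e-3, lr_decay_interval=1000, lr_decay_factor=0.5,
                 batch_size=8, epochs=200, max_iterations=None, rng_seed=0,
                 loss_weights=LossWeights()):
        self.base_channels = base_channels
        self.n_residual_blocks = n_residual_blocks
        self.upsample_factor = upsample_factor
        self.disc_channel_plan = disc_channel_plan
        self.feat_channel_plan = feat_channel_plan
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.lr_decay_interval = lr_decay_interval
        self.lr_decay_factor = lr_decay_factor
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_iterations = max_iterations
        self.rng_seed = rng_seed
        self.loss_weights = loss_weights

    def _config(self) -> SRGANConfig:
        return SRGANConfig(
            base_channels=self.base_channels,
            n_residual_blocks=self.n_residual_blocks,
            upsample_factor=self.upsample_factor,
            disc_channel_plan=tuple(self.disc_channel_plan),
            feat_channel_plan=tuple(self.feat_channel_plan),
            leaky_slope=self.leaky_slope, learning_rate=self.learning_rate,
            lr_decay_interval=self.lr_decay_interval,
            lr_decay_factor=self.lr_decay_factor, batch_size=self.batch_size,
            epochs=self.epochs, max_iterations=self.max_iterations,
            rng_seed=self.rng_seed)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or y.ndim != 3 or X.shape[0] != y.shape[0]:
            raise ValueError("expect paired (n, h, w) LR and (n, H, W) HR stacks")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        f = self.upsample_factor
        if (X.shape[1] * f, X.shape[2] * f) != y.shape[1:]:
            raise ValueError("HR dims must be LR dims x upsample_factor")
        config = self._config()
        weights = self.loss_weights
        rng = np.random.default_rng(self.rng_seed)
        gen = build_generator(config, np.random.default_rng(self.rng_seed + 10))
        disc = build_discriminator(config, np.random.default_rng(self.rng_seed + 11))
        feat = build_feature_extractor(config, np.random.default_rng(self.rng_seed + 12))
        use_gan = weights.w_gan > 0
        use_vgg = weights.w_vgg > 0
        opt_g = nn.Adam(gen, lr=config.learning_rate,
                        decay_interval=config.lr_decay_interval,
                        decay_factor=config.lr_decay_factor)
        opt_d = nn.Adam(disc, lr=config.learning_rate,
                        decay_interval=config.lr_decay_interval,
                        decay_factor=config.lr_decay_factor)
        log = TrainingLog()
        n = X.shape[0]
        bs = min(config.batch_size, n)
        it = 0
        max_it = config.max_iterations or np.inf
        for epoch in range(config.epochs):
            if it >= max_it:
                break
            order = rng.permutation(n)
            for start in range(0, n - bs + 1, bs):
                if it >= max_it:
                    break
                idx = order[start:start + bs]
                lr_b = X[idx][:, None]      # (B, 1, h, w)
                hr_b = y[idx][:, None]
                fake = gen.forward(lr_b, train=True)

                d_loss = 0.0
                if use_gan:
                    # --- discriminator step: real -> 1, generated -> 0
                    disc.zero_grads()
                    p_real = disc.forward(hr_b, train=True)
                    pr = np.clip(p_real, _PCLIP, 1 - _PCLIP)
                    disc.backward(-1.0 / pr / bs)
                    p_fake = disc.forward(fake, train=True)
                    pf = np.clip(p_fake, _PCLIP, 1 - _PCLIP)
                    disc.backward(1.0 / (1.0 - pf) / bs)
                    d_loss = float(-(np.log(pr).mean() + np.log1p(-pf).mean()))
                    opt_d.step()

                # --- generator step
                gen.zero_grads()
                mae = loss_mae(fake, hr_b)
                dfake = weights.w_mae * np.sign(fake - hr_b) / fake[0].size / bs

                gan_l = 0.0
                if use_gan:
                    disc.zero_grads()
                    p_fake = disc.forward(fake, train=True)
                    pf = np.clip(p_fake, _PCLIP, 1 - _PCLIP)
                    gan_l = loss_adversarial(pf)
                    dprob = -weights.w_gan / pf
                    dfake = dfake + disc.backward(dprob)
                    disc.zero_grads()   # discard D grads from the G pass

                vgg_l = 0.0
                if use_vgg:
                    feat.zero_grads()
                    f_real = feat.forward((hr_b + 1.0) / 2.0, train=False)
                    f_fake = feat.forward((fake + 1.0) / 2.0, train=False)
                    vgg_l = loss_perceptual(f_fake, f_real)
                    denom = np.prod(f_fake.shape[-3:]) * bs
                    dfeat = weights.w_vgg * 2.0 * (f_fake - f_real) / denom
                    dfake = dfake + feat.backward(dfeat) / 2.0  # d(shift)/dfake
                    feat.zero_grads()

                gen.backward(dfake)
                opt_g.step()
                it += 1
                log.append(it, mae, gan_l, vgg_l,
                           loss_total(mae, gan_l, vgg_l, weights), d_loss)
        self.generator_ = gen
        self.discriminator_ = disc
        self.feature_net_ = feat
        self.log_ = log
        self.n_iterations_ = it
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "generator_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = self.generator_.forward(X[:, None], train=False)[:, 0]
        return out[0] if single else out


def train(lr_maps: np.ndarray, hr_maps: np.ndarray,
          config: SRGANConfig = SRGANConfig(),
          weights: LossWeights = LossWeights()
          ) -> tuple[SRGANSuperResolver, TrainingLog]:
    """Functional wrapper over :class:`SRGANSuperResolver`."""
    model = SRGANSuperResolver(
        base_channels=config.base_channels,
        n_residual_blocks=config.n_residual_blocks,
        upsample_factor=config.upsample_factor,
        disc_channel_plan=config.disc_channel_plan,
        feat_channel_plan=config.feat_channel_plan,
        leaky_slope=config.leaky_slope, learning_rate=config.learning_rate,
        lr_decay_interval=config.lr_decay_interval,
        lr_decay_factor=config.lr_decay_factor, batch_size=config.batch_size,
        epochs=config.epochs, max_iterations=config.max_iterations,
        rng_seed=config.rng_seed, loss_weights=weights)
    model.fit(lr_maps, hr_maps)
    return model, model.log_


def save_checkpoint(model: SRGANSuperResolver, path) -> None:
    """Persist generator weights together with the configuration, seed
    and loss-weight metadata (numpy .npz)."""
    import json as _json
    from sklearn.utils.validation import check_is_fitted
    check_is_fitted(model, "generator_")
    meta = dict(model.get_params())
    weights = meta.pop("loss_weights")
    meta["loss_weights"] = [weights.w_mae, weights.w_gan, weights.w_vgg]
    arrays = {f"g{i}": p for i, p in enumerate(model.generator_.params)}
    bn_layers = [m for m in nn.iter_modules(model.generator_)
                 if isinstance(m, nn.BatchNorm2d)]
    for i, bn in enumerate(bn_layers):
        arrays[f"bnm{i}"] = bn.run_mean
        arrays[f"bnv{i}"] = bn.run_var
    np.savez(path, meta=_json.dumps(meta, default=list), **arrays)


def load_checkpoint(path) -> SRGANSuperResolver:
    """Rebuild a fitted resolver from :func:`save_checkpoint` output."""
    import json as _json
    with np.load(path, allow_pickle=False) as data:
        meta = _json.loads(str(data["meta"]))
        n_params = sum(1 for name in data.files if name.startswith("g"))
        arrays = [data[f"g{i}"] for i in range(n_params)]
        bn_means = [data[k] for k in sorted(
            (n for n in data.files if n.startswith("bnm")),
            key=lambda s: int(s[3:]))]
        bn_vars = [data[k] for k in sorted(
            (n for n in data.files if n.startswith("bnv")),
            key=lambda s: int(s[3:]))]
    w = meta.pop("loss_weights")
    meta["loss_weights"] = LossWeights(*w)
    for key in ("disc_channel_plan", "feat_channel_plan"):
        meta[key] = tuple(meta[key])
    model = SRGANSuperResolver(**meta)
    config = model._config()
    model.generator_ = build_generator(
        config, np.random.default_rng(model.rng_seed + 10))
    model.discriminator_ = build_discriminator(
        config, np.random.default_rng(model.rng_seed + 11))
    model.feature_net_ = build_feature_extractor(
        config, np.random.default_rng(model.rng_seed + 12))
    for target, source in zip(model.generator_.params, arrays):
        target[...] = source
    bn_layers = [m for m in nn.iter_modules(model.generator_)
                 if isinstance(m, nn.BatchNorm2d)]
    for bn, mean, var in zip(bn_layers, bn_means, bn_vars):
        bn.run_mean = mean
        bn.run_var = var
    model.log_ = TrainingLog()
    model.n_iterations_ = 0
    return model


def super_resolve(model: SRGANSuperResolver, fast_map: QuantMap,
                  spec: NormalizationSpec, out_grid: int | None = None) -> QuantMap:
    """normalize -> generator -> denormalize.

    Input must be on the fast display grid; output lands on
    ``grid x upsample_factor`` with spacing FOV / out-grid and values
    clipped to the physical range.
    """
    factor = model.upsample_factor
    expected = None if out_grid is None else out_grid // factor
    if expected is not None and fast_map.grid != (expected, expected):
        raise ValueError("fast map grid does not match the model's input grid")
    norm = normalize(fast_map, spec)
    sr = model.transform(norm)
    fov = fast_map.pixel_spacing * fast_map.grid[0]
    return denormalize(sr, spec, pixel_spacing=fov / sr.shape[0])
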