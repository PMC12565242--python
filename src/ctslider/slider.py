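"""Slice-level 3D adapters on a frozen vision transformer, with exact
tunable-parameter accounting.

A bottleneck adapter maps L x d token features through a down-projection to
p = d / delta channels, a non-linearity and a zero-initialised up-projection,
added residually::

    Adapter(X) = X + f(X W_down) W_up

The slice-level variant ("Slider") inserts a depth-wise 3D convolution in
the bottleneck: the down-projected tokens of the T slices of a case are
reshaped to a T x H x W x p volume (H, W = patch grid) so the convolution can
mix information across neighbouring slices and patches::

    Slider(X) = X + f(3DConv(X W_down)) W_up

One adapter is inserted at the input of every transformer block of a frozen
ViT backbone; a kernel of (3, 1, 1) mixes along the slice axis only, which
is the default.  Because W_up starts at zero, training begins exactly at the
frozen backbone's function.

Four fine-tuning modes are supported and counted: ``slider`` (adapters +
classification head), ``full`` (entire backbone + head), ``partial`` (last
block + head) and ``linear_probe`` (head only).  The backbone composition
used for desk counting matches a ViT-B/14 at 518 px input: 14x14x3 patch
embedding, a (37*37+1) positional table, a class token, and per block
qkv/attention-out/4x MLP projections, two layer norms and two layer-scale
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from ._nn import (Adam, DepthwiseConv3d, Dropout, GELU, LayerNorm, Linear,
                  Module, MultiHeadSelfAttention, Parameter, cosine_lr,
                  softmax_cross_entropy)

__all__ = [
    "SliderConfig",
    "BackboneConfig",
    "AdapterParams",
    "ParamReport",
    "MODES",
    "adapter_forward",
    "slider_forward",
    "tokens_to_volume",
    "volume_to_tokens",
    "count_tunable_params",
    "assemble_model",
    "SliderViT",
    "SliderClassifier",
    "train_identifier",
    "predict_case",
]

MODES = ("slider", "full", "partial", "linear_probe")

_ALLOWED_KERNELS = {(3, 1, 1), (1, 1, 1), (1, 3, 3), (3, 3, 3)}


@dataclass(frozen=True)
class SliderConfig:
    """Adapter architecture: embed dim d, reduction factor delta (bottleneck
    p = d/delta), depth-wise kernel (k_t, k_h, k_w) and slice/patch-grid
    geometry."""

    d: int = 768
    delta: int = 4
    kernel: tuple[int, int, int] = (3, 1, 1)
    n_blocks: int = 12
    activation: str = "gelu"
    n_classes: int = 2
    T: int = 5
    grid: tuple[int, int] = (37, 37)

    def __post_init__(self):
        if self.d % self.delta:
            raise ValueError(f"embed dim {self.d} not divisible by delta {self.delta}")
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError(f"kernel dims must be odd, got {self.kernel}")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")

    @property
    def p(self) -> int:
        return self.d // self.delta


@dataclass(frozen=True)
class BackboneConfig:
    """Frozen ViT composition.  Defaults correspond to a ViT-B/14 backbone at
    518 px input (embed dim 768, 12 blocks, 37x37 patch grid)."""

    embed_dim: int = 768
    depth: int = 12
    patch_size: int = 14
    image_size: int = 518
    n_heads: int = 12
    mlp_ratio: int = 4
    n_classes: int = 2

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be a multiple of patch_size")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid ** 2


@dataclass
class AdapterParams:
    """Weights of one adapter (functional form)."""

    w_down: np.ndarray                 # (d, p)
    b_down: np.ndarray                 # (p,)
    w_up: np.ndarray                   # (p, d)
    b_up: np.ndarray                   # (d,)
    conv_weight: np.ndarray | None = None   # (p, k_t, k_h, k_w)
    conv_bias: np.ndarray | None = None     # (p,)


@dataclass
class ParamReport:
    mode: str
    count: int
    millions: float
    breakdown: dict[str, int] = field(default_factory=dict)


def _activation(name: str):
    if name == "gelu":
        return GELU()
    if name == "relu":
        return _nn.ReLU()
    if name == "identity":
        class _Id:
            def forward(self, x):
                return x

            def backward(self, g):
                return g
        return _Id()
    raise ValueError(f"unknown activation {name!r}")


def adapter_forward(X: np.ndarray, params: AdapterParams,
                    activation: str = "gelu") -> np.ndarray:
    """Plain bottleneck adapter on (..., d) token features."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != params.w_down.shape[0]:
        raise ValueError(f"feature dim {X.shape[-1]} does not match "
                         f"W_down {params.w_down.shape}")
    act = _activation(activation)
    h = act.forward(X @ params.w_down + params.b_down)
    return X + h @ params.w_up + params.b_up


def tokens_to_volume(X: np.ndarray, H: int, W: int) -> np.ndarray:
    """Reshape (..., L, p) token sequences to (..., H, W, p) patch volumes
    (row-major patch order); lossless inverse of :func:`volume_to_tokens`."""
    X = np.asarray(X)
    if X.shape[-2] != H * W:
        raise ValueError(f"L={X.shape[-2]} does not equal H*W={H * W}")
    return X.reshape(*X.shape[:-2], H, W, X.shape[-1])


def volume_to_tokens(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    h, w, p = X.shape[-3:]
    return X.reshape(*X.shape[:-3], h * w, p)


def slider_forward(X: np.ndarray, params: AdapterParams, config: SliderConfig
                   ) -> np.ndarray:
    """Slice-level adapter on a (T, L, d) stack of patch-token features."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"expected (T, L, d), got shape {X.shape}")
    hgrid, wgrid = config.grid
    if X.shape[1] != hgrid * wgrid:
        raise ValueError(f"L={X.shape[1]} does not match grid {config.grid}")
    if params.conv_weight is None:
        raise ValueError("slider_forward requires depth-wise conv weights")
    act = _activation(config.activation)
    h = X @ params.w_down + params.b_down                      # (T, L, p)
    vol = tokens_to_volume(h, hgrid, wgrid)[None]              # (1, T, H, W, p)
    conv = DepthwiseConv3d(config.p, config.kernel, np.random.default_rng(0))
    conv.weight.value = np.asarray(params.conv_weight, dtype=np.float64)
    conv.bias.value = np.asarray(params.conv_bias, dtype=np.float64)
    vol = conv.forward(vol)
    h = volume_to_tokens(vol[0])
    h = act.forward(h)
    return X + h @ params.w_up + params.b_up


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def _block_params(d: int, mlp_ratio: int) -> int:
    qkv = d * 3 * d + 3 * d
    proj = d * d + d
    mlp = d * mlp_ratio * d + mlp_ratio * d + mlp_ratio * d * d + d
    norms = 2 * 2 * d
    layer_scale = 2 * d
    return qkv + proj + mlp + norms + layer_scale


def _adapter_params(d: int, p: int, kernel: tuple[int, int, int]) -> int:
    kt, kh, kw = kernel
    down = d * p + p
    conv = p * (kt * kh * kw) + p
    up = p * d + d
    return down + conv + up


def count_tunable_params(backbone: BackboneConfig | None = None,
                         slider: SliderConfig | None = None,
                         mode: str = "slider") -> ParamReport:
    """Closed-form tunable-parameter count for a fine-tuning mode.

    ``slider`` mode counts n_blocks adapters (down-projection + bias,
    depth-wise conv + bias over the bottleneck channels, up-projection +
    bias) plus the linear head; ``full`` counts the whole backbone composition
    plus head; ``partial`` one block plus head; ``linear_probe`` the head only.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    backbone = backbone or BackboneConfig()
    d = backbone.embed_dim
    head = d * backbone.n_classes + backbone.n_classes
    breakdown: dict[str, int] = {"head": head}

    if mode == "slider":
        slider = slider or SliderConfig(d=d, n_blocks=backbone.depth)
        if slider.d != d:
            raise ValueError("slider embed dim must match the backbone")
        per_adapter = _adapter_params(d, slider.p, slider.kernel)
        breakdown["adapters"] = slider.n_blocks * per_adapter
        breakdown["per_adapter"] = per_adapter
        count = breakdown["adapters"] + head
    elif mode == "full":
        patch_embed = backbone.patch_size ** 2 * 3 * d + d
        pos_embed = (backbone.n_patches + 1) * d
        cls_token = d
        blocks = backbone.depth * _block_params(d, backbone.mlp_ratio)
        final_norm = 2 * d
        breakdown.update(patch_embed=patch_embed, pos_embed=pos_embed,
                         cls_token=cls_token, blocks=blocks,
                         final_norm=final_norm)
        count = patch_embed + pos_embed + cls_token + blocks + final_norm + head
    elif mode == "partial":
        breakdown["last_block"] = _block_params(d, backbone.mlp_ratio)
        count = breakdown["last_block"] + head
    else:
        count = head
    return ParamReport(mode=mode, count=int(count),
                       millions=round(count / 1e6, 2), breakdown=breakdown)


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

class SliderAdapter(Module):
    """Trainable slice-level adapter over (N, T, L, d) patch tokens."""

    def __init__(self, cfg: SliderConfig, rng: np.random.Generator, name: str):
        self.cfg = cfg
        self.down = Linear(cfg.d, cfg.p, rng, name=f"{name}.down")
        self.conv = DepthwiseConv3d(cfg.p, cfg.kernel, rng, name=f"{name}.conv",
                                    identity_init=True)
        self.up = Linear(cfg.p, cfg.d, rng, name=f"{name}.up", zero_init=True)
        self.act = _activation(cfg.activation)

    def forward(self, x: np.ndarray) -> np.ndarray:
        hgrid, wgrid = self.cfg.grid
        n, t, l, d = x.shape
        h = self.down.forward(x)
        h = self.conv.forward(h.reshape(n, t, hgrid, wgrid, self.cfg.p))
        h = self.act.forward(h.reshape(n, t, l, self.cfg.p))
        return x + self.up.forward(h)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        hgrid, wgrid = self.cfg.grid
        n, t, l, d = gout.shape
        gh = self.act.backward(self.up.backward(gout))
        gh = self.conv.backward(gh.reshape(n, t, hgrid, wgrid, self.cfg.p))
        gx = self.down.backward(gh.reshape(n, t, l, self.cfg.p))
        return gout + gx


class _MLP(Module):
    def __init__(self, d: int, ratio: int, rng: np.random.Generator, name: str):
        self.fc1 = Linear(d, ratio * d, rng, name=f"{name}.fc1")
        self.act = GELU()
        self.fc2 = Linear(ratio * d, d, rng, name=f"{name}.fc2")

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(g)))


class TransformerBlock(Module):
    """Pre-norm ViT block with per-branch layer-scale vectors."""

    def __init__(self, d: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator, name: str):
        self.ln1 = LayerNorm(d, name=f"{name}.ln1")
        self.attn = MultiHeadSelfAttention(d, n_heads, rng, name=f"{name}.attn")
        # layer-scale vectors initialised at 1e-5 (the DINOv2 convention):
        # blocks start near identity, keeping random-init features stable
        self.ls1 = Parameter(f"{name}.ls1", np.full(d, 1e-5))
        self.ln2 = LayerNorm(d, name=f"{name}.ln2")
        self.mlp = _MLP(d, mlp_ratio, rng, name=f"{name}.mlp")
        self.ls2 = Parameter(f"{name}.ls2", np.full(d, 1e-5))
        self._a: np.ndarray | None = None
        self._m: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._a = self.attn.forward(self.ln1.forward(x))
        x1 = x + self.ls1.value * self._a
        self._m = self.mlp.forward(self.ln2.forward(x1))
        return x1 + self.ls2.value * self._m

    def backward(self, g: np.ndarray) -> np.ndarray:
        d = g.shape[-1]
        self.ls2.grad += (g * self._m).reshape(-1, d).sum(axis=0)
        gx1 = g + self.ln2.backward(self.mlp.backward(g * self.ls2.value))
        self.ls1.grad += (gx1 * self._a).reshape(-1, d).sum(axis=0)
        return gx1 + self.ln1.backward(self.attn.backward(gx1 * self.ls1.value))


class SliderViT(Module):
    """ViT backbone with optional per-block slice-level adapters and a linear
    head on the slice-averaged class token."""

    def __init__(self, backbone: BackboneConfig, slider: SliderConfig | None,
                 mode: str, seed: int = 0, dropout: float = 0.0,
                 pooling: str = "cls"):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        if pooling not in ("cls", "patch_mean"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.backbone_cfg = backbone
        self.mode = mode
        self.pooling = pooling
        rng_bb = np.random.default_rng([seed, 0])
        rng_ad = np.random.default_rng([seed, 1])
        d, g = backbone.embed_dim, backbone.grid

        self.patch_embed = Linear(backbone.patch_size ** 2 * 3, d, rng_bb,
                                  name="patch_embed")
        self.pos_embed = Parameter("pos_embed",
                                   rng_bb.normal(0, 0.02, (g * g + 1, d)))
        self.cls_token = Parameter("cls_token", rng_bb.normal(0, 0.02, d))
        self.blocks = [TransformerBlock(d, backbone.n_heads, backbone.mlp_ratio,
                                        rng_bb, name=f"block{i}")
                       for i in range(backbone.depth)]
        self.final_norm = LayerNorm(d, name="final_norm")
        self.head = Linear(d, backbone.n_classes, rng_bb, name="head")
        self.dropout = Dropout(dropout)

        if mode == "slider":
            if slider is None:
                slider = SliderConfig(d=d, n_blocks=backbone.depth, grid=(g, g))
            if slider.d != d or slider.grid != (g, g) or slider.n_blocks != backbone.depth:
                raise ValueError("slider config must match the backbone geometry")
            self.adapters = [SliderAdapter(slider, rng_ad, name=f"adapter{i}")
                             for i in range(backbone.depth)]
        else:
            self.adapters = []
        self.slider_cfg = slider if mode == "slider" else None
        # frozen feature standardisation applied between pooling and head
        # (identity until calibrated on a training set); buffers, not params
        self.feat_mu = np.zeros(d)
        self.feat_sigma = np.ones(d)
        self._freeze()

    def _backbone_modules(self):
        return [self.patch_embed, *self.blocks, self.final_norm]

    def _freeze(self) -> None:
        trainable_backbone = {
            "slider": set(), "linear_probe": set(),
            "full": set(range(len(self.blocks))),
            "partial": {len(self.blocks) - 1},
        }[self.mode]
        for p in (self.pos_embed, self.cls_token):
            p.trainable = self.mode == "full"
        self.patch_embed.set_trainable(self.mode == "full")
        self.final_norm.set_trainable(self.mode == "full")
        for i, blk in enumerate(self.blocks):
            blk.set_trainable(i in trainable_backbone)
        # adapters and head are always trainable
        for ad in self.adapters:
            ad.set_trainable(True)
        self.head.set_trainable(True)

    def n_trainable(self) -> int:
        return int(sum(p.value.size for p in self.parameters() if p.trainable))

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        ps, g = self.backbone_cfg.patch_size, self.backbone_cfg.grid
        n, t, s1, s2, c = images.shape
        if s1 != g * ps or s2 != g * ps or c != 3:
            raise ValueError(f"expected (N, T, {g * ps}, {g * ps}, 3) images, "
                             f"got {images.shape}")
        x = images.reshape(n, t, g, ps, g, ps, c)
        x = x.transpose(0, 1, 2, 4, 3, 5, 6)
        return x.reshape(n, t, g * g, ps * ps * c)

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Case logits from (N, T, S, S, 3) float images in [0, 1]."""
        n, t = images.shape[:2]
        l = self.backbone_cfg.n_patches
        d = self.backbone_cfg.embed_dim
        tok = self.patch_embed.forward(self._patchify(np.asarray(images, dtype=np.float64)))
        x = np.empty((n, t, l + 1, d))
        x[:, :, 0, :] = self.cls_token.value
        x[:, :, 1:, :] = tok
        x += self.pos_embed.value
        for i, blk in enumerate(self.blocks):
            if self.adapters:
                x = np.concatenate(
                    [x[:, :, :1, :], self.adapters[i].forward(x[:, :, 1:, :])], axis=2)
            x = blk.forward(x.reshape(n * t, l + 1, d)).reshape(n, t, l + 1, d)
        x = self.final_norm.forward(x)
        self._n_t = (n, t, l, d)
        if self.pooling == "cls":
            pooled = x[:, :, 0, :].mean(axis=1)
        else:
            pooled = x[:, :, 1:, :].mean(axis=(1, 2))
        pooled = (pooled - self.feat_mu) / self.feat_sigma
        pooled = self.dropout.forward(pooled, train=train, rng=rng)
        return self.head.forward(pooled)

    def pooled_features(self, images: np.ndarray) -> np.ndarray:
        """Raw (un-standardised) pooled case features, evaluation mode."""
        mu, sigma = self.feat_mu, self.feat_sigma
        self.feat_mu, self.feat_sigma = np.zeros_like(mu), np.ones_like(sigma)
        try:
            self.forward(images, train=False)
            n, t, l, d = self._n_t
            x = self.final_norm._cache[0] * self.final_norm.gamma.value + self.final_norm.beta.value
            x = x.reshape(n, t, l + 1, d)
            if self.pooling == "cls":
                return x[:, :, 0, :].mean(axis=1)
            return x[:, :, 1:, :].mean(axis=(1, 2))
        finally:
            self.feat_mu, self.feat_sigma = mu, sigma

    def calibrate_features(self, images: np.ndarray, batch: int = 32) -> None:
        """Freeze the feature standardisation to the given training stacks."""
        feats = np.concatenate([self.pooled_features(images[i:i + batch])
                                for i in range(0, len(images), batch)])
        self.feat_mu = feats.mean(axis=0)
        self.feat_sigma = feats.std(axis=0) + 1e-8

    def backward(self, glogits: np.ndarray) -> None:
        n, t, l, d = self._n_t
        gpooled = self.dropout.backward(self.head.backward(glogits)) / self.feat_sigma
        gx = np.zeros((n, t, l + 1, d))
        if self.pooling == "cls":
            gx[:, :, 0, :] = gpooled[:, None, :] / t
        else:
            gx[:, :, 1:, :] = gpooled[:, None, None, :] / (t * l)
        gx = self.final_norm.backward(gx)
        for i in reversed(range(len(self.blocks))):
            gx = self.blocks[i].backward(gx.reshape(n * t, l + 1, d)).reshape(n, t, l + 1, d)
            if self.adapters:
                gpatch = self.adapters[i].backward(gx[:, :, 1:, :])
                gx = np.concatenate([gx[:, :, :1, :], gpatch], axis=2)
        # gradients w.r.t. pos_embed / cls_token / patch_embed (full mode)
        self.pos_embed.grad += gx.reshape(-1, l + 1, d).sum(axis=0)
        self.cls_token.grad += gx[:, :, 0, :].reshape(-1, d).sum(axis=0)
        self.patch_embed.backward(gx[:, :, 1:, :])


def assemble_model(backbone: BackboneConfig, slider: SliderConfig | None,
                   mode: str, seed: int = 0, dropout: float = 0.0,
                   pooling: str = "cls") -> SliderViT:
    """Build the case-level classifier for a fine-tuning mode.

    The backbone weights are drawn from a seed-derived stream that is
    identical across modes, so a zero-initialised slider model computes
    exactly the frozen backbone + head function at initialisation.

    ``pooling`` selects the d-dimensional case representation fed to the
    head: ``'cls'`` (mean over slices of the class token — appropriate for a
    pretrained backbone whose class token summarises the image) or
    ``'patch_mean'`` (mean over slices and patch tokens — more informative
    when the backbone is randomly initialised).  Either way the head stays
    a single d x n_classes linear layer.
    """
    return SliderViT(backbone, slider, mode, seed=seed, dropout=dropout,
                     pooling=pooling)


class SliderClassifier(BaseEstimator, ClassifierMixin):
    """Case-level PF-ILD classifier over representative-slice stacks.

    Training defaults mirror the reference protocol (80 epochs, batch 8,
    Adam at 2e-4 with cosine annealing, dropout 0.3, class weights 1:1.5);
    the backbone defaults are a compact randomly initialised ViT suitable
    for CPU training rather than a pretrained foundation model.
    """

    def __init__(self, mode: str = "slider", embed_dim: int = 32, depth: int = 2,
                 n_heads: int = 4, patch_size: int = 14, image_size: int = 56,
                 delta: int = 4, kernel: tuple[int, int, int] = (3, 1, 1),
                 epochs: int = 80, batch_size: int = 8, lr: float = 2e-4,
                 class_weight: tuple[float, float] = (1.0, 1.5),
                 dropout: float = 0.3, cosine: bool = True, seed: int = 0,
                 pooling: str = "patch_mean"):
        self.mode = mode
        self.embed_dim = embed_dim
        self.depth = depth
        self.n_heads = n_heads
        self.patch_size = patch_size
        self.image_size = image_size
        self.delta = delta
        self.kernel = kernel
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.class_weight = class_weight
        self.dropout = dropout
        self.cosine = cosine
        self.seed = seed
        self.pooling = pooling

    def _configs(self) -> tuple[BackboneConfig, SliderConfig]:
        bb = BackboneConfig(embed_dim=self.embed_dim, depth=self.depth,
                            patch_size=self.patch_size, image_size=self.image_size,
                            n_heads=self.n_heads)
        sl = SliderConfig(d=self.embed_dim, delta=self.delta, kernel=tuple(self.kernel),
                          n_blocks=self.depth, grid=(bb.grid, bb.grid))
        return bb, sl

    @staticmethod
    def _normalize(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 5 or X.shape[-1] != 3:
            raise ValueError(f"expected (N, T, S, S, 3) stacks, got {X.shape}")
        if X.max() > 1.5:
            X = X / 255.0
        return X

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None):
        X = self._normalize(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training set must contain both classes")
        bb, sl = self._configs()
        self.model_ = assemble_model(bb, sl if self.mode == "slider" else None,
                                     self.mode, seed=self.seed, dropout=self.dropout,
                                     pooling=self.pooling)
        self.model_.calibrate_features(X)
        self.T_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        params = list(self.model_.parameters())
        opt = Adam(params, lr=self.lr)
        rng = np.random.default_rng([self.seed, 2])
        w = np.asarray(self.class_weight, dtype=np.float64)
        log = []
        n = len(X)
        for epoch in range(self.epochs):
            lr = cosine_lr(self.lr, epoch, self.epochs) if self.cosine else self.lr
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.model_.forward(X[idx], train=True, rng=rng)
                loss, glog = softmax_cross_entropy(logits, y[idx], w)
                for p in params:
                    p.grad[...] = 0.0
                self.model_.backward(glog)
                opt.step(lr=lr)
                losses.append(loss)
            row = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr}
            if X_val is not None:
                scores = self._scores(self._normalize(X_val))
                from .evalstats import auroc
                row["val_auroc"] = auroc(np.asarray(y_val, dtype=int), scores)
            log.append(row)
        self.training_log_ = pd.DataFrame(log)
        return self

    def _scores(self, X: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(X), 32):
            logits = self.model_.forward(X[start:start + 32], train=False)
            out.append(_nn.softmax(logits, axis=-1)[:, 1])
        return np.concatenate(out)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("SliderClassifier is not fitted")
        X = self._normalize(X)
        if X.shape[1] != self.T_:
            raise ValueError(f"stack has T={X.shape[1]} slices; model was "
                             f"trained with T={self.T_}")
        s = self._scores(X)
        return np.stack([1.0 - s, s], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_identifier(stacks: np.ndarray, labels: np.ndarray,
                     config: dict | None = None,
                     val: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> tuple[SliderClassifier, pd.DataFrame]:
    """Fit a :class:`SliderClassifier` on per-case RS stacks; returns the
    fitted estimator and its training log."""
    clf = SliderClassifier(**(config or {}))
    if val is not None:
        clf.fit(stacks, labels, X_val=val[0], y_val=val[1])
    else:
        clf.fit(stacks, labels)
    return clf, clf.training_log_


def predict_case(model: SliderClassifier, stack: np.ndarray) -> float:
    """Positive-class probability for a single (T, S, S, 3) RS stack."""
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError(f"expected a single (T, S, S, 3) stack, got {stack.shape}")
    return float(model.predict_proba(stack[None])[0, 1])
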