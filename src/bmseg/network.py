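"""Re-parameterized large-kernel 3D U-Net for metastasis segmentation.

The architecture is a 4-level encoder/decoder. Each encoder block expands
channels with a pointwise convolution, runs two *parallel depthwise*
branches — a very large kernel (default 13x13x13) that supplies the wide
receptive field needed to tell a metastasis from a vessel cross-section, and
a smaller parallel kernel (default 5x5x5) that stabilises optimisation —
each followed by its own normalisation, sums them, applies GELU and projects
back with a second pointwise convolution. After training the two branches
are algebraically *fused* into a single depthwise kernel (structural
re-parameterization): the normalisation is folded into each kernel
(w' = w * gamma / sqrt(var + eps), b' = beta - mean * gamma / sqrt(var + eps)),
the small kernel is zero-padded to the large edge, and kernels and biases are
summed. Fused inference is bit-for-bit equivalent up to float rounding.

The decoder mirrors the encoder with trilinear-style upsampling (nearest
repetition followed by a fixed separable [1/4, 1/2, 1/4] smoothing) and skip
concatenation. Multiscale highlighting of foregrounds (MHF) is realised as
deep supervision: auxiliary two-channel softmax heads at every coarse decoder
scale are trained against max-pooled ground truth (max-pooling, never
averaging, so a single foreground voxel survives to every scale). An
alternative multiplicative foreground-gating form is available via
``mhf_mode="gating"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

BN_EPS = 1e-5
DICE_EPS = 1e-5


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the network.

    ``base_channels`` doubles at every encoder level. ``aux_loss_decay`` is
    the geometric weight of the scale-s auxiliary loss term (decay^s).
    ``input_shape``, when given, is validated at build time: the large kernel
    must fit inside the deepest encoder grid.
    """

    n_levels: int = 4
    in_channels: int = 1
    out_channels: int = 2
    base_channels: int = 16
    large_kernel_edge: int = 13
    parallel_kernel_edge: int = 5
    mhf_enabled: bool = True
    mhf_mode: str = "deep_supervision"  # or "gating"
    aux_loss_decay: float = 0.5
    input_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.large_kernel_edge % 2 == 0 or self.parallel_kernel_edge % 2 == 0:
            raise ValueError("kernel edges must be odd")
        if self.parallel_kernel_edge >= self.large_kernel_edge:
            raise ValueError("parallel kernel edge must be < large kernel edge")
        if not 0.0 < self.aux_loss_decay <= 1.0:
            raise ValueError("aux_loss_decay must lie in (0, 1]")
        if self.mhf_mode not in ("deep_supervision", "gating"):
            raise ValueError(f"unknown mhf_mode {self.mhf_mode!r}")
        if self.input_shape is not None:
            deepest = [s // 2 ** (self.n_levels - 1) for s in self.input_shape]
            if any(self.large_kernel_edge > d for d in deepest):
                raise ValueError(
                    f"large kernel ({self.large_kernel_edge}) exceeds the input "
                    f"extent {tuple(deepest)} at the deepest encoder level "
                    f"(level {self.n_levels - 1})"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["input_shape"] is not None:
            d["input_shape"] = list(d["input_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if d.get("input_shape") is not None:
            d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclass
class NormStats:
    """Per-channel affine normalisation statistics (gamma, beta, mean, var)."""

    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    var: np.ndarray


@dataclass
class BlockParams:
    """Raw parameter arrays of one encoder block, in training (two-branch)
    or fused (single-branch) form."""

    pw_in_w: np.ndarray
    pw_in_b: np.ndarray
    large_kernel: np.ndarray  # (C, e, e, e)
    large_bias: np.ndarray
    large_norm: NormStats | None
    small_kernel: np.ndarray | None
    small_bias: np.ndarray | None
    small_norm: NormStats | None
    pw_out_w: np.ndarray
    pw_out_b: np.ndarray
    fused: bool = False


@dataclass
class MultiscaleOutputs:
    """Softmax probability maps from one forward pass.

    ``final_prob`` is (N, 2, D, H, W); ``aux_probs[s-1]`` is the scale-s map
    at 1/2^s resolution (only populated in training mode with MHF enabled).
    Tensors carry the autodiff graph; use ``.data`` for plain arrays.
    """

    final_prob: Tensor
    final_logits: Tensor
    aux_probs: list[Tensor] = field(default_factory=list)
    aux_logits: list[Tensor] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Layers


class BatchNorm3d:
    """Per-channel normalisation over batch and space with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        shape = (1, -1, 1, 1, 1)
        if training:
            axes = (0, 2, 3, 4)
            mean = ad.tmean(x, axis=axes, keepdims=True)
            centered = ad.add(x, ad.mul(mean, -1.0))
            var = ad.tmean(ad.mul(centered, centered), axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mean.data.reshape(-1)
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            ).astype(np.float32)
            inv = ad.power(ad.add(var, BN_EPS), -0.5)
            xhat = ad.mul(centered, inv)
        else:
            mean = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + BN_EPS)
            xhat = ad.mul(ad.add(x, -mean), inv)
        return ad.add(
            ad.mul(xhat, _reshape_param(self.gamma, shape)),
            _reshape_param(self.beta, shape),
        )

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]


def _reshape_param(p: Parameter, shape) -> Tensor:
    data = p.data.reshape(shape)

    def bwd(out):
        def run():
            p.accumulate(out.grad.reshape(p.data.shape))

        return run

    return ad._make(data, (p,), bwd)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class LargeKernelBlock:
    """Pointwise expand -> parallel depthwise (large + small, each normalised)
    -> sum -> GELU -> pointwise project."""

    def __init__(
        self, channels: int, large_edge: int, small_edge: int, rng: np.random.Generator
    ):
        c, eL, eS = channels, large_edge, small_edge
        self.channels, self.large_edge, self.small_edge = c, eL, eS
        self.pw_in_w = Parameter(_he_init(rng, (c, c), c))
        self.pw_in_b = Parameter(np.zeros(c, dtype=np.float32))
        self.large_k = Parameter(_he_init(rng, (c, eL, eL, eL), eL**3))
        self.large_b = Parameter(np.zeros(c, dtype=np.float32))
        self.large_bn = BatchNorm3d(c)
        self.small_k = Parameter(_he_init(rng, (c, eS, eS, eS), eS**3))
        self.small_b = Parameter(np.zeros(c, dtype=np.float32))
        self.small_bn = BatchNorm3d(c)
        self.pw_out_w = Parameter(_he_init(rng, (c, c), c))
        self.pw_out_b = Parameter(np.zeros(c, dtype=np.float32))
        self._fused_k: np.ndarray | None = None
        self._fused_b: np.ndarray | None = None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        t = ad.conv1x1(x, self.pw_in_w, self.pw_in_b)
        if self._fused_k is not None and not training:
            u = ad.depthwise_conv3d(t, Tensor(self._fused_k), Tensor(self._fused_b))
        else:
            large = self.large_bn(
                ad.depthwise_conv3d(t, self.large_k, self.large_b), training
            )
            small = self.small_bn(
                ad.depthwise_conv3d(t, self.small_k, self.small_b), training
            )
            u = ad.add(large, small)
        v = ad.gelu(u)
        return ad.conv1x1(v, self.pw_out_w, self.pw_out_b)

    def params(self) -> list[Parameter]:
        return [
            self.pw_in_w,
            self.pw_in_b,
            self.large_k,
            self.large_b,
            *self.large_bn.params(),
            self.small_k,
            self.small_b,
            *self.small_bn.params(),
            self.pw_out_w,
            self.pw_out_b,
        ]

    def export_params(self) -> BlockParams:
        def stats(bn: BatchNorm3d) -> NormStats:
            return NormStats(
                gamma=bn.gamma.data.copy(),
                beta=bn.beta.data.copy(),
                mean=bn.running_mean.copy(),
                var=bn.running_var.copy(),
            )

        return BlockParams(
            pw_in_w=self.pw_in_w.data.copy(),
            pw_in_b=self.pw_in_b.data.copy(),
            large_kernel=self.large_k.data.copy(),
            large_bias=self.large_b.data.copy(),
            large_norm=stats(self.large_bn),
            small_kernel=self.small_k.data.copy(),
            small_bias=self.small_b.data.copy(),
            small_norm=stats(self.small_bn),
            pw_out_w=self.pw_out_w.data.copy(),
            pw_out_b=self.pw_out_b.data.copy(),
            fused=False,
        )

    def fuse(self) -> None:
        """Precompute the fused single-branch depthwise kernel for inference."""
        fused = fuse_reparameterize(self.export_params())
        self._fused_k = fused.large_kernel
        self._fused_b = fused.large_bias


# ---------------------------------------------------------------------------
# Re-parameterization


def _fold_norm(
    kernel: np.ndarray, bias: np.ndarray, norm: NormStats, eps: float = BN_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Fold an affine normalisation into a preceding depthwise convolution."""
    if np.any(norm.var <= 0):
        raise ValueError("normalisation variance must be positive")
    scale = norm.gamma / np.sqrt(norm.var + eps)
    w = kernel * scale[:, None, None, None]
    b = (bias - norm.mean) * scale + norm.beta
    return w, b


def _pad_kernel(kernel: np.ndarray, target_edge: int) -> np.ndarray:
    """Zero-pad a depthwise kernel symmetrically so its centre is preserved."""
    e = kernel.shape[-1]
    pad = (target_edge - e) // 2
    if pad < 0 or (target_edge - e) % 2 != 0:
        raise ValueError(f"cannot pad edge {e} to {target_edge}")
    pads = [(0, 0)] + [(pad, pad)] * 3
    return np.pad(kernel, pads)


def fuse_reparameterize(block: BlockParams) -> BlockParams:
    """Merge the two normalised depthwise branches into one equivalent kernel.

    Both normalisations are folded into their kernels, the small kernel is
    zero-padded to the large edge, and kernels and biases are summed. Forward
    outputs of the fused and two-branch forms agree to float rounding.
    """
    if block.fused:
        return block
    eL = block.large_kernel.shape[-1]
    eS = block.small_kernel.shape[-1]
    if eL % 2 == 0 or eS % 2 == 0:
        raise ValueError("kernel edges must be odd (no centre voxel otherwise)")
    wl, bl = _fold_norm(block.large_kernel, block.large_bias, block.large_norm)
    ws, bs = _fold_norm(block.small_kernel, block.small_bias, block.small_norm)
    fused_k = wl + _pad_kernel(ws, eL)
    fused_b = bl + bs
    return BlockParams(
        pw_in_w=block.pw_in_w,
        pw_in_b=block.pw_in_b,
        large_kernel=fused_k,
        large_bias=fused_b,
        large_norm=None,
        small_kernel=None,
        small_bias=None,
        small_norm=None,
        pw_out_w=block.pw_out_w,
        pw_out_b=block.pw_out_b,
        fused=True,
    )


def block_forward(params: BlockParams, x: np.ndarray, training: bool = False) -> np.ndarray:
    """Run one encoder block from raw parameter arrays (inference only).

    Used both for fused inference and as the reference two-branch path in
    fusion-equivalence checks. ``x`` is (N, C, D, H, W).
    """
    with ad.no_grad():
        return _block_forward_impl(params, x)


def _block_forward_impl(params: BlockParams, x: np.ndarray) -> np.ndarray:
    t = ad.conv1x1(Tensor(x), Tensor(params.pw_in_w), Tensor(params.pw_in_b))
    if params.fused:
        u = ad.depthwise_conv3d(
            t, Tensor(params.large_kernel), Tensor(params.large_bias)
        )
    else:

        def branch(k, b, norm):
            y = ad.depthwise_conv3d(t, Tensor(k), Tensor(b))
            scale = (norm.gamma / np.sqrt(norm.var + BN_EPS)).reshape(1, -1, 1, 1, 1)
            shift = (norm.beta - norm.mean * norm.gamma / np.sqrt(norm.var + BN_EPS))
            return ad.add(ad.mul(y, scale), shift.reshape(1, -1, 1, 1, 1))

        u = ad.add(
            branch(params.large_kernel, params.large_bias, params.large_norm),
            branch(params.small_kernel, params.small_bias, params.small_norm),
        )
    v = ad.gelu(u)
    return ad.conv1x1(v, Tensor(params.pw_out_w), Tensor(params.pw_out_b)).data


def random_block_params(
    channels: int, large_edge: int, small_edge: int, rng: np.random.Generator
) -> BlockParams:
    """A randomly parameterised two-branch block with random (valid) running
    statistics — the raw material for fusion-equivalence checks."""

    def norm() -> NormStats:
        return NormStats(
            gamma=rng.uniform(0.5, 1.5, channels).astype(np.float32),
            beta=rng.normal(0, 0.5, channels).astype(np.float32),
            mean=rng.normal(0, 0.5, channels).astype(np.float32),
            var=rng.uniform(0.2, 2.0, channels).astype(np.float32),
        )

    return BlockParams(
        pw_in_w=rng.normal(0, 0.5, (channels, channels)).astype(np.float32),
        pw_in_b=rng.normal(0, 0.1, channels).astype(np.float32),
        large_kernel=rng.normal(0, 0.05, (channels,) + (large_edge,) * 3).astype(
            np.float32
        ),
        large_bias=rng.normal(0, 0.1, channels).astype(np.float32),
        large_norm=norm(),
        small_kernel=rng.normal(0, 0.2, (channels,) + (small_edge,) * 3).astype(
            np.float32
        ),
        small_bias=rng.normal(0, 0.1, channels).astype(np.float32),
        small_norm=norm(),
        pw_out_w=rng.normal(0, 0.5, (channels, channels)).astype(np.float32),
        pw_out_b=rng.normal(0, 0.1, channels).astype(np.float32),
        fused=False,
    )


# ---------------------------------------------------------------------------
# The full network


class _Downsample:
    """Stride-2 depthwise 3x3x3 conv followed by a pointwise channel doubling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.dw_k = Parameter(_he_init(rng, (c_in, 3, 3, 3), 27))
        self.dw_b = Parameter(np.zeros(c_in, dtype=np.float32))
        self.pw_w = Parameter(_he_init(rng, (c_out, c_in), c_in))
        self.pw_b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.depthwise_conv3d(x, self.dw_k, self.dw_b, stride=2)
        return ad.conv1x1(y, self.pw_w, self.pw_b)

    def params(self):
        return [self.dw_k, self.dw_b, self.pw_w, self.pw_b]


def _smoothing_kernel(channels: int) -> np.ndarray:
    k1 = np.array([0.25, 0.5, 0.25], dtype=np.float32)
    k3 = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    return np.broadcast_to(k3, (channels, 3, 3, 3)).copy()


class _Upsample:
    """Nearest x2 + fixed separable smoothing (trilinear) + pointwise mix."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.smooth = Tensor(_smoothing_kernel(c_in))
        self.pw_w = Parameter(_he_init(rng, (c_out, c_in), c_in))
        self.pw_b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.depthwise_conv3d(ad.upsample_nearest2x(x), self.smooth)
        return ad.conv1x1(y, self.pw_w, self.pw_b)

    def params(self):
        return [self.pw_w, self.pw_b]


class _DecoderBlock:
    """Pointwise squeeze of the concatenated features, depthwise 3x3x3 + norm,
    GELU, pointwise."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.pw_in_w = Parameter(_he_init(rng, (c, 2 * c), 2 * c))
        self.pw_in_b = Parameter(np.zeros(c, dtype=np.float32))
        self.dw_k = Parameter(_he_init(rng, (c, 3, 3, 3), 27))
        self.dw_b = Parameter(np.zeros(c, dtype=np.float32))
        self.bn = BatchNorm3d(c)
        self.pw_out_w = Parameter(_he_init(rng, (c, c), c))
        self.pw_out_b = Parameter(np.zeros(c, dtype=np.float32))

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        t = ad.conv1x1(x, self.pw_in_w, self.pw_in_b)
        u = self.bn(ad.depthwise_conv3d(t, self.dw_k, self.dw_b), training)
        return ad.conv1x1(ad.gelu(u), self.pw_out_w, self.pw_out_b)

    def params(self):
        return [
            self.pw_in_w,
            self.pw_in_b,
            self.dw_k,
            self.dw_b,
            *self.bn.params(),
            self.pw_out_w,
            self.pw_out_b,
        ]


class Network:
    """The full encoder/decoder. Build with :func:`build_network`."""

    def __init__(self, config: NetworkConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        L = config.n_levels
        ch = [config.base_channels * 2**i for i in range(L)]
        self.channels = ch
        self.stem_w = Parameter(_he_init(rng, (ch[0], config.in_channels), 1))
        self.stem_b = Parameter(np.zeros(ch[0], dtype=np.float32))
        self.enc_blocks = [
            LargeKernelBlock(
                ch[i], config.large_kernel_edge, config.parallel_kernel_edge, rng
            )
            for i in range(L)
        ]
        self.downs = [_Downsample(ch[i], ch[i + 1], rng) for i in range(L - 1)]
        self.ups = [_Upsample(ch[i + 1], ch[i], rng) for i in range(L - 1)]
        self.dec_blocks = [_DecoderBlock(ch[i], rng) for i in range(L - 1)]
        self.head_w = Parameter(_he_init(rng, (config.out_channels, ch[0]), ch[0]))
        self.head_b = Parameter(np.zeros(config.out_channels, dtype=np.float32))
        # auxiliary heads at scales 1 .. L-1 (aux_heads[s-1] acts at scale s)
        self.aux_heads = [
            (
                Parameter(_he_init(rng, (config.out_channels, ch[s]), ch[s])),
                Parameter(np.zeros(config.out_channels, dtype=np.float32)),
            )
            for s in range(1, L)
        ]
        self._is_fused = False

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        ps = [self.stem_w, self.stem_b, self.head_w, self.head_b]
        for blk in self.enc_blocks:
            ps += blk.params()
        for layer in (*self.downs, *self.ups, *self.dec_blocks):
            ps += layer.params()
        for w, b in self.aux_heads:
            ps += [w, b]
        return ps

    # -- forward ------------------------------------------------------------

    def forward(self, volume: np.ndarray, training_mode: bool = False) -> MultiscaleOutputs:
        """Run the network on one volume (D,H,W) or batch (N,1,D,H,W).

        Spatial edges must be divisible by 2^(n_levels-1). Auxiliary maps are
        produced only in training mode with MHF enabled (deep supervision) —
        at inference only the full-resolution map is computed.
        """
        x = np.asarray(volume, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        L = self.config.n_levels
        div = 2 ** (L - 1)
        if any(s % div != 0 for s in x.shape[-3:]):
            raise ValueError(
                f"input spatial shape {x.shape[-3:]} must be divisible by {div} "
                f"(2^(n_levels-1))"
            )
        t = ad.conv1x1(Tensor(x), self.stem_w, self.stem_b)
        skips = []
        for i in range(L):
            t = self.enc_blocks[i](t, training_mode)
            if i < L - 1:
                skips.append(t)
                t = self.downs[i](t)

        aux_logits: list[Tensor] = [None] * (L - 1)  # index s-1 = scale s
        aux_probs: list[Tensor] = [None] * (L - 1)
        want_aux = training_mode and self.config.mhf_enabled
        gating = self.config.mhf_enabled and self.config.mhf_mode == "gating"

        def attach_aux(feat: Tensor, scale: int) -> Tensor:
            if scale >= 1 and (want_aux or gating):
                w, b = self.aux_heads[scale - 1]
                logits = ad.conv1x1(feat, w, b)
                probs = ad.softmax_channels(logits)
                aux_logits[scale - 1] = logits
                aux_probs[scale - 1] = probs
                if gating:
                    fg = probs.data[:, 1:2]
                    feat = ad.mul(feat, 1.0 + fg)  # highlight foreground regions
            return feat

        d = attach_aux(t, L - 1)
        for i in range(L - 2, -1, -1):
            up = self.ups[i](d)
            d = self.dec_blocks[i](ad.concat_channels([up, skips[i]]), training_mode)
            d = attach_aux(d, i)
        final_logits = ad.conv1x1(d, self.head_w, self.head_b)
        final_prob = ad.softmax_channels(final_logits)
        out = MultiscaleOutputs(final_prob=final_prob, final_logits=final_logits)
        if want_aux:
            out.aux_logits = [t for t in aux_logits if t is not None]
            out.aux_probs = [t for t in aux_probs if t is not None]
        return out

    def predict_foreground(self, volume: np.ndarray) -> np.ndarray:
        """Foreground probability map (D,H,W) at inference settings."""
        with ad.no_grad():
            out = self.forward(volume, training_mode=False)
        return out.final_prob.data[0, 1]

    # -- fusion -------------------------------------------------------------

    def fuse(self) -> "Network":
        """Re-parameterize all encoder blocks in place; returns self."""
        for blk in self.enc_blocks:
            blk.fuse()
        self._is_fused = True
        return self

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        stats = {}
        for j, bn in enumerate(self._norm_layers()):
            stats[f"rm{j}"] = bn.running_mean
            stats[f"rv{j}"] = bn.running_var
        np.savez(
            str(path),
            config_json=np.frombuffer(
                json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
            ),
            **arrays,
            **stats,
        )

    def _norm_layers(self) -> list[BatchNorm3d]:
        layers = []
        for blk in self.enc_blocks:
            layers += [blk.large_bn, blk.small_bn]
        for dec in self.dec_blocks:
            layers.append(dec.bn)
        return layers

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with np.load(str(path)) as archive:
            config = NetworkConfig.from_dict(
                json.loads(bytes(archive["config_json"]).decode())
            )
            net = cls(config, seed=0)
            for i, p in enumerate(net.parameters()):
                p.data = archive[f"p{i}"].copy()
            for j, bn in enumerate(net._norm_layers()):
                bn.running_mean = archive[f"rm{j}"].copy()
                bn.running_var = archive[f"rv{j}"].copy()
        return net


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Construct a network with deterministic initialisation under ``seed``."""
    return Network(config, seed)


# ---------------------------------------------------------------------------
# MHF targets and composite loss


def mhf_targets(gt_mask: np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Foreground-preserving multiscale targets: 2x2x2 max-pooling applied
    s times gives the scale-s target (s = 1..n_scales)."""
    gt = np.asarray(gt_mask).astype(bool)
    div = 2**n_scales
    if any(s % div != 0 for s in gt.shape):
        raise ValueError(
            f"gt shape {gt.shape} must be divisible by 2^{n_scales} = {div}"
        )
    targets = []
    cur = gt
    for _ in range(n_scales):
        d, h, w = cur.shape
        cur = cur.reshape(d // 2, 2, h // 2, 2, w // 2, 2).max(axis=(1, 3, 5))
        targets.append(cur)
    return targets


def composite_loss(
    outputs: MultiscaleOutputs,
    gt_mask: np.ndarray,
    aux_targets: list[np.ndarray] | None = None,
    aux_loss_decay: float = 0.5,
    dice_eps: float = DICE_EPS,
) -> Tensor:
    """Cross-entropy + soft Dice at full scale, plus geometrically decaying
    auxiliary terms at every supervised coarse scale."""
    gt = np.asarray(gt_mask).astype(bool)
    if outputs.final_prob.data.shape[-3:] != gt.shape[-3:]:
        raise ValueError(
            f"prediction shape {outputs.final_prob.data.shape[-3:]} does not "
            f"match ground truth {gt.shape[-3:]}"
        )
    fg = gt[None] if gt.ndim == 3 else gt
    loss = ad.add(
        ad.cross_entropy_fg(outputs.final_logits, fg),
        ad.soft_dice_loss(
            _fg_channel(outputs.final_prob), fg, eps=dice_eps
        ),
    )
    if aux_targets:
        if len(aux_targets) != len(outputs.aux_logits):
            raise ValueError(
                f"{len(aux_targets)} auxiliary targets but "
                f"{len(outputs.aux_logits)} auxiliary outputs"
            )
        for s, (logits, probs, target) in enumerate(
            zip(outputs.aux_logits, outputs.aux_probs, aux_targets), start=1
        ):
            tfg = np.asarray(target).astype(bool)
            tfg = tfg[None] if tfg.ndim == 3 else tfg
            term = ad.add(
                ad.cross_entropy_fg(logits, tfg),
                ad.soft_dice_loss(_fg_channel(probs), tfg, eps=dice_eps),
            )
            loss = ad.add(loss, ad.mul(term, aux_loss_decay**s))
    return loss


def _fg_channel(prob: Tensor) -> Tensor:
    data = prob.data[:, 1]

    def bwd(out):
        def run():
            g = np.zeros_like(prob.data)
            g[:, 1] = out.grad
            prob.accumulate(g)

        return run

    return ad._make(data, (prob,), bwd)


def soft_dice_value(prob_fg: np.ndarray, gt: np.ndarray, eps: float = DICE_EPS) -> float:
    """Plain-number soft-Dice *loss* (1 - dice), for reporting."""
    p = np.asarray(prob_fg, dtype=np.float64)
    g = np.asarray(gt).astype(np.float64)
    return float(1.0 - (2.0 * (p * g).sum() + eps) / (p.sum() + g.sum() + eps))
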