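"""Attention encoder blocks, skip refinement, and network assembly.

The network is a 3-D encoder-decoder for volumetric lesion segmentation
with two interchangeable encoder units:

* **SAEB** (single adaptive encoder block) — a squeeze-and-excitation
  style unit: 3x3x3 conv -> batch norm -> global average pooling ->
  two 1x1x1 channel-transform convs -> *softmax* channel weights ->
  channel-wise rescaling of the batch-normalized map -> ReLU.  The
  softmax (a probability distribution over channels, rather than the
  canonical SE sigmoid) is a deliberate property of this design.
* **DAEB** (dual adaptive encoder block) — a 3x3x3 conv producing T,
  then two parallel attention branches: a sigmoid channel-attention map
  (GAP -> reduce/restore 1x1x1 convs -> sigmoid) rescaling T, and a
  sigmoid spatial-attention map (channel max-pool ++ channel avg-pool
  -> KxKxK conv -> sigmoid) rescaling T; the two rescaled tensors are
  fused by elementwise addition.
* **SegPath** — skip-connection refinement: n parallel iterations, each
  summing a ReLU(BN(1x1x1 conv)) branch and a ReLU(BN(3x3x3 conv))
  branch of the skip tensor; the n iteration outputs are accumulated by
  elementwise addition.  n = 0 degenerates to a plain skip.

Each encoder stage is followed by 3x3x3 / stride-2 max pooling; the
decoder mirrors with kernel-2 / stride-2 transpose convolutions, skip
concatenation and two 3x3x3 conv+BN+ReLU refinements; the head is a
1x1x1 conv to K classes with a per-voxel softmax.

Tensors are channel-last: (batch, H, W, D, C).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class ConfigurationError(ValueError):
    """Inconsistent architectural configuration (shape/channel mismatch)."""


class ValidationError(ValueError):
    """Invalid runtime input (non-finite values, bad dimensions)."""


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Architectural hyperparameters of the segmentation network.

    Parameters
    ----------
    variant:
        ``"SAEB"`` or ``"DAEB"`` — which encoder unit to use.
    n_stages:
        Number of encoder stages (each halves the spatial resolution).
    base_channels:
        Channel width of the first stage.
    channel_growth:
        Width multiplier per stage (stage s has base * growth**s channels).
    se_reduction:
        Bottleneck ratio r of the channel-attention 1x1x1 conv pair.
    segpath_iterations:
        Iteration count n of the skip-refinement path per skip level,
        ordered shallowest to deepest; 0 means a plain skip.
    spatial_kernel:
        Kernel size of the DAEB spatial-attention convolution.
    n_classes:
        Number of output classes K (softmax head).
    input_channels:
        Number of image channels (modalities).
    """

    variant: str = "SAEB"
    n_stages: int = 4
    base_channels: int = 16
    channel_growth: int = 2
    se_reduction: int = 4
    segpath_iterations: list[int] = field(default_factory=lambda: [4, 3, 2, 1])
    spatial_kernel: int = 7
    n_classes: int = 2
    input_channels: int = 1

    def validate(self) -> None:
        if self.variant not in ("SAEB", "DAEB"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.n_stages < 2:
            raise ConfigurationError("n_stages must be >= 2")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")
        for s in range(self.n_stages + 1):
            ch = self.stage_channels(s)
            if ch % self.se_reduction != 0:
                raise ConfigurationError(
                    f"stage {s} width {ch} not divisible by reduction "
                    f"{self.se_reduction}")
        if len(self.segpath_iterations) != self.n_stages:
            raise ConfigurationError(
                "segpath_iterations needs one entry per encoder stage")
        if any(n < 0 for n in self.segpath_iterations):
            raise ConfigurationError("segpath_iterations entries must be >= 0")
        if self.spatial_kernel % 2 != 1 or self.spatial_kernel < 1:
            raise ConfigurationError("spatial_kernel must be odd and positive")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.input_channels < 1:
            raise ConfigurationError("input_channels must be >= 1")

    def stage_channels(self, stage: int) -> int:
        return self.base_channels * self.channel_growth ** stage

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# Parameterized layers
# ---------------------------------------------------------------------------

def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv3d:
    """Same-padded stride-1 3-D convolution layer with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel ** 3 * c_in
        self.w = Tensor(_he_uniform(rng, (kernel, kernel, kernel, c_in, c_out), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.c_in, self.c_out = c_in, c_out

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.c_in:
            raise ConfigurationError(
                f"expected {self.c_in} input channels, got {x.shape[-1]}")
        return ad.conv3d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]

    def kernel_params(self):
        return [self.w]


class ConvTranspose3d2x:
    """Kernel-2 / stride-2 transpose convolution (2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = 8 * c_in
        self.w = Tensor(_he_uniform(rng, (2, 2, 2, c_in, c_out), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d_2x(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]

    def kernel_params(self):
        return [self.w]


class BatchNorm:
    """Per-channel batch normalization over (batch, H, W, D).

    Training mode uses batch statistics; inference uses exponential
    running statistics (momentum 0.9, eps 1e-5).
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=ad.DTYPE)
        self.running_var = np.ones(channels, dtype=ad.DTYPE)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = ad.mean_(x, axis=(0, 1, 2, 3), keepdims=True)
            var = ad.mean_((x - mu) ** 2.0, axis=(0, 1, 2, 3), keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data.ravel())
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data.ravel())
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return self.gamma * xhat + self.beta

    def params(self):
        return [self.gamma, self.beta]

    def kernel_params(self):
        return []


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

def _check_finite(x: Tensor, where: str):
    if not np.all(np.isfinite(x.data)):
        raise ValidationError(f"non-finite values in input to {where}")


class SAEB:
    """Single adaptive encoder block (softmax channel attention)."""

    def __init__(self, c_in: int, c_out: int, reduction: int,
                 rng: np.random.Generator):
        if c_out % reduction:
            raise ConfigurationError(
                f"channels {c_out} not divisible by reduction {reduction}")
        self.conv = Conv3d(c_in, c_out, 3, rng)
        self.bn = BatchNorm(c_out)
        self.reduce = Conv3d(c_out, c_out // reduction, 1, rng)
        self.restore = Conv3d(c_out // reduction, c_out, 1, rng)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        _check_finite(x, "SAEB")
        y_bn = self.bn(self.conv(x), training)
        s = ad.global_avg_pool(y_bn)                       # (b,1,1,1,C)
        s = self.restore(ad.relu(self.reduce(s)))
        a = ad.softmax(s, axis=4)                          # channel distribution
        return ad.relu(a * y_bn)

    def attention_weights(self, x: Tensor, training: bool = False) -> np.ndarray:
        """The softmax channel weights A_c for ``x`` (shape (b, C))."""
        y_bn = self.bn(self.conv(x), training)
        s = self.restore(ad.relu(self.reduce(ad.global_avg_pool(y_bn))))
        return ad.softmax(s, axis=4).data.reshape(x.shape[0], -1)

    def sublayers(self):
        return [self.conv, self.bn, self.reduce, self.restore]


class DAEB:
    """Dual adaptive encoder block (sigmoid channel + spatial attention)."""

    def __init__(self, c_in: int, c_out: int, reduction: int,
                 spatial_kernel: int, rng: np.random.Generator):
        if c_out % reduction:
            raise ConfigurationError(
                f"channels {c_out} not divisible by reduction {reduction}")
        self.conv = Conv3d(c_in, c_out, 3, rng)
        self.reduce = Conv3d(c_out, c_out // reduction, 1, rng)
        self.restore = Conv3d(c_out // reduction, c_out, 1, rng)
        self.spatial = Conv3d(2, 1, spatial_kernel, rng)

    def _maps(self, t: Tensor) -> tuple[Tensor, Tensor]:
        ca = ad.sigmoid(self.restore(ad.relu(self.reduce(ad.global_avg_pool(t)))))
        pooled = ad.concat([ad.max_(t, axis=4, keepdims=True),
                            ad.mean_(t, axis=4, keepdims=True)], axis=4)
        sa = ad.sigmoid(self.spatial(pooled))
        return ca, sa

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        _check_finite(x, "DAEB")
        t = self.conv(x)
        ca, sa = self._maps(t)
        return t * ca + t * sa

    def attention_maps(self, x: Tensor) -> tuple[np.ndarray, np.ndarray]:
        """Sigmoid channel and spatial attention maps (CA, SA) for ``x``."""
        ca, sa = self._maps(self.conv(x))
        return ca.data, sa.data

    def sublayers(self):
        return [self.conv, self.reduce, self.restore, self.spatial]


class SegPath:
    """Skip-path refinement with n parallel 1x1x1 + 3x3x3 iterations."""

    def __init__(self, channels: int, n: int, rng: np.random.Generator):
        if n < 0:
            raise ValidationError("SegPath iteration count must be >= 0")
        self.n = n
        self.branches = []
        for _ in range(n):
            self.branches.append({
                "c1": Conv3d(channels, channels, 1, rng), "bn1": BatchNorm(channels),
                "c3": Conv3d(channels, channels, 3, rng), "bn3": BatchNorm(channels),
            })

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if self.n == 0:
            return x
        _check_finite(x, "SegPath")
        z = None
        for br in self.branches:
            y1 = ad.relu(br["bn1"](br["c1"](x), training))
            y2 = ad.relu(br["bn3"](br["c3"](x), training))
            yi = y1 + y2
            z = yi if z is None else z + yi
        return z

    def sublayers(self):
        out = []
        for br in self.branches:
            out.extend(br.values())
        return out


class DecoderStage:
    """Transpose-conv upsample, skip concat, two conv+BN+ReLU refinements."""

    def __init__(self, c_in: int, c_out: int, c_skip: int, rng: np.random.Generator):
        self.up = ConvTranspose3d2x(c_in, c_out, rng)
        self.conv1 = Conv3d(c_out + c_skip, c_out, 3, rng)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm(c_out)

    def __call__(self, x: Tensor, skip: Tensor, training: bool = False) -> Tensor:
        y = ad.concat([self.up(x), skip], axis=4)
        y = ad.relu(self.bn1(self.conv1(y), training))
        return ad.relu(self.bn2(self.conv2(y), training))

    def sublayers(self):
        return [self.up, self.conv1, self.bn1, self.conv2, self.bn2]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class Network:
    """Full encoder-decoder segmentation network with softmax head."""

    def __init__(self, spec: NetworkSpec, seed: int):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)

        def make_block(c_in, c_out):
            if spec.variant == "SAEB":
                return SAEB(c_in, c_out, spec.se_reduction, rng)
            return DAEB(c_in, c_out, spec.se_reduction, spec.spatial_kernel, rng)

        self.encoders = []
        c_in = spec.input_channels
        for s in range(spec.n_stages):
            self.encoders.append(make_block(c_in, spec.stage_channels(s)))
            c_in = spec.stage_channels(s)
        self.bottleneck = make_block(c_in, spec.stage_channels(spec.n_stages))
        self.segpaths = [
            SegPath(spec.stage_channels(s), spec.segpath_iterations[s], rng)
            for s in range(spec.n_stages)
        ]
        self.decoders = []
        for s in reversed(range(spec.n_stages)):
            c_deep = spec.stage_channels(s + 1)
            c_here = spec.stage_channels(s)
            self.decoders.append(DecoderStage(c_deep, c_here, c_here, rng))
        self.head = Conv3d(spec.stage_channels(0), spec.n_classes, 1, rng)

    # -- plumbing ------------------------------------------------------------
    def _modules(self):
        mods = list(self.encoders) + [self.bottleneck] + self.segpaths + \
            list(self.decoders)
        out = []
        for m in mods:
            out.extend(m.sublayers())
        out.append(self.head)
        return out

    def params(self) -> list[Tensor]:
        return [p for m in self._modules() for p in m.params()]

    def kernel_params(self) -> list[Tensor]:
        return [p for m in self._modules() for p in m.kernel_params()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus BN running statistics, keyed."""
        out = {}
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                out[f"param_{i}_{j}"] = p.data
            if isinstance(m, BatchNorm):
                out[f"running_mean_{i}"] = m.running_mean
                out[f"running_var_{i}"] = m.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                p.data = np.asarray(arrays[f"param_{i}_{j}"], dtype=ad.DTYPE)
            if isinstance(m, BatchNorm):
                m.running_mean = np.asarray(arrays[f"running_mean_{i}"], dtype=ad.DTYPE)
                m.running_var = np.asarray(arrays[f"running_var_{i}"], dtype=ad.DTYPE)

    # -- forward -------------------------------------------------------------
    def forward(self, x, training: bool = False) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim != 5:
            raise ValidationError("input must be (batch, H, W, D, C)")
        if x.shape[-1] != self.spec.input_channels:
            raise ConfigurationError(
                f"expected {self.spec.input_channels} channels, got {x.shape[-1]}")
        div = 2 ** self.spec.n_stages
        for ax, nm in zip(x.shape[1:4], "HWD"):
            if ax % div:
                raise ValidationError(
                    f"spatial dim {nm}={ax} must be divisible by 2^n_stages = {div}")
        _check_finite(x, "network")

        skips = []
        h = x
        for enc, sp in zip(self.encoders, self.segpaths):
            h = enc(h, training)
            skips.append(sp(h, training))
            h = ad.maxpool3d(h)
        h = self.bottleneck(h, training)
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = dec(h, skip, training)
        return ad.softmax(self.head(h), axis=4)

    __call__ = forward


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Build a network with all parameters drawn from one seeded generator."""
    return Network(spec, seed)


def count_parameters(net: Network) -> int:
    """Exact count of trainable scalar parameters."""
    return int(sum(p.size for p in net.params()))
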