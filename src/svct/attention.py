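"""Attention-guided feature scaling and the modified U-Net built from it.

Plain pooling/up-convolution discards information during scale changes.
Here every scale change is guided by two attention branches that are summed:

* **Channel branch** — squeeze-and-excitation: global average pooling gives a
  per-channel descriptor ``V_c``; a two-layer bottleneck (ReLU then sigmoid)
  turns it into weights ``V_cw`` in (0, 1); the input is resampled (bilinear
  x2 for upscaling, 2x2 average pooling for downscaling) and each channel is
  multiplied by its weight.

* **Spatial branch** — the feature map ``F`` (C x HW) is summarised by M
  learned *visual primitives*: an attention map ``P`` (HW x M, each column a
  softmax distribution over positions) pools ``F`` into a primitive bank
  ``FP = F @ P`` (C x M); a scaling map ``D`` (M x s^2 HW, each column a
  softmax distribution over primitives) redistributes the bank over the
  rescaled grid, ``O = FP @ D``.

The fused output is ``Z = O + A`` with spatial size (sH, sW), s in {2, 1/2}.

``P`` is produced by a 1x1 convolution from F; ``D`` by a 3x3 convolution to
``M s^2`` channels followed by channel-to-space rearrangement (upscale) or a
strided 3x3 convolution (downscale).  The U-Net replaces all of its pooling
and up-convolutions with these blocks (AGD down, AGU up).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Tensor

__all__ = ["ChannelAttentionScale", "SpatialAttentionScale", "AttentionScale",
           "ModifiedUNet", "Conv2d", "unet_parameter_count"]


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k=3, stride=1, padding=None,
                 dtype=np.float64, zero_init=False):
        padding = (k // 2) if padding is None else padding
        self.stride, self.padding = stride, padding
        fan_in = cin * k * k
        w = np.zeros((cout, cin, k, k), dtype=dtype) if zero_init else \
            _he_init(rng, (cout, cin, k, k), fan_in, dtype)
        self.w = ad.parameter(w)
        self.b = ad.parameter(np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=self.stride,
                         padding=self.padding)


class Linear(Module):
    def __init__(self, rng, nin, nout, dtype=np.float64):
        self.w = ad.parameter(_he_init(rng, (nout, nin), nin, dtype))
        self.b = ad.parameter(np.zeros(nout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w.transpose(1, 0) + self.b


class ChannelAttentionScale(Module):
    """Squeeze-excite channel weighting fused with fixed resampling.

    ``scale`` is 2 (bilinear upsampling) or 0.5 (2x2 average pooling).
    Bottleneck reduction ratio defaults to 16, floored at 1 unit.
    """

    def __init__(self, rng, channels, scale, reduction=16, dtype=np.float64):
        if scale not in (2, 0.5):
            raise ValueError("scale must be 2 or 0.5")
        hidden = max(channels // reduction, 1)
        self.scale = scale
        self.fc1 = Linear(rng, channels, hidden, dtype)
        self.fc2 = Linear(rng, hidden, channels, dtype)

    def __call__(self, f: Tensor):
        vc = f.mean(axis=(2, 3))                       # (N, C)
        vcw = ad.sigmoid(self.fc2(ad.relu(self.fc1(vc))))
        res = ad.upsample_bilinear2x(f) if self.scale == 2 else ad.avg_pool2d(f)
        n, c = vcw.shape
        a = res * vcw.reshape(n, c, 1, 1)
        return a, vcw


class SpatialAttentionScale(Module):
    """Visual-primitive pooling and redistribution over the rescaled grid."""

    def __init__(self, rng, channels, scale, n_primitives=96, dtype=np.float64):
        if n_primitives < 1:
            raise ValueError("need at least one visual primitive")
        if scale not in (2, 0.5):
            raise ValueError("scale must be 2 or 0.5")
        self.m = n_primitives
        self.scale = scale
        self.p_conv = Conv2d(rng, channels, n_primitives, k=1, dtype=dtype)
        if scale == 2:
            self.d_conv = Conv2d(rng, channels, 4 * n_primitives, k=3, dtype=dtype)
        else:
            self.d_conv = Conv2d(rng, channels, n_primitives, k=3, stride=2,
                                 dtype=dtype)

    def attention_maps(self, f: Tensor):
        n, c, h, w = f.shape
        p_logits = self.p_conv(f).reshape(n, self.m, h * w)
        p = ad.softmax(p_logits, axis=2)               # distributions over HW
        if self.scale == 2:
            d_feat = ad.pixel_shuffle(self.d_conv(f), 2)   # (N, M, 2H, 2W)
        else:
            d_feat = self.d_conv(f)                         # (N, M, H/2, W/2)
        d = ad.softmax(d_feat, axis=1)                 # distributions over M
        return p, d

    def __call__(self, f: Tensor) -> Tensor:
        n, c, h, w = f.shape
        p, d = self.attention_maps(f)
        f2 = f.reshape(n, c, h * w)
        fp = f2 @ p.transpose(0, 2, 1)                 # (N, C, M) primitive bank
        ho, wo = d.shape[2], d.shape[3]
        o = fp @ d.reshape(n, self.m, ho * wo)         # (N, C, sH*sW)
        return o.reshape(n, c, ho, wo)


class AttentionScale(Module):
    """Full attention-guided scaling block: ``Z = O + A`` (AGU or AGD)."""

    def __init__(self, rng, channels, scale, n_primitives=96, reduction=16,
                 dtype=np.float64):
        self.channel = ChannelAttentionScale(rng, channels, scale, reduction, dtype)
        self.spatial = SpatialAttentionScale(rng, channels, scale, n_primitives,
                                             dtype)

    def __call__(self, f: Tensor) -> Tensor:
        a, _ = self.channel(f)
        o = self.spatial(f)
        if o.shape != a.shape:
            raise ValueError(f"branch shapes differ: {o.shape} vs {a.shape}")
        return o + a


class _DoubleConv(Module):
    def __init__(self, rng, cin, cout, dtype):
        self.c1 = Conv2d(rng, cin, cout, dtype=dtype)
        self.c2 = Conv2d(rng, cout, cout, dtype=dtype)

    def __call__(self, x):
        return ad.relu(self.c2(ad.relu(self.c1(x))))


class ModifiedUNet(Module):
    """Encoder-decoder with attention-guided scale changes.

    Every downscale is an AGD block, every upscale an AGU block; skip
    connections concatenate encoder features before each decoder stage.
    With ``residual=True`` the network output is added to (the first
    channel of) its input — the standard choice for image enhancement,
    where predicting the correction is easier than the image.  The final
    1x1 convolution is zero-initialised so a freshly built residual
    network is the identity.
    """

    def __init__(self, rng, in_channels=1, out_channels=1, depth=4,
                 base_width=64, n_primitives=96, reduction=16,
                 residual=True, dtype=np.float64, zero_init_final=True):
        self.depth = depth
        self.residual = residual
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.enc = [_DoubleConv(rng, in_channels, widths[0], dtype)]
        self.down = []
        for i in range(depth):
            self.down.append(AttentionScale(rng, widths[i], 0.5, n_primitives,
                                            reduction, dtype))
            self.enc.append(_DoubleConv(rng, widths[i], widths[i + 1], dtype))
        self.up = []
        self.dec = []
        for i in reversed(range(depth)):
            self.up.append(AttentionScale(rng, widths[i + 1], 2, n_primitives,
                                          reduction, dtype))
            self.dec.append(_DoubleConv(rng, widths[i + 1] + widths[i],
                                        widths[i], dtype))
        self.final = Conv2d(rng, widths[0], out_channels, k=1,
                            dtype=dtype, zero_init=zero_init_final)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"spatial size {(h, w)} not divisible by 2^{self.depth}")
        skips = []
        f = self.enc[0](x)
        for i in range(self.depth):
            skips.append(f)
            f = self.enc[i + 1](self.down[i](f))
        for i in range(self.depth):
            f = self.up[i](f)
            f = self.dec[i](ad.concatenate([f, skips[-1 - i]], axis=1))
        out = self.final(f)
        if self.residual:
            out = out + x[:, :out.shape[1], :, :]
        return out


def unet_parameter_count(in_channels, out_channels, depth, base_width,
                         n_primitives, reduction=16):
    """Closed-form parameter count of :class:`ModifiedUNet`."""
    def conv(cin, cout, k):
        return cout * cin * k * k + cout

    def dconv(cin, cout):
        return conv(cin, cout, 3) + conv(cout, cout, 3)

    def att(c, up):
        hidden = max(c // reduction, 1)
        n = (c * hidden + hidden) + (hidden * c + c)          # squeeze-excite
        n += conv(c, n_primitives, 1)                          # P
        n += conv(c, 4 * n_primitives if up else n_primitives, 3)  # D
        return n

    widths = [base_width * 2 ** i for i in range(depth + 1)]
    total = dconv(in_channels, widths[0])
    for i in range(depth):
        total += att(widths[i], up=False) + dconv(widths[i], widths[i + 1])
    for i in reversed(range(depth)):
        total += att(widths[i + 1], up=True) + dconv(widths[i + 1] + widths[i],
                                                     widths[i])
    total += conv(widths[0], out_channels, 1)
    return total
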