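"""Network stages: sinogram interpolation (SINet), image enhancement (IENet),
edge-conditioned refinement (HENet) and the Wasserstein critic.

The reconstruction cascade is ``y' = IENet(FBP(SINet(x)))``: SINet expands a
sparse sinogram to the intermediate view set (linear angular interpolation
followed by a U-Net correction), the differentiable FBP layer maps it to an
image, and IENet predicts the residual toward the standard-view reference.
HENet consumes the stage-1 output concatenated with its Sobel edge map and
refines it adversarially against a convolutional critic (no normalisation
layers, as required for a valid gradient penalty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Tensor
from .attention import Conv2d, ModifiedUNet
from .geometry import FanBeamProjector, Sinogram

__all__ = ["SINet", "IENet", "HENet", "Discriminator", "DualDomainModel",
           "DualDomainOutput", "angular_interp_matrix"]


def angular_interp_matrix(n_sparse: int, n_target: int) -> np.ndarray:
    """(n_target, n_sparse) periodic linear interpolation along the view axis.

    Requires the sparse views to be the even decimation of the target set
    (angles k * 2pi/n, so interpolation wraps around 2pi).
    """
    if n_target % n_sparse:
        raise ValueError("sparse view set is not an even subset of the target")
    stride = n_target // n_sparse
    W = np.zeros((n_target, n_sparse))
    for j in range(n_target):
        pos = j / stride
        i0 = int(np.floor(pos))
        f = pos - i0
        W[j, i0 % n_sparse] += 1.0 - f
        W[j, (i0 + 1) % n_sparse] += f
    return W


class SINet(Module):
    """Projection-domain interpolation network.

    The sparse sinogram is first expanded to the intermediate view count by
    periodic linear interpolation along the angular axis, then refined by a
    modified U-Net operating on the sinogram as a one-channel image with a
    skip from the interpolated input (zero weights give back the plain
    interpolation).
    """

    def __init__(self, rng, n_sparse, n_target, n_detectors, depth=2,
                 base_width=16, n_primitives=16, dtype=np.float64):
        self.n_sparse, self.n_target = n_sparse, n_target
        self.n_detectors = n_detectors
        self._interp = angular_interp_matrix(n_sparse, n_target)
        self.unet = ModifiedUNet(rng, 1, 1, depth=depth, base_width=base_width,
                                 n_primitives=n_primitives, residual=True,
                                 dtype=dtype)
        self._dtype = dtype

    def interpolate(self, x: np.ndarray) -> np.ndarray:
        return np.tensordot(self._interp, x, axes=(1, -2)) if x.ndim == 2 else \
            np.einsum("ts,nsd->ntd", self._interp, x)

    def __call__(self, x) -> Tensor:
        """x: sparse sinogram array (n_sparse, n_det) or batch (N, ...)."""
        xd = np.asarray(x.data if isinstance(x, Tensor) else x)
        if xd.shape[-2] != self.n_sparse:
            raise ValueError(
                f"expected {self.n_sparse} views, got {xd.shape[-2]}")
        batched = xd.ndim == 3
        xi = self.interpolate(xd).astype(self._dtype)
        t = ad.constant(xi if batched else xi[None])
        out = self.unet(t.reshape(t.shape[0], 1, t.shape[1], t.shape[2]))
        return out[:, 0] if batched else out[0, 0]


class IENet(Module):
    """Image-domain enhancement network (residual U-Net)."""

    def __init__(self, rng, depth=2, base_width=16, n_primitives=16,
                 dtype=np.float64):
        self.unet = ModifiedUNet(rng, 1, 1, depth=depth, base_width=base_width,
                                 n_primitives=n_primitives, residual=True,
                                 dtype=dtype)

    def __call__(self, y: Tensor) -> Tensor:
        batched = y.ndim == 3
        y4 = y.reshape(y.shape[0], 1, *y.shape[1:]) if batched \
            else y.reshape(1, 1, *y.shape)
        out = self.unet(y4)
        return out[:, 0] if batched else out[0, 0]


class HENet(Module):
    """Edge-conditioned refinement generator.

    Shares the IENet backbone architecture but takes two input channels
    (the stage-1 image and its Sobel edge map) and predicts a residual on
    the image channel.
    """

    def __init__(self, rng, depth=2, base_width=16, n_primitives=16,
                 dtype=np.float64):
        self.unet = ModifiedUNet(rng, 2, 1, depth=depth, base_width=base_width,
                                 n_primitives=n_primitives, residual=True,
                                 dtype=dtype)

    def __call__(self, yb: Tensor) -> Tensor:
        """yb: (N, 2, H, W) concatenation of image and edge channels."""
        if yb.ndim != 4 or yb.shape[1] != 2:
            raise ValueError("HENet input must be (N, 2, H, W)")
        return self.unet(yb)

    def refine(self, y_prime: np.ndarray, b: np.ndarray) -> np.ndarray:
        if y_prime.shape != b.shape:
            raise ValueError("image/edge shape mismatch")
        yp = np.asarray(y_prime)
        batched = yp.ndim == 3
        if not batched:
            yp, b = yp[None], np.asarray(b)[None]
        yb = np.stack([yp, b], axis=1)
        out = self(ad.constant(yb))[:, 0].data
        return out if batched else out[0]


class Discriminator(Module):
    """Strided convolutional critic producing one unbounded scalar per image.

    Conv stack with LeakyReLU(0.2) and stride 2 on every other layer, then
    global average pooling and a linear head; no normalisation layers so the
    gradient penalty is well-defined.  ``input_grad`` rebuilds the critic's
    gradient w.r.t. its input as an explicit vector-Jacobian chain of
    autodiff ops (activation masks held fixed), which makes the WGAN-GP
    penalty differentiable w.r.t. the critic parameters.
    """

    def __init__(self, rng, input_size, widths=(64, 64, 128, 128, 256, 512),
                 in_channels=1, dtype=np.float64):
        self.input_size = input_size
        self.convs = []
        cin = in_channels
        size = input_size
        self._strides = []
        for i, w in enumerate(widths):
            stride = 2 if i % 2 == 1 else 1
            self.convs.append(Conv2d(rng, cin, w, k=3, stride=stride,
                                     padding=1, dtype=dtype))
            self._strides.append(stride)
            size = size if stride == 1 else (size + 1) // 2
            cin = w
        self.head = Conv2d(rng, cin, 1, k=1, dtype=dtype)  # 1x1 linear head

    def _check(self, y):
        if y.ndim != 4 or y.shape[2] != self.input_size \
                or y.shape[3] != self.input_size:
            raise ValueError(f"critic expects (N, C, {self.input_size}, "
                             f"{self.input_size}), got {y.shape}")

    def __call__(self, y: Tensor) -> Tensor:
        self._check(y)
        f = y
        for conv in self.convs:
            f = ad.leaky_relu(conv(f), 0.2)
        f = self.head(f)                 # (N, 1, h, w)
        return f.mean(axis=(1, 2, 3))    # (N,)

    def input_grad(self, y: Tensor) -> Tensor:
        """Gradient of the summed scores w.r.t. the input, as a Tensor graph."""
        self._check(y)
        acts, masks, shapes = [], [], []
        f = y
        for conv, s in zip(self.convs, self._strides):
            shapes.append(f.shape[2:])
            pre = ad.conv2d(f, conv.w, conv.b, stride=s, padding=1)
            masks.append(np.where(pre.data > 0, 1.0, 0.2).astype(pre.dtype))
            f = ad.leaky_relu(pre, 0.2)
            acts.append(f)
        # d score / d head-output = 1 / (h*w) per element (global average pool)
        g = ad.constant(np.full((f.shape[0], 1, f.shape[2], f.shape[3]),
                                1.0 / (f.shape[2] * f.shape[3]),
                                dtype=f.dtype))
        g = ad.conv2d_transpose(g, self.head.w, stride=1, padding=0,
                                output_size=(f.shape[2], f.shape[3]))
        for conv, s, m, shp in zip(reversed(self.convs),
                                   reversed(self._strides),
                                   reversed(masks), reversed(shapes)):
            g = g * ad.constant(m)
            g = ad.conv2d_transpose(g, conv.w, stride=s, padding=1,
                                    output_size=shp)
        return g


@dataclass
class DualDomainOutput:
    """Intermediate and final products of the stage-1 cascade."""

    x_prime: Tensor    # interpolated+refined sinogram, (n_int, n_det) or batched
    y_mid: Tensor      # FBP of x_prime
    y_prime: Tensor    # IENet output


class DualDomainModel(Module):
    """SINet -> FBP -> IENet with end-to-end gradient flow."""

    def __init__(self, sinet: SINet, ienet: IENet, projector: FanBeamProjector):
        self.sinet = sinet
        self.ienet = ienet
        self.projector = projector
        if len(projector.view_angles) != sinet.n_target:
            raise ValueError("projector view count must match SINet target")

    def _fbp_t(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            return self.projector.fbp_t(x)

        def fwd(batch):
            return np.stack([self.projector.fbp(s) for s in batch])

        def adj(gs):
            return np.stack([self.projector.fbp_adjoint(i) for i in gs])

        return ad.linear_op(x, fwd, adj)

    def __call__(self, x) -> DualDomainOutput:
        x_prime = self.sinet(x)
        y_mid = self._fbp_t(x_prime)
        y_prime = self.ienet(y_mid)
        return DualDomainOutput(x_prime, y_mid, y_prime)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Inference path returning the stage-1 image as an ndarray."""
        return self(np.asarray(x)).y_prime.data
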