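"""Global-Local Fusion Segmentation Network (GLFS-Net).

Per-instance mask prediction for overlapping structures.  The network takes
two same-size inputs — the whole image (global branch) and the same image
with everything outside the instance's oriented box zeroed (local branch) —
through a *shared-weight* encoder with atrous spatial pyramid pooling.  The
global features pass a squeeze-and-excitation gate:

    Z_G[c]   = mean over H x W of channel c          (squeeze)
    S_G      = sigmoid(FC2(relu(FC1(Z_G))))          (excite, gates in (0,1))
    X~_G     = S_G * X_G                             (channel-wise rescale)

and are fused with the local features by element-wise addition followed by a
1x1 convolution.  A DeepLabv3+-style decoder concatenates channel-reduced
stride-4 low-level features with the 4x-upsampled fused features, refines
with two 3x3 convolutions and upsamples 4x again, producing per-pixel
foreground logits at the input resolution.  Because each instance is
segmented independently, masks of overlapping instances may both claim the
shared pixels — the behaviour a single-label semantic head cannot express.

Training combines the decoder loss with an auxiliary pixel head on the
fused stride-16 features: L = a1 * L_decode + a2 * L_aux, defaults
a1 = 1, a2 = 0.4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import OrientedBox, rasterize_obb
from .nn import functional as F
from .nn.autograd import Tensor


@dataclass
class GLFSConfig:
    in_channels: int = 3
    base_channels: int = 8          # encoder width; doubles at stride 4 and 16
    aspp_channels: int = 16
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    se_reduction: int = 16
    low_level_channels: int = 8     # after the decoder's 1x1 reduction
    decoder_channels: int = 16
    loss_alpha1: float = 1.0
    loss_alpha2: float = 0.4
    threshold: float = 0.5
    local_fill: str = "zero"        # or "mean"


def build_local_image(image: np.ndarray, obb: OrientedBox,
                      fill: str = "zero") -> np.ndarray:
    """Zero (or mean-fill) everything outside the instance's oriented box.

    The output has the same dimensions as the input; pixels inside the
    rotated rectangle keep their original values.
    """
    image = np.asarray(image)
    region = rasterize_obb(obb, image.shape[:2])
    if not region.any():
        warnings.warn("oriented box lies fully outside the image; "
                      "local image is empty", stacklevel=2)
    bg = float(image.mean()) if fill == "mean" else 0.0
    out = np.full_like(image, bg)
    if image.ndim == 3:
        out[region, :] = image[region, :]
    else:
        out[region] = image[region]
    return out


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling with image-level pooling branch."""

    def __init__(self, cin: int, cout: int, rates: tuple[int, ...], rng):
        self.conv1 = nn.Conv2d(cin, cout, k=1, rng=rng)
        self.branches = [nn.Conv2d(cin, cout, k=3, dilation=r, rng=rng)
                         for r in rates]
        self.pool_conv = nn.Conv2d(cin, cout, k=1, rng=rng)
        self.project = nn.Conv2d(cout * (2 + len(rates)), cout, k=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        outs = [self.conv1(x).relu()]
        outs += [b(x).relu() for b in self.branches]
        pooled = F.global_avg_pool(x).reshape(n, c, 1, 1)
        pooled = self.pool_conv(pooled).relu()
        ones = Tensor(np.ones((1, 1, h, w), dtype=x.data.dtype))
        outs.append(pooled * ones)  # broadcast the image-level context
        return self.project(nn.concat(outs, axis=1)).relu()


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate; gates strictly in (0, 1)."""

    def __init__(self, channels: int, reduction: int, rng):
        hidden = max(channels // reduction, 2)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        z = F.global_avg_pool(x)                 # (N, C) squeeze
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        s = self.gates(x)
        n, c = s.shape
        return s, x * s.reshape(n, c, 1, 1)


class Encoder(nn.Module):
    """Shared-weight encoder: strides 2-4-8-16, low-level taken at stride 4."""

    def __init__(self, cfg: GLFSConfig, rng):
        c = cfg.base_channels
        self.stem = nn.ConvBlock(cfg.in_channels, c, stride=2, rng=rng)
        self.stage2 = nn.ConvBlock(c, 2 * c, stride=2, rng=rng)     # stride 4
        self.stage3 = nn.ConvBlock(2 * c, 2 * c, stride=2, rng=rng)  # stride 8
        self.stage4 = nn.ConvBlock(2 * c, 4 * c, stride=2, rng=rng)  # stride 16
        self.low_channels = 2 * c
        self.out_channels = 4 * c

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x = self.stem(x)
        low = self.stage2(x)
        x = self.stage3(low)
        x = self.stage4(x)
        return x, low


class GLFSNet(nn.Module):
    """Bilateral global/local network with SE-gated fusion and mask decoder."""

    def __init__(self, cfg: GLFSConfig | None = None, seed: int = 0):
        self.cfg = cfg or GLFSConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg
        self.encoder = Encoder(c, rng)
        self.aspp = ASPP(self.encoder.out_channels, c.aspp_channels,
                         c.aspp_rates, rng)
        self.se = SEBlock(c.aspp_channels, c.se_reduction, rng)
        self.fuse_conv = nn.Conv2d(c.aspp_channels, c.decoder_channels, k=1,
                                   rng=rng)
        self.low_reduce = nn.Conv2d(self.encoder.low_channels,
                                    c.low_level_channels, k=1, rng=rng)
        self.refine1 = nn.ConvBlock(c.decoder_channels + c.low_level_channels,
                                    c.decoder_channels, rng=rng)
        self.refine2 = nn.ConvBlock(c.decoder_channels, c.decoder_channels,
                                    rng=rng)
        self.head = nn.Conv2d(c.decoder_channels, 1, k=1, rng=rng)
        self.aux_head = nn.Conv2d(c.decoder_channels, 1, k=1, rng=rng)

    # -- pieces (exposed for tests and composition) ----------------------
    def prep(self, img: np.ndarray) -> Tensor:
        """(H, W) or (H, W, 3) float image -> (1, C, H, W) Tensor."""
        img = np.asarray(img, dtype=np.float32)
        if img.ndim == 2:
            img = np.repeat(img[None], self.cfg.in_channels, axis=0)
        else:
            img = img.transpose(2, 0, 1)
        h, w = img.shape[1:]
        if h % 16 or w % 16:
            raise ValueError(f"input sides must be divisible by 16, got {h}x{w}")
        return Tensor(img[None])

    def encode_bilateral(self, global_t: Tensor, local_t: Tensor):
        """Shared weights applied to both inputs; ASPP per branch."""
        if global_t.shape != local_t.shape:
            raise ValueError("global/local inputs must have the same shape")
        eg, low = self.encoder(global_t)
        el, _ = self.encoder(local_t)
        return self.aspp(eg), self.aspp(el), low

    def fuse(self, xg_gated: Tensor, xl: Tensor) -> Tensor:
        """Element-wise addition of the branches, then a 1x1 convolution."""
        if xg_gated.shape != xl.shape:
            raise ValueError("branch features must have the same shape")
        return self.fuse_conv(xg_gated + xl)

    def decode(self, high: Tensor, low: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (decoder logits at input resolution, aux logits at s16)."""
        aux = self.aux_head(high)
        up = F.upsample_bilinear(high, 4)
        lowr = self.low_reduce(low)
        x = nn.concat([up, lowr], axis=1)
        x = self.refine2(self.refine1(x))
        logits = self.head(x)
        return F.upsample_bilinear(logits, 4), aux

    def forward(self, global_img: np.ndarray, local_img: np.ndarray):
        xg, xl, low = self.encode_bilateral(self.prep(global_img),
                                            self.prep(local_img))
        s, xg_t = self.se(xg)
        fused = self.fuse(xg_t, xl)
        logits, aux = self.decode(fused, low)
        return logits, aux, s

    # -- losses & inference ----------------------------------------------
    def loss(self, logits: Tensor, aux: Tensor, target: np.ndarray) -> Tensor:
        """L = a1 * decoder BCE + a2 * auxiliary BCE.

        The auxiliary head is supervised at its native stride 16 against the
        block-center subsample of the target, so exact predictions drive
        both terms to zero.
        """
        t = np.asarray(target, dtype=np.float32)[None, None]
        main = F.bce_with_logits(logits, t)
        t16 = t[:, :, 8::16, 8::16]
        aux_l = F.bce_with_logits(aux, t16)
        return main * self.cfg.loss_alpha1 + aux_l * self.cfg.loss_alpha2

    def predict_mask(self, global_img: np.ndarray,
                     local_img: np.ndarray) -> np.ndarray:
        logits, _, _ = self.forward(global_img, local_img)
        prob = 1.0 / (1.0 + np.exp(-logits.data[0, 0]))
        return prob >= self.cfg.threshold


def segment_instance(image: np.ndarray, det, model: GLFSNet) -> np.ndarray:
    """Full-resolution binary mask for one detection (category on the det)."""
    local = build_local_image(image, det.box, fill=model.cfg.local_fill)
    return model.predict_mask(image, local)


def train_instances(model: GLFSNet, triples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                    iters: int = 300, lr: float = 1e-2, momentum: float = 0.9,
                    weight_decay: float = 5e-4, optimizer: str = "sgd",
                    poly_power: float = 0.9, min_lr: float = 1e-4,
                    seed: int = 0, log_every: int = 0) -> list[float]:
    """Per-instance training on (global, local, target-mask) triples.

    SGD with momentum 0.9, weight decay 5e-4 and polynomial learning-rate
    decay (power 0.9) are the defaults; Adam is available for fast
    desk-scale overfitting.  Returns the per-iteration loss history.
    """
    if optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=lr, momentum=momentum,
                     weight_decay=weight_decay)
    else:
        opt = nn.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    history = []
    for it in range(iters):
        g, l, t = triples[int(rng.integers(len(triples)))]
        opt.zero_grad()
        logits, aux, _ = model.forward(g, l)
        loss = model.loss(logits, aux, t)
        loss.backward()
        opt.lr = nn.poly_decay(lr, it, iters, poly_power, min_lr)
        opt.step()
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(f"segmentation loss diverged at iteration {it}")
        history.append(val)
        if log_every and it % log_every == 0:
            avg = float(np.mean(history[-log_every:]))
            print(f"[glfs] iter {it:4d} loss {avg:.4f}")
    return history
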