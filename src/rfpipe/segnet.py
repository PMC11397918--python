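"""2D encoder-decoder networks (U-Net and Attention U-Net) for liver-ROI
segmentation of B-mode images, with training and full-resolution mask
recovery.

Each encoder level is (3x3 conv + batch norm + ReLU) x 2 followed by 2x2
max pooling; the decoder up-samples with 2x2 transpose convolutions and
concatenates skip features, which the attention variant first gates with an
additive attention block (1x1 mappings of gating and skip features, ReLU,
1x1 conv + sigmoid, multiplicative gating).  The head is a 1x1 convolution
to a single sigmoid logit map, trained with binary cross-entropy and Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .bmode import BModeImage, resize_image, resize_mask

SIGNAL_SHAPE = (1247, 256)


@dataclass(frozen=True)
class SegConfig:
    arch: str = "unet"                      # "unet" | "attention_unet"
    in_channels: int = 3
    input_shape: tuple[int, int] = (192, 256)   # height x width
    encoder_widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    batch_size: int = 2
    epochs: int = 100
    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ("unet", "attention_unet"):
            raise ValueError(f"unknown arch {self.arch!r}")
        w = self.encoder_widths
        if any(a >= b for a, b in zip(w, w[1:])):
            raise ValueError("encoder widths must strictly increase")
        depth = len(w) - 1
        if any(s % (2 ** depth) for s in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by 2^{depth}")


@dataclass
class LiverMask:
    pixels: np.ndarray
    source_frame_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("mask values must be binary")
        self.pixels = self.pixels.astype(np.uint8)


# ---------------------------------------------------------------------------
# Network blocks
# ---------------------------------------------------------------------------

class DoubleConv(nn.Module):
    """(conv3x3 + batch norm + ReLU) twice."""

    def __init__(self, c_in, c_out, rng, input_grad=True):
        self.block = nn.Sequential(
            nn.Conv2d(c_in, c_out, 3, rng, input_grad=input_grad),
            nn.BatchNorm2d(c_out), nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, rng), nn.BatchNorm2d(c_out), nn.ReLU())

    def params(self):
        return self.block.params()

    def modules(self):
        yield self
        yield from self.block.modules()

    def forward(self, x, train=True):
        return self.block.forward(x, train=train)

    def backward(self, grad):
        return self.block.backward(grad)


class AttentionGate(nn.Module):
    """Additive attention over a skip tensor, gated by a decoder feature of
    the same spatial size: alpha = sigmoid(psi(relu(Wg g + Wx x)))."""

    def __init__(self, channels, rng, inter: int | None = None):
        inter = inter or max(1, channels // 2)
        self.Wg = nn.Conv2d(channels, inter, 1, rng)
        self.Wx = nn.Conv2d(channels, inter, 1, rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng)
        self.relu = nn.ReLU()
        self.sig = nn.Sigmoid()

    def params(self):
        return self.Wg.params() + self.Wx.params() + self.psi.params()

    def modules(self):
        yield self
        yield from self.Wg.modules()
        yield from self.Wx.modules()
        yield from self.psi.modules()

    def forward(self, x, g, train=True):
        q = self.relu.forward(self.Wg.forward(g, train) + self.Wx.forward(x, train))
        self._alpha = self.sig.forward(self.psi.forward(q, train))
        self._x = x
        return x * self._alpha

    def backward(self, grad):
        dx_gate = grad * self._alpha
        dalpha = (grad * self._x).sum(axis=1, keepdims=True)
        dq = self.psi.backward(self.sig.backward(dalpha))
        ds = self.relu.backward(dq)
        dg = self.Wg.backward(ds)
        dx = dx_gate + self.Wx.backward(ds)
        return dx, dg

    def coefficients(self) -> np.ndarray:
        """Attention map from the most recent forward pass."""
        return self._alpha


class UNet(nn.Module):
    """U-Net / Attention U-Net over (B, C, H, W) tensors; sigmoid-logit head."""

    def __init__(self, cfg: SegConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.encoder_widths
        self.depth = len(w) - 1
        self.attention = cfg.arch == "attention_unet"
        self.enc = []
        c = cfg.in_channels
        for lvl, wi in enumerate(w[:-1]):
            self.enc.append(DoubleConv(c, wi, rng, input_grad=lvl > 0))
            c = wi
        self.pools = [nn.MaxPool2d(2) for _ in range(self.depth)]
        self.bottleneck = DoubleConv(w[-2], w[-1], rng)
        self.ups, self.gates, self.dec = [], [], []
        for i in reversed(range(self.depth)):
            self.ups.append(nn.ConvTranspose2d(w[i + 1], w[i], rng))
            self.gates.append(AttentionGate(w[i], rng) if self.attention else None)
            self.dec.append(DoubleConv(2 * w[i], w[i], rng))
        self.head = nn.Conv2d(w[0], 1, 1, rng)

    def params(self):
        out = []
        for blk in self.enc:
            out.extend(blk.params())
        out.extend(self.bottleneck.params())
        for up, gate, dec in zip(self.ups, self.gates, self.dec):
            out.extend(up.params())
            if gate is not None:
                out.extend(gate.params())
            out.extend(dec.params())
        out.extend(self.head.params())
        return out

    def modules(self):
        yield self
        for blk in self.enc:
            yield from blk.modules()
        for pool in self.pools:
            yield from pool.modules()
        yield from self.bottleneck.modules()
        for up, gate, dec in zip(self.ups, self.gates, self.dec):
            yield from up.modules()
            if gate is not None:
                yield from gate.modules()
            yield from dec.modules()
        yield from self.head.modules()

    def forward(self, x, train=True):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels}-channel input, got {x.shape}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, gate, dec, skip in zip(self.ups, self.gates, self.dec,
                                       reversed(skips)):
            g = up.forward(x, train)
            s = skip if gate is None else gate.forward(skip, g, train)
            x = dec.forward(np.concatenate([s, g], axis=1), train)
            self._skip_channels.append(s.shape[1])
        return self.head.forward(x, train)

    def backward(self, grad):
        grad = self.head.backward(grad)
        dskips = []
        # walk decoder levels back from the head (finest, last list entry)
        # to the bottleneck (coarsest, first list entry)
        for i in reversed(range(self.depth)):
            up, gate, dec = self.ups[i], self.gates[i], self.dec[i]
            cs = self._skip_channels[i]
            d = dec.backward(grad)
            ds, dg = d[:, :cs], d[:, cs:]
            if gate is not None:
                ds, dg_extra = gate.backward(ds)
                dg = dg + dg_extra
            dskips.append(ds)
            grad = up.backward(dg)
        grad = self.bottleneck.backward(grad)
        # dskips were collected finest-first; the encoder unwinds coarsest-first
        for blk, pool, ds in zip(reversed(self.enc), reversed(self.pools),
                                 reversed(dskips)):
            grad = pool.backward(grad) + ds
            grad = blk.backward(grad)
        return grad


def build_segnet(cfg: SegConfig) -> UNet:
    """Build a (seeded) U-Net or Attention U-Net from its configuration."""
    return UNet(cfg)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _to_batch(images: np.ndarray, in_channels: int) -> np.ndarray:
    """(N, H, W) grayscale stack -> (N, C, H, W) with replicated channels."""
    x = np.asarray(images, dtype=nn.DTYPE)
    if x.ndim != 3:
        raise ValueError("expected a (N, H, W) image stack")
    return np.repeat(x[:, None], in_channels, axis=1)


def _epoch_loss(net: UNet, images, masks, batch_size) -> float:
    total, n = 0.0, 0
    for i in range(0, len(images), batch_size):
        xb = _to_batch(images[i:i + batch_size], net.cfg.in_channels)
        yb = np.asarray(masks[i:i + batch_size], dtype=nn.DTYPE)[:, None]
        logits = net.forward(xb, train=False)
        loss, _ = nn.bce_with_logits(logits, yb)
        total += loss * xb.shape[0]
        n += xb.shape[0]
    return total / n


def train_segnet(net: UNet, train_images, train_masks,
                 val_images=None, val_masks=None,
                 cfg: SegConfig | None = None, verbose: bool = False):
    """Train with Adam on binary cross-entropy; keeps the parameters of the
    epoch with the best validation loss (training loss if no validation
    set).  Returns (net, history DataFrame)."""
    cfg = cfg or net.cfg
    if len(train_images) == 0:
        raise ValueError("empty training set")
    if len(train_images) != len(train_masks):
        raise ValueError("images and masks must pair up")
    opt = nn.Adam(net.params(), lr=cfg.lr, betas=cfg.betas)
    rng = np.random.default_rng(cfg.seed + 1)
    train_images = np.asarray(train_images, dtype=nn.DTYPE)
    train_masks = np.asarray(train_masks, dtype=nn.DTYPE)
    history = []
    best_loss, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_images))
        ep_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = _to_batch(train_images[idx], cfg.in_channels)
            yb = train_masks[idx][:, None]
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.bce_with_logits(logits, yb)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        train_loss = ep_loss / n_seen
        if val_images is not None and len(val_images):
            val_loss = _epoch_loss(net, np.asarray(val_images, dtype=nn.DTYPE),
                                   np.asarray(val_masks, dtype=nn.DTYPE),
                                   cfg.batch_size)
        else:
            val_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_state = val_loss, net.get_state()
        if verbose:
            print(f"epoch {epoch:3d} train {train_loss:.4f} val {val_loss:.4f}")
    if best_state is not None:
        net.set_state(best_state)
    # small batches make the EMA batch-norm statistics noisy; replace them
    # with exact pooled statistics of the training set under the kept weights
    nn.recalibrate_batchnorm(net, (
        _to_batch(train_images[i:i + cfg.batch_size], cfg.in_channels)
        for i in range(0, len(train_images), cfg.batch_size)))
    return net, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def segment(net: UNet, image: BModeImage | np.ndarray,
            threshold: float = 0.5) -> LiverMask:
    """Predict a binary liver mask in network space (input_shape)."""
    pixels = image.pixels if isinstance(image, BModeImage) else np.asarray(image)
    fid = image.source_frame_id if isinstance(image, BModeImage) else ""
    if pixels.shape != net.cfg.input_shape:
        pixels = resize_image(pixels, net.cfg.input_shape)
    x = _to_batch(pixels[None], net.cfg.in_channels)
    probs = nn.sigmoid(net.forward(x, train=False))[0, 0]
    return LiverMask(pixels=(probs > threshold).astype(np.uint8),
                     source_frame_id=fid)


def threshold_mask(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map at the decision threshold."""
    return (np.asarray(probs) > threshold).astype(np.uint8)


def clean_mask(mask: LiverMask | np.ndarray,
               closing_size: int = 5) -> LiverMask:
    """Morphological cleanup of a predicted mask: binary closing, hole
    filling, then keep the largest connected component.  Small-speckle
    holes in an otherwise solid liver band would otherwise break the
    contiguous runs the axial gating relies on."""
    from scipy import ndimage

    pixels = mask.pixels if isinstance(mask, LiverMask) else np.asarray(mask)
    fid = mask.source_frame_id if isinstance(mask, LiverMask) else ""
    m = pixels.astype(bool)
    if closing_size > 1:
        m = ndimage.binary_closing(m, np.ones((closing_size, closing_size)))
    m = ndimage.binary_fill_holes(m)
    labels, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    return LiverMask(pixels=m.astype(np.uint8), source_frame_id=fid)


def resize_mask_to_signal(mask: LiverMask | np.ndarray,
                          out_shape: tuple[int, int] = SIGNAL_SHAPE) -> LiverMask:
    """Bicubic resize of a network-space mask back to the RF signal grid,
    re-binarized at 0.5."""
    pixels = mask.pixels if isinstance(mask, LiverMask) else np.asarray(mask)
    fid = mask.source_frame_id if isinstance(mask, LiverMask) else ""
    return LiverMask(pixels=resize_mask(pixels, out_shape),
                     source_frame_id=fid)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: UNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.get_state()
    np.savez(path, *state)
    cfg = asdict(net.cfg)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))
    return path


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    cfg_d = json.loads(path.with_suffix(".json").read_text())
    for k in ("input_shape", "encoder_widths", "betas"):
        cfg_d[k] = tuple(cfg_d[k])
    net = build_segnet(SegConfig(**cfg_d))
    with np.load(path) as z:
        net.set_state([z[f"arr_{i}"] for i in range(len(z.files))])
    return net
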