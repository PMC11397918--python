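"""B-mode image reconstruction, dataset splitting, and image augmentation.

B-mode images are reconstructed on the raw sample-by-line grid (no scan
conversion): Hilbert-transform envelope detection per scan line followed by
logarithmic compression to a fixed dynamic range (default 40 dB), mapping
the frame maximum to 1 and the floor to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from skimage.transform import resize as _sk_resize

from .sim import RFFrame


@dataclass
class BModeImage:
    pixels: np.ndarray           # 2D, values in [0, 1]
    dynamic_range_db: float = 40.0
    source_frame_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("B-mode pixels must be 2D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("B-mode pixels must lie in [0, 1]")


@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    ratios: tuple[float, float, float]

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if (parts[0] & parts[1]) or (parts[0] & parts[2]) or (parts[1] & parts[2]):
            raise ValueError("split parts must be disjoint")


# ---------------------------------------------------------------------------
# Envelope detection and log compression
# ---------------------------------------------------------------------------

def envelope(rf_line: np.ndarray) -> np.ndarray:
    """Envelope of one scan line: magnitude of its analytic signal."""
    rf_line = np.asarray(rf_line, dtype=np.float64)
    if rf_line.ndim != 1 or rf_line.size < 2:
        raise ValueError("rf_line must be 1D with length >= 2")
    if not np.all(np.isfinite(rf_line)):
        raise ValueError("rf_line must be finite")
    return np.abs(hilbert(rf_line))


def envelope_frame(rf: np.ndarray | RFFrame) -> np.ndarray:
    """Per-line envelope of a whole frame (axial x lateral)."""
    samples = rf.samples if isinstance(rf, RFFrame) else np.asarray(rf, float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("RF samples must be finite")
    return np.abs(hilbert(samples, axis=0))


def log_compress(env: np.ndarray, dynamic_range_db: float = 40.0,
                 source_frame_id: str = "") -> BModeImage:
    """Log-compress an envelope image to [0, 1].

    pixel = clip((20*log10(env / env_max) + DR) / DR, 0, 1): the frame
    maximum maps to 1 and envelopes DR decibels below it map to 0.
    """
    env = np.asarray(env, dtype=np.float64)
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be > 0")
    env_max = env.max() if env.size else 0.0
    if env_max <= 0:
        raise ValueError("all-zero envelope: no reference maximum")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / env_max)
    pixels = np.clip((db + dynamic_range_db) / dynamic_range_db, 0.0, 1.0)
    return BModeImage(pixels=pixels, dynamic_range_db=dynamic_range_db,
                      source_frame_id=source_frame_id)


def reconstruct_bmode(frame: RFFrame, dynamic_range_db: float = 40.0) -> BModeImage:
    """Hilbert envelope detection + log compression for one RF frame."""
    return log_compress(envelope_frame(frame), dynamic_range_db,
                        source_frame_id=frame.frame_id)


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def split_dataset(ids: list, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Shuffle ids and split train/val/test.

    Train and validation get floor(ratio * N); the remainder goes to test
    (613 ids at 60:20:20 -> 367/122/124).  Ids are participant identifiers,
    so the split is participant-level by construction.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    train, val, test = (perm[:n_train], perm[n_train:n_train + n_val],
                        perm[n_train + n_val:])
    if not (train and val and test):
        raise ValueError(f"split of {n} ids at {ratios} leaves an empty part")
    return DatasetSplit(train, val, test, tuple(ratios))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def rotate90(img: np.ndarray, k: int) -> np.ndarray:
    """Rotate by k*90 degrees; non-square results are resized back to the
    input shape so batches stay rectangular."""
    out = np.rot90(img, k)
    if out.shape != img.shape:
        out = resize_image(out, img.shape)
    return out


def _jitter(img: np.ndarray, rng: np.random.Generator,
            amount: float = 0.1) -> np.ndarray:
    """Brightness/contrast (and saturation, for 3-channel input) jitter of
    +-``amount``; output clipped back to [0, 1]."""
    out = img.astype(np.float64)
    out = out * (1.0 + rng.uniform(-amount, amount))            # brightness
    mean = out.mean()
    out = (out - mean) * (1.0 + rng.uniform(-amount, amount)) + mean  # contrast
    if out.ndim == 3 and out.shape[-1] == 3:                    # saturation
        gray = out.mean(axis=-1, keepdims=True)
        out = gray + (out - gray) * (1.0 + rng.uniform(-amount, amount))
    return np.clip(out, 0.0, 1.0)


def _random_crop_resize(img: np.ndarray, mask: np.ndarray,
                        rng: np.random.Generator):
    """Crop a uniformly chosen 80-100% area window and resize back."""
    h, w = img.shape[:2]
    frac = np.sqrt(rng.uniform(0.8, 1.0))
    ch, cw = max(1, int(round(frac * h))), max(1, int(round(frac * w)))
    r0 = rng.integers(0, h - ch + 1)
    c0 = rng.integers(0, w - cw + 1)
    img_c = resize_image(img[r0:r0 + ch, c0:c0 + cw], (h, w))
    mask_c = resize_mask(mask[r0:r0 + ch, c0:c0 + cw], (h, w))
    return img_c, mask_c


def augment_images(images: list[np.ndarray], masks: list[np.ndarray],
                   seed: int = 0, jitter: float = 0.1):
    """Append exactly one augmented copy per image/mask pair (doubling the
    lists): random 0/90/180/270 rotation and random crop-and-resize applied
    identically to image and mask, photometric jitter to the image only."""
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    rng = np.random.default_rng(seed)
    out_imgs, out_masks = list(images), list(masks)
    for img, mask in zip(images, masks):
        img = np.asarray(img, dtype=np.float64)
        mask = np.asarray(mask)
        if img.shape[:2] != mask.shape[:2]:
            raise ValueError(f"image/mask shape mismatch: {img.shape} vs {mask.shape}")
        k = int(rng.integers(0, 4))
        a_img, a_mask = rotate90(img, k), rotate90_mask(mask, k)
        a_img, a_mask = _random_crop_resize(a_img, a_mask, rng)
        a_img = _jitter(a_img, rng, jitter)
        out_imgs.append(a_img)
        out_masks.append(a_mask)
    return out_imgs, out_masks


def rotate90_mask(mask: np.ndarray, k: int) -> np.ndarray:
    out = np.rot90(mask, k)
    if out.shape != mask.shape:
        out = resize_mask(out, mask.shape)
    return out


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------

def resize_image(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic resize (order-3 spline); a constant image stays constant."""
    out_shape = tuple(int(s) for s in out_shape)
    if any(s <= 0 for s in out_shape):
        raise ValueError(f"out_shape must be positive, got {out_shape}")
    if tuple(img.shape[:2]) == out_shape:
        return np.array(img, dtype=np.float64, copy=True)
    return _sk_resize(np.asarray(img, dtype=np.float64), out_shape, order=3,
                      mode="edge", anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, out_shape: tuple[int, int],
                threshold: float = 0.5) -> np.ndarray:
    """Bicubic resize of a binary mask followed by re-binarization."""
    res = resize_image(np.asarray(mask, dtype=np.float64), out_shape)
    return (res >= threshold).astype(np.uint8)
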