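"""1D CNN fibrosis-stage classifier on gated ROI spectrum lines, with
whole-frame vote aggregation.

Each 768-point line of a gated sample is an independent training instance
carrying the sample's binary label.  The network is four (1D convolution +
tanh + max pool) stages followed by four fully-connected layers (tanh on
hidden layers, 2 logits out), trained with cross-entropy and Adam.  At test
time the 256 per-line predictions of a frame are tallied: the frame counts
as correctly classified only when the fraction of agreeing lines strictly
exceeds 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .roispec import GatedSample, GATE_LEN, WINDOW_LINES


@dataclass(frozen=True)
class ClfConfig:
    conv_channels: tuple[int, int, int, int] = (8, 16, 32, 32)
    kernel_sizes: tuple[int, int, int, int] = (7, 5, 5, 3)
    pool_sizes: tuple[int, int, int, int] = (2, 2, 2, 2)
    fc_widths: tuple[int, int, int, int] = (256, 64, 16, 2)
    input_len: int = GATE_LEN
    batch_size: int = 256
    epochs: int = 100
    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        for name, v in (("conv_channels", self.conv_channels),
                        ("kernel_sizes", self.kernel_sizes),
                        ("pool_sizes", self.pool_sizes),
                        ("fc_widths", self.fc_widths)):
            if len(v) != 4:
                raise ValueError(f"{name} must have exactly 4 entries")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")
        if self.fc_widths[-1] != 2:
            raise ValueError("final fully-connected width must be 2 classes")
        L = self.input_len
        for p in self.pool_sizes:
            if L % p:
                raise ValueError(f"pooled length {L} not divisible by {p}")
            L //= p
            if L == 0:
                raise ValueError("pooled length reaches 0")

    @property
    def flat_len(self) -> int:
        L = self.input_len
        for p in self.pool_sizes:
            L //= p
        return L * self.conv_channels[-1]


@dataclass
class FramePrediction:
    """Per-frame vote tally of the 256 line predictions against the label."""

    n_correct: int
    n_wrong: int
    p: float                 # n_correct / (n_correct + n_wrong)
    frame_correct: bool      # p > 0.5, strictly
    predicted_class: int
    score: float = np.nan    # mean positive-class probability over lines
    source_frame_id: str = ""
    true_label: int = -1


def build_clf(cfg: ClfConfig) -> nn.Sequential:
    """Build the seeded 1D CNN: conv(tanh)+pool x 4, flatten, fc x 4."""
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Module] = []
    c = 1
    for i, (ch, k, p) in enumerate(zip(cfg.conv_channels, cfg.kernel_sizes,
                                       cfg.pool_sizes)):
        layers += [nn.Conv1d(c, ch, k, rng, input_grad=i > 0),
                   nn.Tanh(), nn.MaxPool1d(p)]
        c = ch
    layers.append(nn.Flatten())
    w_in = cfg.flat_len
    for i, w in enumerate(cfg.fc_widths):
        layers.append(nn.Linear(w_in, w, rng))
        if i < len(cfg.fc_widths) - 1:
            layers.append(nn.Tanh())
        w_in = w
    return nn.Sequential(*layers)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _lines_and_labels(samples: list[GatedSample]):
    """Flatten gated samples into per-line instances: (n*256, 1, 768)."""
    x = np.stack([s.values for s in samples]).astype(nn.DTYPE)  # (n, 768, 256)
    x = x.transpose(0, 2, 1).reshape(-1, x.shape[1])[:, :, None]  # lines as rows
    y = np.repeat(np.array([s.label for s in samples], dtype=np.int64),
                  WINDOW_LINES)
    return x, y


def _eval_loss(net, x, y, batch_size):
    total = 0.0
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        loss, _, _ = nn.softmax_cross_entropy(logits, y[i:i + batch_size])
        total += loss * len(logits)
    return total / len(x)


def train_clf(net: nn.Sequential, train_samples: list[GatedSample],
              val_samples: list[GatedSample] | None = None,
              cfg: ClfConfig | None = None, verbose: bool = False):
    """Train on individual lines with Adam/cross-entropy; the parameters of
    the epoch with the best validation loss are retained.  Returns
    (net, history DataFrame)."""
    cfg = cfg or ClfConfig()
    if not train_samples:
        raise ValueError("empty training set")
    labels = {s.label for s in train_samples}
    if len(labels) < 2:
        raise ValueError(f"single-class training data (labels {labels})")
    x, y = _lines_and_labels(train_samples)
    xv = yv = None
    if val_samples:
        xv, yv = _lines_and_labels(val_samples)
    opt = nn.Adam(net.params(), lr=cfg.lr, betas=cfg.betas)
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    best_loss, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        ep_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = net.forward(x[idx], train=True)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
        train_loss = ep_loss / len(x)
        val_loss = (_eval_loss(net, xv, yv, cfg.batch_size)
                    if xv is not None else train_loss)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_state = val_loss, net.get_state()
        if verbose:
            print(f"epoch {epoch:3d} train {train_loss:.4f} val {val_loss:.4f}")
    if best_state is not None:
        net.set_state(best_state)
    return net, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Prediction and frame aggregation
# ---------------------------------------------------------------------------

def _line_probs(net, sample: GatedSample, batch_size: int = 256) -> np.ndarray:
    """(256, 2) class probabilities, one row per line of the gated frame."""
    x = sample.values.T[:, :, None].astype(nn.DTYPE)  # (256, 768, 1)
    probs = []
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        _, _, p = nn.softmax_cross_entropy(logits, np.zeros(len(logits), dtype=int))
        probs.append(p)
    return np.concatenate(probs)


def predict_frame(net, sample: GatedSample, true_label: int | None = None,
                  batch_size: int = 256) -> FramePrediction:
    """Tally the 256 per-line argmax predictions against the frame label.

    The frame counts correct only when p = n_c/(n_c + n_w) strictly exceeds
    0.5; at an exact tie the predicted class is the one opposite the true
    label, so a tied frame is counted incorrect.
    """
    if true_label is None:
        true_label = sample.label
    probs = _line_probs(net, sample, batch_size)
    pred = probs.argmax(axis=1)
    n_c = int((pred == true_label).sum())
    n_w = int(len(pred) - n_c)
    p = n_c / (n_c + n_w)
    votes = np.bincount(pred, minlength=2)
    if votes[0] == votes[1]:
        predicted = 1 - true_label
    else:
        predicted = int(votes.argmax())
    return FramePrediction(n_correct=n_c, n_wrong=n_w, p=p,
                           frame_correct=p > 0.5, predicted_class=predicted,
                           score=float(probs[:, 1].mean()),
                           source_frame_id=sample.source_frame_id,
                           true_label=int(true_label))


def score_frames(net, samples: list[GatedSample],
                 batch_size: int = 256) -> np.ndarray:
    """Continuous per-frame score for ROC analysis: the mean positive-class
    probability over the frame's 256 lines."""
    return np.array([float(_line_probs(net, s, batch_size)[:, 1].mean())
                     for s in samples])


def predictions_table(preds: list[FramePrediction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "frame_id": p.source_frame_id, "true_label": p.true_label,
        "predicted_class": p.predicted_class, "n_correct": p.n_correct,
        "n_wrong": p.n_wrong, "p": p.p, "score": p.score,
        "frame_correct": p.frame_correct} for p in preds])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: nn.Sequential, cfg: ClfConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, *net.get_state())
    path.with_suffix(".json").write_text(json.dumps(asdict(cfg), indent=2))
    return path


def load_checkpoint(path: str | Path):
    path = Path(path)
    cfg_d = json.loads(path.with_suffix(".json").read_text())
    for k in ("conv_channels", "kernel_sizes", "pool_sizes", "fc_widths", "betas"):
        cfg_d[k] = tuple(cfg_d[k])
    cfg = ClfConfig(**cfg_d)
    net = build_clf(cfg)
    with np.load(path) as z:
        net.set_state([z[f"arr_{i}"] for i in range(len(z.files))])
    return net, cfg
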