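"""ROI spectrum signals: masking, normalization, and the sliding-gate /
sliding-window augmentation with class balancing.

A spectrum frame is multiplied elementwise by the (resized, binary) liver
ROI mask, min-max normalized over the whole frame, and then cut into gated
samples: per eligible scan line a 768-point gate slides down the liver run
in steps of 20 points; the gated columns are concatenated laterally and a
768 x 256 window slides across them to emit classifier input frames.

Note the mask rows index depth while spectrum rows index frequency bins;
the product is taken literally on the shared 1247 x 256 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectrumFrame

GATE_LEN = 768
GATE_STEP = 20
WINDOW_LINES = 256


@dataclass
class ROISpectrumFrame:
    values: np.ndarray          # (1247, 256), zeros outside the mask
    kind: str
    mask: np.ndarray            # binary (1247, 256)
    label: int | None = None
    source_frame_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")


@dataclass
class GatedSample:
    values: np.ndarray          # (768, 256)
    label: int
    source_frame_id: str = ""
    window_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (GATE_LEN, WINDOW_LINES):
            raise ValueError(
                f"gated sample must be {(GATE_LEN, WINDOW_LINES)}, "
                f"got {self.values.shape}")


@dataclass(frozen=True)
class BinaryTask:
    """A fibrosis-stage dichotomy, e.g. >=F2 is {2,3,4} vs {0,1}."""

    name: str
    positive_stages: frozenset = field(default_factory=frozenset)
    negative_stages: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.positive_stages | self.negative_stages != frozenset(range(5)) \
                or self.positive_stages & self.negative_stages:
            raise ValueError("positive/negative stages must partition {0..4}")

    def label_of(self, stage: int) -> int:
        return 1 if stage in self.positive_stages else 0


def task(name: str) -> BinaryTask:
    """The four binary staging tasks: '>=F1' ... '>=F4' (aliases geF1...geF4)."""
    name = name.replace(">=F", "geF")
    if name not in {"geF1", "geF2", "geF3", "geF4"}:
        raise ValueError(f"unknown task {name!r}")
    cut = int(name[-1])
    return BinaryTask(name=f">=F{cut}",
                      positive_stages=frozenset(range(cut, 5)),
                      negative_stages=frozenset(range(cut)))


TASKS = tuple(task(f"geF{i}") for i in (1, 2, 3, 4))


# ---------------------------------------------------------------------------
# Masking and normalization
# ---------------------------------------------------------------------------

def apply_mask(spec: SpectrumFrame, mask: np.ndarray,
               label: int | None = None) -> ROISpectrumFrame:
    """Elementwise product of a spectrum frame with a binary ROI mask."""
    mask = np.asarray(mask)
    if mask.shape != spec.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} != spectrum shape {spec.values.shape}")
    binary = (mask > 0).astype(np.float64)
    return ROISpectrumFrame(values=spec.values * binary, kind=spec.kind,
                            mask=(mask > 0).astype(np.uint8),
                            label=spec.label if label is None else label,
                            source_frame_id=spec.source_frame_id)


def normalize(roi: ROISpectrumFrame) -> ROISpectrumFrame:
    """Min-max normalize the whole frame (masked zeros included) to [0, 1]."""
    vmin, vmax = roi.values.min(), roi.values.max()
    if vmax == vmin:
        raise ValueError("degenerate frame: max equals min")
    values = (roi.values - vmin) / (vmax - vmin)
    return ROISpectrumFrame(values=values, kind=roi.kind, mask=roi.mask,
                            label=roi.label,
                            source_frame_id=roi.source_frame_id,
                            normalized=True)


# ---------------------------------------------------------------------------
# Sliding gate and sliding window
# ---------------------------------------------------------------------------

def _longest_run(col_mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest contiguous run of ones in a column."""
    m = np.flatnonzero(col_mask)
    if m.size == 0:
        return 0, 0
    breaks = np.flatnonzero(np.diff(m) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [m.size - 1]))
    lengths = ends - starts + 1
    best = int(np.argmax(lengths))
    return int(m[starts[best]]), int(lengths[best])


def segments_per_line(run_len: int, gate_len: int = GATE_LEN,
                      gate_step: int = GATE_STEP, strict: bool = False) -> int:
    """Number of gate placements on a liver run of ``run_len`` samples."""
    min_len = gate_len + 1 if strict else gate_len
    if run_len < min_len:
        return 0
    return (run_len - gate_len) // gate_step + 1


def eligible_line_count(mask: np.ndarray, gate_len: int = GATE_LEN,
                        strict: bool = False) -> int:
    """Number of scan lines whose longest liver run holds the full gate."""
    mask = np.asarray(mask)
    return sum(
        segments_per_line(_longest_run(mask[:, l])[1], gate_len,
                          GATE_STEP, strict) > 0
        for l in range(mask.shape[1]))


def gate_lines(roi: ROISpectrumFrame, gate_len: int = GATE_LEN,
               gate_step: int = GATE_STEP, strict: bool = False) -> np.ndarray:
    """Slide the axial gate down every eligible line.

    A line is eligible when its longest contiguous liver run holds the full
    gate (run length >= gate_len; ``strict=True`` demands a strictly longer
    run).  Segments start at run offsets 0, gate_step, 2*gate_step, ... and
    are concatenated laterally in line order then offset order, producing a
    (gate_len, L_lateral) array.
    """
    cols = []
    eligible = 0
    for l in range(roi.values.shape[1]):
        start, run = _longest_run(roi.mask[:, l])
        n_seg = segments_per_line(run, gate_len, gate_step, strict)
        if n_seg == 0:
            continue
        eligible += 1
        for k in range(n_seg):
            off = start + k * gate_step
            cols.append(roi.values[off:off + gate_len, l])
    if not cols:
        raise ValueError(
            "no eligible scan line: 0 lines have a liver run holding the "
            f"{gate_len}-point gate")
    return np.stack(cols, axis=1)


def window_frames(gated: np.ndarray, n_aug: int,
                  label: int = 0, source_frame_id: str = "",
                  pad_lateral: bool = False) -> list[GatedSample]:
    """Slide a (gate_len x 256)-line window laterally over the gated columns.

    The step is max(1, floor((L_lateral - 256) / n_aug)); exactly ``n_aug``
    windows are emitted, with start columns clipped so every window fits.
    """
    if n_aug < 1:
        raise ValueError("n_aug must be >= 1")
    gated = np.asarray(gated, dtype=np.float64)
    L = gated.shape[1]
    if L < WINDOW_LINES:
        if not pad_lateral:
            raise ValueError(
                f"L_lateral={L} < {WINDOW_LINES}; enable pad_lateral to "
                "reflect-pad narrow frames")
        reps = np.pad(gated, ((0, 0), (0, WINDOW_LINES - L)), mode="reflect")
        gated, L = reps, WINDOW_LINES
    step = max(1, (L - WINDOW_LINES) // n_aug)
    out = []
    for i in range(n_aug):
        start = min(i * step, L - WINDOW_LINES)
        out.append(GatedSample(values=gated[:, start:start + WINDOW_LINES],
                               label=label, source_frame_id=source_frame_id,
                               window_index=i))
    return out


# ---------------------------------------------------------------------------
# Balancing and assembly
# ---------------------------------------------------------------------------

def augmentation_factor(train_labels) -> int:
    """Nearest-integer ratio of majority to minority class counts (>= 1)."""
    labels = np.asarray(list(train_labels))
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to balance")
    return max(1, int(np.rint(max(n0, n1) / min(n0, n1))))


def balance_and_assemble(frames: list[ROISpectrumFrame], tsk: BinaryTask,
                         ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                         seed: int = 0,
                         gate_len: int = GATE_LEN, gate_step: int = GATE_STEP,
                         pad_lateral: bool = False):
    """Participant-level split, then train-only minority augmentation.

    Frames are split by participant (floor/floor/remainder rounding, seeded
    shuffle) BEFORE windowing, so near-duplicate windows of one participant
    never straddle split parts.  Within the training portion, each
    minority-class frame emits n_aug = round(N_major / N_minor) windows and
    each majority-class frame one; validation and test frames emit one each.

    Returns (train, val, test) lists of :class:`GatedSample` with binary
    task labels.
    """
    from .bmode import split_dataset

    if not frames:
        raise ValueError("no frames")
    by_id = {f.source_frame_id: f for f in frames}
    if len(by_id) != len(frames):
        raise ValueError("frames must carry unique source_frame_id values")
    split = split_dataset(sorted(by_id), ratios=ratios, seed=seed)

    def labels_of(ids):
        return [tsk.label_of(by_id[i].label) for i in ids]

    for part, ids in (("train", split.train_ids), ("val", split.val_ids),
                      ("test", split.test_ids)):
        labs = labels_of(ids)
        if len(set(labs)) < 2:
            raise ValueError(f"class absent from the {part} split part")

    train_labels = labels_of(split.train_ids)
    n1, n0 = train_labels.count(1), train_labels.count(0)
    minority = 1 if n1 < n0 else 0
    n_aug = augmentation_factor(train_labels)

    def emit(ids, augment):
        out = []
        for fid in ids:
            f = by_id[fid]
            y = tsk.label_of(f.label)
            gated = gate_lines(f, gate_len, gate_step)
            k = n_aug if (augment and y == minority) else 1
            out.extend(window_frames(gated, k, label=y, source_frame_id=fid,
                                     pad_lateral=pad_lateral))
        return out

    return (emit(split.train_ids, True), emit(split.val_ids, False),
            emit(split.test_ids, False))


def save_samples(samples: list[GatedSample], path, task_name: str = ""):
    """Write gated samples to an NPZ shard (x float32, y int8, frame ids)
    with a CSV manifest."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = np.stack([s.values for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.int8)
    fids = np.array([s.source_frame_id for s in samples])
    np.savez(path, x=x, y=y, frame_id=fids, task=np.array(task_name))
    pd.DataFrame({"frame_id": fids, "label": y,
                  "window_index": [s.window_index for s in samples]}
                 ).to_csv(path.with_suffix(".csv"), index=False)
    return path


def load_samples(path) -> list[GatedSample]:
    with np.load(path, allow_pickle=False) as z:
        return [GatedSample(values=z["x"][i], label=int(z["y"][i]),
                            source_frame_id=str(z["frame_id"][i]))
                for i in range(z["x"].shape[0])]
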