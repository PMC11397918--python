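"""Synthetic ultrasound RF phantom simulator.

Generates labeled frames of backscattered radiofrequency (RF) signals with
ground-truth liver masks, emulating a convex-array acquisition: 256 scan
lines of 1247 samples, 3 MHz pulse center frequency, 12 MHz sampling.

Scatterer model
---------------
Each scan line is an impulse train convolved with a Gaussian-enveloped
cosine pulse (a 1D per-line model; no lateral point-spread coupling).  The
liver parenchyma band between two smooth per-line boundary curves carries
diffuse sub-resolution scatterers whose density and amplitude variability
depend on the METAVIR fibrosis stage (F0-F4); fibrotic stages additionally
gain sparse bright discrete scatterers emulating echogenic septa, whose
coherent contribution changes the statistics of the per-line frequency
spectra (diffuse density and amplitude spread alone wash out of min-max
normalized spectra by the central limit theorem).  Outside the liver band,
a brighter band of wall-like scatterers stands in for the abdominal wall
and sub-hepatic interfaces.

The resolution cell is defined as the -6 dB length of the pulse envelope in
samples; scatterer densities are expressed per resolution cell.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

#: Per-stage participant proportions of the emulated fibrosis cohort
#: (F0..F4), used by :func:`stage_counts` in "paper" proportions mode.
COHORT_STAGE_COUNTS = (27, 49, 51, 49, 61)

STAGES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition grid and pulse parameters."""

    n_samples: int = 1247
    n_lines: int = 256
    fs: float = 12e6      # sampling frequency [Hz]
    fc: float = 3e6       # pulse center frequency [Hz]
    pulse_bw: float = 0.6  # fractional -6 dB bandwidth of the pulse
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_lines < 1:
            raise ValueError("n_samples and n_lines must be >= 1")
        if not (0 < self.fc < self.fs / 2):
            raise ValueError(f"need 0 < fc < fs/2, got fc={self.fc}, fs={self.fs}")
        if not (0 < self.pulse_bw <= 1):
            raise ValueError(f"pulse_bw must be in (0, 1], got {self.pulse_bw}")


def default_density(stage: int) -> float:
    """Mean diffuse scatterers per resolution cell at a fibrosis stage."""
    return 10.0 * (1.0 + 0.4 * stage)


def default_amplitude_cv(stage: int) -> float:
    """Coefficient of variation of diffuse scatterer amplitudes at a stage."""
    return 0.3 * (1.0 + 0.3 * stage)


def default_septa_rate(stage: int, effect: float = 1.0) -> float:
    """Mean count of bright discrete (septa-like) scatterers per line."""
    return 1.5 * stage * effect


@dataclass(frozen=True)
class PhantomSpec:
    """Tissue description for one simulated frame.

    The stage-dependent parameters default to monotone maps of the METAVIR
    stage so that class separation is controlled by a single ``effect_scale``
    knob: diffuse density and amplitude CV grow with stage, and fibrotic
    stages gain bright discrete scatterers (``septa_rate`` per line at
    ``septa_amplitude`` times the diffuse per-bin spectral RMS).
    """

    stage: int = 0
    scatterer_density_per_cell: float | None = None  # default: map of stage
    amplitude_cv: float | None = None                # default: map of stage
    septa_rate: float | None = None                  # default: map of stage
    septa_amplitude: float = 2.0
    effect_scale: float = 1.0
    liver_top_range: tuple[float, float] = (150.0, 350.0)
    liver_bottom_range: tuple[float, float] = (900.0, 1200.0)
    boundary_wobble: float = 20.0   # amplitude of cosine boundary perturbation [samples]
    wall_amplitude: float = 4.0     # relative echogenicity of the non-liver bands
    wall_density_per_cell: float = 12.0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be in {STAGES}, got {self.stage}")
        if self.density <= 0:
            raise ValueError("scatterer density must be > 0")

    @property
    def density(self) -> float:
        if self.scatterer_density_per_cell is not None:
            return self.scatterer_density_per_cell
        return default_density(self.stage)

    @property
    def amp_cv(self) -> float:
        if self.amplitude_cv is not None:
            return self.amplitude_cv
        return default_amplitude_cv(self.stage) * min(1.0, self.effect_scale)

    @property
    def septa(self) -> float:
        if self.septa_rate is not None:
            return self.septa_rate
        return default_septa_rate(self.stage, self.effect_scale)


@dataclass
class RFFrame:
    """One acquisition: real-valued samples on the (axial x lateral) grid."""

    samples: np.ndarray                 # (n_samples, n_lines) float32
    acq: AcquisitionSpec
    label: int | None = None            # METAVIR stage, when known
    truth_mask: np.ndarray | None = None  # (n_samples, n_lines) uint8
    frame_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.shape != (self.acq.n_samples, self.acq.n_lines):
            raise ValueError(
                f"samples shape {self.samples.shape} does not match acquisition "
                f"{(self.acq.n_samples, self.acq.n_lines)}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")


# ---------------------------------------------------------------------------
# Pulse
# ---------------------------------------------------------------------------

def make_pulse(acq: AcquisitionSpec) -> np.ndarray:
    """Gaussian-enveloped cosine at ``fc`` sampled at ``fs``, unit peak.

    The Gaussian sigma is set so the envelope's -6 dB full width equals
    ``pulse_bw``-fractional bandwidth of the carrier in the spectral domain,
    i.e. a narrower fractional bandwidth yields a longer pulse.  Length is
    odd and covers +-4 sigma.
    """
    # -6 dB spectral half-width (Hz) -> Gaussian sigma in time
    f6 = acq.pulse_bw * acq.fc / 2.0
    sigma_f = f6 / np.sqrt(2.0 * np.log(2.0))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)          # seconds
    sigma_n = sigma_t * acq.fs                        # samples
    half = max(1, int(np.ceil(4.0 * sigma_n)))
    n = np.arange(-half, half + 1)
    envelope = np.exp(-0.5 * (n / sigma_n) ** 2)
    pulse = envelope * np.cos(2.0 * np.pi * acq.fc / acq.fs * n)
    pulse = pulse / np.max(np.abs(pulse))
    return pulse.astype(np.float64)


def resolution_cell_samples(acq: AcquisitionSpec) -> float:
    """Resolution cell length: the -6 dB width of the pulse envelope, in samples."""
    f6 = acq.pulse_bw * acq.fc / 2.0
    sigma_f = f6 / np.sqrt(2.0 * np.log(2.0))
    sigma_n = acq.fs / (2.0 * np.pi * sigma_f)
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_n


# ---------------------------------------------------------------------------
# Frame simulation
# ---------------------------------------------------------------------------

def _boundary_curves(phantom: PhantomSpec, acq: AcquisitionSpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Smooth cosine-perturbed top/bottom liver boundaries per line."""
    lines = np.arange(acq.n_lines)

    def curve(lo, hi):
        base = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        cycles = rng.uniform(0.5, 2.0)
        wob = phantom.boundary_wobble * np.cos(
            2 * np.pi * cycles * lines / max(1, acq.n_lines) + phase)
        return base, base + wob

    top_base, top = curve(*phantom.liver_top_range)
    # draw the bottom jointly so the liver band stays deep enough for the
    # downstream 768-point axial gate despite the boundary wobble
    blo, bhi = phantom.liver_bottom_range
    min_band = 768 + 2 * phantom.boundary_wobble + 10
    blo = min(max(blo, top_base + min_band), bhi)
    _, bottom = curve(blo, bhi)
    top = np.clip(np.round(top), 0, acq.n_samples - 2).astype(int)
    bottom = np.clip(np.round(bottom), 1, acq.n_samples).astype(int)
    bad = bottom <= top
    bottom[bad] = np.minimum(top[bad] + 1, acq.n_samples)
    return top, bottom


def _scatter_train(rng: np.random.Generator, start: int, stop: int,
                   density_per_sample: float, mean_amp: float, cv: float,
                   n_samples: int) -> np.ndarray:
    """Impulse train on [start, stop): Poisson count, uniform depths,
    gamma-distributed positive amplitudes with the given CV, random sign."""
    train = np.zeros(n_samples)
    span = stop - start
    if span <= 0 or density_per_sample <= 0:
        return train
    count = rng.poisson(density_per_sample * span)
    if count == 0:
        return train
    depths = rng.integers(start, stop, size=count)
    if cv > 0:
        shape = 1.0 / cv ** 2
        amps = rng.gamma(shape, mean_amp / shape, size=count)
    else:
        amps = np.full(count, mean_amp)
    amps *= rng.choice((-1.0, 1.0), size=count)
    np.add.at(train, depths, amps)
    return train


def simulate_frame(phantom: PhantomSpec, acq: AcquisitionSpec,
                   seed: int, frame_id: str = "") -> RFFrame:
    """Simulate one RF frame; bit-reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    top, bottom = _boundary_curves(phantom, acq, rng)
    if np.all(bottom - top <= 0):
        raise ValueError("empty liver band: bottom <= top on every line")

    pulse = make_pulse(acq)
    cell = resolution_cell_samples(acq)
    liver_dens = phantom.density / cell          # per sample
    wall_dens = phantom.wall_density_per_cell / cell

    n, m = acq.n_samples, acq.n_lines
    frame = np.empty((n, m), dtype=np.float32)
    mask = np.zeros((n, m), dtype=np.uint8)

    # expected diffuse per-bin spectral RMS, reference scale for septa
    diffuse_count = liver_dens * np.mean(bottom - top)
    septa_amp = phantom.septa_amplitude * np.sqrt(
        max(diffuse_count, 1.0) * (1.0 + phantom.amp_cv ** 2))

    for l in range(m):
        t, b = int(top[l]), int(bottom[l])
        train = _scatter_train(rng, t, b, liver_dens, 1.0, phantom.amp_cv, n)
        train += _scatter_train(rng, 0, t, wall_dens, phantom.wall_amplitude,
                                0.3, n)
        train += _scatter_train(rng, b, n, wall_dens, phantom.wall_amplitude,
                                0.3, n)
        n_septa = rng.poisson(phantom.septa)
        if n_septa > 0 and b - t > 0:
            depths = rng.integers(t, b, size=n_septa)
            amps = septa_amp * rng.uniform(0.7, 1.3, size=n_septa)
            amps *= rng.choice((-1.0, 1.0), size=n_septa)
            np.add.at(train, depths, amps)
        frame[:, l] = np.convolve(train, pulse, mode="same")
        mask[t:b, l] = 1

    return RFFrame(samples=frame, acq=acq, label=phantom.stage,
                   truth_mask=mask, frame_id=frame_id)


# ---------------------------------------------------------------------------
# Dataset simulation and container I/O
# ---------------------------------------------------------------------------

def stage_counts(total: int, proportions: str = "paper") -> tuple[int, ...]:
    """Per-stage frame counts for a dataset of ``total`` frames.

    ``proportions='paper'`` mirrors the emulated cohort's stage mix
    (27:49:51:49:61); ``'balanced'`` splits as evenly as possible.  Largest
    remainders absorb the rounding so the counts always sum to ``total``.
    """
    if proportions == "balanced":
        base = [total // 5] * 5
        for i in range(total % 5):
            base[i] += 1
        return tuple(base)
    if proportions != "paper":
        raise ValueError(f"unknown proportions mode: {proportions!r}")
    ref = np.array(COHORT_STAGE_COUNTS, dtype=float)
    exact = ref / ref.sum() * total
    counts = np.floor(exact).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in range(rem):
        counts[order[i]] += 1
    return tuple(int(c) for c in counts)


def derive_seed(master_seed: int, index: int, stream: str = "frame") -> int:
    """Stable per-item seed derived from a master seed (order-independent)."""
    h = hashlib.sha256(f"{master_seed}:{stream}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def simulate_dataset(n_per_stage: int | None = None,
                     total: int | None = None,
                     proportions: str = "paper",
                     stages: tuple[int, ...] = STAGES,
                     acq: AcquisitionSpec | None = None,
                     phantoms: dict[int, PhantomSpec] | None = None,
                     effect_scale: float = 1.0,
                     seed: int = 0) -> list[RFFrame]:
    """Simulate a labeled dataset.

    Either ``n_per_stage`` (balanced: that many frames per stage) or
    ``total`` (split by ``proportions``) must be given.  Per-frame seeds are
    derived from the master ``seed`` by a counter-based hash so datasets are
    order-independent.
    """
    if (n_per_stage is None) == (total is None):
        raise ValueError("give exactly one of n_per_stage or total")
    if n_per_stage is not None:
        if n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")
        counts = {s: n_per_stage for s in stages}
    else:
        per = stage_counts(total, proportions)
        counts = {s: per[s] for s in STAGES}
    acq = acq or AcquisitionSpec()
    phantoms = phantoms or {}
    frames = []
    idx = 0
    for s in sorted(counts):
        ph = phantoms.get(s, PhantomSpec(stage=s, effect_scale=effect_scale))
        for _ in range(counts[s]):
            fid = f"sim{idx:05d}"
            frames.append(simulate_frame(ph, acq, derive_seed(seed, idx), fid))
            idx += 1
    return frames


def save_dataset(frames: list[RFFrame], path: str | Path) -> Path:
    """Write a dataset container (NPZ: rf float32, mask uint8, label int8,
    meta JSON) plus a CSV manifest next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rf = np.stack([f.samples for f in frames])
    mask = np.stack([
        f.truth_mask if f.truth_mask is not None
        else np.zeros_like(f.samples, dtype=np.uint8)
        for f in frames])
    label = np.array([(-1 if f.label is None else f.label) for f in frames],
                     dtype=np.int8)
    acq = frames[0].acq
    meta = json.dumps({"acq": asdict(acq),
                       "frame_ids": [f.frame_id for f in frames]})
    np.savez(path, rf=rf.astype(np.float32), mask=mask.astype(np.uint8),
             label=label, meta=np.array(meta))
    manifest = pd.DataFrame({"frame_id": [f.frame_id for f in frames],
                             "stage": label})
    manifest.to_csv(path.with_suffix(".csv"), index=False)
    return path


def load_dataset(path: str | Path) -> list[RFFrame]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        acq = AcquisitionSpec(**meta["acq"])
        frames = []
        for i, fid in enumerate(meta["frame_ids"]):
            lab = int(z["label"][i])
            frames.append(RFFrame(
                samples=z["rf"][i], acq=acq,
                label=None if lab < 0 else lab,
                truth_mask=z["mask"][i], frame_id=fid))
    return frames
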