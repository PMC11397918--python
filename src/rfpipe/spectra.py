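"""Per-scan-line frequency spectra of RF frames.

For a scan line ``s`` of length N the complex spectrum is the full N-point
two-sided FFT (no windowing, no zero-padding), and

* amplitude = |FFT(s)|
* phase     = angle(FFT(s))   (angle(0) := 0)
* power     = |FFT(s)|^2 / N

Spectra are computed over the entire line before any ROI masking, so a
spectrum frame has the same 1247 x 256 shape as its RF frame.  Bins are in
standard FFT order (DC first, positive then negative frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import RFFrame

KINDS = ("amplitude", "phase", "power")


@dataclass
class SpectrumFrame:
    values: np.ndarray           # (n_samples, n_lines)
    kind: str
    source_frame_id: str = ""
    label: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)


def spectrum_line(s: np.ndarray, kind: str) -> np.ndarray:
    """Amplitude, phase, or power spectrum of one scan line."""
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("input must be a 1D array of length >= 1")
    if not np.all(np.isfinite(s)):
        raise ValueError("input must be finite")
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    sf = np.fft.fft(s)
    if kind == "amplitude":
        return np.abs(sf)
    if kind == "phase":
        return np.angle(sf)
    return np.abs(sf) ** 2 / s.size


def spectrum_frame(rf: RFFrame | np.ndarray, kind: str) -> SpectrumFrame:
    """Apply :func:`spectrum_line` independently to each scan line (column)."""
    if isinstance(rf, RFFrame):
        samples, fid, label = rf.samples, rf.frame_id, rf.label
    else:
        samples, fid, label = np.asarray(rf, dtype=np.float64), "", None
    if not np.all(np.isfinite(samples)):
        raise ValueError("RF samples must be finite")
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    sf = np.fft.fft(samples, axis=0)
    if kind == "amplitude":
        values = np.abs(sf)
    elif kind == "phase":
        values = np.angle(sf)
    else:
        values = np.abs(sf) ** 2 / samples.shape[0]
    return SpectrumFrame(values=values, kind=kind, source_frame_id=fid,
                         label=label)
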