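"""Shared short-time spectral helpers (Hamming-windowed magnitude STFT)."""
from __future__ import annotations

import numpy as np

DEFAULT_WINDOW = 512
DEFAULT_OVERLAP = 0.5


def frame_spectra(
    samples: np.ndarray,
    rate: float,
    window: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Magnitude spectra of overlapping Hamming-windowed frames.

    Returns ``(frequencies, magnitudes, padded)`` where ``magnitudes`` has one
    row per frame.  Clips shorter than one analysis window are zero-padded to
    a single window and flagged with ``padded=True``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a mono sample vector")
    padded = False
    if x.size < window:
        x = np.pad(x, (0, window - x.size))
        padded = True
    hop = max(1, int(round(window * (1.0 - overlap))))
    n_frames = 1 + (x.size - window) // hop
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(window)[None, :]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(window, d=1.0 / rate)
    return freqs, mags, padded
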