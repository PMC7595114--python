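"""Per-grunt spectro-temporal descriptors and spectral dissimilarity.

The descriptor set treats a grunt's mean magnitude spectrum (Hamming STFT,
window 512, 50 % overlap, band-limited to 0.2–8 kHz, normalised to unit sum)
as a probability mass function over frequency and summarises it by its
moments, quantiles, mode and three noisiness indices:

* ``sh`` — normalised Shannon entropy of the spectrum,
* ``sfm`` — spectral flatness (Wiener entropy): geometric / arithmetic mean,
* ``entropy_h`` — product of ``sh`` and the normalised entropy of the
  Hilbert amplitude envelope (spectral × temporal noisiness).

``mean`` and ``centroid`` are definitionally identical (both Σ fᵢpᵢ); both
are computed and exported, and the discriminant scoring stage is required to
tolerate this exact collinearity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.fft
from scipy.signal import hilbert

from ._spectral import DEFAULT_OVERLAP, DEFAULT_WINDOW, frame_spectra
from .audio_io import AudioRecording, bandpass_fir, normalize_amplitude
from .segmentation import CallSegment, refine_call_bounds

__all__ = [
    "MeanSpectrum",
    "SpectralProperties",
    "GruntFeatures",
    "mean_spectrum",
    "spectral_properties",
    "dominant_frequency",
    "entropy_h",
    "grunt_features",
    "spectral_dissimilarity",
    "extract_feature_table",
    "ACOUSTIC_SCORE_VARIABLES",
]

DEFAULT_BAND = (200.0, 8000.0)
#: Band used for between-context spectral comparison: the grunts' main range.
DISSIMILARITY_BAND = (200.0, 2000.0)

#: The nine spectral inputs of the acoustic discriminant score.
ACOUSTIC_SCORE_VARIABLES = (
    "mean",
    "median",
    "mode",
    "q25",
    "q75",
    "centroid",
    "sh",
    "sfm",
    "entropy_h",
)


@dataclass
class MeanSpectrum:
    """Band-limited, unit-sum mean magnitude spectrum of a clip."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    padded: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.frequencies.shape != self.amplitudes.shape:
            raise ValueError("frequencies and amplitudes must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if abs(self.amplitudes.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")


@dataclass
class SpectralProperties:
    mean: float
    median: float
    mode: float
    q25: float
    q75: float
    iqr: float
    centroid: float
    sh: float
    sfm: float


@dataclass
class GruntFeatures:
    """One row of the acoustic feature table."""

    duration: float
    log_duration: float
    mean: float
    median: float
    mode: float
    q25: float
    q75: float
    iqr: float
    centroid: float
    dominant_freq: float  # kHz
    sh: float
    sfm: float
    entropy_h: float
    padded: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def mean_spectrum(
    clip: AudioRecording,
    window: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    band: tuple[float, float] = DEFAULT_BAND,
) -> MeanSpectrum:
    """Average the per-frame magnitude spectra of a clip.

    Frames use a Hamming window of ``window`` samples with the given
    fractional overlap; the averaged spectrum is restricted to ``band`` and
    renormalised to unit sum.  Clips shorter than one window are zero-padded
    and flagged.
    """
    freqs, mags, padded = frame_spectra(clip.samples, clip.rate, window, overlap)
    spec = mags.mean(axis=0)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no FFT bins at rate {clip.rate}")
    spec = spec[mask]
    total = spec.sum()
    if total <= 0.0:
        raise ValueError("silent clip: mean spectrum has no energy in band")
    return MeanSpectrum(frequencies=freqs[mask], amplitudes=spec / total, padded=padded)


def _hilbert_envelope(samples: np.ndarray) -> np.ndarray:
    """Hilbert amplitude envelope, computed at a fast FFT length."""
    n = samples.size
    env = np.abs(hilbert(samples, N=scipy.fft.next_fast_len(n)))[:n]
    return env


def _pmf_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a PMF, normalised to [0, 1] by log2 of its length."""
    if p.size <= 1:
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(p.size))


def spectral_properties(s: MeanSpectrum) -> SpectralProperties:
    """Moment/quantile/entropy summary of a mean spectrum.

    Quantiles are the smallest frequency at which the cumulative mass reaches
    the target; the mode breaks amplitude ties toward the lowest frequency.
    """
    f, p = s.frequencies, s.amplitudes
    mean = float((f * p).sum())
    cum = np.cumsum(p)
    q25 = float(f[np.searchsorted(cum, 0.25)])
    median = float(f[np.searchsorted(cum, 0.5)])
    q75 = float(f[np.searchsorted(cum, 0.75)])
    mode = float(f[np.argmax(p)])  # argmax returns the first (lowest) maximum
    sh = _pmf_entropy(p)
    arith = p.mean()
    nz = p[p > 0]
    # geometric mean over all bins: any zero amplitude sends it to zero
    geo = math.exp(np.log(nz).mean()) if nz.size == p.size else 0.0
    sfm = float(geo / arith) if arith > 0 else 0.0
    return SpectralProperties(
        mean=mean,
        median=median,
        mode=mode,
        q25=q25,
        q75=q75,
        iqr=q75 - q25,
        centroid=mean,
        sh=sh,
        sfm=sfm,
    )


def dominant_frequency(
    clip: AudioRecording,
    window: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Mean over frames of the peak-energy frequency, in kHz."""
    freqs, mags, _ = frame_spectra(clip.samples, clip.rate, window, overlap)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    sub = mags[:, mask]
    if sub.sum() <= 0:
        raise ValueError("silent clip: no energy in band")
    peaks = freqs[mask][np.argmax(sub, axis=1)]
    return float(peaks.mean() / 1000.0)


def entropy_h(
    clip: AudioRecording,
    window: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Combined spectro-temporal entropy.

    The product of the spectral Shannon entropy of the mean spectrum and the
    normalised entropy of the Hilbert amplitude envelope (itself treated as a
    PMF over samples).  Bounded in [0, 1]: a pure tone with a flat envelope
    scores ~0, sustained band-limited noise scores ~1.
    """
    spec = mean_spectrum(clip, window, overlap, band)
    sh = _pmf_entropy(spec.amplitudes)
    env = _hilbert_envelope(clip.samples)
    total = env.sum()
    if total <= 0.0:
        raise ValueError("silent clip")
    th = _pmf_entropy(env / total)
    return float(sh * th)


def grunt_features(
    clip: AudioRecording,
    segment: CallSegment,
    window: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    band: tuple[float, float] = DEFAULT_BAND,
    spectrum: MeanSpectrum | None = None,
) -> GruntFeatures:
    """Full descriptor row for one refined grunt clip.

    ``spectrum`` may pass a precomputed mean spectrum of the same clip to
    avoid a second STFT.
    """
    if segment.type != "grunt":
        raise ValueError(f"expected a grunt, got {segment.type!r}")
    spec = spectrum if spectrum is not None else mean_spectrum(clip, window, overlap, band)
    props = spectral_properties(spec)
    dom = dominant_frequency(clip, window, overlap, band)
    th_env = _hilbert_envelope(clip.samples)
    th = _pmf_entropy(th_env / th_env.sum())
    duration = segment.duration
    return GruntFeatures(
        duration=duration,
        log_duration=math.log(duration),
        mean=props.mean,
        median=props.median,
        mode=props.mode,
        q25=props.q25,
        q75=props.q75,
        iqr=props.iqr,
        centroid=props.centroid,
        dominant_freq=dom,
        sh=props.sh,
        sfm=props.sfm,
        entropy_h=props.sh * th,
        padded=spec.padded,
    )


def spectral_dissimilarity(
    s1: MeanSpectrum,
    s2: MeanSpectrum,
    band: tuple[float, float] = DISSIMILARITY_BAND,
) -> float:
    """Dissimilarity D between two mean spectra: half the L1 distance.

    Both spectra are restricted to ``band`` and renormalised before
    comparison; D is symmetric and bounded in [0, 1] (0 for identical
    spectra, 1 for disjoint support).
    """
    if s1.frequencies.shape != s2.frequencies.shape or not np.allclose(
        s1.frequencies, s2.frequencies
    ):
        raise ValueError("spectra must share frequency bins")
    mask = (s1.frequencies >= band[0]) & (s1.frequencies <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} outside the spectra's support")
    p1 = s1.amplitudes[mask]
    p2 = s2.amplitudes[mask]
    if p1.sum() <= 0 or p2.sum() <= 0:
        raise ValueError("a spectrum has no mass in the comparison band")
    p1 = p1 / p1.sum()
    p2 = p2 / p2.sum()
    return float(0.5 * np.abs(p1 - p2).sum())


def extract_feature_table(
    dataset,
    pad: float = 0.05,
    threshold_frac: float = 0.05,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Run the acoustic pipeline over every annotated grunt of a dataset.

    ``dataset`` must expose an ``annotations`` table (with design keys) and a
    ``render_call(call_id, pad)`` method returning the padded call clip (as a
    written study would be sliced from its trial-phase WAVs).  Each clip is
    band-passed, boundary-refined by the amplitude threshold, normalised and
    measured.

    Returns ``(features, spectra, frequencies)``: the per-grunt feature table
    (one row per grunt, including refined absolute onset), the matrix of
    per-grunt mean spectra and their shared frequency bins.
    """
    rows = []
    spectra = []
    freqs = None
    ann = dataset.annotations
    grunts = ann[ann["type"] == "grunt"]
    for rec in grunts.itertuples():
        clip = dataset.render_call(rec.call_id, pad=pad)
        filtered = bandpass_fir(clip, band[0], band[1])
        seg = refine_call_bounds(
            filtered, threshold_frac=threshold_frac, call_id=rec.call_id
        )
        i0 = int(round(seg.onset * filtered.rate))
        i1 = int(round(seg.offset * filtered.rate))
        grunt_clip = normalize_amplitude(filtered.copy_with(filtered.samples[i0:i1]))
        spec = mean_spectrum(grunt_clip, band=band)
        feats = grunt_features(grunt_clip, seg, band=band, spectrum=spec)
        if freqs is None:
            freqs = spec.frequencies
        spectra.append(spec.amplitudes)
        row = feats.as_dict()
        row.update(
            {
                "call_id": rec.call_id,
                "clip_id": rec.clip_id,
                "piglet": rec.piglet,
                "trial": rec.trial,
                "phase": rec.phase,
                # refined onset mapped back to the phase timeline
                "onset_s": rec.onset_s - pad + seg.onset,
            }
        )
        rows.append(row)
    features = pd.DataFrame(rows)
    keys = dataset.phases[
        ["piglet", "trial", "phase", "partner", "treatment", "replicate"]
    ]
    features = features.merge(keys, on=["piglet", "trial", "phase"], how="left")
    return features, np.asarray(spectra), freqs
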