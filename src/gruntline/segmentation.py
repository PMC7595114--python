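"""Call-boundary refinement and grunt-rhythm computation.

Annotated call windows are refined by the 5 % amplitude-threshold rule: a
call starts where the smoothed amplitude envelope first reaches 5 % of its
maximum and ends at the last supra-threshold sample of the longest
contiguous supra-threshold run.  Rhythm is the mean inter-grunt interval
(IGI), measured onset-to-onset.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import AudioRecording

__all__ = [
    "CallSegment",
    "VocalRhythm",
    "envelope",
    "refine_call_bounds",
    "inter_grunt_intervals",
    "rhythm_table",
]

CALL_TYPES = ("grunt", "squeak", "bark", "scream", "mixed")


@dataclass
class CallSegment:
    """One annotated (and possibly boundary-refined) call."""

    clip_id: str
    call_id: str
    onset: float
    offset: float
    type: str = "grunt"

    def __post_init__(self) -> None:
        if self.type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.type!r}")
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class VocalRhythm:
    """Per piglet × trial × phase grunt-rhythm summary.

    ``mean_igi`` is defined only when at least two grunts were produced;
    otherwise it is NaN (missing, not zero).
    """

    piglet: int
    trial: int
    phase: int
    mean_igi: float
    n_grunts: int


def envelope(rec: AudioRecording, smooth_ms: float = 5.0) -> np.ndarray:
    """Amplitude envelope: moving average of the rectified signal.

    The 5 ms smoothing window sets the temporal resolution of the boundary
    detector; duration errors are therefore quoted in units of this frame.
    """
    n = max(1, int(round(rec.rate * smooth_ms / 1000.0)))
    if rec.samples.size <= n:
        raise ValueError("clip shorter than the smoothing window")
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(np.abs(rec.samples), size=n, mode="constant")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def refine_call_bounds(
    clip: AudioRecording,
    threshold_frac: float = 0.05,
    smooth_ms: float = 5.0,
    clip_id: str | None = None,
    call_id: str = "",
    call_type: str = "grunt",
) -> CallSegment:
    """Detect call boundaries by amplitude thresholding within one clip.

    The clip is assumed to contain a single annotated call plus optional
    padding.  If several supra-threshold runs exist (e.g. an echo or a noise
    burst), the longest one wins and a warning is emitted.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    env = envelope(clip, smooth_ms=smooth_ms)
    peak = env.max()
    if peak <= 0.0:
        raise ValueError("clip is silent; cannot refine boundaries")
    mask = env >= threshold_frac * peak
    runs = _runs(mask)
    if not runs:  # unreachable for threshold < 1: the peak itself qualifies
        raise RuntimeError("envelope never crossed the threshold")
    if len(runs) > 1:
        warnings.warn(
            f"{len(runs)} supra-threshold runs in clip "
            f"{clip_id or clip.id!r}; keeping the longest",
            stacklevel=2,
        )
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    onset = start / clip.rate
    offset = stop / clip.rate
    return CallSegment(
        clip_id=clip_id if clip_id is not None else clip.id,
        call_id=call_id,
        onset=onset,
        offset=offset,
        type=call_type,
    )


def inter_grunt_intervals(
    segments: list[CallSegment], piglet: int = -1, trial: int = -1, phase: int = 0
) -> VocalRhythm:
    """Mean inter-grunt interval of one piglet × trial × phase.

    Intervals are successive onset-to-onset differences of grunts sorted by
    onset; the summary is their arithmetic mean.
    """
    grunts = [s for s in segments if s.type == "grunt"]
    if any(s.type != "grunt" for s in segments):
        raise ValueError("inter_grunt_intervals expects grunt segments only")
    onsets = np.sort([s.onset for s in grunts])
    n = onsets.size
    if n < 2:
        return VocalRhythm(piglet, trial, phase, math.nan, n)
    mean_igi = float(np.mean(np.diff(onsets)))
    return VocalRhythm(piglet, trial, phase, mean_igi, n)


def rhythm_table(annotations: pd.DataFrame, onset_col: str = "onset_s") -> pd.DataFrame:
    """Per piglet × trial × phase rhythm summary from an annotation table.

    Expects grunt rows with ``piglet``, ``trial``, ``phase`` keys and an
    onset column in the phase timeline.  Rows with fewer than two grunts get
    NaN ``mean_igi``.
    """
    rows = []
    grunts = annotations[annotations["type"] == "grunt"]
    for (piglet, trial, phase), grp in grunts.groupby(["piglet", "trial", "phase"]):
        onsets = np.sort(grp[onset_col].to_numpy(dtype=float))
        mean_igi = float(np.mean(np.diff(onsets))) if onsets.size >= 2 else math.nan
        rows.append(
            {
                "piglet": piglet,
                "trial": trial,
                "phase": phase,
                "mean_igi": mean_igi,
                "n_grunts": int(onsets.size),
            }
        )
    return pd.DataFrame(rows)
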