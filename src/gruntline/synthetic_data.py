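"""Synthetic study generator.

Builds a complete in-silico replica of the anticipation experiment: 60
weaned piglets housed three per pen over two replicates, half with
additional human contact (treatment H+) and half with minimal contact (H);
each piglet is conditioned over twelve trials to associate a stimulus with
the arrival of either its pen mates (partner C) or a familiar human
(partner H).  The analysed trials are 10–12: each has an initial phase −1
(random 10–30 s) and a 20 s anticipation phase 0; on trial 12 the partner's
entrance is delayed by 90 s, split into three 30 s phases 1–3.  Behaviour
(zone occupancy, door watching, freezing) is generated for the conditioning
trial blocks (2–4, 6–8, 10–12) so the door-preference analysis has its
trial-block factor.

Grunts are rendered as an additive harmonic stack (f0 plus integer
harmonics with a spectral tilt) mixed with band-limited noise at a
controllable harmonic-to-noise ratio, Tukey-windowed at the edges, on a
quiet low-frequency background bed.  Condition effects (inter-grunt
interval, duration, spectral noisiness) are applied in log/logit space so
rendered parameters stay in range, and every per-grunt target parameter is
exported in a ground-truth table, which is the reference surface for
recovery tests.

Every random draw comes from a stream keyed by (seed, purpose, piglet,
trial, phase), so identical (config, seed) gives byte-identical datasets
and a single effect toggles only its targeted observable's target
parameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft
import yaml
from scipy.signal.windows import tukey
from scipy.special import expit

from .audio_io import AudioRecording, write_wav

__all__ = [
    "StudyDesign",
    "GruntSynthParams",
    "EffectConfig",
    "StudyDataset",
    "PhaseContext",
    "synth_grunt",
    "synth_background_noise",
    "simulate_behaviour_phase",
    "simulate_study",
]

TRIAL_BLOCKS = {
    "beginning": (2, 3, 4),
    "middle": (6, 7, 8),
    "end": (10, 11, 12),
}

_PHASE_CODE = {-1: 1, 0: 2, 1: 3, 2: 4, 3: 5}

# rng stream tags
_PIGLET, _ONSET, _DURATION, _NOISINESS, _F0, _BEHAVIOUR, _RENDER, _BED = range(1, 9)


class ConfigurationError(ValueError):
    """Raised for invalid study configurations."""


@dataclass
class StudyDesign:
    """Experimental design template.

    Defaults reproduce the study layout: 60 piglets in 2 replicates, pens of
    3, treatments balanced over pens, trials 10–12 analysed with phase −1
    drawn uniformly on 10–30 s, a fixed 20 s anticipation phase, and three
    30 s delayed phases on the last trial.
    """

    n_piglets: int = 60
    n_replicates: int = 2
    piglets_per_pen: int = 3
    trials_analysed: tuple[int, ...] = (10, 11, 12)
    delayed_trial: int = 12
    phase_m1_range: tuple[float, float] = (10.0, 30.0)
    phase0_duration: float = 20.0
    delayed_phase_duration: float = 30.0
    n_delayed_phases: int = 3
    rate: float = 44100.0
    background_q25: float = 250.0

    def __post_init__(self) -> None:
        if self.n_piglets <= 0:
            raise ConfigurationError("need at least one piglet")
        per_cell = self.piglets_per_pen * self.n_replicates * 2  # 2 treatments
        if self.n_piglets % per_cell:
            raise ConfigurationError(
                f"n_piglets must be a multiple of {per_cell} to balance pens, "
                "replicates and treatments"
            )
        if self.delayed_trial not in self.trials_analysed:
            raise ConfigurationError("the delayed trial must be analysed")
        lo, hi = self.phase_m1_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid phase −1 duration range")
        if self.rate < 16000:
            raise ConfigurationError("sample rate must be at least 16 kHz")

    @property
    def behaviour_trials(self) -> tuple[int, ...]:
        return tuple(t for block in TRIAL_BLOCKS.values() for t in block)

    def partner(self, piglet: int, trial: int) -> str:
        """Alternating partner schedule; both partners occur in trials 10–12."""
        return "C" if (piglet + trial) % 2 == 0 else "H"

    def treatment(self, piglet: int) -> str:
        return "H" if (piglet // self.piglets_per_pen) % 2 == 0 else "H+"

    def replicate(self, piglet: int) -> int:
        return 1 if piglet < self.n_piglets // self.n_replicates else 2

    def pen(self, piglet: int) -> int:
        return piglet // self.piglets_per_pen

    def phases_of_trial(self, trial: int) -> list[int]:
        phases = [-1, 0]
        if trial == self.delayed_trial:
            phases += list(range(1, self.n_delayed_phases + 1))
        return phases

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("trials_analysed", "phase_m1_range"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


@dataclass
class GruntSynthParams:
    """Rendering parameters of one grunt."""

    duration: float = 0.27
    f0: float = 300.0
    harmonic_to_noise: float = 0.5
    spectral_tilt: float = -6.0        # dB per octave over the harmonic stack
    band: tuple[float, float] = (200.0, 2000.0)
    ramp: float = 0.01                 # onset/offset ramp, s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.harmonic_to_noise <= 1.0:
            raise ValueError("harmonic_to_noise must lie in [0, 1]")


@dataclass
class EffectConfig:
    """Condition effects and variance components, in log/logit space.

    The default values encode the directions the analysis is designed to
    detect: grunting is faster (shorter IGI) when conspecifics are
    anticipated, grunts lengthen when a human is anticipated and during the
    delayed phases, spectral noisiness rises during anticipation of
    conspecifics, and less-familiarised piglets (treatment H) produce longer
    grunts on human trials.
    """

    igi_partner_effect: float = 1.5          # s; C faster than H in phase 0
    duration_anticipation_H: float = 1.3     # × grunt duration, phase 0, partner H
    duration_delay_effect: float = 1.3       # × grunt duration, phases 1–3
    noisiness_anticipation_C: float = -1.2   # logit shift of h2n, phase 0, partner C
    treatment_duration_effect: float = 1.15  # × duration, treatment H on H trials
    door_preference_effect: float = 1.0      # growth of C-door attraction over trials
    anticipation_behaviour_effect: float = 1.0  # phase-0 door approach / watching
    piglet_random_sd: float = 0.15           # between-piglet SD (log/logit spaces)
    residual_sd: float = 0.35                # within-piglet SD of log duration
    h2n_residual_sd: float = 0.5             # within-piglet SD of logit h2n
    igi_piglet_sd: float = 0.8               # between-piglet SD of target IGI, s
    igi_log_sd: float = 0.35                 # lognormal spread of individual gaps
    base_igi: float = 6.0                    # mean IGI outside the stimulus, s
    igi_anticipation: float = 5.0            # mean IGI in phase 0 (partner H), s
    median_duration: float = 0.27            # baseline grunt duration median, s

    def __post_init__(self) -> None:
        for name in (
            "piglet_random_sd",
            "residual_sd",
            "h2n_residual_sd",
            "igi_piglet_sd",
            "igi_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @classmethod
    def zero(cls, **overrides) -> "EffectConfig":
        """All condition effects off; variance components keep their defaults."""
        base = dict(
            igi_partner_effect=0.0,
            duration_anticipation_H=1.0,
            duration_delay_effect=1.0,
            noisiness_anticipation_C=0.0,
            treatment_duration_effect=1.0,
            door_preference_effect=0.0,
            anticipation_behaviour_effect=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(k) for k in key]])


def _shaped_noise(
    rng: np.random.Generator, n: int, rate: float, low: float, high: float
) -> np.ndarray:
    """Unit-RMS white noise FFT-brick-walled to [low, high] Hz.

    The FFT runs at the next fast transform length and is truncated back, so
    arbitrary clip lengths stay cheap.
    """
    n_fast = scipy.fft.next_fast_len(n)
    white = rng.standard_normal(n_fast)
    spec = scipy.fft.rfft(white)
    freqs = scipy.fft.rfftfreq(n_fast, 1.0 / rate)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = scipy.fft.irfft(spec, n_fast)[:n]
    return x / math.sqrt(np.mean(x**2))


def synth_grunt(
    params: GruntSynthParams, rate: float = 44100.0, seed=0
) -> AudioRecording:
    """Render one grunt: harmonic stack plus band-limited noise.

    The harmonic component stacks integer multiples of f0 up to the band
    ceiling with a fixed dB/octave tilt and random phases; the noise
    component is FFT-band-limited white noise.  The two are mixed at the
    requested harmonic-to-noise energy ratio, Tukey-windowed, and peak-scaled
    to 0.9.
    """
    if rate < 16000:
        raise ValueError("rate must be at least 16 kHz")
    n = int(round(params.duration * rate))
    min_frames = 4 * int(round(0.005 * rate))  # four 5 ms envelope frames
    if n < min_frames:
        raise ValueError(
            f"duration {params.duration} s shorter than 4 envelope frames"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    h2n = params.harmonic_to_noise

    harm = np.zeros(n)
    if h2n > 0:
        n_harm = max(1, int(params.band[1] // params.f0))
        k = np.arange(1, n_harm + 1)
        amps = 10.0 ** (params.spectral_tilt * np.log2(k) / 20.0)
        phases = rng.uniform(0, 2 * math.pi, n_harm)
        harm = (
            amps[:, None] * np.sin(2 * math.pi * params.f0 * np.outer(k, t) + phases[:, None])
        ).sum(axis=0)
        harm /= math.sqrt(np.mean(harm**2))

    noise = np.zeros(n)
    if h2n < 1:
        noise = _shaped_noise(rng, n, rate, params.band[0], params.band[1])

    x = math.sqrt(h2n) * harm + math.sqrt(1.0 - h2n) * noise
    alpha = min(1.0, 2.0 * params.ramp / params.duration)
    x *= tukey(n, alpha)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return AudioRecording(samples=x, rate=rate, id="grunt")


def synth_background_noise(
    q25_target: float = 250.0, duration: float = 0.5, rate: float = 44100.0, seed=0
) -> AudioRecording:
    """Background-noise bed with a prescribed spectral first quartile.

    The noise is spectrally flat from 0 to 4 × ``q25_target``, so its
    cumulative normalised spectrum reaches 0.25 exactly at the target (up to
    one FFT bin).
    """
    high = 4.0 * q25_target
    if high >= rate / 2.0:
        raise ValueError(
            f"q25 target {q25_target} Hz infeasible: shaping band ceiling "
            f"{high} Hz reaches Nyquist at rate {rate}"
        )
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("duration too short")
    rng = np.random.default_rng(seed)
    x = _shaped_noise(rng, n, rate, 0.0, high)
    x *= min(0.1, 0.9 / np.max(np.abs(x)))
    return AudioRecording(samples=x, rate=rate, id="background")


# ---------------------------------------------------------------------------
# behaviour generation: semi-Markov walk over the 16-zone grid

_ZONE_IDS = np.arange(1, 17)
_COORDS = {z: ((z - 1) // 4, (z - 1) % 4) for z in _ZONE_IDS}
_NEAR_C = (5, 9)    # left wall, middle rows
_NEAR_H = (8, 12)   # right wall, middle rows


def _door_dist(zone: int, door_zones: tuple[int, ...]) -> int:
    r, c = _COORDS[zone]
    return min(abs(r - _COORDS[d][0]) + abs(c - _COORDS[d][1]) for d in door_zones)


def _neighbours(zone: int) -> list[int]:
    r, c = _COORDS[zone]
    out = []
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < 4 and 0 <= cc < 4:
            out.append(rr * 4 + cc + 1)
    return out


@dataclass
class PhaseContext:
    """Condition of one piglet × trial × phase."""

    piglet: int
    trial: int
    phase: int
    partner: str
    treatment: str
    duration: float


def simulate_behaviour_phase(
    ctx: PhaseContext, effects: EffectConfig, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Generate the behaviour events of one phase.

    Zone occupancy is a semi-Markov walk over the 4 × 4 grid whose
    transitions are biased toward the doors: a baseline conspecifics-door
    preference growing over the conditioning, plus a strong bias toward the
    *upcoming* partner's door during the anticipation phase.  Watching and
    freezing are independent Poisson event channels that may overlap zone
    occupancy.  Returns the event rows and the realised per-minute ground
    truth.
    """
    dur = ctx.duration
    rng = _rng(seed, _BEHAVIOUR, ctx.piglet, ctx.trial, _PHASE_CODE[ctx.phase])

    attract_c = 1.0 + effects.door_preference_effect * (ctx.trial / 12.0)
    attract_h = 1.0
    dwell_boost = set()
    if ctx.phase == 0:
        boost = 4.0 * effects.anticipation_behaviour_effect
        if ctx.partner == "C":
            attract_c += boost
            dwell_boost = set(_NEAR_C)
        else:
            attract_h += boost
            dwell_boost = set(_NEAR_H)

    log_ac, log_ah = math.log(attract_c), math.log(attract_h)

    def weight(zone: int) -> float:
        return math.exp(
            -0.5 * log_ac * _door_dist(zone, _NEAR_C)
            - 0.5 * log_ah * _door_dist(zone, _NEAR_H)
        )

    rows = []
    t = 0.0
    zone = int(rng.choice([1, 2, 3, 4]))  # entrance wall
    while t < dur:
        mean_dwell = 3.0
        if zone in dwell_boost:
            mean_dwell *= 1.0 + 2.0 * effects.anticipation_behaviour_effect
        stay = rng.exponential(mean_dwell)
        stop = min(t + stay, dur)
        rows.append(
            {
                "piglet": ctx.piglet,
                "trial": ctx.trial,
                "phase": ctx.phase,
                "event_type": "zone",
                "start_s": t,
                "stop_s": stop,
                "zone_id": zone,
            }
        )
        t = stop
        if t >= dur:
            break
        nbs = _neighbours(zone)
        w = np.array([weight(nb) for nb in nbs])
        zone = int(rng.choice(nbs, p=w / w.sum()))

    def poisson_intervals(rate_per_min: float, mean_len: float) -> list[tuple]:
        raw = []
        for _ in range(rng.poisson(rate_per_min * dur / 60.0)):
            start = rng.uniform(0, dur)
            stop = min(start + rng.exponential(mean_len), dur)
            if stop > start:
                raw.append((start, stop))
        # a state channel cannot be active twice at once: merge overlaps
        merged: list[list[float]] = []
        for start, stop in sorted(raw):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], stop)
            else:
                merged.append([start, stop])
        return [tuple(m) for m in merged]

    for door, base_rate in (("c", 2.0), ("h", 2.0)):
        rate = base_rate
        if ctx.phase == 0 and ctx.partner.lower() == door:
            rate *= 1.0 + 3.0 * effects.anticipation_behaviour_effect
        for start, stop in poisson_intervals(rate, 1.2):
            rows.append(
                {
                    "piglet": ctx.piglet,
                    "trial": ctx.trial,
                    "phase": ctx.phase,
                    "event_type": f"watch_{door}",
                    "start_s": start,
                    "stop_s": stop,
                    "zone_id": np.nan,
                }
            )

    for start, stop in poisson_intervals(1.0, 2.0):
        rows.append(
            {
                "piglet": ctx.piglet,
                "trial": ctx.trial,
                "phase": ctx.phase,
                "event_type": "freeze",
                "start_s": start,
                "stop_s": stop,
                "zone_id": np.nan,
            }
        )

    events = pd.DataFrame(rows)

    per_min = 60.0 / dur
    zones = events[events["event_type"] == "zone"]
    zdur = (zones["stop_s"] - zones["start_s"]).to_numpy()
    zid = zones["zone_id"].astype(int)
    n_zones = int(zid.nunique())
    time_c = float(zdur[zid.isin(_NEAR_C)].sum())
    time_h = float(zdur[zid.isin(_NEAR_H)].sum())
    upcoming_watch = f"watch_{ctx.partner.lower()}"
    watches = events[events["event_type"] == upcoming_watch]
    freezes = events[events["event_type"] == "freeze"]
    truth = {
        "piglet": ctx.piglet,
        "trial": ctx.trial,
        "phase": ctx.phase,
        "freezing_time": float((freezes["stop_s"] - freezes["start_s"]).sum()) * per_min,
        "avg_time_per_zone": dur / n_zones if n_zones else math.nan,
        "n_zones_explored": n_zones * per_min,
        "watch_door_time": float((watches["stop_s"] - watches["start_s"]).sum()) * per_min,
        "watch_door_count": len(watches) * per_min,
        "near_door_time": (time_c if ctx.partner == "C" else time_h) * per_min,
        "near_c_door_time": time_c * per_min,
        "near_h_door_time": time_h * per_min,
    }
    return events, truth


# ---------------------------------------------------------------------------
# full study assembly

_MIN_GAP = 0.75          # s; keeps rendered calls clear of each other
_MIN_DURATION = 0.08     # s
_MAX_DURATION = 0.55     # s
_FIRST_ONSET = 0.1       # s


@dataclass
class StudyDataset:
    """All tables of one simulated study, plus deterministic audio rendering.

    Audio is rendered on demand (per call or per trial-phase clip) from the
    ground-truth parameters, so datasets stay light until written out.
    """

    design: StudyDesign
    effects: EffectConfig
    seed: int
    design_table: pd.DataFrame
    phases: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame
    behaviour: pd.DataFrame
    behaviour_truth: pd.DataFrame

    def _truth_row(self, call_id: str) -> pd.Series:
        if not hasattr(self, "_call_index"):
            self._call_index = {
                cid: i for i, cid in enumerate(self.truth["call_id"])
            }
        try:
            return self.truth.iloc[self._call_index[call_id]]
        except KeyError:
            raise KeyError(f"unknown call id {call_id!r}") from None

    def render_call(self, call_id: str, pad: float = 0.05) -> AudioRecording:
        """The annotated call window plus ``pad`` seconds of background."""
        row = self._truth_row(call_id)
        idx = int(row.call_index)
        grunt = synth_grunt(
            GruntSynthParams(
                duration=float(row.duration_s),
                f0=float(row.f0_hz),
                harmonic_to_noise=float(row.harmonic_to_noise),
            ),
            rate=self.design.rate,
            seed=[self.seed, _RENDER, idx],
        )
        bed = synth_background_noise(
            self.design.background_q25,
            duration=float(row.duration_s) + 2 * pad,
            rate=self.design.rate,
            seed=[self.seed, _BED, idx],
        )
        x = bed.samples * 0.004 / math.sqrt(np.mean(bed.samples**2))
        start = int(round(pad * self.design.rate))
        x[start : start + grunt.samples.size] += grunt.samples
        return AudioRecording(samples=x, rate=self.design.rate, id=call_id)

    def render_clip(self, piglet: int, trial: int, phase: int) -> AudioRecording:
        """The full trial-phase clip with every call at its annotated onset."""
        ph = self.phases[
            (self.phases.piglet == piglet)
            & (self.phases.trial == trial)
            & (self.phases.phase == phase)
        ]
        if ph.empty:
            raise KeyError(f"no phase ({piglet}, {trial}, {phase})")
        dur = float(ph.iloc[0].duration_s)
        rate = self.design.rate
        bed = synth_background_noise(
            self.design.background_q25,
            duration=dur,
            rate=rate,
            seed=[self.seed, _BED, piglet, trial, _PHASE_CODE[phase]],
        )
        x = bed.samples * 0.004 / math.sqrt(np.mean(bed.samples**2))
        calls = self.truth[
            (self.truth.piglet == piglet)
            & (self.truth.trial == trial)
            & (self.truth.phase == phase)
        ]
        for row in calls.itertuples():
            grunt = synth_grunt(
                GruntSynthParams(
                    duration=float(row.duration_s),
                    f0=float(row.f0_hz),
                    harmonic_to_noise=float(row.harmonic_to_noise),
                ),
                rate=rate,
                seed=[self.seed, _RENDER, int(row.call_index)],
            )
            start = int(round(row.onset_s * rate))
            stop = min(start + grunt.samples.size, x.size)
            x[start:stop] += grunt.samples[: stop - start]
        clip_id = f"p{piglet:02d}_t{trial:02d}_ph{phase}"
        return AudioRecording(samples=x, rate=rate, id=clip_id)

    def save(self, outdir: str | Path, audio: bool = False) -> None:
        """Write the CSV tables (and optionally every trial-phase WAV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.design_table.to_csv(outdir / "design.csv", index=False)
        self.phases.to_csv(outdir / "phases.csv", index=False)
        self.annotations.to_csv(outdir / "annotations.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.behaviour.to_csv(outdir / "behaviour.csv", index=False)
        self.behaviour_truth.to_csv(outdir / "behaviour_truth.csv", index=False)
        if audio:
            wavdir = outdir / "audio"
            wavdir.mkdir(exist_ok=True)
            for _, ph in self.phases.iterrows():
                clip = self.render_clip(ph.piglet, ph.trial, ph.phase)
                write_wav(clip, wavdir / f"{clip.id}.wav")


def _phase_durations(design: StudyDesign, piglet: int, trial: int, seed: int) -> dict:
    durations = {}
    for phase in design.phases_of_trial(trial):
        if phase == -1:
            rng = _rng(seed, _ONSET, piglet, trial, _PHASE_CODE[-1], 99)
            durations[-1] = float(rng.uniform(*design.phase_m1_range))
        elif phase == 0:
            durations[0] = design.phase0_duration
        else:
            durations[phase] = design.delayed_phase_duration
    return durations


def _grunt_onsets(
    target_igi: float, duration: float, rng: np.random.Generator, igi_log_sd: float
) -> np.ndarray:
    onsets = []
    t = _FIRST_ONSET + rng.uniform(0.0, max(target_igi / 2, _MIN_GAP))
    while t + _MAX_DURATION + 0.1 <= duration:
        onsets.append(t)
        gap = target_igi * rng.lognormal(-(igi_log_sd**2) / 2.0, igi_log_sd)
        t += max(gap, _MIN_GAP)
    return np.asarray(onsets)


def simulate_study(
    design: StudyDesign | None = None,
    effects: EffectConfig | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Generate one full synthetic study.

    Deterministic for a given (design, effects, seed); every generated call
    has an annotation row, and the per-grunt target parameters (the means
    the draws came from) are exported in the truth table for recovery and
    effect-propagation tests.
    """
    design = design or StudyDesign()
    effects = effects or EffectConfig()

    design_rows = []
    phase_rows = []
    ann_rows = []
    truth_rows = []
    behaviour_frames = []
    behaviour_truth_rows = []
    call_index = 0

    block_of = {t: b for b, ts in TRIAL_BLOCKS.items() for t in ts}

    for piglet in range(design.n_piglets):
        prng = _rng(seed, _PIGLET, piglet)
        dur_intercept = prng.normal(0.0, effects.piglet_random_sd)
        h2n_intercept = prng.normal(0.0, effects.piglet_random_sd)
        igi_intercept = prng.normal(0.0, effects.igi_piglet_sd)
        voice_f0 = prng.uniform(260.0, 420.0)
        treatment = design.treatment(piglet)
        replicate = design.replicate(piglet)
        pen = design.pen(piglet)

        for trial in design.behaviour_trials:
            partner = design.partner(piglet, trial)
            analysed = trial in design.trials_analysed
            design_rows.append(
                {
                    "piglet": piglet,
                    "pen": pen,
                    "replicate": replicate,
                    "treatment": treatment,
                    "partner": partner,
                    "trial": trial,
                    "trial_block": block_of[trial],
                    "analysed": analysed,
                }
            )
            durations = _phase_durations(design, piglet, trial, seed)
            phases = design.phases_of_trial(trial) if analysed else [-1]
            for phase in phases:
                dur = durations[phase]
                phase_rows.append(
                    {
                        "piglet": piglet,
                        "trial": trial,
                        "phase": phase,
                        "duration_s": dur,
                        "partner": partner,
                        "treatment": treatment,
                        "replicate": replicate,
                        "trial_block": block_of[trial],
                    }
                )
                ctx = PhaseContext(piglet, trial, phase, partner, treatment, dur)
                events, btruth = simulate_behaviour_phase(ctx, effects, seed)
                behaviour_frames.append(events)
                behaviour_truth_rows.append(btruth)

                if not analysed:
                    continue

                # --- vocal output of this phase ---
                pc = _PHASE_CODE[phase]
                if phase == 0:
                    target_igi = effects.igi_anticipation + igi_intercept
                    if partner == "C":
                        target_igi -= effects.igi_partner_effect
                else:
                    target_igi = effects.base_igi + igi_intercept
                target_igi = max(target_igi, 1.2)

                rng_on = _rng(seed, _ONSET, piglet, trial, pc)
                onsets = _grunt_onsets(target_igi, dur, rng_on, effects.igi_log_sd)
                n = onsets.size

                mu_logdur = math.log(effects.median_duration) + dur_intercept
                if phase == 0 and partner == "H":
                    mu_logdur += math.log(effects.duration_anticipation_H)
                if phase in (1, 2, 3):
                    mu_logdur += math.log(effects.duration_delay_effect)
                if partner == "H" and treatment == "H":
                    mu_logdur += math.log(effects.treatment_duration_effect)
                rng_dur = _rng(seed, _DURATION, piglet, trial, pc)
                durations_g = np.clip(
                    np.exp(mu_logdur + rng_dur.normal(0, effects.residual_sd, n)),
                    _MIN_DURATION,
                    _MAX_DURATION,
                )

                mu_logit = h2n_intercept
                if phase == 0 and partner == "C":
                    mu_logit += effects.noisiness_anticipation_C
                rng_h2n = _rng(seed, _NOISINESS, piglet, trial, pc)
                h2n = np.clip(
                    expit(mu_logit + rng_h2n.normal(0, effects.h2n_residual_sd, n)),
                    0.02,
                    0.98,
                )

                rng_f0 = _rng(seed, _F0, piglet, trial, pc)
                f0 = voice_f0 * np.exp(rng_f0.normal(0, 0.05, n))

                clip_id = f"p{piglet:02d}_t{trial:02d}_ph{phase}"
                for j in range(n):
                    call_id = f"{clip_id}_g{j:02d}"
                    ann_rows.append(
                        {
                            "clip_id": clip_id,
                            "call_id": call_id,
                            "piglet": piglet,
                            "trial": trial,
                            "phase": phase,
                            "onset_s": onsets[j],
                            "offset_s": onsets[j] + durations_g[j],
                            "type": "grunt",
                        }
                    )
                    truth_rows.append(
                        {
                            "call_index": call_index,
                            "call_id": call_id,
                            "clip_id": clip_id,
                            "piglet": piglet,
                            "trial": trial,
                            "phase": phase,
                            "partner": partner,
                            "treatment": treatment,
                            "replicate": replicate,
                            "onset_s": onsets[j],
                            "duration_s": durations_g[j],
                            "f0_hz": f0[j],
                            "harmonic_to_noise": h2n[j],
                            "mu_log_duration": mu_logdur,
                            "mu_logit_h2n": mu_logit,
                            "target_igi": target_igi,
                        }
                    )
                    call_index += 1

    return StudyDataset(
        design=design,
        effects=effects,
        seed=seed,
        design_table=pd.DataFrame(design_rows),
        phases=pd.DataFrame(phase_rows),
        annotations=pd.DataFrame(ann_rows),
        truth=pd.DataFrame(truth_rows),
        behaviour=pd.concat(behaviour_frames, ignore_index=True),
        behaviour_truth=pd.DataFrame(behaviour_truth_rows),
    )
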