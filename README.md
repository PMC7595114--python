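# gruntline

Spectro-temporal analysis of piglet grunts during the anticipation of
pseudo-social rewards.

Piglets that have learned that a stimulus announces the arrival of either
their pen mates (partner *C*) or a familiar human (partner *H*) express
that anticipation vocally: the rate, duration and spectral structure of
their grunts shift with the expected partner, and shift again when the
partner's arrival is delayed. `gruntline` is a reusable implementation of
the full analysis chain for such experiments, aimed at bioacousticians and
animal-welfare researchers:

- **audio_io** — WAV I/O, 0.2–8 kHz linear-phase FIR band-pass (zero net
  delay), amplitude normalisation, background-noise spectral profiling
  (Q25).
- **segmentation** — call-boundary refinement by the 5 % amplitude-envelope
  threshold ("timer" rule); inter-grunt-interval (IGI) rhythm.
- **features** — per-grunt mean spectrum (Hamming STFT, window 512, 50 %
  overlap) summarised as a PMF over frequency: mean/median/mode/quartiles/
  centroid, Shannon spectral entropy *sh*, spectral flatness *sfm*,
  combined spectro-temporal entropy *H*, dominant frequency; spectral
  dissimilarity `D = ½ Σ|p₁ − p₂|` between context mean spectra.
- **ethogram** — six per-minute behaviour variables over a 16-zone room
  grid, each relative to the upcoming partner's door.
- **scoring** — Fisher discriminant scores (two behavioural, one acoustic)
  fitted on the pre-stimulus and anticipation phases only and *projected*
  onto the delayed phases, with pooled within-group standardisation, sign
  anchors, and a ridge that tolerates the exact mean = centroid
  collinearity.
- **stats** — linear mixed models (random intercept per piglet, REML),
  per-term Wald chi-square ANOVA, Tukey-adjusted estimated-marginal-mean
  contrasts, and `run_full_analysis` for the complete recipe (score
  models, phase-0 IGI model, door-preference trial-block model, per-phase
  spectral dissimilarity, machine-readable sign-pattern summary).
- **synthetic_data** — a deterministic generator that emulates the study
  design (60 piglets, 2 replicates, treatments H/H+, trials 10–12 with a
  20 s anticipation phase and three 30 s delayed phases), rendering grunts
  as harmonic-plus-noise audio with configurable condition effects and
  exporting the full ground truth, so every stage is testable with no
  recorded data.

See `docs/methods.md` for the model, parameter and design details.

## Worked example

```python
import gruntline as gl

# a full synthetic study with the default (expected-direction) effects
dataset = gl.simulate_study(seed=1)
results = gl.run_full_analysis(dataset)

print(results.acoustic_model.loadings_table().round(2))
sp = results.sign_pattern
print(f"grunts analysed:        {sp['n_grunts']}")
print(f"phase-0 IGI, C minus H: {sp['igi_c_minus_h_phase0']:.2f} s "
      f"(p = {sp['igi_partner_p']:.2e})")
print(f"log-duration, H 0 vs -1: +{sp['duration_h_phase0_minus_m1']:.2f} "
      f"(Tukey p = {sp['duration_h_phase0_minus_m1_p']:.2e})")
print(f"spectral dissimilarity D(phase 0) = {sp['diffspec']['0']:.3f}")
```

prints (seed 1):

```
            LD1
mean       0.40
median     0.13
mode      -0.24
q25        0.39
q75       -0.12
centroid   0.40
sh         0.42
sfm       -0.01
entropy_h -0.59
grunts analysed:        2561
phase-0 IGI, C minus H: -1.58 s (p = 2.07e-28)
log-duration, H 0 vs -1: +0.24 (Tukey p = 1.31e-20)
spectral dissimilarity D(phase 0) = 0.054
```

Reading this: piglets grunt ~1.6 s faster (shorter inter-grunt interval)
when anticipating conspecifics; grunts on human trials lengthen by ~27 %
(e^0.24) during the anticipation phase; and the between-partner spectral
dissimilarity peaks in phase 0 — the anticipation-specific vocal
signature the analysis is designed to detect. The acoustic discriminant
weights the entropy measures against the spectral moments, with the
identical mean and centroid columns receiving identical loadings.

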