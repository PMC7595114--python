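# Methods

## The analysis this package implements

Weaned piglets conditioned to associate an audio-visual stimulus with the
arrival of a pseudo-social partner — either pen mates (partner **C**) or a
familiar human (partner **H**) — express their anticipation both spatially
and vocally. The pipeline quantifies that expression from three inputs: the
audio of each trial phase with a call-annotation table, a behaviour event
log, and the trial design. Its stages are:

1. **Preprocessing** (`audio_io`). All acoustic measurements run on a
   0.2–8 kHz band-passed, peak-normalised signal. The filter is a
   windowed-sinc (Hamming) linear-phase FIR, 1 025 taps at 44.1 kHz and
   scaled proportionally at other rates, applied centred so it adds no net
   group delay: call boundaries stay aligned with annotation times. The
   200 Hz floor sits above the background noise's first spectral quartile
   (Q25 ≈ 250 Hz for the modelled room noise), so nothing below it is
   interpreted. Background noise is profiled from 20 fragments of 0.5 s by
   averaging Hamming-frame magnitude spectra.

2. **Boundary refinement and rhythm** (`segmentation`). Within each
   annotated call window, the call is the longest contiguous run where the
   amplitude envelope (moving average of the rectified signal, 5 ms window)
   stays at or above 5 % of its maximum; duration is the length of that
   run. All duration tolerances in the tests are stated in units of this
   5 ms envelope frame. Grunt rhythm is the mean inter-grunt interval
   (IGI), onset-to-onset — a convention chosen because it is robust to the
   duration effects the pipeline itself studies; it is only defined for
   phases with at least two grunts (otherwise missing, never zero).

3. **Spectral descriptors** (`features`). Each grunt's mean spectrum is
   the average magnitude STFT (Hamming, window 512, 50 % overlap),
   band-limited and renormalised to a unit-sum PMF over frequency. From it:
   mean, median, mode, Q25, Q75, IQR, centroid (all Hz), normalised Shannon
   spectral entropy `sh`, spectral flatness `sfm` (geometric/arithmetic
   mean), and `entropy_h = sh × th` where `th` is the normalised entropy of
   the Hilbert amplitude envelope. Dominant frequency is the per-frame
   spectral peak averaged over the call (kHz). Spectra are linear
   magnitude, not power, so the quantile semantics match the seminal
   bioacoustic toolchains. **mean and centroid are definitionally
   identical**; both are computed, exported and fed to the acoustic score,
   so the scoring stage must tolerate exact collinearity (see below).
   Between-context spectral dissimilarity is
   `D = ½ Σ|p₁ᵢ − p₂ᵢ|` on spectra renormalised within 0.2–2 kHz (the
   grunts' main energy range); D is a proper metric bounded in [0, 1].

4. **Ethogram variables** (`ethogram`). The room is a 4×4 grid of 16
   zones; the C and H doors each touch two (configurable) zones. Six
   variables per piglet × trial × phase, computed relative to the
   *upcoming* partner's door and standardised per minute (× 60 / phase
   duration): freezing time, average time per zone (seconds: phase
   duration / zones visited), zones explored, door-watching time and
   count, and near-door time. Door-specific occupancy times are kept
   separately for the door-preference analysis. Ethogram states are
   independent channels and may overlap.

5. **Discriminant scores** (`scoring`). Two behavioural axes (LD1bev,
   LD2bev; per-phase rows) and one acoustic axis (LD1ac; per-grunt rows)
   are Fisher discriminants fitted **only on phases −1 and 0**,
   discriminating the crossed phase × treatment × partner factor (8
   groups). Delayed phases 1–3 are never refit — they are projected onto
   the stored axes, which is what makes them a negative control: if the
   delayed state resembled anticipation, its projected scores would, too.
   Variables are centred and scaled by the pooled within-group SD before
   axis extraction so loadings are comparable across variables; whether
   the original analysis standardised is not documented anywhere, so this
   contract is the package's own definition and is stated here
   deliberately. Exact collinearity (mean = centroid) is handled by a
   ridge of 1e-8 × mean diagonal on the within-group covariance; the fit
   is deterministic, and projections agree with a fit on de-duplicated
   inputs to < 1e-6. Axis signs are fixed by anchors (near-door time
   negative on the behavioural axes, `entropy_h` negative on the acoustic
   axis) so reported loading signs are reproducible.

6. **Mixed models** (`stats`). Each response (the three scores, log grunt
   duration, mean IGI, near-door time) gets a linear mixed model with a
   random intercept per piglet (REML), fixed effects being the two-way
   interactions among phase, partner and treatment plus replicate × partner
   and replicate × treatment. The IGI model is restricted to the
   anticipation phase (its value depends strongly on the number of grunts,
   which the 20 s fixed window controls) and to piglets with ≥ 2 grunts
   there. The door-preference model uses phase −1 occupancy over
   conditioning trial blocks (beginning 2–4, middle 6–8, end 10–12) with a
   trial_block × partner × treatment three-way interaction. Factors are
   **sum-to-zero coded** and the ANOVA is a per-term joint Wald chi-square;
   in the balanced designs generated here this coincides with the
   conventional Type-II car-style table. Post hoc comparisons are estimated
   marginal means over a factor grid with all pairwise differences within
   one family adjusted by the Tukey studentized-range method; degrees of
   freedom are large-sample (no Kenward–Roger-style correction — with ~60
   subjects the difference is negligible). When a contrast's Bonferroni
   bound is already below 1e-10, it is reported in place of the
   studentized-range quadrature, which is indistinguishable at that
   magnitude. The contrast family is all pairwise cells of one
   interaction's marginal grid (e.g. the 10 phase × partner cells); which
   family the original analysis pooled is not fully determinable, so the
   family is an explicit argument of `tukey_contrasts`. Residuals, fitted
   values and random effects are exported as tables for visual diagnostics
   rather than auto-judged.

## The synthetic study

`synthetic_data` generates a full in-silico replica of the experiment:
60 piglets, two replicates, pens of three, treatments H/H+ balanced over
pens; trials 10–12 analysed with phase −1 drawn uniformly on 10–30 s, a
20 s phase 0, and three 30 s delayed phases on trial 12; behaviour is also
generated for trial blocks 2–4 and 6–8 so the door-preference model has
its factor. Partners alternate across trials so every piglet meets both
among the analysed trials.

Grunts are an additive harmonic stack (f0 plus integer harmonics, −6
dB/octave tilt, random phases) mixed with 0.2–2 kHz band-limited noise at
a harmonic-to-noise energy ratio `h2n`, Tukey-windowed with 10 ms ramps,
peak 0.9, on a quiet background bed whose spectral Q25 is 250 Hz. The
ramp length matters: the 5 % timer clips ~0.14 × ramp off each edge, so a
10 ms attack keeps annotated duration and timer-measured duration within
one envelope frame. A caveat of the default analysis resolution: with a
512-point window at 44.1 kHz the main lobe (~4 bins ≈ 345 Hz) is wider
than a typical f0, so individual harmonics of low-pitched grunts are not
resolved in the default mean spectrum; `sfm` still falls monotonically
with harmonic content (rank correlation < −0.9), which is the property
the noisiness contrast uses.

Condition effects are applied to distribution parameters in log/logit
space so rendered values stay in range; defaults encode the directions
the analysis is designed to detect, at magnitudes consistent with a
duration shift from a 0.27 s median to ~0.35 s:

| parameter | default | meaning |
|---|---|---|
| `igi_partner_effect` | 1.5 s | phase-0 IGI shorter before conspecifics |
| `igi_anticipation` / `base_igi` | 5 / 6 s | mean IGI in / outside phase 0 |
| `duration_anticipation_H` | ×1.3 | longer grunts in phase 0 on H trials |
| `duration_delay_effect` | ×1.3 | longer grunts in phases 1–3 (both partners) |
| `noisiness_anticipation_C` | −1.2 logit | noisier spectra in phase 0 on C trials |
| `treatment_duration_effect` | ×1.15 | H-treatment piglets longer on H trials |
| `piglet_random_sd` / `residual_sd` | 0.15 / 0.35 | between-/within-piglet SD (log duration) |

These rates yield ~2 300–2 600 grunts per study (a handful per piglet and
phase), matching the sparse grunting the analysis has to cope with —
including phase-0 cells where a piglet grunts fewer than twice and drops
out of the rhythm model.

Behaviour is a semi-Markov walk over the zone grid with door-directed
transition bias (a conspecifics-door preference growing over the
conditioning, plus a strong bias toward the upcoming door during phase 0),
with watching and freezing as independent, overlap-merged Poisson
channels. Zone occupancy tiles each phase exactly, so the time-in-zone sum
equals the phase duration.

Every random draw comes from a generator keyed by (seed, purpose, piglet,
trial, phase). Two consequences the tests rely on: identical
configuration and seed give byte-identical datasets including rendered
audio; and switching one effect on changes only its targeted observable's
target parameters in the exported ground-truth table.

What the generator does **not** emulate: vocal-tract resonances and
formants, within-call pitch contours, call types other than grunts,
recording-chain artefacts, and any correlation between behavioural and
vocal state beyond the shared design. Passing tests therefore demonstrate
that the pipeline recovers known structure of this generative family —
not that the biological conclusions would replicate on new recordings.

## Numerical choices and degenerate inputs

- Spectral quantiles are "smallest frequency with cumulative mass ≥ q";
  the spectral mode breaks ties toward the lowest frequency.
- Grunts shorter than one FFT window are zero-padded to 512 samples and
  flagged in the feature table rather than dropped.
- Log duration uses the natural log (any base is a monotone rescaling; the
  tests do not depend on it).
- A clip whose annotation window contains several supra-threshold bursts
  keeps the longest run and emits a warning, preserving the
  one-row-per-annotation contract.
- `fit_lda` refuses groups with fewer than two rows (naming them) and
  variables with zero within-group variance.
- `fit_lmm` refuses aliased fixed-effect designs (naming the columns) and
  non-finite fits; boundary fits with a zero random-effect variance are
  returned (the degenerate limit in which the estimates equal OLS).
- The timer cannot fail to cross its threshold for thresholds < 1 (the
  envelope maximum itself qualifies); silence is rejected earlier.

## Problem sizes used by the test suite

Unit tests run on 12-piglet studies; the acceptance suite uses the full
60-piglet design: 20 replicate studies with default effects and 10 with
all effects zeroed for the direction-pattern and false-positive checks,
500/100 replicates for mixed-model Type-I calibration and planted-effect
recovery, and 200 grunts for timer recovery. `scripts/acceptance.py`
repeats the same computations at 200/50 calibration replicates and one
full study. The zero-effect check is read per test family: across the
monitored interaction terms and replicates, the rejection rate at α = 0.05
must stay at or below 10 %.

## Known limitations

- The Wald chi-square ANOVA is asymptotic and mildly liberal (empirical
  Type-I error ≈ 0.05–0.06 at 60 subjects); a parametric-bootstrap or
  Kenward–Roger refit would be the conservative alternative.
- Tukey adjustment uses the studentized-range distribution, which is exact
  for balanced one-way families; for the crossed families here it is the
  standard approximation, not an exact multivariate-t computation.
- The acoustic score is fitted on per-grunt rows, so piglets contributing
  more grunts weigh more in the discriminant; the mixed model downstream
  (random intercept per piglet) absorbs this for inference but the axis
  itself is observation-weighted.
- No de-novo call detection: call windows come from the annotation table,
  as in a manually annotated study.
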