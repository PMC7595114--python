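import numpy as np
import pandas as pd
import pytest

from gruntline import (
    EffectConfig,
    GruntSynthParams,
    StudyDesign,
    simulate_behaviour_phase,
    simulate_study,
    synth_background_noise,
    synth_grunt,
)
from gruntline.synthetic_data import ConfigurationError, PhaseContext


class TestDesign:
    def test_invalid_piglet_count(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(n_piglets=0)
        with pytest.raises(ConfigurationError):
            StudyDesign(n_piglets=13)

    def test_every_piglet_meets_both_partners(self, small_design):
        for piglet in range(small_design.n_piglets):
            partners = {
                small_design.partner(piglet, t)
                for t in small_design.trials_analysed
            }
            assert partners == {"C", "H"}

    def test_phase_structure(self, small_dataset):
        ph = small_dataset.phases
        analysed = ph[ph.trial.isin((10, 11, 12))]
        delayed = analysed[analysed.phase > 0]
        assert set(delayed.trial) == {12}
        m1 = analysed[analysed.phase == -1]
        assert ((m1.duration_s >= 10.0) & (m1.duration_s <= 30.0)).all()
        assert (analysed[analysed.phase == 0].duration_s == 20.0).all()
        assert (delayed.duration_s == 30.0).all()


class TestSynthGrunt:
    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError, match="envelope frames"):
            synth_grunt(GruntSynthParams(duration=0.01), seed=1)

    def test_low_rate_raises(self):
        with pytest.raises(ValueError):
            synth_grunt(GruntSynthParams(duration=0.3), rate=8000, seed=1)

    def test_peak_bounded(self):
        g = synth_grunt(GruntSynthParams(duration=0.3), seed=1)
        assert np.max(np.abs(g.samples)) <= 1.0

    def test_pure_harmonic_line_spectrum(self):
        from gruntline import mean_spectrum, spectral_properties

        g = synth_grunt(
            GruntSynthParams(duration=0.4, f0=300.0, harmonic_to_noise=1.0), seed=2
        )
        # a 4096-point window resolves the 300 Hz line spacing (the default
        # 512 window's main lobe is wider than f0 and blurs the lines)
        spec = mean_spectrum(g, window=4096, band=(200.0, 2000.0))
        props = spectral_properties(spec)
        assert props.sfm < 0.2
        peaks = spec.frequencies[spec.amplitudes > 0.3 * spec.amplitudes.max()]
        assert all(min(abs(p - 300.0 * k) for k in range(1, 7)) < 22.0 for p in peaks)

    def test_pure_noise_flat_spectrum(self):
        from gruntline import mean_spectrum, spectral_properties

        g = synth_grunt(
            GruntSynthParams(duration=0.4, harmonic_to_noise=0.0), seed=3
        )
        props = spectral_properties(mean_spectrum(g, band=(200.0, 2000.0)))
        assert props.sfm > 0.8

    def test_energy_above_8khz_negligible(self):
        g = synth_grunt(GruntSynthParams(duration=0.3), seed=4)
        spec = np.abs(np.fft.rfft(g.samples)) ** 2
        freqs = np.fft.rfftfreq(g.samples.size, 1 / g.rate)
        assert spec[freqs > 8000].sum() < 0.01 * spec.sum()


class TestBackgroundNoise:
    def test_sample_count(self):
        bed = synth_background_noise(duration=0.5, rate=44100, seed=1)
        assert bed.samples.size == 22050

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError):
            synth_background_noise(q25_target=6000.0, rate=44100, seed=1)


class TestDeterminism:
    def test_identical_seed_identical_tables(self, small_design):
        a = simulate_study(small_design, seed=7)
        b = simulate_study(small_design, seed=7)
        for name in ("annotations", "truth", "behaviour", "phases"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_identical_seed_identical_audio(self, small_design):
        a = simulate_study(small_design, seed=7)
        b = simulate_study(small_design, seed=7)
        cid = a.truth.call_id.iloc[10]
        assert np.array_equal(a.render_call(cid).samples, b.render_call(cid).samples)

    def test_different_seed_differs(self, small_design):
        a = simulate_study(small_design, seed=7)
        b = simulate_study(small_design, seed=8)
        assert not a.truth.duration_s.equals(b.truth.duration_s)


class TestAnnotationsAndTruth:
    def test_every_grunt_annotated(self, small_dataset):
        assert set(small_dataset.truth.call_id) == set(
            small_dataset.annotations.call_id
        )

    def test_calls_within_phase_bounds(self, small_dataset):
        merged = small_dataset.annotations.merge(
            small_dataset.phases, on=["piglet", "trial", "phase"]
        )
        assert (merged.onset_s >= 0).all()
        assert (merged.offset_s <= merged.duration_s).all()

    def test_igi_effect_direction_in_truth(self):
        ds = simulate_study(StudyDesign(n_piglets=12), seed=3)
        phase0 = ds.truth[ds.truth.phase == 0]
        mean_c = phase0[phase0.partner == "C"].target_igi.mean()
        mean_h = phase0[phase0.partner == "H"].target_igi.mean()
        assert mean_c < mean_h

    def test_render_clip_covers_whole_phase(self, small_dataset):
        row = small_dataset.phases.iloc[0]
        clip = small_dataset.render_clip(row.piglet, row.trial, row.phase)
        assert clip.duration == pytest.approx(row.duration_s, abs=1e-3)


def condition_targets(ds, column):
    """Map condition cell -> unique target parameter value(s)."""
    return (
        ds.truth.groupby(["phase", "partner", "treatment"])[column]
        .mean()
        .round(10)
    )


class TestEffectPropagation:
    """A single effect must move only its targeted observable's targets."""

    def test_igi_effect_leaves_duration_and_noisiness_targets(self):
        design = StudyDesign(n_piglets=12)
        base = simulate_study(design, EffectConfig.zero(), seed=5)
        mod = simulate_study(
            design, EffectConfig.zero(igi_partner_effect=2.0), seed=5
        )
        # per-piglet duration/noisiness targets are untouched
        for col in ("mu_log_duration", "mu_logit_h2n"):
            a = base.truth.groupby(["piglet", "phase"])[col].first()
            b = mod.truth.groupby(["piglet", "phase"])[col].first()
            assert np.allclose(a, b)
        assert not np.allclose(
            condition_targets(base, "target_igi"), condition_targets(mod, "target_igi")
        )

    def test_duration_effect_targets_duration_only(self):
        design = StudyDesign(n_piglets=12)
        base = simulate_study(design, EffectConfig.zero(), seed=5)
        mod = simulate_study(
            design, EffectConfig.zero(duration_anticipation_H=1.5), seed=5
        )
        a = base.truth.groupby(["piglet", "phase"])["target_igi"].first()
        b = mod.truth.groupby(["piglet", "phase"])["target_igi"].first()
        assert np.allclose(a, b)
        h0_base = base.truth.query("phase == 0 and partner == 'H'").mu_log_duration
        h0_mod = mod.truth.query("phase == 0 and partner == 'H'").mu_log_duration
        assert np.allclose(h0_mod.mean() - h0_base.mean(), np.log(1.5))
        other_base = base.truth.query("phase != 0").mu_log_duration.mean()
        other_mod = mod.truth.query("phase != 0").mu_log_duration.mean()
        assert np.allclose(other_base, other_mod)

    def test_noisiness_effect_shifts_logit_target(self):
        design = StudyDesign(n_piglets=12)
        base = simulate_study(design, EffectConfig.zero(), seed=5)
        mod = simulate_study(
            design, EffectConfig.zero(noisiness_anticipation_C=-1.0), seed=5
        )
        c0_shift = (
            mod.truth.query("phase == 0 and partner == 'C'").mu_logit_h2n.mean()
            - base.truth.query("phase == 0 and partner == 'C'").mu_logit_h2n.mean()
        )
        assert c0_shift == pytest.approx(-1.0)


class TestBehaviourPhase:
    def ctx(self, **kw):
        base = dict(
            piglet=0, trial=10, phase=0, partner="C", treatment="H", duration=20.0
        )
        base.update(kw)
        return PhaseContext(**base)

    def test_events_within_bounds(self):
        events, _ = simulate_behaviour_phase(self.ctx(), EffectConfig(), seed=1)
        assert (events.start_s >= 0).all()
        assert (events.stop_s <= 20.0 + 1e-9).all()
        zones = events[events.event_type == "zone"]
        assert zones.zone_id.astype(int).between(1, 16).all()

    def test_door_preference_direction(self):
        effects = EffectConfig.zero(door_preference_effect=4.0)
        time_c = time_h = 0.0
        for s in range(30):
            _, truth = simulate_behaviour_phase(
                self.ctx(phase=-1, duration=30.0, piglet=s), effects, seed=s
            )
            time_c += truth["near_c_door_time"]
            time_h += truth["near_h_door_time"]
        assert time_c > time_h

    def test_null_door_symmetry(self):
        effects = EffectConfig.zero()
        time_c = time_h = 0.0
        for s in range(60):
            _, truth = simulate_behaviour_phase(
                self.ctx(phase=-1, duration=30.0, piglet=s), effects, seed=s
            )
            time_c += truth["near_c_door_time"]
            time_h += truth["near_h_door_time"]
        assert abs(time_c - time_h) / (time_c + time_h + 1e-9) < 0.25


class TestNullFeatureRecovery:
    def test_zero_effects_leave_features_null(self):
        """With no condition effects, phase-0 C vs H grunt targets differ
        only by sampling noise (t-test non-significant in most replicates)."""
        from scipy.stats import ttest_ind

        hits = 0
        n_rep = 12
        for s in range(n_rep):
            ds = simulate_study(StudyDesign(n_piglets=12), EffectConfig.zero(), seed=40 + s)
            ph0 = ds.truth[ds.truth.phase == 0]
            for col in ("duration_s", "harmonic_to_noise"):
                p = ttest_ind(
                    ph0[ph0.partner == "C"][col], ph0[ph0.partner == "H"][col]
                ).pvalue
                hits += p < 0.05
        assert hits <= 0.15 * (2 * n_rep)


def test_save_writes_tables(tmp_path, small_dataset):
    small_dataset.save(tmp_path)
    for name in (
        "design.csv",
        "phases.csv",
        "annotations.csv",
        "truth.csv",
        "behaviour.csv",
        "behaviour_truth.csv",
    ):
        assert (tmp_path / name).exists()
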