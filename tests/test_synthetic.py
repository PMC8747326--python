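"""Generator tests: geometry, marker structure, determinism, cohort layout."""

import numpy as np
import pytest

from tcmdetect import (
    DEFAULT_EXERCISES,
    ExerciseSpec,
    SensorModel,
    SubjectProfile,
    generate_cohort,
    generate_session,
    simulate_repetition,
    tilt_angle,
)
from tcmdetect.synthetic import TiltWaveform, AxisEffect, default_exercise


def flat_spec(baselines=(0.0, 0.0, 0.0), amplitudes=(0.0, 0.0, 0.0), tcm=()):
    return ExerciseSpec(
        name="prone_rocking",
        rep_duration_mean=2.0,
        rep_duration_cv=0.0,
        tilt_waveforms=tuple(
            TiltWaveform(b, a) for b, a in zip(baselines, amplitudes)
        ),
        tcm_effects=tuple(tcm),
    )


QUIET = SensorModel(noise_sd=0.0)
G = 9.81


class TestSimulateRepetition:
    def test_static_aligned_sensor_reads_plus_g(self):
        """Zero-amplitude waveforms at 0 deg baseline: A_Z = +g, tilt 0."""
        seg = simulate_repetition(flat_spec(), "CPE", 1.0, QUIET, rng_seed=0)
        for s in range(3):
            az = seg[3 * s + 2]
            assert np.allclose(az, az[0])
            assert abs(az[0] - G) < QUIET.lsb
            phi = tilt_angle(seg[3 * s], seg[3 * s + 1], az)
            assert np.all(np.abs(phi) < 0.2)

    def test_orthogonal_baseline_reads_zero_z(self):
        """90 deg baseline on sensor 2: A_Z2 ~ 0 and recovered tilt 90 deg."""
        seg = simulate_repetition(
            flat_spec(baselines=(0.0, 90.0, 0.0)), "CPE", 1.0, QUIET, rng_seed=0
        )
        assert np.all(np.abs(seg[5]) <= QUIET.lsb)
        phi = tilt_angle(seg[3], seg[4], seg[5])
        assert np.all(np.abs(phi - 90.0) < 0.2)

    def test_zero_tcm_effects_make_categories_bit_identical(self):
        spec = default_exercise("rowing").with_effect_scale(0.0)
        a = simulate_repetition(spec, "CPE", 2.5, rng_seed=42)
        b = simulate_repetition(spec, "TCM", 2.5, rng_seed=42)
        np.testing.assert_array_equal(a, b)

    def test_nonzero_tcm_effects_change_the_signal(self):
        spec = default_exercise("rowing")
        a = simulate_repetition(spec, "CPE", 2.5, rng_seed=42)
        b = simulate_repetition(spec, "TCM", 2.5, rng_seed=42)
        assert not np.array_equal(a, b)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_repetition(flat_spec(), "CPE", 0.0, QUIET)
        with pytest.raises(ValueError):
            simulate_repetition(flat_spec(), "WRONG", 1.0, QUIET)
        with pytest.raises(ValueError):
            default_exercise("situps")

    def test_tilt_recovery_matches_generating_trajectory(self):
        """Noise-free, oscillation-free signals recover phi(t) to quantization error."""
        spec = flat_spec(baselines=(15.0, 30.0, 60.0), amplitudes=(25.0, 10.0, 5.0))
        n = int(2.0 * QUIET.sampling_rate)
        u = (np.arange(n) + 0.5) / n
        seg = simulate_repetition(spec, "CPE", 2.0, QUIET, rng_seed=3)
        for s in range(3):
            expected = spec.tilt_waveforms[s].angles(u)
            phi = tilt_angle(seg[3 * s], seg[3 * s + 1], seg[3 * s + 2])
            assert np.max(np.abs(phi - expected)) < 0.25  # ~2 LSB in angle

    def test_quantization_grid_and_clipping(self):
        sm = SensorModel(noise_sd=0.0, resolution_bits=12)
        x = np.array([0.0, 1.234, -50.0, 100.0])
        q = sm.quantize(x)
        assert np.all(np.abs(q) <= sm.full_scale)
        np.testing.assert_allclose(np.round(q / sm.lsb), q / sm.lsb, atol=1e-9)


class TestGenerateSession:
    def test_six_repetitions_give_seven_markers(self):
        rec = generate_session("S01", default_exercise("prone_rocking"), "CPE", 1, rng_seed=5)
        assert rec.markers.size == 7
        assert np.all(np.diff(rec.markers) > 0)
        assert rec.markers[-1] <= rec.n_samples

    def test_zero_duration_cv_gives_equal_repetition_lengths(self):
        spec = flat_spec(amplitudes=(10.0, 10.0, 10.0))
        rec = generate_session("S01", spec, "CPE", 1, QUIET, rng_seed=5)
        lengths = np.diff(rec.markers)
        assert np.all(lengths == lengths[0])

    def test_same_seed_reproduces_identical_recording(self):
        spec = default_exercise("bird_dog")
        a = generate_session("S01", spec, "TCM", 2, rng_seed=9)
        b = generate_session("S01", spec, "TCM", 2, rng_seed=9)
        np.testing.assert_array_equal(a.channels, b.channels)
        np.testing.assert_array_equal(a.markers, b.markers)

    def test_set_index_validated(self):
        with pytest.raises(ValueError):
            generate_session("S01", flat_spec(), "CPE", 4, rng_seed=0)


class TestGenerateCohort:
    def test_one_subject_three_exercises_gives_18_recordings(self):
        recs, manifest = generate_cohort(n_subjects=1, master_seed=0)
        assert len(recs) == 18  # 1 subject x 3 exercises x 2 categories x 3 sets
        assert len(manifest) == 18

    def test_keep_sides_counts_24_sets_per_subject(self):
        recs, manifest = generate_cohort(n_subjects=1, master_seed=0, keep_sides=True)
        assert len(recs) == 24  # 2 categories x 4 counted exercises x 3 sets
        assert set(manifest["exercise"]) == {
            "prone_rocking", "bird_dog_left", "bird_dog_right", "rowing"
        }

    def test_cohort_determinism(self):
        a, _ = generate_cohort(n_subjects=2, exercises=["rowing"], master_seed=3)
        b, _ = generate_cohort(n_subjects=2, exercises=["rowing"], master_seed=3)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.channels, rb.channels)

    def test_effect_scale_zero_makes_categories_generatively_identical(self):
        spec = default_exercise("prone_rocking").with_effect_scale(0.0)
        profile = SubjectProfile.draw(np.random.default_rng(5))
        cpe = generate_session("S01", spec, "CPE", 1, rng_seed=77, profile=profile)
        tcm = generate_session("S01", spec, "TCM", 1, rng_seed=77, profile=profile)
        np.testing.assert_array_equal(cpe.channels, tcm.channels)
        np.testing.assert_array_equal(cpe.markers, tcm.markers)

    def test_separability_is_monotone_in_effect_scale(self):
        """Downstream LOSO accuracy does not decrease along the effect grid."""
        from tcmdetect import build_feature_matrix, loso_evaluate, preprocess_cohort

        accs = []
        for scale in (0.0, 0.5, 1.0, 2.0):
            recs, _ = generate_cohort(
                n_subjects=30, exercises=["prone_rocking"], master_seed=7,
                effect_scale=scale,
            )
            fm = build_feature_matrix(preprocess_cohort(recs))
            accs.append(loso_evaluate(fm, ["var_Y2"]).accuracy)
        one_subject = 6 / 180  # sampling-noise tolerance: one held-out subject
        assert all(b >= a - one_subject for a, b in zip(accs, accs[1:])), accs

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            generate_cohort(n_subjects=0)
        with pytest.raises(ValueError):
            generate_cohort(n_subjects=1, exercises=[])
        with pytest.raises(ValueError):
            generate_cohort(n_subjects=1, effect_scale=-1.0)
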