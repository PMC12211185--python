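"""Generator correctness: determinism, containment, intensities, templates."""

import numpy as np
import pytest

from cardionano.core import Window
from cardionano.synthgen import (
    ClusterModel,
    ContractionModel,
    EmitterStackModel,
    TransientModel,
    contraction_template,
    gen_calcium_trace,
    gen_clustered,
    gen_contraction,
    gen_csr,
    gen_frame_stack,
    transient_template,
)

WINDOW = Window.square(2000.0)


class TestCSR:
    def test_empty_pattern(self):
        assert gen_csr(0, WINDOW, seed=1).n == 0

    def test_containment_and_count(self):
        p = gen_csr(300, WINDOW, seed=1)
        assert p.n == 300
        assert np.all(WINDOW.contains(p.points))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            gen_csr(-1, WINDOW)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            Window(0, 0, -5, 10)


class TestClustered:
    def test_determinism(self):
        m = ClusterModel(WINDOW, 10, 20, 25.0, 1e-6, 10.0, seed=7)
        a, b = gen_clustered(m), gen_clustered(m)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_different_seeds_differ(self):
        m1 = ClusterModel(WINDOW, 10, 20, 25.0, seed=1)
        m2 = ClusterModel(WINDOW, 10, 20, 25.0, seed=2)
        assert gen_clustered(m1).points.shape != gen_clustered(m2).points.shape or not np.array_equal(
            gen_clustered(m1).points, gen_clustered(m2).points
        )

    def test_degenerate_limit_offspring_coincide_with_parent(self):
        m = ClusterModel(WINDOW, 1, 50, 0.0, 0.0, 0.0, seed=3)
        p = gen_clustered(m)
        assert p.n > 0
        assert np.ptp(p.points[:, 0]) == 0 and np.ptp(p.points[:, 1]) == 0

    def test_single_cluster_spread_is_sigma_sum(self):
        # per-axis SD of offspring = sqrt(cluster_sigma^2 + jitter^2)
        big = Window(-1e5, -1e5, 1e5, 1e5)  # no boundary truncation
        sds = []
        for seed in range(40):
            m = ClusterModel(big, 1, 400, 20.0, 0.0, 10.0, seed=seed)
            p = gen_clustered(m)
            centered = p.points - p.points.mean(axis=0)
            sds.append(centered.std(ddof=1, axis=0))
        expected = np.hypot(20.0, 10.0)
        assert np.mean(sds) == pytest.approx(expected, rel=0.03)

    def test_expected_intensity(self):
        # E[N] = n_parents * offspring_mean + background_rate * area,
        # verified within 3 SD of the ensemble mean over 200 seeds
        m_kwargs = dict(n_parents=10, offspring_mean=10, cluster_sigma=5.0,
                        background_rate=2e-5, loc_precision_sigma=2.0)
        expected = 10 * 10 + 2e-5 * WINDOW.area
        counts = [
            gen_clustered(ClusterModel(WINDOW, seed=s, **m_kwargs)).n
            for s in range(200)
        ]
        counts = np.asarray(counts, float)
        sem = counts.std(ddof=1) / np.sqrt(len(counts))
        # slight deficit expected from boundary truncation of offspring
        assert abs(counts.mean() - expected) < 3 * sem + 0.01 * expected

    def test_validation(self):
        with pytest.raises(ValueError):
            ClusterModel(WINDOW, -1, 10, 5.0)
        with pytest.raises(ValueError):
            ClusterModel(WINDOW, 1, -10, 5.0)
        with pytest.raises(ValueError):
            ClusterModel(WINDOW, 1, 10, -5.0)


class TestFrameStack:
    def test_zero_emitters_only_background(self):
        m = EmitterStackModel(
            np.zeros((0, 2)), field_shape=(16, 16), frame_count=5,
            background_mean=50.0, background_sd=2.0, seed=0,
        )
        stack, truth = gen_frame_stack(m)
        assert len(truth) == 0
        assert abs(stack.frames.mean() - 50.0) < 1.0

    def test_single_emitter_spot_in_scheduled_frames(self):
        m = EmitterStackModel(
            np.array([[800.0, 800.0]]), field_shape=(16, 16), pixel_size=100.0,
            frame_count=8, blink_schedule=[[(3, 5)]],
            background_mean=0.0, background_sd=0.0, seed=0,
        )
        stack, truth = gen_frame_stack(m)
        sums = stack.frames.sum(axis=(1, 2))
        assert np.all(sums[[3, 4]] > 100)
        assert np.all(sums[[0, 1, 2, 5, 6, 7]] == 0)
        # the spot sits at the emitter position
        peak = np.unravel_index(np.argmax(stack.frames[3]), stack.frames[3].shape)
        assert peak == (7, 7)  # pixel containing (800, 800) nm at 100 nm/px
        assert truth.loc[0, "n_on_frames"] == 2

    def test_emitter_outside_field_rejected(self):
        with pytest.raises(ValueError):
            EmitterStackModel(np.array([[1e6, 0.0]]), field_shape=(16, 16))

    def test_determinism(self):
        m = EmitterStackModel(
            np.array([[500.0, 700.0]]), field_shape=(12, 12), frame_count=6, seed=9
        )
        a, _ = gen_frame_stack(m)
        b, _ = gen_frame_stack(m)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestCalcium:
    def test_noise_free_matches_template_everywhere(self):
        m = TransientModel(noise_sd=0.0, seed=0)
        tr = gen_calcium_trace(m)
        np.testing.assert_allclose(tr.values, transient_template(m, tr.time))

    def test_min_and_max(self):
        m = TransientModel(diastolic=1.0, systolic=1.8, tau=0.4, noise_sd=0.0)
        tr = gen_calcium_trace(m)
        assert tr.values.min() == pytest.approx(1.0)
        assert tr.values.max() == pytest.approx(1.8)

    def test_ten_onsets_in_20s_at_half_hz(self):
        tr = gen_calcium_trace(TransientModel(duration=20.0, pacing_hz=0.5))
        assert len(tr.stim_onsets) == 10

    def test_validation(self):
        with pytest.raises(ValueError):
            TransientModel(systolic=0.9, diastolic=1.0)
        with pytest.raises(ValueError):
            TransientModel(tau=-1.0)
        with pytest.raises(ValueError):
            TransientModel(rise_time=3.0, pacing_hz=0.5)


class TestContraction:
    def test_thirty_beats_in_default_recording(self):
        m = ContractionModel(beat_hz=1.0, fps=50.0, frame_count=1500, noise_sd=0.0)
        tr = gen_contraction(m)
        # 30 s at 1 Hz: 30 distinct pulses above half amplitude
        above = tr.values > 0.5 * m.amplitude
        n_pulses = int(np.sum(np.diff(above.astype(int)) == 1))
        n_pulses += int(above[0])
        assert n_pulses == 30

    def test_zero_amplitude_flat(self):
        m = ContractionModel(amplitude=0.0, noise_sd=0.0)
        assert np.all(gen_contraction(m).values == 0)
        stack, _ = gen_contraction(m, as_stack=True)
        assert np.allclose(stack.frames, stack.frames[0])

    def test_template_matches_trace(self):
        m = ContractionModel(noise_sd=0.0, seed=4)
        tr = gen_contraction(m)
        np.testing.assert_allclose(tr.values, contraction_template(m, tr.time))

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            ContractionModel(beat_hz=0.5, fps=50.0, frame_count=100)
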