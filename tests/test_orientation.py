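"""FFT angle spectra, weighted circular density modes, angle conventions."""

import numpy as np
import pytest

from plasmonet import orientation, synthetic
from plasmonet.images import GrayImage, ImageStack, rotate_image
from plasmonet.orientation import (
    AngleDistribution,
    CharacteristicAngleSeries,
    characteristic_angle,
    final_state_angles,
    frame_tube_angles,
    orientation_time_course,
    power_spectrum_angles,
    tube_angle_from_spectral,
)


def _grating(side=128, freq=0.1):
    c = np.arange(side)
    img = 128 + 100 * np.sin(2 * np.pi * freq * c)[None, :] * np.ones((side, 1))
    return GrayImage(np.clip(img, 0, 255))


def _circular_error(a, b):
    d = abs((a - b) % 180.0)
    return min(d, 180.0 - d)


class TestPowerSpectrum:
    def test_constant_image_is_flagged_empty(self):
        dist = power_spectrum_angles(GrayImage(np.full((128, 128), 77.0)))
        assert dist.empty
        with pytest.raises(ValueError):
            characteristic_angle(dist)

    def test_non_square_or_small_crops_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum_angles(GrayImage(np.zeros((128, 100))))
        with pytest.raises(ValueError):
            power_spectrum_angles(GrayImage(np.zeros((32, 32))))

    def test_grating_concentrates_weight_at_spectral_zero(self):
        dist = power_spectrum_angles(_grating())
        dev = np.minimum(dist.angles_deg, 180.0 - dist.angles_deg)
        assert dist.weights[dev <= 5.0].sum() / dist.weights.sum() >= 0.9

    def test_rotated_grating_moves_spectral_angle(self):
        rot = rotate_image(_grating(), 45.0)
        dist = power_spectrum_angles(rot)
        peaks, _ = characteristic_angle(dist)
        assert _circular_error(peaks[0], 45.0) <= 5.0

    def test_angles_always_folded_to_half_turn(self):
        img, _ = synthetic.make_tube_network_image(synthetic.TubeNetworkSpec(seed=3))
        dist = power_spectrum_angles(img)
        assert np.all((dist.angles_deg >= 0) & (dist.angles_deg < 180))
        peaks, _ = characteristic_angle(dist)
        assert np.all((peaks >= 0) & (peaks < 180))


class TestCharacteristicAngle:
    def test_single_angle_mass_is_its_own_mode(self):
        dist = AngleDistribution(np.full(50, 37.0), np.ones(50))
        peaks, dens = characteristic_angle(dist)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(37.0, abs=0.5)

    def test_concentrated_sample_mode_recovered(self):
        rng = np.random.default_rng(1)
        angles = (30.0 + rng.normal(0, 4.0, 400)) % 180.0
        dist = AngleDistribution(angles, rng.uniform(0.5, 1.5, 400))
        peaks, _ = characteristic_angle(dist)
        assert _circular_error(peaks[0], 30.0) <= 2.0

    def test_balanced_bimodal_sample_yields_both_modes(self):
        rng = np.random.default_rng(2)
        angles = np.concatenate(
            [20.0 + rng.normal(0, 3.0, 300), 80.0 + rng.normal(0, 3.0, 300)]
        ) % 180.0
        dist = AngleDistribution(angles, np.ones(600))
        peaks, _ = characteristic_angle(dist)
        assert len(peaks) == 2
        assert min(_circular_error(p, 20.0) for p in peaks) <= 3.0
        assert min(_circular_error(p, 80.0) for p in peaks) <= 3.0

    @pytest.mark.parametrize("spectral,tube", [(0.0, 90.0), (90.0, 0.0), (135.0, 45.0)])
    def test_orthogonality_correction(self, spectral, tube):
        assert tube_angle_from_spectral(spectral) == tube


class TestRecovery:
    @pytest.mark.parametrize("theta", [0, 30, 75, 120, 165])
    def test_single_mode_network_angle_recovered(self, theta):
        spec = synthetic.TubeNetworkSpec(orientation_modes=((theta, 1.0),), seed=42)
        img, _ = synthetic.make_tube_network_image(spec)
        angles, _ = frame_tube_angles(img)
        assert _circular_error(angles[0], theta) <= 3.0

    @pytest.mark.parametrize("phi", [15.0, 45.0, 90.0])
    def test_rotation_equivariance(self, phi):
        spec = synthetic.TubeNetworkSpec(orientation_modes=((20.0, 1.0),), seed=5)
        img, _ = synthetic.make_tube_network_image(spec)
        base = frame_tube_angles(img)[0][0]
        rotated = frame_tube_angles(rotate_image(img, phi))[0][0]
        assert _circular_error(rotated, base + phi) <= 3.0

    def test_three_mode_networks_yield_three_peaks(self):
        hits = 0
        for seed in range(10):
            spec = synthetic.TubeNetworkSpec(
                orientation_modes=((20.0, 1.0), (75.0, 1.0), (130.0, 1.0)),
                n_tubes=90,
                seed=seed,
            )
            img, _ = synthetic.make_tube_network_image(spec)
            angles, _ = frame_tube_angles(img)
            hits += len(angles) == 3
        assert hits >= 9


class TestTimeCourse:
    def _stack_from_images(self, images, interval=30.0):
        frames = np.stack([img.pixels for img in images])
        return ImageStack(frames, interval, "min")

    def test_constant_network_gives_constant_series(self):
        spec = synthetic.TubeNetworkSpec(orientation_modes=((30.0, 1.0),), seed=9)
        img, _ = synthetic.make_tube_network_image(spec)
        stack = self._stack_from_images([img] * 4)
        series = orientation_time_course(stack, [-90, -60, -30, 0])
        for peaks in series.peak_angles_deg:
            assert _circular_error(peaks[0], 30.0) <= 3.0

    def test_tree_to_mesh_transition_adds_second_peak(self):
        tree = synthetic.make_tube_network_image(
            synthetic.TubeNetworkSpec(orientation_modes=((20.0, 1.0),), seed=10)
        )[0]
        mesh = synthetic.make_tube_network_image(
            synthetic.TubeNetworkSpec(
                orientation_modes=((20.0, 0.5), (75.0, 0.5)), n_tubes=80, seed=11
            )
        )[0]
        stack = self._stack_from_images([tree, tree, mesh, mesh])
        series = orientation_time_course(stack, [-90, -60, -30, 0])
        assert len(series.peak_angles_deg[0]) == 1
        assert len(series.peak_angles_deg[-1]) == 2

    def test_empty_stack_rejected(self):
        stack = ImageStack(np.zeros((1, 64, 64)), 5.0, "min")
        with pytest.raises(ValueError):
            orientation_time_course(stack, [])


class TestFinalState:
    def _series(self, entries):
        t_n = np.array([t for t, _, _ in entries], dtype=float)
        return CharacteristicAngleSeries(
            t_n,
            tuple(np.asarray(a, dtype=float) for _, a, _ in entries),
            tuple(np.asarray(d, dtype=float) for _, _, d in entries),
        )

    def test_constant_series_gives_its_angle(self):
        series = self._series([(-300 + 30 * k, [25.0], [1.0]) for k in range(11)])
        _, peaks, _ = final_state_angles(series)
        assert _circular_error(peaks[0], 25.0) <= 1.0

    def test_persistent_two_peaks_both_reported(self):
        series = self._series(
            [(-300 + 30 * k, [20.0, 75.0], [1.0, 0.8]) for k in range(11)]
        )
        _, peaks, _ = final_state_angles(series)
        assert len(peaks) == 2
        assert min(_circular_error(p, 20.0) for p in peaks) <= 3.0
        assert min(_circular_error(p, 75.0) for p in peaks) <= 3.0

    def test_window_without_entries_rejected(self):
        series = self._series([(-500.0, [25.0], [1.0])])
        with pytest.raises(ValueError):
            final_state_angles(series, window=(-300.0, 0.0))
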