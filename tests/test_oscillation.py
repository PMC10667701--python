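"""Block averaging, lowess smoothing, period/frequency extraction."""

import numpy as np
import pytest

from plasmonet import synthetic
from plasmonet.images import ImageStack
from plasmonet.oscillation import (
    block_frequency,
    grid_mean_series,
    normalize_frequency,
    nyquist_frequency_hz,
    omission_cutoff_rad_s,
    oscillation_map,
    peak_periods,
    sample_frequency,
    smooth_series,
    OscillationMap,
)


class TestNyquistBookkeeping:
    def test_nyquist_at_5s_sampling(self):
        assert nyquist_frequency_hz(5.0) == pytest.approx(0.1)

    def test_omission_cutoff_is_half_nyquist(self):
        assert omission_cutoff_rad_s(5.0) == pytest.approx(2 * np.pi * 0.05)


class TestGridSeries:
    def test_constant_stack_gives_constant_series(self):
        frames = np.full((121, 320, 320), 90, dtype=np.uint8)
        stack = ImageStack(frames, 5.0, "s")
        grid = grid_mean_series(stack)
        assert grid.series.shape == (32, 32, 121)
        assert np.all(grid.series == 90.0)

    def test_grid_has_1024_blocks(self):
        frames = np.zeros((3, 320, 320), dtype=np.uint8)
        grid = grid_mean_series(ImageStack(frames, 5.0, "s"))
        assert grid.grid * grid.grid == 1024

    def test_blockwise_programmed_values_recovered(self):
        spec = synthetic.OscillationMovieSpec(
            period_field=np.full((32, 32), 100.0), noise_sd=0.0
        )
        stack, _ = synthetic.make_oscillation_movie(spec)
        grid = grid_mean_series(stack)
        t = 5.0 * np.arange(121)
        expected = 128.0 + 40.0 * np.sin(2 * np.pi * t / 100.0)
        assert np.abs(grid.series[7, 19] - expected).max() <= 0.5

    def test_indivisible_roi_rejected(self):
        frames = np.zeros((3, 320, 320), dtype=np.uint8)
        with pytest.raises(ValueError):
            grid_mean_series(ImageStack(frames, 5.0, "s"), roi_px=320, block_px=7)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        out = smooth_series(np.full(121, 5.0))
        assert np.abs(out - 5.0).max() < 1e-9

    def test_linear_ramp_unchanged(self):
        ramp = np.arange(121, dtype=float)
        assert np.abs(smooth_series(ramp) - ramp).max() < 1e-6

    def test_noisy_sinusoid_tracks_clean_signal(self):
        rng = np.random.default_rng(0)
        t = 5.0 * np.arange(121)
        clean = np.sin(2 * np.pi * t / 100.0)
        smoothed = smooth_series(clean + rng.normal(0, 0.2, t.size))
        assert np.corrcoef(smoothed, clean)[0, 1] >= 0.95

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.arange(5.0))


class TestPeriods:
    def test_sampled_sinusoid_gives_five_100s_gaps(self):
        t = 5.0 * np.arange(121)
        gaps = peak_periods(np.sin(2 * np.pi * t / 100.0), 5.0)
        assert len(gaps) == 5
        assert np.all(np.abs(gaps - 100.0) <= 5.0)

    def test_monotone_series_has_no_periods(self):
        assert peak_periods(np.arange(50.0), 5.0).size == 0

    def test_two_peaks_sixty_seconds_apart(self):
        y = np.zeros(50)
        y[10] = y[22] = 1.0  # 12 frames * 5 s = 60 s
        assert peak_periods(y, 5.0).tolist() == [60.0]


class TestBlockFrequency:
    def test_uniform_100s_periods(self):
        T, omega, omitted, _ = block_frequency([100.0] * 5, 5.0)
        assert T == 100.0
        assert omega == pytest.approx(2 * np.pi / 100.0)  # ~0.06283 rad/s
        assert not omitted

    def test_fast_oscillation_omitted_above_half_nyquist(self):
        T, omega, omitted, reason = block_frequency([15.0, 15.0], 5.0)
        assert omega == pytest.approx(0.4189, abs=1e-4)
        assert omitted and reason == "above half-Nyquist"

    def test_empty_periods_omitted(self):
        _, _, omitted, reason = block_frequency([], 5.0)
        assert omitted and reason == "no peaks"

    def test_mode_tie_breaks_toward_longer_period(self):
        T, _, _, _ = block_frequency([100.0, 100.0, 150.0, 150.0], 5.0)
        assert T == 150.0


class TestSampleFrequency:
    def _map_from_omegas(self, omegas):
        omegas = np.asarray(omegas, dtype=float)
        g = omegas.shape[0]
        omitted = np.isnan(omegas)
        return OscillationMap(
            period_s=2 * np.pi / omegas,
            omega_rad_s=omegas,
            omitted=omitted,
            reason=np.where(omitted, "no peaks", "").astype(object),
            frame_interval_s=5.0,
        )

    def test_uniform_field_median(self):
        m = self._map_from_omegas(np.full((4, 4), 0.05))
        assert sample_frequency(m) == pytest.approx(0.05)

    def test_half_and_half_median_is_midpoint(self):
        field = np.full((4, 4), 0.05)
        field[2:] = 0.07
        assert sample_frequency(self._map_from_omegas(field)) == pytest.approx(0.06)

    def test_median_invariant_under_block_permutation(self):
        rng = np.random.default_rng(3)
        field = rng.uniform(0.03, 0.09, (6, 6))
        shuffled = rng.permutation(field.ravel()).reshape(6, 6)
        assert sample_frequency(self._map_from_omegas(field)) == pytest.approx(
            sample_frequency(self._map_from_omegas(shuffled))
        )

    def test_all_omitted_rejected(self):
        m = self._map_from_omegas(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            sample_frequency(m)


class TestMapPipeline:
    def test_map_complete_and_below_cutoff(self):
        # small grid keeps the lowess loop quick; two programmed regions
        field = np.full((8, 8), 100.0)
        field[4:] = 150.0
        spec = synthetic.OscillationMovieSpec(
            period_field=field, roi_px=80, block_px=10, noise_sd=8.0, seed=4
        )
        stack, periods = synthetic.make_oscillation_movie(spec)
        grid = grid_mean_series(stack, roi_px=80)
        m = oscillation_map(grid)
        assert m.n_retained + int(m.omitted.sum()) == 64
        kept = m.omega_rad_s[~m.omitted]
        assert np.all(kept <= omission_cutoff_rad_s(5.0) + 1e-12)
        # recovered frequencies track the programmed two-region field
        truth = 2 * np.pi / periods
        assert np.nanmax(np.abs(m.omega_rad_s - truth)) <= 1.5 * 2 * np.pi * 5.0 / 100.0**2


class TestNormalization:
    def test_control_normalized_by_own_median_is_one(self):
        vals = np.array([0.04, 0.05, 0.06])
        assert np.median(normalize_frequency(vals, vals)) == pytest.approx(1.0)

    def test_ratio_to_control_median(self):
        assert normalize_frequency([0.08], [0.03, 0.04, 0.05])[0] == pytest.approx(2.0)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_frequency([0.05], [])
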