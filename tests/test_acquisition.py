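import numpy as np
import pytest

from respispec.acquisition import (
    NoiseModel,
    SpectrometerConfig,
    TimeResolvedSpectra,
    apply_noise,
    render_frame,
    simulate_acquisition,
)
from respispec.card_optics import LaserSpot
from respispec.motion import MotionSpec
from respispec.pipeline import detrend, dft_spectrum, extract_waveform


class TestRenderFrame:
    def test_zero_reflectance_gives_flat_baseline(self):
        cfg = SpectrometerConfig()
        frame = render_frame(0.0, cfg)
        assert np.all(frame == 150.0)

    def test_full_reflectance_peak_bin(self):
        cfg = SpectrometerConfig()
        frame = render_frame(1.0, cfg)
        k = np.argmin(np.abs(cfg.wavelength_grid - 632.8))
        assert frame[k] == pytest.approx(150.0 + 10000.0)
        assert np.argmax(frame) == k
        assert np.all(frame > 0)

    def test_line_integral_linear_in_reflectance(self, small_cfg):
        # area above baseline must scale linearly with the reflected fraction
        areas = {
            r: np.trapezoid(render_frame(r, small_cfg) - small_cfg.baseline,
                            small_cfg.wavelength_grid)
            for r in (0.25, 0.5, 1.0)
        }
        slope = areas[1.0] / 1.0
        for r, area in areas.items():
            assert area == pytest.approx(slope * r, rel=1e-12)

    def test_out_of_range_reflectance_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            render_frame(1.5, small_cfg)

    def test_grid_not_covering_line_is_configuration_error(self):
        cfg = SpectrometerConfig(wavelength_grid=np.linspace(700.0, 800.0, 64))
        with pytest.raises(ValueError, match="632.8"):
            render_frame(0.5, cfg)


class TestSimulateAcquisition:
    def test_frame_count(self, small_sim):
        cube = small_sim(duration=60.0)
        assert cube.n_frames == 600

    def test_same_seed_bit_identical(self, small_sim):
        noise = NoiseModel(seed=123)
        a = small_sim(noise=noise)
        b = small_sim(noise=noise)
        assert np.array_equal(a.intensities, b.intensities)

    def test_different_seeds_differ(self, small_sim):
        a = small_sim(noise=NoiseModel(seed=1))
        b = small_sim(noise=NoiseModel(seed=2))
        assert not np.array_equal(a.intensities, b.intensities)

    def test_noiseless_is_deterministic(self, small_sim):
        a = small_sim()
        b = small_sim()
        assert np.array_equal(a.intensities, b.intensities)

    @pytest.mark.parametrize("frequency", [0.3291, 0.98760, 1.6])
    def test_noiseless_laser_slice_fundamental(self, small_sim, frequency):
        """The 632 nm section of a noiseless recording oscillates at the
        platform frequency: its DFT peak lands within one bin of it."""
        cube = small_sim(frequency=frequency, displacement=2.0)
        wave = detrend(extract_waveform(cube))
        spectrum = dft_spectrum(wave, zero_pad_factor=1)
        mask = spectrum.frequencies >= 0.05
        peak = spectrum.frequencies[mask][np.argmax(spectrum.magnitudes[mask])]
        assert abs(peak - frequency) <= spectrum.resolution

    def test_nyquist_violation_raises(self, small_cfg):
        spec = MotionSpec(frequency=6.0, displacement=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_acquisition(spec, cfg=small_cfg)


class TestApplyNoise:
    def _flat_cube(self, value=1000.0, n=10_000):
        return TimeResolvedSpectra(
            intensities=np.full((n, 4), value),
            time_axis=np.arange(n) / 10.0,
            wavelength_axis=np.array([631.0, 632.0, 633.0, 634.0]),
        )

    def test_zero_noise_is_identity(self):
        cube = self._flat_cube()
        assert apply_noise(cube, NoiseModel.zero()) is cube

    def test_read_noise_sd_recovered_from_samples(self):
        cube = self._flat_cube()
        noise = NoiseModel(read_noise_sd=10.0, shot_noise_scale=0.0,
                           drift_amplitude=0.0, seed=7)
        noisy = apply_noise(cube, noise)
        sd = np.std(noisy.intensities - cube.intensities)
        assert sd == pytest.approx(10.0, rel=0.05)

    def test_shot_noise_scales_with_signal(self):
        lo, hi = 100.0, 10000.0
        noise = NoiseModel(read_noise_sd=0.0, shot_noise_scale=0.05,
                           drift_amplitude=0.0, seed=3)
        sd_lo = np.std(apply_noise(self._flat_cube(lo), noise).intensities - lo)
        sd_hi = np.std(apply_noise(self._flat_cube(hi), noise).intensities - hi)
        assert sd_lo == pytest.approx(0.05 * lo, rel=0.05)
        assert sd_hi == pytest.approx(0.05 * hi, rel=0.05)

    def test_output_clamped_at_zero(self):
        cube = self._flat_cube(value=5.0, n=2000)
        noisy = apply_noise(cube, NoiseModel(read_noise_sd=100.0, seed=0))
        assert np.min(noisy.intensities) >= 0.0

    def test_drift_is_slow_sinusoid_across_frames(self):
        cube = self._flat_cube(value=1000.0, n=1200)
        noise = NoiseModel(read_noise_sd=0.0, shot_noise_scale=0.0,
                           drift_amplitude=50.0, drift_period=60.0, seed=5)
        delta = apply_noise(cube, noise).intensities - cube.intensities
        # identical across wavelengths within a frame, oscillating over time
        assert np.allclose(delta, delta[:, :1])
        assert delta[:, 0].max() == pytest.approx(50.0, rel=0.01)
        assert delta[:, 0].min() == pytest.approx(-50.0, rel=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(read_noise_sd=-1.0), dict(drift_amplitude=10.0, drift_period=0.0)],
    )
    def test_invalid_noise_model_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NoiseModel(**kwargs)


class TestContainers:
    def test_wavelength_grid_must_increase(self):
        with pytest.raises(ValueError):
            SpectrometerConfig(wavelength_grid=np.array([632.0, 631.0, 633.0]))

    def test_axis_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TimeResolvedSpectra(
                intensities=np.ones((3, 4)),
                time_axis=np.arange(2) / 10.0,
                wavelength_axis=np.arange(4.0),
            )

    def test_non_uniform_time_axis_rejected(self):
        with pytest.raises(ValueError):
            TimeResolvedSpectra(
                intensities=np.ones((3, 2)),
                time_axis=np.array([0.0, 0.1, 0.35]),
                wavelength_axis=np.array([632.0, 633.0]),
            )

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            TimeResolvedSpectra(
                intensities=np.full((2, 2), -1.0),
                time_axis=np.arange(2) / 10.0,
                wavelength_axis=np.array([632.0, 633.0]),
            )
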