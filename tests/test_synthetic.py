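"""Simulator ground truth: geometry, conservation, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemokymo.synthetic import (
    SPEED_OF_LIGHT,
    SimKymographSpec,
    SimPenetratingSpec,
    SimVesselSpec,
    faced_geometry,
    simulate_kymograph,
    simulate_penetrating_trace,
    simulate_vessel_video,
)


def _constant(v):
    return lambda t: np.full_like(t, float(v))


class TestKymographSimulator:
    def test_streak_slope_matches_velocity(self):
        # v = 1 mm/s at 0.5 um/px, 1 kHz: streaks advance 2 px per line
        spec = SimKymographSpec(line_rate=1000, pixel_size=0.5, line_length=50,
                                duration=0.2, velocity_fn=_constant(1.0),
                                rbc_linear_density=60, seed=0)
        k, truth = simulate_kymograph(spec)
        disp_um = np.diff(truth.params["cumulative_displacement_um"])
        assert np.allclose(disp_um / spec.pixel_size, 2.0)
        # rendered: adjacent lines are 2-px shifted copies
        a = k.data[50] - k.data[50].mean()
        b = k.data[51] - k.data[51].mean()
        corr = np.correlate(b, a, mode="full")
        assert np.argmax(corr) - (a.size - 1) == 2

    def test_zero_velocity_gives_static_bands(self):
        spec = SimKymographSpec(duration=0.2, velocity_fn=_constant(0.0), seed=1)
        k, _ = simulate_kymograph(spec)
        assert np.ptp(k.data, axis=0).max() == pytest.approx(0.0, abs=1e-12)

    def test_sinusoidal_velocity_has_spectral_peak_at_drive(self):
        from hemokymo.velocimetry import PIVConfig, piv_velocity

        spec = SimKymographSpec(
            line_rate=2000, pixel_size=0.5, duration=2.0,
            velocity_fn=lambda t: 2.0 * (1 + 0.5 * np.sin(2 * np.pi * 10 * t)),
            seed=2)
        k, _ = simulate_kymograph(spec)
        tr = piv_velocity(k, PIVConfig(window_ms=2, stride_ms=1))
        v = tr.velocity - np.nanmean(tr.velocity)
        v[~np.isfinite(v)] = 0.0
        amp = np.abs(np.fft.rfft(v))
        freq = np.fft.rfftfreq(v.size, tr.sampling_interval)
        assert freq[np.argmax(amp[1:]) + 1] == pytest.approx(10.0, abs=0.5)

    def test_photon_conservation_noiseless(self):
        spec = SimKymographSpec(duration=0.1, velocity_fn=_constant(3.0), seed=3)
        k, truth = simulate_kymograph(spec)
        expected = spec.background_level * (
            1 - spec.contrast * truth.occlusion_fraction)
        assert np.allclose(k.data.mean(axis=1), expected, atol=1e-9)

    def test_advection_consistency(self):
        # integrated velocity equals rendered displacement (trajectories)
        spec = SimKymographSpec(
            duration=0.2, line_rate=1000,
            velocity_fn=lambda t: 2 + np.sin(2 * np.pi * 5 * t), seed=4)
        k, truth = simulate_kymograph(spec)
        pos = truth.trajectories  # (n_lines, n_cells), wrapped
        disp = truth.params["cumulative_displacement_um"]
        unwrapped = truth.params["initial_positions"][None, :] + disp[:, None]
        assert np.allclose(pos, np.mod(unwrapped, spec.line_length), atol=1e-9)

    def test_rejects_nonfinite_velocity_and_memory_cap(self):
        with pytest.raises(ValueError, match="non-finite"):
            simulate_kymograph(SimKymographSpec(
                duration=0.01, velocity_fn=lambda t: np.full_like(t, np.nan)))
        with pytest.raises(ValueError, match="memory cap"):
            SimKymographSpec(duration=10.0, line_rate=1e6,
                             max_lines=1_000_000).validate()

    @pytest.mark.parametrize("bad", [
        dict(contrast=0.0), dict(contrast=1.5), dict(line_rate=-1.0),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimKymographSpec(**bad).validate()


class TestVesselSimulator:
    def test_empty_lumen_is_gain_shaded_background(self):
        gain = np.linspace(0.6, 1.4, 48)
        spec = SimVesselSpec(fov=(24, 48), duration=0.01, n_rbc=0,
                             lumen_radius=4.0, faced_gain_profile=gain, seed=5)
        stack, truth = simulate_vessel_video(spec)
        # every frame identical (no cells, no motion, no noise)
        assert np.ptp(stack.data, axis=0).max() == pytest.approx(0.0, abs=1e-12)
        # outside the lumen the frame is outside_level times the gain
        # (0.5% slack for the soft lumen-edge tail reaching the border row)
        assert np.allclose(stack.data[0, 0, :], spec.outside_level * gain,
                           rtol=5e-3)

    def test_single_file_mode_forces_axial_cells(self):
        spec = SimVesselSpec(fov=(24, 48), duration=0.01, n_rbc=5,
                             lumen_radius=3.0, rbc_radius=3.0, seed=6)
        _, truth = simulate_vessel_video(spec)
        assert np.allclose(truth.radial_offsets, 0.0)

    def test_r0_outside_lumen_rejected(self):
        with pytest.raises(ValueError, match="r0"):
            SimVesselSpec(lumen_radius=5.0, r0=5.0).validate()

    def test_parabolic_vessel_recovery(self, parabolic_vessel):
        """Poiseuille limit: Vmax and Vmax/Vavg recovered within 2%."""
        import warnings

        from hemokymo.profiles import fit_blunted_parabola, radial_profile
        from hemokymo.velocimetry import PIVConfig

        spec, stack, truth, axis = parabolic_vessel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = radial_profile(stack, axis, np.linspace(-7, 7, 15),
                                  PIVConfig(window_ms=10, stride_ms=2))
        fit = fit_blunted_parabola(prof, R=spec.lumen_radius)
        assert fit.vmax == pytest.approx(spec.vmax, rel=0.02)
        assert fit.bluntness == pytest.approx(2.0, rel=0.02)


class TestPenetratingSimulator:
    def test_zero_flux_flat_baseline(self):
        trace, truth = simulate_penetrating_trace(
            SimPenetratingSpec(mean_flux=0.0, duration=1.0, seed=7))
        assert np.ptp(trace) == 0.0
        assert truth.event_times.size == 0

    def test_dense_flux_warns_about_merging(self):
        with pytest.warns(UserWarning, match="inter-event gap"):
            simulate_penetrating_trace(SimPenetratingSpec(
                mean_flux=300.0, transit_sigma=2e-3, duration=1.0, seed=8))

    def test_event_times_strictly_increasing_within_record(self):
        _, truth = simulate_penetrating_trace(
            SimPenetratingSpec(mean_flux=50.0, duration=5.0, seed=9))
        assert np.all(np.diff(truth.event_times) > 0)
        assert truth.event_times.max() < 5.0


class TestDeterminism:
    def test_generators_bit_identical_for_same_seed(self):
        k1 = simulate_kymograph(SimKymographSpec(
            duration=0.05, noise_model="poisson", seed=42,
            velocity_fn=_constant(2.0)))[0].data
        k2 = simulate_kymograph(SimKymographSpec(
            duration=0.05, noise_model="poisson", seed=42,
            velocity_fn=_constant(2.0)))[0].data
        assert np.array_equal(k1, k2)
        v1 = simulate_vessel_video(SimVesselSpec(
            fov=(16, 32), duration=0.01, noise_model="poisson", seed=42))[0].data
        v2 = simulate_vessel_video(SimVesselSpec(
            fov=(16, 32), duration=0.01, noise_model="poisson", seed=42))[0].data
        assert np.array_equal(v1, v2)
        p1 = simulate_penetrating_trace(SimPenetratingSpec(
            noise_model="poisson", duration=1.0, seed=42))[0]
        p2 = simulate_penetrating_trace(SimPenetratingSpec(
            noise_model="poisson", duration=1.0, seed=42))[0]
        assert np.array_equal(p1, p2)

    def test_different_seeds_differ(self):
        a = simulate_penetrating_trace(SimPenetratingSpec(
            noise_model="poisson", duration=1.0, seed=1))[0]
        b = simulate_penetrating_trace(SimPenetratingSpec(
            noise_model="poisson", duration=1.0, seed=2))[0]
        assert not np.array_equal(a, b)


class TestFacedGeometry:
    @pytest.mark.parametrize("dtheta, alpha, S, n_expected, delay_expected", [
        (1.0, 0.0125, 300.0, 80, 2.0),
        (1.0, 0.0188, 225.0, 53, 1.5),
        (1.0, 0.0125, 150.0, 80, 1.0),
    ])
    def test_printed_configurations(self, dtheta, alpha, S, n_expected,
                                    delay_expected):
        n, delay = faced_geometry(dtheta, alpha, S)
        assert n == n_expected
        assert delay == pytest.approx(delay_expected, abs=0.005)

    def test_rejects_alpha_not_smaller_than_dtheta(self):
        with pytest.raises(ValueError):
            faced_geometry(1.0, 1.0, 300.0)
        with pytest.raises(ValueError):
            faced_geometry(1.0, -0.1, 300.0)

    @given(ratio=st.integers(2, 500), alpha=st.floats(1e-3, 0.5),
           S=st.floats(10.0, 1000.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_closed_form_oracle(self, ratio, alpha, S):
        """n = floor(dtheta/alpha) and delay = 2S/c, by direct evaluation."""
        dtheta = ratio * alpha
        n, delay = faced_geometry(dtheta, alpha, S)
        assert n == ratio  # exact integer ratio must not be floored away
        exact_ns = 2 * S * 1e-3 / SPEED_OF_LIGHT * 1e9
        assert delay == pytest.approx(exact_ns, rel=5e-3)
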