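"""TIFF round trips, gain normalization, binning, rigid registration."""

import warnings

import numpy as np
import pytest

from hemokymo import io as hio
from hemokymo.containers import FrameStack, Kymograph, PolylineROI
from hemokymo.prep import bin_time, normalize_kymograph, normalize_stack, register_rigid
from hemokymo.synthetic import SimVesselSpec, simulate_vessel_video


class TestTiffRoundTrip:
    @pytest.mark.parametrize("dtype", [np.uint16, np.float32])
    def test_stack_round_trip(self, tmp_path, dtype):
        rng = np.random.default_rng(0)
        data = (rng.uniform(0, 1000, (3, 12, 16))).astype(dtype)
        stack = FrameStack(data, frame_rate=1000.0, pixel_size=0.5)
        hio.write_stack(stack, tmp_path / "s.tif")
        back = hio.read_stack(tmp_path / "s.tif")
        assert back.n_frames == 3
        assert np.array_equal(back.data, data)
        assert back.frame_rate == pytest.approx(1000.0)
        assert back.pixel_size == pytest.approx(0.5)

    def test_missing_metadata_raises_and_sidecar_overrides(self, tmp_path):
        import tifffile
        import yaml

        tifffile.imwrite(tmp_path / "bare.tif", np.zeros((2, 8, 8), np.uint16))
        with pytest.raises(ValueError, match="frame rate"):
            hio.read_stack(tmp_path / "bare.tif")
        with open(tmp_path / "bare.yaml", "w") as fh:
            yaml.safe_dump({"frame_rate": 250.0, "pixel_size": 2.0}, fh)
        s = hio.read_stack(tmp_path / "bare.tif")
        assert (s.frame_rate, s.pixel_size) == (250.0, 2.0)

    def test_kymograph_csv_and_tiff(self, tmp_path):
        k = Kymograph(np.random.default_rng(1).uniform(0, 1, (20, 9)), 1e6, 0.25)
        hio.write_kymograph(k, tmp_path / "k.csv")
        back = hio.read_kymograph(tmp_path / "k.csv")
        assert np.allclose(back.data, k.data)
        assert back.line_rate == 1e6
        hio.write_kymograph(k, tmp_path / "k.tif")
        back2 = hio.read_kymograph(tmp_path / "k.tif")
        assert np.allclose(back2.data, k.data, atol=1e-6)


class TestNormalization:
    def test_uniform_kymograph_identity(self):
        k = Kymograph(np.full((50, 30), 7.0), 1000.0, 0.5)
        out, gain = normalize_kymograph(k)
        assert np.allclose(out.data, k.data)
        assert np.allclose(gain.factors, 1.0)
        assert not gain.excluded_mask.any()

    def test_synthetic_gain_removed(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(50, 100, (200, 40))
        g = 0.5 + np.linspace(0, 1, 40)
        k = Kymograph(base * g[None, :], 1000.0, 0.5)
        out, gain = normalize_kymograph(k)
        inc = ~gain.excluded_mask
        # the time-summed trace absorbs both the gain and the data's own
        # column structure, so normalized column means are constant
        col_means = out.data[:, inc].mean(axis=0)
        assert np.abs(col_means / col_means.mean() - 1).max() < 0.01

    def test_boost_cap_excludes_dim_columns(self):
        base = np.full((100, 20), 80.0)
        g = np.ones(20)
        g[0] = 0.1  # would need a 10x boost
        k = Kymograph(base * g[None, :], 1000.0, 0.5)
        out, gain = normalize_kymograph(k, boost_cap=5.0)
        assert gain.excluded_mask[0]
        assert np.allclose(out.data[:, 0], base[:, 0] * 0.1)  # untouched
        assert np.allclose(out.data[:, 1:], base[:, 1:], rtol=1e-6)

    def test_all_zero_column_flagged(self):
        data = np.full((60, 10), 5.0)
        data[:, 3] = 0.0
        out, gain = normalize_kymograph(Kymograph(data, 1000.0, 0.5))
        assert gain.excluded_mask[3]

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        k = Kymograph(rng.uniform(10, 90, (150, 25)) *
                      np.linspace(0.6, 1.4, 25)[None, :], 1000.0, 0.5)
        once, _ = normalize_kymograph(k)
        twice, gain2 = normalize_kymograph(once)
        inc = ~gain2.excluded_mask
        assert np.abs(twice.data[:, inc] / once.data[:, inc] - 1).max() < 1e-6

    def test_stack_gain_recovery_from_simulator(self):
        """FACED gain estimated from the brightest rows flattens the
        time-averaged background within 2%."""
        gain = 0.7 + 0.6 * np.sin(np.linspace(0, np.pi, 96))
        spec = SimVesselSpec(fov=(40, 96), duration=0.5, n_rbc=40, beta=0.5,
                             modulation_depths=(0.3,), faced_gain_profile=gain,
                             seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, _ = simulate_vessel_video(spec)
        norm, gp = normalize_stack(stack)
        outside_row = norm.data.mean(axis=0)[1, :]  # parenchyma row
        assert np.abs(outside_row / outside_row.mean() - 1).max() < 0.02

    def test_stack_unit_gain_identity(self):
        flat = FrameStack(np.full((5, 12, 16), 9.0), 1000.0, 0.5)
        out2, gain2 = normalize_stack(flat)
        assert np.allclose(out2.data, flat.data)
        assert np.allclose(gain2.factors, 1.0)

    def test_short_stack_and_few_rows(self):
        with pytest.raises(ValueError):
            normalize_stack(FrameStack(np.ones((1, 12, 16)), 1000.0, 0.5))
        with pytest.warns(UserWarning, match="rows"):
            normalize_stack(FrameStack(np.random.default_rng(5).uniform(
                1, 2, (4, 6, 16)), 1000.0, 0.5), n_lines=10)


class TestBinTime:
    def test_identity_floor_and_rate(self):
        k = Kymograph(np.arange(100, dtype=float).reshape(10, 10), 1e6, 0.5)
        assert np.array_equal(bin_time(k, 1).data, k.data)
        b = bin_time(k, 3)
        assert b.data.shape == (3, 10)  # 10th line dropped
        assert b.line_rate == pytest.approx(1e6 / 3)
        # 1 MHz binned by 10 -> 100 kHz
        k2 = Kymograph(np.ones((1000, 8)), 1e6, 0.5)
        assert bin_time(k2, 10).line_rate == pytest.approx(1e5)

    def test_mean_conserves_summed_intensity(self):
        rng = np.random.default_rng(6)
        s = FrameStack(rng.uniform(0, 1, (9, 6, 7)), 900.0, 0.5)
        b = bin_time(s, 3)
        assert b.data.sum() * 3 == pytest.approx(s.data.sum())

    def test_factor_exceeding_length_raises(self):
        with pytest.raises(ValueError):
            bin_time(Kymograph(np.ones((5, 4)), 1000.0, 0.5), 6)


class TestRegisterRigid:
    @staticmethod
    def _moving_stack(motion, seed=8, **kw):
        spec = SimVesselSpec(fov=(40, 96), duration=motion.shape[0] / 1000.0,
                             n_rbc=30, vmax=0.0, motion_trace=motion,
                             seed=seed, **kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, truth = simulate_vessel_video(spec)
        return stack, truth

    def test_square_wave_motion_recovered(self):
        n = 60
        motion = np.zeros((n, 2))
        motion[:, 0] = 3 * np.sign(np.sin(np.arange(n) / 5 + 0.3))
        motion[:, 1] = -2 * np.sign(np.cos(np.arange(n) / 7))
        stack, truth = self._moving_stack(motion)
        _, disp = register_rigid(stack, reference=0)
        err = disp - (motion - motion[0])
        assert np.sqrt((err**2).mean()) < 0.25

    def test_motionless_stack_near_zero_shifts(self):
        stack, _ = self._moving_stack(np.zeros((10, 2)))
        _, disp = register_rigid(stack, reference=0)
        assert np.abs(disp).max() < 0.1

    def test_inverse_consistency(self):
        from scipy import ndimage

        stack, _ = self._moving_stack(np.zeros((6, 2)))
        shifted = stack.data.copy()
        applied = np.array([[0, 0], [1.5, -2.0], [-2.5, 1.0],
                            [3.0, 0.5], [-1.0, -1.5], [2.0, 2.0]])
        for k in range(6):
            shifted[k] = ndimage.shift(stack.data[k],
                                       (applied[k, 1], applied[k, 0]),
                                       order=1, mode="nearest")
        reg, disp = register_rigid(
            FrameStack(shifted, stack.frame_rate, stack.pixel_size),
            reference=0)
        err = disp - applied
        assert np.sqrt((err**2).mean()) < 0.25

    def test_registration_removes_piv_discontinuities(self):
        """Axis-parallel brain motion corrupts kymograph PIV; registration
        restores the velocity estimate."""
        from hemokymo.kymo import extract_kymograph
        from hemokymo.velocimetry import PIVConfig, piv_velocity

        n = 120
        motion = np.zeros((n, 2))
        motion[:, 0] = 3 * np.sign(np.sin(2 * np.pi * np.arange(n) / 40))
        spec = SimVesselSpec(fov=(64, 96), duration=n / 1000.0, n_rbc=12,
                             lumen_radius=4.0, rbc_radius=2.5, vmax=2.0,
                             outside_level=100.0, outside_texture=0.5,
                             vessel_axis=np.array([[0.0, 31.5], [95.0, 31.5]]),
                             motion_trace=motion, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, _ = simulate_vessel_video(spec)
            roi = PolylineROI(np.array([[6.0, 31.5], [89.0, 31.5]]))
            cfg = PIVConfig(window_ms=2, stride_ms=1)
            raw = piv_velocity(extract_kymograph(stack, roi), cfg)
            reg, _ = register_rigid(stack, reference=0)
            fixed = piv_velocity(extract_kymograph(reg, roi), cfg)
        jump_raw = np.nanmax(np.abs(np.diff(raw.velocity)))
        jump_fix = np.nanmax(np.abs(np.diff(fixed.velocity)))
        assert jump_fix < 0.5          # smooth after registration
        assert jump_raw > 5 * jump_fix  # motion steps visible without it
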