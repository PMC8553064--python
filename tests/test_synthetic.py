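"""Speckle generator: geometry, field statistics, dynamics, camera, study layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from biospeckle.errors import ConfigError, InvalidGeometryError, UndersamplingError
from biospeckle.synthetic import (
    CameraModel,
    DecorrelationModel,
    OpticalGeometry,
    StudyConfig,
    default_rho_map,
    derive_seed,
    evolve_field,
    generate_base_field,
    plateau_for_rho,
    render_camera,
    rho_for_plateau,
    simulate_ba_matrix,
    simulate_sequence,
    simulate_study,
    theoretical_speckle_size,
)


class TestSpeckleSize:
    def test_study_geometry_matches_printed_value(self):
        """635 nm, 167 mm, 2.45 mm beam -> ~43.4 um objective speckle."""
        size = theoretical_speckle_size(
            OpticalGeometry(wavelength_nm=635, distance_mm=167, beam_width_mm=2.45)
        )
        assert size == pytest.approx(43.4, rel=5e-3)

    def test_unit_identity(self):
        g = OpticalGeometry(wavelength_nm=500, distance_mm=1000, beam_width_mm=1.0)
        assert theoretical_speckle_size(g) == pytest.approx(500.0)

    @given(
        lam=st.floats(300, 1500),
        d=st.floats(50, 2000),
        a=st.floats(0.1, 10),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity_in_wavelength_and_inverse_in_beam_width(self, lam, d, a):
        base = theoretical_speckle_size(OpticalGeometry(lam, d, a))
        assert theoretical_speckle_size(OpticalGeometry(2 * lam, d, a)) == pytest.approx(2 * base)
        assert theoretical_speckle_size(OpticalGeometry(lam, d, 2 * a)) == pytest.approx(base / 2)

    @pytest.mark.parametrize("bad", [
        dict(wavelength_nm=-1), dict(distance_mm=0), dict(beam_width_mm=-0.1),
        dict(pixel_pitch_um=0), dict(distance_mm=1.0, beam_width_mm=2.0),
    ])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(InvalidGeometryError):
            OpticalGeometry(**bad)


class TestBaseField:
    def test_intensity_is_negative_exponential(self):
        """Fully developed speckle: |E|^2 ~ Exp(1). KS test on pixels
        subsampled beyond the correlation length."""
        fld = generate_base_field((512, 512), 2.5, seed=7)
        intensity = np.abs(fld) ** 2
        sub = intensity[::5, ::5].ravel()  # ~decorrelated samples
        d, p = stats.kstest(sub, "expon")
        assert p > 0.01, f"KS distance {d:.4f}, p={p:.4f}"

    @pytest.mark.parametrize("size_px", [3.0, 6.0, 10.0])
    def test_autocovariance_fwhm_tracks_requested_size(self, size_px):
        from biospeckle.ba import estimate_speckle_size

        fld = generate_base_field((256, 256), size_px, seed=11)
        est = estimate_speckle_size(np.abs(fld) ** 2)
        assert est == pytest.approx(size_px, rel=0.15)

    def test_fwhm_matches_brute_force_autocovariance(self):
        """FFT autocovariance agrees with a direct shift-and-multiply
        computation of the normalized covariance at small lags."""
        fld = generate_base_field((128, 128), 6.0, seed=3)
        I = np.abs(fld) ** 2
        Ic = I - I.mean()
        var = (Ic**2).mean()
        direct = [np.mean(Ic * np.roll(Ic, s, axis=1)) / var for s in range(10)]
        spec = np.abs(np.fft.fft2(Ic)) ** 2
        cov = np.fft.ifft2(spec).real / Ic.size / var
        assert np.allclose(direct, cov[0, :10], atol=1e-10)

    def test_same_seed_bit_identical(self):
        a = generate_base_field((64, 64), 4.0, seed=5)
        b = generate_base_field((64, 64), 4.0, seed=5)
        assert np.array_equal(a, b)

    def test_undersampled_speckle_rejected(self):
        with pytest.raises(UndersamplingError):
            generate_base_field((64, 64), 1.5, seed=0)


class TestEvolveField:
    def test_rho_one_is_identity(self):
        fld = generate_base_field((64, 64), 4.0, seed=1)
        out = evolve_field(fld, 1.0, seed=2, speckle_size_px=4.0)
        assert np.array_equal(out, fld)

    def test_rho_zero_decorrelates(self):
        fld = generate_base_field((256, 256), 3.0, seed=1)
        out = evolve_field(fld, 0.0, seed=2, speckle_size_px=3.0)
        r = np.corrcoef(np.abs(fld).ravel() ** 2, np.abs(out).ravel() ** 2)[0, 1]
        assert abs(r) < 0.05

    def test_siegert_single_step(self):
        """One step at rho=0.9: intensity correlation ~ rho^2 = 0.81."""
        rs = []
        for seed in range(20):
            fld = generate_base_field((256, 256), 3.0, seed=100 + seed)
            out = evolve_field(fld, 0.9, seed=200 + seed, speckle_size_px=3.0)
            rs.append(np.corrcoef(np.abs(fld).ravel() ** 2, np.abs(out).ravel() ** 2)[0, 1])
        mean, se = np.mean(rs), np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(mean - 0.81) < 3 * se + 0.005

    def test_invalid_rho_rejected(self):
        fld = generate_base_field((64, 64), 4.0, seed=1)
        for rho in (-0.1, 1.1):
            with pytest.raises(ConfigError):
                evolve_field(fld, rho, seed=2, speckle_size_px=4.0)


class TestRenderCamera:
    def test_noiseless_high_depth_preserves_pattern(self):
        cam = CameraModel(bit_depth=16, readout_noise_e=0.0)
        I = np.abs(generate_base_field((64, 64), 4.0, seed=3)) ** 2
        # keep the exponential intensity tail well below full scale so the
        # comparison probes linearity, not saturation
        frame = render_camera(I, cam, seed=0, target_mean_gray=2000.0)
        r = np.corrcoef(I.ravel(), frame.ravel().astype(float))[0, 1]
        assert r > 0.9999

    def test_constant_field_noise_variance(self):
        """Readout noise in gray levels: sigma = readout_e / full_well."""
        cam = CameraModel(bit_depth=16, readout_noise_e=200.0, full_well_scale=50.0)
        frame = render_camera(np.full((256, 256), 1.0), cam, seed=4, target_mean_gray=1000)
        sigma_gray = 200.0 / 50.0
        # quantization adds ~1/12 of a gray level of variance
        assert frame.astype(float).var() == pytest.approx(sigma_gray**2 + 1 / 12, rel=0.05)

    def test_clipping_to_full_scale(self):
        cam = CameraModel(bit_depth=8, readout_noise_e=0.0)
        I = np.ones((32, 32))
        I[0, 0] = 1e6
        frame = render_camera(I, cam, seed=0, target_mean_gray=64)
        assert frame[0, 0] == 255

    def test_negative_intensity_rejected(self):
        with pytest.raises(ConfigError):
            render_camera(np.array([[-1.0, 1.0]]), CameraModel(), seed=0)


class TestSimulateSequence:
    def test_frame_count_and_metadata(self, geometry, camera):
        seq = simulate_sequence(
            geometry, camera, DecorrelationModel(0.9, "control"),
            fps=15, duration_s=2.0, seed=1, shape=(64, 64), plant_id=3, age_dap=14,
        )
        assert seq.n_frames == 30
        assert seq.frames.dtype == np.uint8
        assert seq.condition == "control" and seq.plant_id == 3 and seq.age_dap == 14
        assert seq.frames.max() <= camera.max_gray

    def test_phantom_is_static_up_to_noise(self, geometry, camera):
        seq = simulate_sequence(
            geometry, camera, DecorrelationModel(1.0, "phantom"),
            fps=15, duration_s=2.0, seed=2, shape=(64, 64),
        )
        r = np.corrcoef(seq.frames[0].ravel().astype(float),
                        seq.frames[-1].ravel().astype(float))[0, 1]
        assert r > 0.999

    def test_ba_matches_siegert_closed_form(self, geometry, noiseless_camera):
        """Seed-averaged BA_k of simulated sequences tracks 1 - rho^(2k)."""
        from biospeckle.ba import ba_curve

        rho, n_seeds = 0.9, 12
        curves = np.stack([
            ba_curve(simulate_sequence(
                geometry, noiseless_camera, DecorrelationModel(rho, "x"),
                fps=15, duration_s=11 / 15, seed=300 + s, shape=(128, 128),
            )).ba
            for s in range(n_seeds)
        ])
        k = np.arange(1, 11)
        expected = 1 - rho ** (2 * k)
        se = curves.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        assert np.all(np.abs(curves.mean(axis=0) - expected) < 3 * se + 0.01)

    def test_batch_path_agrees_with_sequence_path(self, geometry, noiseless_camera):
        """The vectorized calibration engine and the frame-by-frame camera
        pipeline are two routes to the same BA statistics."""
        from biospeckle.ba import ba_curve

        rho = 0.8
        batch = simulate_ba_matrix(30, rho, 6, shape=(128, 128),
                                   speckle_size_px=3.0, seed=9)
        geom = OpticalGeometry(pixel_pitch_um=theoretical_speckle_size(geometry) / 3.0)
        seq_ba = np.stack([
            ba_curve(simulate_sequence(
                geom, noiseless_camera, DecorrelationModel(rho, "x"),
                fps=15, duration_s=6 / 15, seed=400 + s, shape=(128, 128),
            )).ba
            for s in range(30)
        ])
        assert np.allclose(batch.mean(axis=0), seq_ba.mean(axis=0), atol=0.02)


class TestPlateauCalibration:
    @pytest.mark.parametrize("plateau", [0.5, 0.7, 0.9])
    def test_rho_plateau_round_trip(self, plateau):
        rho = rho_for_plateau(plateau)
        assert 0 < rho < 1
        assert plateau_for_rho(rho) == pytest.approx(plateau, abs=1e-9)

    def test_control_decorrelates_fastest(self):
        m = default_rho_map(("control", "100Hz", "1kHz", "10kHz"), (30,))
        assert m[("control", 30)] < m[("100Hz", 30)] < m[("1kHz", 30)] < m[("10kHz", 30)]

    def test_phantom_rho_is_one(self):
        assert default_rho_map(("phantom",), (30,))[("phantom", 30)] == 1.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError):
            default_rho_map(("ultrasound",), (30,))


class TestSimulateStudy:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_study():
        return StudyConfig(
            conditions=("control", "rock"), ages=(30,), n_plants=2,
            duration_s=0.5, shape=(32, 32),
        )

    def test_fifteen_sequences_per_plant_per_condition(self, tiny_study):
        seqs = list(simulate_study(tiny_study, master_seed=1))
        assert len(seqs) == 2 * 2 * 15
        per = [s for s in seqs if s.plant_id == 1 and s.condition == "control"]
        assert len(per) == 15

    def test_same_master_seed_identical_datasets(self, tiny_study):
        a = list(simulate_study(tiny_study, master_seed=7))
        b = list(simulate_study(tiny_study, master_seed=7))
        assert all(np.array_equal(x.frames, y.frames) for x, y in zip(a, b))

    def test_different_master_seed_differs(self, tiny_study):
        a = next(iter(simulate_study(tiny_study, master_seed=1)))
        b = next(iter(simulate_study(tiny_study, master_seed=2)))
        assert not np.array_equal(a.frames, b.frames)

    def test_missing_condition_in_rho_map(self):
        cfg = StudyConfig(conditions=("control", "rock"), ages=(30,),
                          rho_map={("control", 30): 0.99})
        with pytest.raises(ConfigError):
            list(simulate_study(cfg, master_seed=0))


def test_derive_seed_stable_and_bounded():
    s1 = derive_seed(42, "a", 1, 2)
    assert s1 == derive_seed(42, "a", 1, 2)
    assert s1 != derive_seed(42, "a", 1, 3)
    assert 0 <= s1 < 2**31
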