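"""Forward model: Fourier-optics correctness, symmetries, bead and noise."""

import numpy as np
import pytest

from phaseret import (
    AmplitudeVector,
    MicroscopeConfig,
    NoiseParams,
    POINT_SCANNING,
    PSFStack,
    WIDEFIELD,
    add_noise,
    bead_convolve,
    compute_psf,
    simulation_grid,
    standardize,
)
from phaseret.psf import bead_kernel
from phaseret.zernike import synthesize_wavefront


def direct_dft_psf(a: AmplitudeVector, config: MicroscopeConfig) -> np.ndarray:
    """Directly summed Fourier integral (matrix DFT, no FFT): the oracle."""
    grid = simulation_grid(config)
    phi = synthesize_wavefront(a, grid).phase
    n0, lam = config.immersion_index, config.wavelength
    kz = np.sqrt(np.maximum((n0 / lam) ** 2 - grid.kx**2 - grid.ky**2, 0.0))
    n = grid.n
    m = np.arange(n) - n // 2  # centered sample indices
    w = np.exp(-2j * np.pi * np.outer(m, m) / n)  # DFT matrix, centered
    z = (np.arange(config.nz) - (config.nz - 1) / 2.0) * config.axial_voxel
    planes = []
    for zi in z:
        field = np.where(
            grid.mask, np.exp(2j * np.pi * (phi / lam - zi * kz)), 0.0
        )
        planes.append(np.abs(w @ field @ w.T) ** 2)
    return np.stack(planes) / float(grid.mask.sum()) ** 2


class TestComputePsf:
    def test_energy_conserved_per_plane_before_crop(self):
        stack = compute_psf(AmplitudeVector.zeros(), POINT_SCANNING, crop=False)
        sums = stack.intensity.sum(axis=(1, 2))
        assert sums.std() / sums.mean() < 1e-3

    def test_unaberrated_peak_is_one_and_central(self):
        stack = compute_psf(AmplitudeVector.zeros(), POINT_SCANNING)
        nz, ny, nx = stack.shape
        peak = np.unravel_index(stack.intensity.argmax(), stack.shape)
        assert peak[1:] == (ny // 2, nx // 2)
        assert peak[0] in (nz // 2 - 1, nz // 2)  # even nz straddles focus
        assert stack.intensity.max() == pytest.approx(1.0, abs=0.01)

    def test_unaberrated_stack_axially_symmetric(self):
        stack = compute_psf(AmplitudeVector.zeros(), POINT_SCANNING)
        dev = np.abs(stack.intensity - stack.intensity[::-1])
        assert dev.max() / stack.intensity.max() < 1e-6

    def test_even_mode_sign_flip_mirrors_stack_axially(self):
        plus = compute_psf(AmplitudeVector.single(5, 0.05), POINT_SCANNING, crop=False)
        minus = compute_psf(AmplitudeVector.single(5, -0.05), POINT_SCANNING, crop=False)
        dev = np.abs(minus.intensity[::-1] - plus.intensity)
        assert dev.max() / plus.intensity.max() < 1e-6

    def test_even_modes_share_focal_plane_for_both_signs(self):
        """The single-plane ambiguity mechanism: with only even modes, +a and
        -a are indistinguishable at z = 0."""
        cfg = POINT_SCANNING.replace(shape=(5, 32, 32))  # odd nz: exact z=0 plane
        rng = np.random.default_rng(3)
        a = AmplitudeVector.zeros()
        for j in (5, 6, 11, 12, 13, 14, 15):
            a.values[a.index_list.index(j)] = rng.uniform(-0.075, 0.075)
        plus = compute_psf(a, cfg).intensity[2]
        minus = compute_psf(AmplitudeVector(-a.values), cfg).intensity[2]
        assert np.abs(plus - minus).max() / plus.max() < 1e-6

    def test_odd_mode_sign_flip_point_reflects_each_plane(self):
        cfg = POINT_SCANNING
        plus = compute_psf(AmplitudeVector.single(7, 0.06), cfg, crop=False)
        minus = compute_psf(AmplitudeVector.single(7, -0.06), cfg, crop=False)
        # lateral point reflection about the DC sample on the periodic grid
        reflected = np.roll(plus.intensity[:, ::-1, ::-1], (1, 1), axis=(1, 2))
        assert np.abs(minus.intensity - reflected).max() / plus.intensity.max() < 1e-6
        # axial intensity profile is untouched
        np.testing.assert_allclose(
            plus.intensity.sum(axis=(1, 2)),
            minus.intensity.sum(axis=(1, 2)),
            rtol=1e-10,
        )

    def test_strehl_never_exceeds_unaberrated_peak(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = AmplitudeVector(rng.uniform(-0.075, 0.075, 11))
            stack = compute_psf(a, POINT_SCANNING)
            assert stack.intensity.max() <= 1.0 + 1e-9

    def test_fft_matches_direct_sum_small_pupil(self):
        """FFT path vs a directly summed Fourier integral on an 8x8 pupil."""
        cfg = MicroscopeConfig(
            na=1.4, wavelength=0.755, immersion_index=1.518,
            lateral_voxel=0.1, axial_voxel=0.1, shape=(4, 8, 8),
            oversample_factor=1,
        )
        a = AmplitudeVector(np.random.default_rng(5).uniform(-0.075, 0.075, 11))
        fft_stack = compute_psf(a, cfg, crop=False).intensity
        oracle = direct_dft_psf(a, cfg)
        assert np.abs(fft_stack - oracle).max() / oracle.max() < 1e-10

    def test_fft_matches_direct_sum_point_scanning_grid(self):
        cfg = POINT_SCANNING.replace(shape=(3, 32, 32))
        a = AmplitudeVector(np.random.default_rng(6).uniform(-0.075, 0.075, 11))
        fft_stack = compute_psf(a, cfg, crop=False).intensity
        oracle = direct_dft_psf(a, cfg)
        assert np.abs(fft_stack - oracle).max() / oracle.max() < 1e-10

    def test_na_exceeding_immersion_index_rejected(self):
        with pytest.raises(ValueError):
            MicroscopeConfig(
                na=1.4, wavelength=0.755, immersion_index=1.33,
                lateral_voxel=0.03, axial_voxel=0.03, shape=(8, 8, 8),
            )

    def test_aliasing_voxel_size_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            MicroscopeConfig(
                na=1.4, wavelength=0.755, immersion_index=1.518,
                lateral_voxel=0.30, axial_voxel=0.30, shape=(8, 8, 8),
            )


class TestBeadConvolution:
    def test_zero_diameter_is_identity(self):
        stack = compute_psf(AmplitudeVector.zeros(), WIDEFIELD)
        assert bead_convolve(stack, 0.0) is stack

    def test_total_intensity_preserved_for_interior_support(self):
        # compact blob well inside the volume: no edge truncation
        cfg = WIDEFIELD
        z, y, x = np.indices(cfg.shape)
        blob = np.exp(-(((z - 25) ** 2 + (y - 25) ** 2 + (x - 25) ** 2) / 8.0))
        stack = PSFStack(blob, cfg)
        out = bead_convolve(stack, 0.2, supersample=3)
        assert out.intensity.sum() == pytest.approx(stack.intensity.sum(), rel=1e-3)

    def test_smoothing_reduces_peak(self):
        stack = compute_psf(AmplitudeVector.zeros(), WIDEFIELD)
        out = bead_convolve(stack, 0.2, supersample=3)
        assert out.intensity.max() < stack.intensity.max()

    def test_kernel_unit_sum_and_sphere_shape(self):
        k = bead_kernel(WIDEFIELD, 0.2, supersample=3)
        assert k.sum() == pytest.approx(1.0)
        assert k.shape == (3, 3, 3)
        assert k[1, 1, 1] == k.max()

    def test_oversized_kernel_rejected(self):
        stack = compute_psf(AmplitudeVector.zeros(), WIDEFIELD)
        with pytest.raises(ValueError):
            bead_convolve(stack, 20.0)


class TestNoise:
    def test_disabled_noise_is_identity(self):
        stack = compute_psf(AmplitudeVector.zeros(), POINT_SCANNING)
        out = add_noise(stack, NoiseParams(0.0, 0.0), rng=0)
        np.testing.assert_array_equal(out.intensity, stack.intensity)

    def test_deterministic_given_seed(self):
        stack = compute_psf(AmplitudeVector.single(5, 0.05), POINT_SCANNING)
        a = add_noise(stack, rng=42)
        b = add_noise(stack, rng=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_poisson_variance_matches_mean(self):
        cfg = WIDEFIELD
        const = PSFStack(np.full(cfg.shape, 0.5), cfg)  # 125000 voxels
        out = add_noise(const, NoiseParams(500.0, 0.0), rng=1)
        counts = out.intensity * (500.0 / 0.5)  # back to photon units
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_output_clipped_non_negative(self):
        stack = compute_psf(AmplitudeVector.zeros(), POINT_SCANNING)
        out = add_noise(stack, NoiseParams(50.0, 0.2), rng=3)
        assert out.intensity.min() >= 0.0


class TestStandardize:
    def test_zero_mean_unit_variance(self):
        stack = compute_psf(AmplitudeVector.single(6, 0.04), POINT_SCANNING)
        x = standardize(stack)
        assert abs(x.mean()) < 1e-10
        assert x.std() == pytest.approx(1.0)

    def test_gain_and_offset_invariance(self):
        stack = compute_psf(AmplitudeVector.single(6, 0.04), POINT_SCANNING)
        scaled = 7.5 * stack.intensity + 0.0
        np.testing.assert_allclose(standardize(stack), standardize(scaled), atol=1e-9)
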