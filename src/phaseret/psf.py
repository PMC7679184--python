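"""Scalar Fourier-optics simulation of aberrated 3D bead images.

For an aberration phi (um) on the pupil, each defocus plane z of the
intensity PSF is the squared modulus of the 2D Fourier transform of the pupil
field

    h(x, y, z) = | F[ P(kx,ky) * exp(2 pi i phi / lambda)
                      * exp(-2 pi i z sqrt(n0^2/lambda^2 - kx^2 - ky^2)) ] |^2

with P the binary pupil (1 inside NA/lambda, 0 outside) and n0 the immersion
index. The model is scalar (no vectorial high-NA corrections, no pupil
amplitude attenuation) and assumes NA < n0 so the axial propagation root is
real over the whole pupil.

Simulation runs on a laterally padded k-space grid (``oversample_factor``
times the requested size) and is center-cropped afterwards, which suppresses
wrap-around from the periodicity of the FFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .config import MicroscopeConfig, NoiseParams
from .zernike import AmplitudeVector, PupilGrid, synthesize_wavefront

__all__ = [
    "PSFStack",
    "simulation_grid",
    "compute_psf",
    "bead_convolve",
    "add_noise",
    "standardize",
    "bead_kernel",
    "simulate_bead_image",
]


@dataclass
class PSFStack:
    """3D intensity image with voxel metadata.

    ``intensity`` is (nz, ny, nx), non-negative and finite; ``z_offsets`` are
    the plane positions in um, uniformly spaced by the axial voxel size and
    centered on focus (for even nz the two central planes straddle z = 0).
    """

    intensity: np.ndarray
    config: MicroscopeConfig
    z_offsets: np.ndarray = field(default=None)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (nz, ny, nx) array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensity")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if self.z_offsets is None:
            nz = self.intensity.shape[0]
            self.z_offsets = (np.arange(nz) - (nz - 1) / 2.0) * self.config.axial_voxel
        self.z_offsets = np.asarray(self.z_offsets, dtype=float)
        if len(self.z_offsets) != self.intensity.shape[0]:
            raise ValueError("one z offset per plane required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def simulation_grid(config: MicroscopeConfig) -> PupilGrid:
    """Padded k-space grid the simulator runs on.

    The grid has ``oversample_factor * max(nx, ny)`` samples per axis with
    spacing dk = 1 / (N_sim * dx), so the cropped image keeps the requested
    voxel size while FFT periodicity artifacts fall outside the crop.
    """
    nz, ny, nx = config.shape
    n_sim = config.oversample_factor * max(nx, ny)
    dk = 1.0 / (n_sim * config.lateral_voxel)
    return PupilGrid(n=n_sim, dk=dk, cutoff=config.cutoff)


def _pupil_phase_factors(a: AmplitudeVector, config: MicroscopeConfig, grid: PupilGrid):
    phi = synthesize_wavefront(a, grid).phase  # um
    n0, lam = config.immersion_index, config.wavelength
    k2 = grid.kx**2 + grid.ky**2
    kz = np.sqrt(np.maximum((n0 / lam) ** 2 - k2, 0.0))  # real: NA < n0
    aberration = np.where(grid.mask, np.exp(2j * np.pi * phi / lam), 0.0)
    return aberration, kz


def compute_psf(
    a: AmplitudeVector, config: MicroscopeConfig, crop: bool = True
) -> PSFStack:
    """Noiseless, bead-free aberrated PSF stack.

    The stack is normalized so the in-focus peak of the *unaberrated* PSF is 1
    (i.e. the peak value of an aberrated stack is its Strehl ratio). With
    ``crop=False`` the full padded lateral grid is returned, on which per-plane
    energy is conserved exactly (Parseval).
    """
    grid = simulation_grid(config)
    aberration, kz = _pupil_phase_factors(a, config, grid)
    nz, ny, nx = config.shape
    z = (np.arange(nz) - (nz - 1) / 2.0) * config.axial_voxel

    # all planes at once: (nz, N, N) pupil fields
    defocus = np.exp(-2j * np.pi * z[:, None, None] * kz[None, :, :])
    fields = aberration[None, :, :] * defocus
    imgs = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(fields, axes=(1, 2)), axes=(1, 2)),
        axes=(1, 2),
    )
    intensity = np.abs(imgs) ** 2
    peak_norm = float(grid.mask.sum()) ** 2  # unaberrated in-focus peak
    intensity /= peak_norm

    if crop:
        n = grid.n
        y0, x0 = n // 2 - ny // 2, n // 2 - nx // 2
        intensity = intensity[:, y0 : y0 + ny, x0 : x0 + nx]
    return PSFStack(intensity, config, z)


def bead_kernel(
    config: MicroscopeConfig, diameter: float, supersample: int = 1
) -> np.ndarray:
    """Voxelized solid sphere, unit sum, shape (kz, ky, kx).

    A voxel belongs to the sphere if its center is within the radius; with
    ``supersample`` > 1 each voxel is subdivided and weighted by the fraction
    of sub-centers inside, which matters when the bead spans only ~2 voxels.
    """
    r = diameter / 2.0
    dx, dz = config.lateral_voxel, config.axial_voxel
    hx = int(np.floor(r / dx))
    hz = int(np.floor(r / dz))
    zz = (np.arange(-hz, hz + 1) * dz)[:, None, None]
    yy = (np.arange(-hx, hx + 1) * dx)[None, :, None]
    xx = (np.arange(-hx, hx + 1) * dx)[None, None, :]
    if supersample <= 1:
        inside = (zz**2 + yy**2 + xx**2 <= r**2).astype(float)
    else:
        s = supersample
        off = (np.arange(s) - (s - 1) / 2.0) / s
        inside = np.zeros((2 * hz + 1, 2 * hx + 1, 2 * hx + 1))
        for oz in off * dz:
            for oy in off * dx:
                for ox in off * dx:
                    inside += (
                        (zz + oz) ** 2 + (yy + oy) ** 2 + (xx + ox) ** 2 <= r**2
                    )
        inside /= s**3
    total = inside.sum()
    if total == 0:  # bead smaller than half a voxel: point emitter
        inside[hz, hx, hx] = 1.0
        total = 1.0
    return inside / total


def bead_convolve(
    stack: PSFStack, diameter: float | None = None, supersample: int = 1
) -> PSFStack:
    """Convolve the PSF with a solid fluorescent sphere of the given diameter.

    ``diameter=None`` uses the config's bead size; 0 returns the input
    unchanged. The kernel has unit sum, so total intensity is preserved away
    from the stack borders.
    """
    if diameter is None:
        diameter = stack.config.bead_diameter
    if diameter < 0:
        raise ValueError("bead diameter must be >= 0")
    if diameter == 0:
        return stack
    kernel = bead_kernel(stack.config, diameter, supersample=supersample)
    if any(k > s for k, s in zip(kernel.shape, stack.shape)):
        raise ValueError(
            f"bead kernel {kernel.shape} larger than stack {stack.shape}"
        )
    if kernel.size == 1:
        return stack
    out = fftconvolve(stack.intensity, kernel, mode="same")
    return PSFStack(np.maximum(out, 0.0), stack.config, stack.z_offsets)


def add_noise(
    stack: PSFStack,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> PSFStack:
    """Apply Poisson shot noise and additive Gaussian read noise.

    The stack is scaled so its maximum equals the expected peak photon count,
    Poisson counts are drawn per voxel, zero-mean Gaussian noise with standard
    deviation ``gaussian_sigma`` (as a fraction of the peak) is added, and the
    result is rescaled to the input's intensity scale. Negative values are
    clipped to 0 last. Deterministic for a given generator state.
    """
    if noise is None:
        noise = stack.config.noise
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = stack.intensity
    peak = float(x.max())
    if peak == 0 or (noise.poisson_photons_at_peak == 0 and noise.gaussian_sigma == 0):
        return PSFStack(x.copy(), stack.config, stack.z_offsets)
    if noise.poisson_photons_at_peak > 0:
        scale = noise.poisson_photons_at_peak / peak
        out = rng.poisson(x * scale).astype(float)
        if noise.gaussian_sigma > 0:
            out += rng.normal(
                0.0, noise.gaussian_sigma * noise.poisson_photons_at_peak, x.shape
            )
        out /= scale
    else:
        out = x + rng.normal(0.0, noise.gaussian_sigma * peak, x.shape)
    return PSFStack(np.maximum(out, 0.0), stack.config, stack.z_offsets)


def standardize(stack: PSFStack | np.ndarray) -> np.ndarray:
    """Per-volume standardization to zero mean and unit variance.

    Applied to every stack before it enters the network, which makes
    predictions invariant to acquisition gain and offset.
    """
    x = stack.intensity if isinstance(stack, PSFStack) else np.asarray(stack, float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - mu) / sd


def simulate_bead_image(
    a: AmplitudeVector,
    config: MicroscopeConfig,
    rng: np.random.Generator | int | None = None,
    noisy: bool = True,
) -> PSFStack:
    """Full image-formation chain: PSF, bead convolution, noise."""
    stack = compute_psf(a, config)
    supersample = 3 if config.bead_diameter > 1.5 * config.lateral_voxel else 1
    stack = bead_convolve(stack, supersample=supersample)
    if noisy:
        stack = add_noise(stack, rng=rng)
    return stack
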