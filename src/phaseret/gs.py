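"""Multi-plane Gerchberg-Saxton phase retrieval baseline.

GS alternates between two constraint sets: in each defocus plane the field
modulus must equal the square root of the measured intensity, and in the
pupil the field must have unit amplitude inside the NA cutoff and vanish
outside. One iteration propagates the current pupil estimate to every
z-plane with the scalar defocus kernel, replaces each plane's modulus while
keeping its phase, back-propagates, and averages the per-plane pupil
estimates before re-imposing the support constraint (parallel plane
combination, which is stabler than sequential cycling for tens of planes).

The retrieved pupil phase is finally projected onto Zernike modes; piston,
tip, tilt and defocus — which encode bead position rather than aberration —
are removed, and modes 5..15 are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MicroscopeConfig
from .psf import PSFStack
from .zernike import (
    AmplitudeVector,
    DEFAULT_INDEX_LIST,
    PupilGrid,
    WavefrontMap,
    decompose_wavefront,
    synthesize_wavefront,
)

__all__ = ["GSResult", "gs_retrieve", "remove_trivial_modes"]


@dataclass
class GSResult:
    """Output of one GS run."""

    pupil_phase: WavefrontMap  # um, trivial modes removed
    amplitudes: AmplitudeVector  # Noll 5..15 (or the requested list)
    iterations_run: int
    residual: np.ndarray  # per-iteration data misfit


def remove_trivial_modes(w: WavefrontMap) -> WavefrontMap:
    """Subtract the least-squares piston/tip/tilt/defocus component.

    These four modes correspond to a global phase offset, a lateral bead
    shift and an axial focus shift; they carry no aberration information and
    would otherwise contaminate the RMSE. Idempotent.
    """
    trivial = decompose_wavefront(w, index_list=(1, 2, 3, 4))
    return WavefrontMap(w.phase - synthesize_wavefront(trivial, w.grid).phase, w.grid)


def _auto_pad_factor(n: int, dx: float, cutoff: float, min_radius: float = 3.0) -> int:
    """Smallest power-of-two image-space padding that samples the pupil
    with at least ``min_radius`` k-space samples of radius."""
    for p in (1, 2, 4, 8, 16):
        if cutoff / (1.0 / (p * n * dx)) >= min_radius:
            return p
    return 16


def _retrieval_grid(
    stack: PSFStack, config: MicroscopeConfig, pad_factor: int
) -> PupilGrid:
    n = stack.shape[1]
    if stack.shape[1] != stack.shape[2]:
        raise ValueError("GS retrieval expects square lateral planes")
    n_pad = pad_factor * n
    dk = 1.0 / (n_pad * config.lateral_voxel)
    return PupilGrid(n=n_pad, dk=dk, cutoff=config.cutoff)


def gs_retrieve(
    stack: PSFStack,
    config: MicroscopeConfig | None = None,
    n_iter: int = 30,
    index_list=DEFAULT_INDEX_LIST,
    pad_factor: int | None = None,
    seed: int | None = None,
) -> GSResult:
    """Estimate the pupil phase of a measured PSF stack by alternating
    projections.

    Parameters
    ----------
    stack
        Measured (or simulated) 3D bead image.
    config
        Optical parameters; defaults to ``stack.config``.
    n_iter
        Number of full multi-plane iterations (default 30).
    index_list
        Noll indices reported after removal of piston/tip/tilt/defocus.
    pad_factor
        Image-space zero-padding applied before the FFTs. The field of view
        of a bead crop is often so small that the raw k-space sampling
        resolves the pupil with only a handful of samples; padding refines
        dk. The measured-modulus constraint is enforced only inside the
        measured window — outside it the model amplitude is kept. ``None``
        picks the smallest power of two that gives the pupil at least 3
        samples of radius (heavier padding enlarges the unconstrained
        region and was found to help neither accuracy nor noise robustness).
    seed
        If given, start from a seeded random pupil phase instead of zero
        phase (useful for restarts); the default zero start is deterministic.

    Notes
    -----
    The per-iteration residual is the relative L2 misfit between the modeled
    and measured plane amplitudes; it is non-increasing in expectation but
    not guaranteed monotone. Wrapped-phase jumps on the pupil raise an
    error: at the amplitude ranges this package targets (|phi| well below
    lambda/2) the retrieved phase never wraps, and silent unwrapping could
    hide a diverged run.
    """
    config = config or stack.config
    nz, ny, nx = stack.shape
    if pad_factor is None:
        pad_factor = _auto_pad_factor(nx, config.lateral_voxel, config.cutoff)
    grid = _retrieval_grid(stack, config, pad_factor)
    mask = grid.mask
    lam, n0 = config.wavelength, config.immersion_index
    kz = np.sqrt(
        np.maximum((n0 / lam) ** 2 - (grid.kx**2 + grid.ky**2), 0.0)
    )
    z = stack.z_offsets
    defocus = np.exp(-2j * np.pi * z[:, None, None] * kz[None, :, :])

    # measured moduli, embedded centrally in the padded grid; the modulus
    # constraint acts only inside this window
    n = grid.n
    y0, x0 = n // 2 - ny // 2, n // 2 - nx // 2
    win = (slice(None), slice(y0, y0 + ny), slice(x0, x0 + nx))
    measured = np.sqrt(np.clip(stack.intensity, 0.0, None))
    meas_norm = np.sqrt((measured**2).sum(axis=(1, 2), keepdims=True))
    meas_norm[meas_norm == 0] = 1.0
    measured_unit = measured / meas_norm

    if seed is None:
        phase0 = np.zeros_like(grid.kx)
    else:
        phase0 = np.random.default_rng(seed).uniform(-np.pi, np.pi, grid.kx.shape)
    pupil = np.where(mask, np.exp(1j * phase0), 0.0)

    residual = np.empty(n_iter)
    for it in range(n_iter):
        fields = pupil[None] * defocus
        planes = np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(fields, axes=(1, 2)), axes=(1, 2)),
            axes=(1, 2),
        )
        amp_win = np.abs(planes[win])
        model_norm = np.sqrt((amp_win**2).sum(axis=(1, 2), keepdims=True))
        model_norm[model_norm == 0] = 1.0
        residual[it] = float(
            np.sqrt(((amp_win / model_norm - measured_unit) ** 2).sum())
            / np.sqrt(len(z))
        )
        # modulus replacement inside the window, keeping phase; the per-plane
        # scale is matched to the model so retrieval is gain-free
        with np.errstate(invalid="ignore", divide="ignore"):
            phase_factor = np.where(amp_win > 0, planes[win] / amp_win, 1.0)
        planes[win] = (measured_unit * model_norm) * phase_factor
        back = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(planes, axes=(1, 2)), axes=(1, 2)),
            axes=(1, 2),
        )
        back *= np.conj(defocus)
        avg = back.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pupil = np.where(mask & (np.abs(avg) > 0), avg / np.abs(avg), mask * 1.0)

    phase_um = np.where(mask, np.angle(pupil), 0.0) * lam / (2 * np.pi)
    _check_no_wraps(phase_um, mask, lam)
    wavefront = remove_trivial_modes(WavefrontMap(phase_um, grid))
    amplitudes = decompose_wavefront(wavefront, index_list)
    return GSResult(wavefront, amplitudes, n_iter, residual)


def _check_no_wraps(phase_um: np.ndarray, mask: np.ndarray, lam: float) -> None:
    """Detect 2-pi jumps between neighboring interior pupil samples.

    The outermost two rings of mask samples are excluded: their averaged
    field amplitude is small and their angle correspondingly noisy, which
    would otherwise mimic a wrap on noisy data.
    """
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(mask, iterations=2)
    jump = 0.6 * lam  # well past any smooth per-sample phase difference
    for ax in (0, 1):
        d = np.abs(np.diff(phase_um, axis=ax))
        both = (
            interior[:-1, :] & interior[1:, :]
            if ax == 0
            else interior[:, :-1] & interior[:, 1:]
        )
        if np.any(d[both] > jump):
            raise RuntimeError(
                "wrapped phase detected on the pupil; the aberration exceeds "
                "the unambiguous range of this retrieval (|phi| ~ lambda/2)"
            )
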