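"""Noll-indexed Zernike modes on a sampled pupil.

The wavefront aberration phi(kx, ky) -- the optical-path deviation from an
ideal spherical wavefront, in micrometres -- is expressed as a sum of Zernike
polynomials over the pupil disk,

    phi(kx, ky) = sum_i a_i Z_i(kx, ky),

with ``Z_i`` the i-th Noll-indexed mode and ``a_i`` its amplitude in um.
Modes carry the unit-RMS (Noll) normalization: the mean of ``Z_i**2`` over the
unit disk is 1, so each coefficient equals the RMS wavefront contribution of
its mode and ``sqrt(sum a_i**2)`` is the RMS of the whole wavefront.

Azimuthal parity matters physically: modes with even azimuthal frequency m
satisfy Z(-kx, -ky) = Z(kx, ky) (sign flips mirror the PSF axially), odd-m
modes are antisymmetric (sign flips point-reflect the PSF laterally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ZernikeMode",
    "AmplitudeVector",
    "PupilGrid",
    "WavefrontMap",
    "noll_to_nm",
    "nm_to_noll",
    "evaluate_mode",
    "synthesize_wavefront",
    "decompose_wavefront",
    "rms_error",
    "DEFAULT_INDEX_LIST",
    "EVEN_MODES_5_15",
    "ODD_MODES_5_15",
]

#: Noll indices used as the default regression target: the first 11
#: non-trivial modes, excluding piston, tip, tilt and defocus.
DEFAULT_INDEX_LIST: tuple[int, ...] = tuple(range(5, 16))

_NOLL_NAMES = {
    1: "piston",
    2: "tip",
    3: "tilt",
    4: "defocus",
    5: "oblique astigmatism",
    6: "vertical astigmatism",
    7: "vertical coma",
    8: "horizontal coma",
    9: "vertical trefoil",
    10: "oblique trefoil",
    11: "primary spherical",
    12: "vertical secondary astigmatism",
    13: "oblique secondary astigmatism",
    14: "vertical quadrafoil",
    15: "oblique quadrafoil",
}


@dataclass(frozen=True)
class ZernikeMode:
    """One Zernike mode identified by its Noll index.

    Attributes
    ----------
    noll_index : int
        Single-integer Noll enumeration, >= 1.
    n : int
        Radial degree.
    m : int
        Signed azimuthal frequency; ``m < 0`` selects the sine term,
        ``m > 0`` the cosine term. ``|m| <= n`` and ``n - |m|`` is even.
    name : str
        Conventional name (populated for indices 1..15).
    parity : str
        ``"even"`` if m is even (wavefront point-symmetric), else ``"odd"``.
    """

    noll_index: int
    n: int
    m: int
    name: str = ""
    parity: str = field(init=False, default="")

    def __post_init__(self):
        object.__setattr__(self, "parity", "even" if self.m % 2 == 0 else "odd")


def noll_to_nm(j: int) -> ZernikeMode:
    """Map a Noll index to its (n, m) pair.

    Noll's enumeration orders modes by radial degree n, then by increasing
    azimuthal frequency |m|; within a +/-|m| pair the even index takes the
    cosine (m > 0) term and the odd index the sine (m < 0) term.
    """
    if not isinstance(j, (int, np.integer)) or j < 1:
        raise ValueError(f"Noll index must be an integer >= 1, got {j!r}")
    j = int(j)
    # radial degree: smallest n with cumulative mode count >= j
    n = 0
    while (n + 1) * (n + 2) // 2 < j:
        n += 1
    # position within the degree-n group (1-based)
    r = j - n * (n + 1) // 2
    abs_ms = list(range(n % 2, n + 1, 2))  # |m| ascending
    count = 0
    for am in abs_ms:
        width = 1 if am == 0 else 2
        if count + width >= r:
            if am == 0:
                m = 0
            else:
                m = am if j % 2 == 0 else -am
            return ZernikeMode(j, n, m, _NOLL_NAMES.get(j, ""))
        count += width
    raise AssertionError("unreachable")  # pragma: no cover


def nm_to_noll(n: int, m: int) -> int:
    """Inverse of :func:`noll_to_nm` (raises if (n, m) is not a valid pair)."""
    if n < 0 or abs(m) > n or (n - abs(m)) % 2:
        raise ValueError(f"invalid Zernike degree pair (n={n}, m={m})")
    base = n * (n + 1) // 2
    r = 0
    for am in range(n % 2, n + 1, 2):
        width = 1 if am == 0 else 2
        if am == abs(m):
            if m == 0:
                return base + r + 1
            j1, j2 = base + r + 1, base + r + 2
            # even index -> cosine (m > 0), odd index -> sine (m < 0)
            for j in (j1, j2):
                if (m > 0) == (j % 2 == 0):
                    return j
        r += width
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class AmplitudeVector:
    """Ordered Zernike coefficients in um (RMS per mode).

    ``values[i]`` is the amplitude of mode ``index_list[i]``. The default
    index list is Noll 5..15 (piston, tip, tilt and defocus excluded: they
    displace or refocus the image rather than aberrate it).
    """

    values: np.ndarray
    index_list: tuple[int, ...] = DEFAULT_INDEX_LIST

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.index_list = tuple(int(i) for i in self.index_list)
        if self.values.ndim != 1 or len(self.values) != len(self.index_list):
            raise ValueError(
                f"{len(self.values)} values for {len(self.index_list)} indices"
            )
        if any(i < 1 for i in self.index_list):
            raise ValueError("Noll indices must be >= 1")
        if any(b <= a for a, b in zip(self.index_list, self.index_list[1:])):
            raise ValueError("index_list must be strictly increasing")

    @classmethod
    def zeros(cls, index_list: Sequence[int] = DEFAULT_INDEX_LIST) -> "AmplitudeVector":
        return cls(np.zeros(len(tuple(index_list))), tuple(index_list))

    @classmethod
    def single(
        cls, noll_index: int, amplitude: float,
        index_list: Sequence[int] = DEFAULT_INDEX_LIST,
    ) -> "AmplitudeVector":
        """Vector with one non-zero mode."""
        a = cls.zeros(index_list)
        a.values[a.index_list.index(noll_index)] = amplitude
        return a

    def norm(self) -> float:
        """RMS of the synthesized wavefront: sqrt(sum a_i**2), in um."""
        return float(np.sqrt(np.sum(self.values**2)))

    def __add__(self, other: "AmplitudeVector") -> "AmplitudeVector":
        if self.index_list != other.index_list:
            raise ValueError("mismatched index lists")
        return AmplitudeVector(self.values + other.values, self.index_list)

    def __sub__(self, other: "AmplitudeVector") -> "AmplitudeVector":
        if self.index_list != other.index_list:
            raise ValueError("mismatched index lists")
        return AmplitudeVector(self.values - other.values, self.index_list)


def _parity_class(indices: Iterable[int], parity: str) -> tuple[int, ...]:
    return tuple(j for j in indices if noll_to_nm(j).parity == parity)


#: Even/odd azimuthal-parity classes within the default target modes.
EVEN_MODES_5_15: tuple[int, ...] = _parity_class(DEFAULT_INDEX_LIST, "even")
ODD_MODES_5_15: tuple[int, ...] = _parity_class(DEFAULT_INDEX_LIST, "odd")


@dataclass
class PupilGrid:
    """Cartesian sampling of the back pupil in spatial frequency.

    kx, ky are in cycles per um; the pupil support is the open disk
    kx**2 + ky**2 < cutoff**2 with cutoff = NA / lambda. DC sits at sample
    ``floor(N/2)`` along each axis, so the mask is point-symmetric about the
    grid center for both even and odd N.
    """

    n: int
    dk: float
    cutoff: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("grid side must be >= 2")
        if self.dk <= 0 or self.cutoff <= 0:
            raise ValueError("dk and cutoff must be positive")
        c = np.arange(self.n) - self.n // 2
        self.kx = (c * self.dk)[None, :] * np.ones((self.n, 1))
        self.ky = (c * self.dk)[:, None] * np.ones((1, self.n))
        self.mask = self.kx**2 + self.ky**2 < self.cutoff**2
        if not self.mask.any():
            raise ValueError(
                "empty pupil mask: cutoff smaller than one k-space sample"
            )

    @classmethod
    def for_pupil(cls, n: int, na: float, wavelength: float, dk: float) -> "PupilGrid":
        return cls(n=n, dk=dk, cutoff=na / wavelength)

    @property
    def rho(self) -> np.ndarray:
        """Radial pupil coordinate normalized to 1 at the cutoff."""
        return np.sqrt(self.kx**2 + self.ky**2) / self.cutoff

    @property
    def theta(self) -> np.ndarray:
        return np.arctan2(self.ky, self.kx)


@dataclass
class WavefrontMap:
    """Phase aberration in um sampled on a pupil grid (meaningful on the mask)."""

    phase: np.ndarray
    grid: PupilGrid

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != (self.grid.n, self.grid.n):
            raise ValueError("phase shape does not match grid")
        if not np.all(np.isfinite(self.phase[self.grid.mask])):
            raise ValueError("non-finite phase on the pupil mask")

    def rms(self) -> float:
        """RMS of the phase over the pupil mask, in um."""
        return float(np.sqrt(np.mean(self.phase[self.grid.mask] ** 2)))


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def evaluate_mode(mode: ZernikeMode | int, grid: PupilGrid) -> WavefrontMap:
    """Sample one Zernike mode on the pupil, unit-RMS normalized.

    With Noll normalization the disk average of Z**2 is 1, so a coefficient of
    1 um produces a wavefront of 1 um RMS. Values outside the mask are 0.
    """
    if isinstance(mode, (int, np.integer)):
        mode = noll_to_nm(mode)
    rho, theta = grid.rho, grid.theta
    r = _radial_poly(mode.n, abs(mode.m), rho)
    if mode.m == 0:
        z = math.sqrt(mode.n + 1) * r
    elif mode.m > 0:
        z = math.sqrt(2 * (mode.n + 1)) * r * np.cos(mode.m * theta)
    else:
        z = math.sqrt(2 * (mode.n + 1)) * r * np.sin(-mode.m * theta)
    return WavefrontMap(np.where(grid.mask, z, 0.0), grid)


def synthesize_wavefront(a: AmplitudeVector, grid: PupilGrid) -> WavefrontMap:
    """phi = sum_i a_i Z_i sampled on the pupil mask."""
    phase = np.zeros((grid.n, grid.n))
    for j, amp in zip(a.index_list, a.values):
        if amp != 0.0:
            phase += amp * evaluate_mode(j, grid).phase
    return WavefrontMap(phase, grid)


def _design_matrix(grid: PupilGrid, index_list: Sequence[int]) -> np.ndarray:
    return np.column_stack(
        [evaluate_mode(j, grid).phase[grid.mask] for j in index_list]
    )


def decompose_wavefront(
    w: WavefrontMap, index_list: Sequence[int] = DEFAULT_INDEX_LIST
) -> AmplitudeVector:
    """Least-squares projection of a phase map onto Zernike modes.

    Solves ``min_a || phi_mask - B a ||`` over the masked samples (minimum-norm
    solution if the design is rank deficient on a tiny mask). Round-trips
    :func:`synthesize_wavefront` up to discretization error.
    """
    index_list = tuple(int(i) for i in index_list)
    b = _design_matrix(w.grid, index_list)
    if b.shape[0] < b.shape[1]:
        raise ValueError(
            f"pupil mask has {b.shape[0]} samples, fewer than "
            f"{b.shape[1]} requested modes"
        )
    coef, *_ = np.linalg.lstsq(b, w.phase[w.grid.mask], rcond=None)
    return AmplitudeVector(coef, index_list)


def rms_error(
    a_true: AmplitudeVector, a_pred: AmplitudeVector, grid: PupilGrid
) -> float:
    """Wavefront RMSE between two amplitude vectors, in um.

    Reconstructs both wavefronts on the pupil and takes the RMS of their
    difference over the mask. Under unit-RMS modes this equals
    ``sqrt(sum (a_true - a_pred)**2)`` up to discretization error.
    """
    if a_true.index_list != a_pred.index_list:
        raise ValueError("mismatched index lists")
    return synthesize_wavefront(a_true - a_pred, grid).rms()
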