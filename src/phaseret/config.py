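"""Microscope configuration: optics, sampling, bead and noise parameters.

Two named presets ship with the package, matching the setups the model was
designed around:

* ``point_scanning`` — confocal-style point-scanning system, NA 1.4 oil
  immersion (n0 = 1.518), lambda = 0.755 um, 32x32x32 voxels at 30 nm
  isotropic, 80 nm gold bead.
* ``widefield`` — epifluorescence system, NA 1.1 water immersion (n0 = 1.33),
  lambda = 0.488 um, 50x50x50 voxels at 86 nm lateral / 100 nm axial,
  200 nm fluorescent bead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition noise model.

    poisson_photons_at_peak
        Expected photon count at the brightest voxel; shot noise is Poisson
        at that scaling. Set to 0 to disable the Poisson step.
    gaussian_sigma
        Standard deviation of additive read noise, as a fraction of the peak.
    """

    poisson_photons_at_peak: float = 300.0
    gaussian_sigma: float = 0.02

    def __post_init__(self):
        if self.poisson_photons_at_peak < 0 or self.gaussian_sigma < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class MicroscopeConfig:
    """Full optical + sampling description of one imaging setup.

    Lengths are in micrometres. ``shape`` is (nz, ny, nx) in z-y-x order,
    matching the axis order of simulated stacks.
    """

    na: float
    wavelength: float
    immersion_index: float
    lateral_voxel: float
    axial_voxel: float
    shape: tuple[int, int, int]
    bead_diameter: float = 0.0
    noise: NoiseParams = NoiseParams()
    oversample_factor: int = 2
    name: str = ""

    def __post_init__(self):
        if not 0 < self.na < self.immersion_index:
            raise ValueError(
                f"need 0 < NA < n0 for a propagating pupil; got NA={self.na}, "
                f"n0={self.immersion_index}"
            )
        if self.wavelength <= 0 or self.lateral_voxel <= 0 or self.axial_voxel <= 0:
            raise ValueError("wavelength and voxel sizes must be positive")
        nyquist = self.wavelength / (2 * self.na)
        if self.lateral_voxel >= nyquist:
            raise ValueError(
                f"lateral voxel {self.lateral_voxel} um aliases the pupil: "
                f"must be < lambda/(2 NA) = {nyquist:.4f} um"
            )
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers (nz, ny, nx)")
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")
        if self.bead_diameter < 0:
            raise ValueError("bead_diameter must be >= 0")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def nz(self) -> int:
        return self.shape[0]

    @property
    def cutoff(self) -> float:
        """Pupil cutoff NA/lambda in cycles per um."""
        return self.na / self.wavelength

    def z_offsets(self):
        """Plane z positions in um, step = axial voxel, centered on focus."""
        import numpy as np

        nz = self.nz
        return (np.arange(nz) - (nz - 1) / 2.0) * self.axial_voxel

    def replace(self, **kwargs) -> "MicroscopeConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MicroscopeConfig":
        d = dict(d)
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseParams(**d["noise"])
        d["shape"] = tuple(d["shape"])
        return cls(**d)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "MicroscopeConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        """Short stable hash used to tag outputs and checkpoints."""
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


POINT_SCANNING = MicroscopeConfig(
    na=1.4,
    wavelength=0.755,
    immersion_index=1.518,
    lateral_voxel=0.030,
    axial_voxel=0.030,
    shape=(32, 32, 32),
    bead_diameter=0.080,
    name="point_scanning",
)

WIDEFIELD = MicroscopeConfig(
    na=1.1,
    wavelength=0.488,
    immersion_index=1.33,
    lateral_voxel=0.086,
    axial_voxel=0.100,
    shape=(50, 50, 50),
    bead_diameter=0.200,
    name="widefield",
)

# Down-scaled point-scanning-like setup used for fast CPU training
# demonstrations and tests: 16^3 voxels at 60 nm isotropic keeps roughly the
# same physical field of view as the 32^3/30 nm preset while shrinking the
# network input eightfold.
POINT_SCANNING_SMALL = MicroscopeConfig(
    na=1.4,
    wavelength=0.755,
    immersion_index=1.518,
    lateral_voxel=0.060,
    axial_voxel=0.060,
    shape=(16, 16, 16),
    bead_diameter=0.080,
    name="point_scanning_small",
)

NAMED_CONFIGS = {
    "point_scanning": POINT_SCANNING,
    "widefield": WIDEFIELD,
    "point_scanning_small": POINT_SCANNING_SMALL,
}


def get_config(name: str) -> MicroscopeConfig:
    """Look up a shipped configuration by name."""
    try:
        return NAMED_CONFIGS[name]
    except KeyError:
        raise KeyError(
            f"unknown config {name!r}; available: {sorted(NAMED_CONFIGS)}"
        ) from None
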