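"""File I/O: multi-page TIFF stacks, amplitude CSV tables, config sidecars.

Stacks are written as 32-bit float multi-page TIFF, one z-plane per page in
order of increasing z, with voxel sizes in the ImageJ-style resolution
metadata and the full microscope configuration in a JSON sidecar next to the
file (``<name>.tif`` + ``<name>.tif.json``).

Amplitude tables are long-format CSV with columns ``psf_id, noll_index,
amplitude_um``, preceded by a ``#`` header comment recording the package
version and the config hash.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import MicroscopeConfig
from .psf import PSFStack
from .zernike import AmplitudeVector

__all__ = [
    "write_stack",
    "read_stack",
    "write_amplitudes_csv",
    "read_amplitudes_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: PSFStack, path: str | Path) -> None:
    """Write a PSF stack as float32 multi-page TIFF plus a config sidecar."""
    path = Path(path)
    dx, dz = stack.config.lateral_voxel, stack.config.axial_voxel
    tifffile.imwrite(
        path,
        stack.intensity.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dx),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    _sidecar(path).write_text(json.dumps(stack.config.to_dict(), indent=2))


def read_stack(path: str | Path, config: MicroscopeConfig | None = None) -> PSFStack:
    """Read a stack written by :func:`write_stack`.

    The microscope configuration is taken from the JSON sidecar unless given
    explicitly; a bare TIFF without either raises.
    """
    path = Path(path)
    intensity = np.asarray(tifffile.imread(path), dtype=float)
    if intensity.ndim == 2:
        intensity = intensity[None]
    if config is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no config sidecar {sidecar.name}; pass config= explicitly"
            )
        config = MicroscopeConfig.from_dict(json.loads(sidecar.read_text()))
    return PSFStack(np.maximum(intensity, 0.0), config)


def _header_comment(config: MicroscopeConfig | None) -> str:
    from . import __version__

    chash = config.config_hash() if config is not None else "none"
    return f"# phaseret {__version__}, config {chash}\n"


def write_amplitudes_csv(
    amplitudes: AmplitudeVector | Mapping[str, AmplitudeVector],
    path: str | Path,
    config: MicroscopeConfig | None = None,
) -> None:
    """Write one or many amplitude vectors as a long-format CSV table."""
    if isinstance(amplitudes, AmplitudeVector):
        amplitudes = {"psf_0": amplitudes}
    rows = [
        {"psf_id": pid, "noll_index": j, "amplitude_um": v}
        for pid, a in amplitudes.items()
        for j, v in zip(a.index_list, a.values)
    ]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_amplitudes_csv(path: str | Path) -> dict[str, AmplitudeVector]:
    """Read a long-format amplitude table into per-PSF amplitude vectors."""
    df = pd.read_csv(path, comment="#")
    out: dict[str, AmplitudeVector] = {}
    for pid, group in df.groupby("psf_id", sort=False):
        group = group.sort_values("noll_index")
        out[str(pid)] = AmplitudeVector(
            group["amplitude_um"].to_numpy(),
            tuple(int(j) for j in group["noll_index"]),
        )
    return out
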