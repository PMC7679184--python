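"""Seeded, unbounded stream of (amplitudes, PSF) training pairs.

Training data is generated on the fly rather than materialized as a fixed
dataset: every pair is an independent draw, so the network never sees the
same image twice and cannot overfit a finite training set. Amplitudes are
sampled i.i.d. uniform on [-0.075, 0.075] um per mode (the experimentally
expected range); the corresponding stack runs through the full image
formation chain (scalar PSF, bead convolution, noise).

For the 11 default modes this amplitude distribution gives input wavefronts
with a median RMS of ~0.14 um — the reference scale against which retrieval
errors are judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .config import MicroscopeConfig
from .psf import PSFStack, simulate_bead_image, standardize
from .zernike import AmplitudeVector, DEFAULT_INDEX_LIST

__all__ = [
    "TrainingPair",
    "sample_amplitudes",
    "pair_stream",
    "freeze_validation_set",
    "DEFAULT_AMPLITUDE_RANGE",
]

#: Half-width of the uniform per-mode amplitude distribution, in um.
DEFAULT_AMPLITUDE_RANGE = 0.075


@dataclass
class TrainingPair:
    """One supervised example: ground-truth amplitudes and the bead image."""

    amplitudes: AmplitudeVector
    stack: PSFStack

    def network_input(self) -> np.ndarray:
        """Standardized (zero-mean, unit-variance) stack for the CNN."""
        return standardize(self.stack)


def sample_amplitudes(
    rng: np.random.Generator | int | None,
    range_um: float = DEFAULT_AMPLITUDE_RANGE,
    index_list: Sequence[int] = DEFAULT_INDEX_LIST,
    active_indices: Sequence[int] | None = None,
) -> AmplitudeVector:
    """Draw one amplitude vector, i.i.d. uniform on [-range_um, +range_um].

    ``active_indices`` restricts the draw to a subset of modes (the rest stay
    exactly 0), used for single-mode and parity-class experiments.
    """
    if range_um <= 0:
        raise ValueError("amplitude range must be positive")
    index_list = tuple(int(i) for i in index_list)
    if not index_list:
        raise ValueError("empty index list")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = rng.uniform(-range_um, range_um, len(index_list))
    if active_indices is not None:
        active = set(int(i) for i in active_indices)
        unknown = active - set(index_list)
        if unknown:
            raise ValueError(f"active indices {sorted(unknown)} not in index list")
        values = np.where([j in active for j in index_list], values, 0.0)
    return AmplitudeVector(values, index_list)


def pair_stream(
    config: MicroscopeConfig,
    range_um: float = DEFAULT_AMPLITUDE_RANGE,
    index_list: Sequence[int] = DEFAULT_INDEX_LIST,
    seed: int | None = 0,
    active_indices: Sequence[int] | None = None,
    noisy: bool = True,
) -> Iterator[TrainingPair]:
    """Unbounded generator of independent training pairs.

    Fully reproducible from ``seed``; each pair consumes a fixed amount of
    generator state, so the first n pairs are identical across runs.
    """
    rng = np.random.default_rng(seed)
    while True:
        a = sample_amplitudes(rng, range_um, index_list, active_indices)
        stack = simulate_bead_image(a, config, rng=rng, noisy=noisy)
        yield TrainingPair(a, stack)


def freeze_validation_set(
    config: MicroscopeConfig,
    n: int = 200,
    seed: int = 123,
    range_um: float = DEFAULT_AMPLITUDE_RANGE,
    index_list: Sequence[int] = DEFAULT_INDEX_LIST,
    active_indices: Sequence[int] | None = None,
    noisy: bool = True,
) -> list[TrainingPair]:
    """Materialize a fixed held-out set (default 200 pairs, dedicated seed).

    Validation aberrations follow the same mixed-mode uniform distribution as
    training unless restricted via ``active_indices``.
    """
    if n < 1:
        raise ValueError("need at least one validation pair")
    stream = pair_stream(
        config, range_um, index_list, seed=seed,
        active_indices=active_indices, noisy=noisy,
    )
    return [next(stream) for _ in range(n)]
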