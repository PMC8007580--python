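"""Synthetic 3D phantoms with ordinal striatal ground truth.

Each phantom volume emulates the qualitative appearance of a spatially
normalised DaTSCAN SPECT study: two ellipsoidal high-uptake regions (the
"striata") on a uniform low-uptake background, with the regional signal
decreasing monotonically with the ordinal class —

* class 0 (no alteration): both ellipsoids at full amplitude;
* class 1 (slight alteration): exactly one side reduced, the affected side
  chosen at random per image;
* class 2 (severe alteration): both sides reduced.

Default intensities follow typical DaTSCAN count statistics: background 20,
specific striatal amplitude 40 above background (a binding ratio around 3),
a 40% amplitude loss per affected side, additive Gaussian noise of sd 8
(roughly Poisson at these counts), and a multiplicative per-image, per-side
binding variability of sd 0.10 reflecting inter-subject uptake differences
and physiological asymmetry — the component that makes the "slight" class
genuinely confusable with its neighbours.  A local-mean smoothing of radius
1 emulates scanner resolution.

The generator returns the volumes, the labels and the ground-truth signal
mask (the union of the two ellipsoids), and is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from ordivox.volumes import OrdinalDataset, Volume, assemble_dataset

__all__ = ["PhantomConfig", "generate_phantom_dataset", "phantom_dataset"]


@dataclass
class PhantomConfig:
    """Geometry, intensities and sample sizes of the phantom study."""

    dims: tuple[int, int, int] = (24, 28, 20)
    class_counts: tuple[int, int, int] = (80, 25, 30)
    centers: tuple[tuple[float, float, float], ...] = ((11.5, 9.0, 9.5), (11.5, 18.0, 9.5))
    semi_axes: tuple[float, float, float] = (4.0, 3.0, 5.0)
    background_mean: float = 20.0
    signal_amplitude: float = 40.0  # mu_s - mu_b at full binding
    reduction_fraction: float = 0.4  # delta as a fraction of the amplitude
    noise_sd: float = 8.0
    binding_variability: float = 0.10  # sd of the per-image, per-side gain
    smoothing_radius: int = 1

    def __post_init__(self) -> None:
        R, C, Z = self.dims
        if min(self.dims) < 1:
            raise ValueError("dims must be positive")
        if any(n < 1 for n in self.class_counts):
            raise ValueError("every class needs at least one image")
        delta = self.reduction_fraction * self.signal_amplitude
        if not self.background_mean < self.background_mean + self.signal_amplitude - delta:
            raise ValueError("reduced signal must stay above background")
        if not 0 < self.reduction_fraction < 1:
            raise ValueError("reduction fraction must lie in (0, 1)")
        for (r0, c0, z0) in self.centers:
            a, b, c = self.semi_axes
            if not (a <= r0 <= R - 1 - a and b <= c0 <= C - 1 - b and c <= z0 <= Z - 1 - c):
                raise ValueError(
                    f"ellipsoid at {(r0, c0, z0)} with semi-axes {self.semi_axes} "
                    f"does not fit inside dims {self.dims}"
                )

    @property
    def n_images(self) -> int:
        return int(sum(self.class_counts))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))


def _ellipsoid_mask(
    dims: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    R, C, Z = dims
    r, c, z = np.meshgrid(
        np.arange(R), np.arange(C), np.arange(Z), indexing="ij"
    )
    a, b, cc = semi_axes
    r0, c0, z0 = center
    return ((r - r0) / a) ** 2 + ((c - c0) / b) ** 2 + ((z - z0) / cc) ** 2 <= 1.0


def generate_phantom_dataset(
    config: PhantomConfig | None = None, seed: int | None = None
) -> tuple[list[Volume], np.ndarray, Volume]:
    """Generate labelled phantom volumes with a ground-truth signal mask.

    Returns ``(volumes, labels, mask)`` where ``mask`` is a binary volume
    marking the union of the two ellipsoids.  Class order within the list is
    all class-0 images, then class 1, then class 2.  Deterministic given
    ``seed``.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    side_masks = [
        _ellipsoid_mask(config.dims, ctr, config.semi_axes) for ctr in config.centers
    ]
    n_sides = len(side_masks)

    volumes: list[Volume] = []
    labels: list[int] = []
    for label, n in enumerate(config.class_counts):
        for _ in range(n):
            if label == 0:
                reduced = np.zeros(n_sides, dtype=bool)
            elif label == 1:
                reduced = np.zeros(n_sides, dtype=bool)
                reduced[rng.integers(0, n_sides)] = True
            else:
                reduced = np.ones(n_sides, dtype=bool)
            data = np.full(config.dims, config.background_mean)
            for s, mask in enumerate(side_masks):
                gain = max(rng.normal(1.0, config.binding_variability), 0.05)
                level = 1.0 - (config.reduction_fraction if reduced[s] else 0.0)
                data[mask] += config.signal_amplitude * gain * level
            if config.noise_sd > 0:
                data = data + rng.normal(0.0, config.noise_sd, size=config.dims)
            if config.smoothing_radius > 0:
                data = uniform_filter(
                    data, size=2 * config.smoothing_radius + 1, mode="nearest"
                )
            volumes.append(Volume(np.clip(data, 0.0, None)))
            labels.append(label)

    mask = Volume(np.logical_or.reduce(side_masks).astype(float))
    return volumes, np.asarray(labels, dtype=int), mask


def phantom_dataset(
    config: PhantomConfig | None = None, seed: int | None = None
) -> tuple[OrdinalDataset, np.ndarray]:
    """Convenience: phantom as an :class:`OrdinalDataset` plus the flattened
    feature indices of the ground-truth signal voxels."""
    from ordivox.volumes import flatten

    volumes, labels, mask = generate_phantom_dataset(config, seed)
    dataset = assemble_dataset(volumes, labels)
    signal = np.flatnonzero(flatten(mask) > 0)
    return dataset, signal
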