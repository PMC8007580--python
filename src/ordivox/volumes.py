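"""3D volumes, the canonical voxel flattening, and labelled ordinal datasets.

Every downstream stage (voxel ranking, macrovoxel pooling, classification)
works on 1D feature vectors; this module owns the bijection between a 3D
coordinate ``(row, col, layer)`` and its feature index.  The flattening order
is fixed, 0-based, layer-outermost::

    index = layer * R * C + row * C + col

for a volume of ``R`` rows, ``C`` columns and ``Z`` layers.  Any fixed
bijection would do for the methods; this one is documented and stable so that
feature indices, macrovoxel members and exported masks always agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "OrdinalDataset",
    "linear_index",
    "flatten",
    "unflatten",
    "read_volume",
    "write_volume",
    "assemble_dataset",
    "read_dataset_csv",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class Volume:
    """A 3D non-negative intensity grid with dims ``(rows, cols, layers)``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={data.ndim}")
        if data.size == 0:
            raise ValueError("volume must contain at least one voxel")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        object.__setattr__(self, "data", data)

    @property
    def dims(self) -> tuple[int, int, int]:
        """(rows, cols, layers)."""
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume):
            return NotImplemented
        return self.dims == other.dims and np.array_equal(self.data, other.data)


@dataclass
class OrdinalDataset:
    """N flattened feature vectors with ordinal labels in ``{0..L-1}``.

    Parameters
    ----------
    X : (N, S) array of feature values.
    y : (N,) integer labels.
    L : number of ordered classes.
    class_priors : (L,) empirical class frequencies (count / N).
    dims : original volume dims, if the features are flattened voxels.
    feature_indices : (S,) map from column to the feature's index in the full
        (flattened-volume) feature space; ``arange(S)`` when no subset has
        been taken.
    """

    X: np.ndarray
    y: np.ndarray
    L: int
    class_priors: np.ndarray = field(default=None)  # type: ignore[assignment]
    dims: tuple[int, int, int] | None = None
    feature_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2D (N, S) matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= self.L):
            raise ValueError(f"labels must lie in 0..{self.L - 1}")
        if self.class_priors is None:
            counts = np.bincount(self.y, minlength=self.L).astype(float)
            self.class_priors = counts / max(len(self.y), 1)
        else:
            self.class_priors = np.asarray(self.class_priors, dtype=float)
        if self.feature_indices is None:
            self.feature_indices = np.arange(self.X.shape[1])
        else:
            self.feature_indices = np.asarray(self.feature_indices, dtype=int)
            if self.feature_indices.shape != (self.X.shape[1],):
                raise ValueError("feature_indices must have one entry per column")

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.L)

    def subset(self, rows: np.ndarray) -> "OrdinalDataset":
        """Dataset restricted to the given pattern indices (priors recomputed)."""
        rows = np.asarray(rows, dtype=int)
        return OrdinalDataset(
            X=self.X[rows],
            y=self.y[rows],
            L=self.L,
            dims=self.dims,
            feature_indices=self.feature_indices.copy(),
        )

    def select_features(self, columns: Sequence[int]) -> "OrdinalDataset":
        """Dataset restricted to the given feature columns.

        ``feature_indices`` keeps tracking the original (full-volume) feature
        ids, so macrovoxel geometry remains available after reduction.
        """
        cols = np.asarray(list(columns), dtype=int)
        return OrdinalDataset(
            X=self.X[:, cols],
            y=self.y.copy(),
            L=self.L,
            class_priors=self.class_priors.copy(),
            dims=self.dims,
            feature_indices=self.feature_indices[cols],
        )

    def column_of(self, feature_index: int) -> int:
        """Column holding the given original feature index (KeyError if absent)."""
        hits = np.flatnonzero(self.feature_indices == feature_index)
        if hits.size == 0:
            raise KeyError(f"feature index {feature_index} not present in dataset")
        return int(hits[0])


def linear_index(
    coord: tuple[int, int, int], dims: tuple[int, int, int]
) -> int:
    """Map a 0-based ``(row, col, layer)`` coordinate to its feature index.

    ``index = layer * R * C + row * C + col`` — a bijection onto
    ``0 .. R*C*Z - 1``.
    """
    row, col, layer = (int(v) for v in coord)
    R, C, Z = (int(v) for v in dims)
    if not (0 <= row < R and 0 <= col < C and 0 <= layer < Z):
        raise IndexError(f"coordinate {coord} out of bounds for dims {dims}")
    return layer * R * C + row * C + col


def flatten(volume: Volume) -> np.ndarray:
    """Reshape a volume to a 1D feature vector in the canonical order."""
    # (Z, R, C) contiguous order == layer-outermost, then row, then column.
    return np.ascontiguousarray(np.moveaxis(volume.data, 2, 0)).ravel()


def unflatten(vector: np.ndarray, dims: tuple[int, int, int]) -> Volume:
    """Inverse of :func:`flatten`."""
    vector = np.asarray(vector, dtype=float)
    R, C, Z = (int(v) for v in dims)
    if vector.ndim != 1 or vector.size != R * C * Z:
        raise ValueError(
            f"vector of length {vector.size} does not match dims {dims}"
        )
    return Volume(np.moveaxis(vector.reshape(Z, R, C), 0, 2))


def read_volume(path: str | Path) -> Volume:
    """Load a NIfTI volume. No resampling or registration is applied."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except (nib.filebasedimages.ImageFileError, OSError) as exc:
        raise ValueError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with an identity affine."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def assemble_dataset(
    volumes: Sequence[Volume], labels: Sequence[int], L: int | None = None
) -> OrdinalDataset:
    """Stack flattened volumes into an :class:`OrdinalDataset`.

    Class priors are the empirical label frequencies; a warning is issued for
    classes in ``0..L-1`` with no patterns.
    """
    if len(volumes) != len(labels):
        raise ValueError("need exactly one label per volume")
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    dims = volumes[0].dims
    for i, v in enumerate(volumes):
        if v.dims != dims:
            raise ValueError(f"volume {i} has dims {v.dims}, expected {dims}")
    y = np.asarray(labels, dtype=int)
    if y.min() < 0:
        raise ValueError("labels must be non-negative integers")
    if L is None:
        L = int(y.max()) + 1
    if y.max() >= L:
        raise ValueError(f"label {y.max()} outside 0..{L - 1}")
    missing = [l for l in range(L) if not np.any(y == l)]
    if missing:
        warnings.warn(f"classes {missing} have no patterns", stacklevel=2)
    X = np.stack([flatten(v) for v in volumes])
    return OrdinalDataset(X=X, y=y, L=L, dims=dims)


def write_dataset_csv(dataset: OrdinalDataset, path: str | Path) -> None:
    """One row per image, one column per voxel (``v<index>``), final column ``label``."""
    cols = {f"v{idx}": dataset.X[:, j] for j, idx in enumerate(dataset.feature_indices)}
    frame = pd.DataFrame(cols)
    frame["label"] = dataset.y
    frame.to_csv(path, index=False)


def read_dataset_csv(
    path: str | Path, dims: tuple[int, int, int] | None = None
) -> OrdinalDataset:
    """Read the CSV layout written by :func:`write_dataset_csv`."""
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ValueError("dataset CSV must have a final 'label' column")
    y = frame.pop("label").to_numpy(dtype=int)
    feature_indices = np.array([int(c.lstrip("v")) for c in frame.columns])
    return OrdinalDataset(
        X=frame.to_numpy(dtype=float),
        y=y,
        L=int(y.max()) + 1,
        dims=dims,
        feature_indices=feature_indices,
    )
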