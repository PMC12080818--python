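"""In-memory containers for hyperspectral cubes and binary change masks.

Axis convention throughout the package: ``(row, col, band)``, 0-based.
Band-exclusion lists at the user-facing boundary are 1-based to match the
``B001 ... B242`` naming used for sensor band identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class HyperCube:
    """A real-valued hyperspectral cube indexed ``(row, col, band)``.

    Parameters
    ----------
    values
        3-D array of radiance/reflectance values; coerced to ``float64``.
        Units are treated as opaque: integer digital numbers are not
        rescaled on load.
    band_labels
        Optional strictly increasing tuple of original 1-based band
        identifiers retained after band exclusion.  ``None`` means the
        cube still carries its full original band set.
    """

    values: np.ndarray
    band_labels: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(
                f"HyperCube requires a 3-D (row, col, band) array, got ndim={values.ndim}"
            )
        if min(values.shape) < 1:
            raise ValueError(f"HyperCube axes must be nonempty, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("HyperCube values must be finite (no NaN/Inf)")
        object.__setattr__(self, "values", values)
        if self.band_labels is not None:
            labels = tuple(int(b) for b in self.band_labels)
            if len(labels) != values.shape[2]:
                raise ValueError(
                    f"band_labels has length {len(labels)} but cube has {values.shape[2]} bands"
                )
            if any(b2 <= b1 for b1, b2 in zip(labels, labels[1:])):
                raise ValueError("band_labels must be strictly increasing")
            object.__setattr__(self, "band_labels", labels)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def bands(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HyperCube):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.band_labels == other.band_labels
        )


@dataclass(frozen=True)
class ChangeMask:
    """Binary change labels on the scene grid: 1 = changed, 0 = unchanged."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"ChangeMask requires a 2-D array, got ndim={labels.ndim}")
        binary = (labels != 0).astype(np.uint8)
        object.__setattr__(self, "labels", binary)

    @property
    def rows(self) -> int:
        return self.labels.shape[0]

    @property
    def cols(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_changed(self) -> int:
        return int(self.labels.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChangeMask):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)
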