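"""Mirror boundary filling so 3x3 windows exist at every original pixel.

Each band plane is enlarged by one pixel on every side using edge-inclusive
symmetric reflection: for pad width 1 the new border duplicates the nearest
interior row/column and corners duplicate the nearest interior corner.  This
convention is well defined even on 1-pixel-wide scenes, where edge-exclusive
reflection would index out of range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import HyperCube

__all__ = ["PaddedCube", "pad_mirror", "unpad"]


@dataclass(frozen=True)
class PaddedCube:
    """A ``(rows+2, cols+2, bands)`` cube whose interior equals its source.

    ``origin_offset`` maps original pixel ``(r, c)`` to padded ``(r+1, c+1)``.
    """

    values: np.ndarray
    origin_offset: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"PaddedCube requires a 3-D array, got ndim={values.ndim}")
        if values.shape[0] < 3 or values.shape[1] < 3:
            raise ValueError(f"padded planes must be at least 3x3, got {values.shape}")
        object.__setattr__(self, "values", values)

    @property
    def interior(self) -> np.ndarray:
        return self.values[1:-1, 1:-1, :]


def pad_mirror(cube: HyperCube | np.ndarray) -> PaddedCube:
    """Mirror-fill every band plane with a 1-pixel edge-inclusive border."""
    values = cube.values if isinstance(cube, HyperCube) else np.asarray(cube, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError(f"pad_mirror requires a 3-D (row, col, band) array, got ndim={values.ndim}")
    padded = np.pad(values, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
    return PaddedCube(padded)


def unpad(padded: PaddedCube | np.ndarray) -> np.ndarray:
    """Strip the 1-pixel border, recovering the original cube exactly."""
    values = padded.values if isinstance(padded, PaddedCube) else np.asarray(padded)
    return values[1:-1, 1:-1, :].copy()
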