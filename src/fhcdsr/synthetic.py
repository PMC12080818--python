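"""Seeded generator of bi-temporal hyperspectral scenes with known change.

The generator emulates the structure of agricultural change-detection
benchmarks: a grid partitioned into contiguous class patches (seeded
Voronoi cells), smooth nonnegative per-class spectral signatures (sums of
Gaussian bumps over the band axis, giving vegetation-like correlated
bands), a planted set of spatially contiguous change blobs where the class
switches between dates, additive Gaussian noise drawn independently per
date, and an optional global radiometric gain applied to the T2 date to
model inter-date illumination drift.

Every draw flows from the single spec seed, in a fixed order (signatures,
class layout, change blobs, then the two noise fields), so two specs that
differ only in ``noise_sigma`` share the same scene layout and the same
underlying unit-variance noise pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cube import ChangeMask, HyperCube

__all__ = ["SceneSpec", "generate_scene"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic bi-temporal scene.

    Defaults define the package's standard benchmark scene: a 64x64 grid
    with 40 bands, 4 crop classes in patches of characteristic size 16
    pixels, 10% of pixels switching class at T2, noise at 5% of the mean
    signal amplitude, and a 5% radiometric gain on the second date (so
    detectors must cope with a global intensity drift, not just additive
    noise).
    """

    rows: int = 64
    cols: int = 64
    bands: int = 40
    n_classes: int = 4
    n_bumps: int = 3
    change_fraction: float = 0.10
    region_scale: int = 16
    noise_sigma: float = 0.05
    gain_t2: float = 1.05
    seed: int = 17

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.bands) < 1:
            raise ValueError("rows, cols and bands must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes so change is definable")
        if not 0.0 <= self.change_fraction < 1.0:
            raise ValueError("change_fraction must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.gain_t2 <= 0:
            raise ValueError("gain_t2 must be positive")
        if self.region_scale < 1:
            raise ValueError("region_scale must be a positive pixel count")

    def with_(self, **kwargs) -> "SceneSpec":
        return replace(self, **kwargs)


def _signatures(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """(n_classes, bands) smooth nonnegative class spectra."""
    bands = np.arange(spec.bands, dtype=np.float64)
    sigs = np.full((spec.n_classes, spec.bands), 0.15)
    for k in range(spec.n_classes):
        amps = rng.uniform(0.5, 1.2, spec.n_bumps)
        centers = rng.uniform(0, spec.bands - 1, spec.n_bumps)
        widths = rng.uniform(spec.bands / 12.0, spec.bands / 5.0, spec.n_bumps)
        for a, c, w in zip(amps, centers, widths):
            sigs[k] += a * np.exp(-0.5 * ((bands - c) / w) ** 2)
    return sigs


def _voronoi_classes(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Contiguous class patches: nearest-site labels on a seeded point set."""
    n_sites = max(spec.n_classes, int(round(spec.rows * spec.cols / spec.region_scale**2)))
    sites = np.column_stack(
        [rng.uniform(0, spec.rows, n_sites), rng.uniform(0, spec.cols, n_sites)]
    )
    site_class = np.empty(n_sites, dtype=np.int64)
    site_class[: spec.n_classes] = np.arange(spec.n_classes)  # every class present
    site_class[spec.n_classes :] = rng.integers(0, spec.n_classes, n_sites - spec.n_classes)
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    d2 = ((pix[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    return site_class[np.argmin(d2, axis=1)].reshape(spec.rows, spec.cols)


def _grow_blob(
    rng: np.random.Generator,
    taken: np.ndarray,
    budget: int,
    rows: int,
    cols: int,
) -> np.ndarray:
    """Randomized 4-connected region growth of exactly ``budget`` free pixels."""
    free = np.flatnonzero(~taken.ravel())
    if free.size < budget:
        raise ValueError(
            "change_fraction unreachable with the requested blob geometry; "
            "lower change_fraction or region_scale"
        )
    blob = np.zeros_like(taken)
    seed_flat = int(free[rng.integers(free.size)])
    frontier = [divmod(seed_flat, cols)]
    count = 0
    while count < budget:
        if not frontier:
            # blob boxed in by existing blobs: restart growth from a free pixel
            remaining = np.flatnonzero(~(taken | blob).ravel())
            frontier = [divmod(int(remaining[rng.integers(remaining.size)]), cols)]
        r, c = frontier.pop(int(rng.integers(len(frontier))))
        if taken[r, c] or blob[r, c]:
            continue
        blob[r, c] = True
        count += 1
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < rows and 0 <= nc < cols and not (taken[nr, nc] or blob[nr, nc]):
                frontier.append((nr, nc))
    return blob


def generate_scene(spec: SceneSpec) -> tuple[HyperCube, HyperCube, ChangeMask]:
    """Generate (T1 cube, T2 cube, truth mask), fully reproducible from seed.

    The truth mask marks exactly the pixels whose class assignment differs
    between the two dates: ``floor(change_fraction * rows * cols)`` pixels,
    grown as contiguous blobs, each blob's classes shifted by a nonzero
    offset so every pixel inside it genuinely switches class.
    """
    rng = np.random.default_rng(spec.seed)
    sigs = _signatures(rng, spec)
    class_t1 = _voronoi_classes(rng, spec)

    n_pixels = spec.rows * spec.cols
    target = int(np.floor(spec.change_fraction * n_pixels))
    class_t2 = class_t1.copy()
    if target > 0:
        n_blobs = max(1, int(round(target / spec.region_scale**2)))
        budgets = np.full(n_blobs, target // n_blobs)
        budgets[: target % n_blobs] += 1
        taken = np.zeros((spec.rows, spec.cols), dtype=bool)
        for budget in budgets:
            blob = _grow_blob(rng, taken, int(budget), spec.rows, spec.cols)
            offset = int(rng.integers(1, spec.n_classes))
            class_t2[blob] = (class_t1[blob] + offset) % spec.n_classes
            taken |= blob
    truth = ChangeMask((class_t2 != class_t1).astype(np.uint8))

    amp = float(sigs.mean())
    eps1 = rng.standard_normal((spec.rows, spec.cols, spec.bands))
    eps2 = rng.standard_normal((spec.rows, spec.cols, spec.bands))
    t1 = sigs[class_t1] + spec.noise_sigma * amp * eps1
    t2 = spec.gain_t2 * (sigs[class_t2] + spec.noise_sigma * amp * eps2)
    return HyperCube(t1), HyperCube(t2), truth
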